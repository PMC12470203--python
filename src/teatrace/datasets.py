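"""Bundled reference survey: a published 12-garden Se-enriched tea study.

The per-site tables of the survey (soil chemistry, organ concentrations,
infusion concentrations, and the printed per-site summary columns —
activation rates, pollution indices, leaching rates, annual risks) are
re-entered here as plain CSVs.  Organ and infusion values are the printed
site means (replicate = 1); printed standard deviations live in the
``*_summary`` tables with n = 3 for summary-statistics ANOVA.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core_data import Study, read_infusion, read_organs, read_soil

__all__ = ["load_reference_study", "load_soil_summary", "load_infusion_summary"]


def _path(name: str):
    return resources.files("teatrace").joinpath("data", name)


def load_reference_study() -> Study:
    """The reference survey as a validated :class:`~teatrace.core_data.Study`."""
    with resources.as_file(_path("survey_soil.csv")) as p:
        soil = read_soil(p)
    with resources.as_file(_path("survey_organs.csv")) as p:
        organs = read_organs(p)
    with resources.as_file(_path("survey_infusion.csv")) as p:
        infusion = read_infusion(p)
    return Study(soil=soil, organs=organs, infusion=infusion)


def load_soil_summary() -> pd.DataFrame:
    """Printed per-site soil summary columns (mean, sd, n = 3 per site)."""
    with resources.as_file(_path("survey_soil_summary.csv")) as p:
        return pd.read_csv(p)


def load_infusion_summary() -> pd.DataFrame:
    """Printed per-site infusion, leaching, and annual-risk columns."""
    with resources.as_file(_path("survey_infusion_summary.csv")) as p:
        return pd.read_csv(p)
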