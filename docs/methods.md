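# Methods

`teatrace` quantifies how cadmium (Cd) moves through the
soil → tea tree → tea infusion continuum in selenium (Se)-enriched tea
gardens, and what that movement implies for the health risk of drinking
the tea. This note records the models, the parameter choices, the
synthetic-data design, and the numerical conventions behind the package.

## Transfer indices

All indices are simple ratios; the care is in the units and the
aggregation order.

* **Pollution index** `Pi = C_soil / S`, with the tea-garden soil Cd
  evaluation standard `S = 0.300 mg/kg`. Verbal classes: `Pi < 0.7`
  safe, `0.7 ≤ Pi ≤ 1.0` below the safety standard, `Pi > 1.0` slight
  pollution. The classing is a labelling helper only; nothing downstream
  branches on it.
* **Activation rate** `AR = available / total × 100` (percent). Soil
  totals are stored in mg/kg and available (DTPA/NaHCO₃-extractable)
  fractions in µg/kg — the printed units of field surveys — so the
  µg→mg factor of 1000 is applied inside this formula and nowhere else.
  The sentinel `AR(1000·x, x) = 100 %` is a unit-conversion test.
* **Enrichment coefficient** `EC = C_organ / C_soil` and **transport
  coefficient** `TC = C_distal / C_proximal` for the sanctioned adjacent
  pairs fibrous root → taproot → main stem → lateral stem, with both old
  and young leaves attached to the lateral stem, and the infusion
  attached to young leaves. Non-adjacent pairs are a contract error;
  the chain telescopes (`∏ TC = C_end / C_start`) and `EC_child /
  EC_parent = TC` exactly, both held as property tests.
* **Leaching rate** `µ = (C_inf × V) / (C_tea × m × 1000) × 100`: the
  mass of the element in one brewed infusion over its mass in the dry
  tea, with the standard assay brew of m = 5 g tea in V = 100 mL of
  boiling water for 10 min.

**Aggregation order.** Indices are computed per replicate, averaged to a
site, then averaged across sites — a *mean of ratios*, not a ratio of
means. On the bundled reference survey this convention reproduces the
published cross-site chain means (0.29, 0.97/0.98, 1.16) to within one
unit of the last printed decimal; rounding of the printed per-site
inputs is the only noise source. Division by zero (a below-LOQ value)
yields NaN with a warning rather than an exception, so one degenerate
field record cannot abort a run.

The published per-site leaching rates are *not* exactly recoverable from
the published infusion and young-leaf concentrations (the tea analysed
was processed green tea and the leaf values are rounded to 2 d.p.), so
pooled checks against the printed leaching and risk columns treat those
printed per-site values as inputs, while the pipeline always computes
leaching forward from its own tables.

## Risk model

Daily dose and average individual annual carcinogenic risk:

    D = I · C · µ / W            R = (1 − exp(−D·q)) / A

with defaults I = 0.0114 kg/d (dry tea intake), W = 70 kg (body
weight), q = 6.1 (mg kg⁻¹ d⁻¹)⁻¹ (Cd carcinogenic intensity
coefficient), A = 70 (averaging constant). W and A are numerically
equal but physically distinct; both are independently configurable and
the model is implemented exactly as written, leaving the interpretation
of A to this note. R is increasing in D, bounded by 1/A, and linear in
dose with relative Taylor error x/2 + x²/12 + O(x³), x = D·q — under
1e-5 for every measured tea-drinking dose (≲ 3·10⁻⁶ mg kg⁻¹ d⁻¹). That
linearity is what lets a printed total-transfer (µ = 1) risk be scaled
by a measured leaching fraction to recover the measured-leaching risk;
`tea_concentration_from_total_risk` inverts the model for exactly this
use, since surveys print risks but not the unrounded tea concentrations
behind them. Two scenarios are always reported: measured leaching and
the worst-case total transfer (µ = 1). Only Cd is risk-modelled; Se
columns pass through to reports. All reference risks sit 2–3 orders of
magnitude below the ICRP maximum acceptable level of 5·10⁻⁵ a⁻¹.

## Statistics layer

* **Pearson matrix**: pairwise-complete r, two-sided p via the t
  transform `t = r√((n−2)/(1−r²))`, stars at 0.05/0.01. No
  multiple-testing correction anywhere, matching standard practice in
  this survey literature.
* **ANOVA + LSD letters**: one-way ANOVA; Fisher's *protected* LSD
  (pairwise t tests on the pooled MSE only when the omnibus F is
  significant — the textbook default, and it suppresses spurious
  letters). The compact letter display uses insert-and-absorb over the
  pairwise-rejection graph, groups in descending-mean order so the
  largest mean reads "a"; the display provably shares a letter exactly
  for the non-rejected pairs, checked exhaustively for ≤ 6 groups. The
  summary-statistics variant rebuilds SS_between/SS_within algebraically
  from (mean, sd, n) and is bit-identical to the raw-data path — that is
  what lets published mean ± sd tables (n = 3) be re-lettered.
* **OLS**: closed-form least squares with r², two-sided slope p, and the
  pointwise confidence band of the conditional mean (narrowest at x̄).
  A test cross-checks it against statsmodels.
* **Two-phase threshold regression**: two *independent* OLS lines below
  and above a breakpoint — a discontinuous two-phase model, not a
  continuity-constrained broken stick, matching how organ-level Se–Cd
  thresholds are reported. Search mode scans the midpoints between
  consecutive sorted unique x (so candidates are well-separated from the
  data), requires ≥ 3 points per segment, minimises total SSE, and
  breaks ties toward the smaller breakpoint. Points with x equal to the
  breakpoint fall in the lower segment. Whether the 2.0 mg/kg fibrous-root
  Se threshold is treated as known or searched is the caller's choice;
  both modes are first-class. Normality screening is delegated to any
  standard routine (e.g. `scipy.stats.shapiro`) and is advisory only.

## Synthetic study generator

The generator emits complete studies with the structure the analysis
assumes: 12 gardens × 3 replicates × 6 organs plus one infusion per
garden. Defaults are the reference survey's printed summary state: soil
Cd uniform on 0.18–0.55 mg/kg, Se on 1.46–5.50 mg/kg; mean activation
rates 20.93 % (Cd) and 2.27 % (Se); fibrous-root EC 3.49 (Cd) and 0.66
(Se); TC chains (0.29, 0.97, 1.16, 0.26, 0.07) for Cd and (0.51, 0.72,
0.63, 2.0, 0.95) for Se; mean leaching 13.33 % (Cd) and 22.62 % (Se);
breakpoint 2.0 mg/kg Se in fibrous roots.

Design choices:

* **Lognormal multiplicative noise** everywhere (positivity guaranteed;
  scatter is CV-like, as in replicate columns of survey tables), driven
  by a single `noise_cv` knob (default 0.05). The real study's
  quadrat/plant/assay variance layers cannot be separated from published
  tables, so one knob stands in for all levels; consequently between-site
  scatter of e.g. leaching is narrower than in the real survey.
* **Se–Cd coupling** is encoded only in the fibrous-root equation, as an
  additive term on the enrichment-coefficient scale:
  `Cd_fr = C_soil,Cd · (EC + s(Se_fr) · (Se_fr − bp)) · noise`, with
  slope s = +0.6 below the breakpoint and −0.6 above. Placing the term
  on the EC scale keeps concentrations structurally positive and makes
  the matched recovery analysis (site-level EC vs fibrous-root Se) free
  of the confounding soil-Cd variance; the slope magnitudes were chosen
  by a power argument — with 12 sites and these noise levels the sign of
  both segments should be recoverable in nearly every seed. Downstream
  organs inherit the antagonism through the chain. The realized mean
  fibrous EC sits somewhat below the nominal 3.49 because the coupling
  term is negative on average over the Se range; ground truth records the
  realized values.
* **Soil covariates** (pH, SOM, TN, TP, AP, AK) are drawn through a
  Gaussian copula so the configured correlation signs with the Cd
  activation scatter hold (pH −0.6, AK +0.6, TN +0.4); their marginal
  magnitudes are plausible for acidic tea-garden topsoils but are free
  parameters, not claims about any particular survey.
* **Ground truth** (latent site concentrations, realized leaching) is
  written next to the data and never read by the pipeline under test.
  Identical config + seed gives byte-identical files.

What passing recovery tests show: the index estimators are unbiased and
tight under the generative model (median chain-TC error < 10 % over 20
seeds; leaching mean within 1 percentage point; breakpoint within one
grid step at site level). What they do not show: robustness to the
heavier-tailed, multi-level noise, detection-limit censoring, and
spatial structure of real field data, none of which the generator
emulates.

## Report layer and problem sizes

`run_pipeline` composes load/simulate → indices → report tables →
correlation → segmented regression, logs record counts per stage, and
writes its resolved configuration next to the outputs. Display rounding
(2 d.p. for ratios/concentrations, 3 significant digits for risks) is
confined to the report tables; `indices.csv` and all computation stay at
full precision, and a test recomputes displayed cells from the unrounded
store. Test-suite problem sizes (12–200 sites, 20–60 point regressions,
20-seed recovery studies) match the desk scale of the survey itself;
everything runs in seconds.

## Known limitations

* Only the single-factor pollution index is implemented — no Nemerow
  composite or Hakanson ecological-risk indices.
* Risk is single-element (Cd), single-pathway (infusion ingestion), with
  fixed intake and body weight; no population Monte-Carlo, no
  non-carcinogenic hazard quotient.
* No automatic outlier exclusion in the threshold regression (published
  practice flags "abnormal" points without stating a rule); callers
  exclude manually.
* The two-phase model is discontinuous by design; a continuity-
  constrained variant is out of scope.
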