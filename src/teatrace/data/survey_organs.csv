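site_id,organ,element,replicate,conc_mg_kg
no.1,fibrous_root,Cd,1,0.62
no.1,taproot,Cd,1,0.30
no.1,main_stem,Cd,1,0.33
no.1,lateral_stem,Cd,1,0.29
no.1,old_leaf,Cd,1,0.05
no.1,young_leaf,Cd,1,0.02
no.2,fibrous_root,Cd,1,1.95
no.2,taproot,Cd,1,0.34
no.2,main_stem,Cd,1,0.27
no.2,lateral_stem,Cd,1,0.20
no.2,old_leaf,Cd,1,0.05
no.2,young_leaf,Cd,1,0.02
no.3,fibrous_root,Cd,1,1.97
no.3,taproot,Cd,1,0.19
no.3,main_stem,Cd,1,0.41
no.3,lateral_stem,Cd,1,0.21
no.3,old_leaf,Cd,1,0.07
no.3,young_leaf,Cd,1,0.02
no.4,fibrous_root,Cd,1,0.80
no.4,taproot,Cd,1,0.29
no.4,main_stem,Cd,1,0.40
no.4,lateral_stem,Cd,1,0.28
no.4,old_leaf,Cd,1,0.06
no.4,young_leaf,Cd,1,0.01
no.5,fibrous_root,Cd,1,1.06
no.5,taproot,Cd,1,0.32
no.5,main_stem,Cd,1,0.20
no.5,lateral_stem,Cd,1,0.17
no.5,old_leaf,Cd,1,0.06
no.5,young_leaf,Cd,1,0.02
no.6,fibrous_root,Cd,1,0.94
no.6,taproot,Cd,1,0.18
no.6,main_stem,Cd,1,0.22
no.6,lateral_stem,Cd,1,0.39
no.6,old_leaf,Cd,1,0.09
no.6,young_leaf,Cd,1,0.04
no.7,fibrous_root,Cd,1,1.29
no.7,taproot,Cd,1,0.40
no.7,main_stem,Cd,1,0.20
no.7,lateral_stem,Cd,1,0.35
no.7,old_leaf,Cd,1,0.10
no.7,young_leaf,Cd,1,0.02
no.8,fibrous_root,Cd,1,1.51
no.8,taproot,Cd,1,0.24
no.8,main_stem,Cd,1,0.20
no.8,lateral_stem,Cd,1,0.39
no.8,old_leaf,Cd,1,0.09
no.8,young_leaf,Cd,1,0.02
no.9,fibrous_root,Cd,1,1.36
no.9,taproot,Cd,1,0.31
no.9,main_stem,Cd,1,0.31
no.9,lateral_stem,Cd,1,0.30
no.9,old_leaf,Cd,1,0.08
no.9,young_leaf,Cd,1,0.02
no.10,fibrous_root,Cd,1,1.22
no.10,taproot,Cd,1,0.39
no.10,main_stem,Cd,1,0.30
no.10,lateral_stem,Cd,1,0.28
no.10,old_leaf,Cd,1,0.05
no.10,young_leaf,Cd,1,0.02
no.11,fibrous_root,Cd,1,0.76
no.11,taproot,Cd,1,0.36
no.11,main_stem,Cd,1,0.22
no.11,lateral_stem,Cd,1,0.18
no.11,old_leaf,Cd,1,0.07
no.11,young_leaf,Cd,1,0.01
no.12,fibrous_root,Cd,1,0.51
no.12,taproot,Cd,1,0.18
no.12,main_stem,Cd,1,0.13
no.12,lateral_stem,Cd,1,0.26
no.12,old_leaf,Cd,1,0.06
no.12,young_leaf,Cd,1,0.01
no.1,fibrous_root,Se,1,0.69
no.1,taproot,Se,1,0.40
no.1,main_stem,Se,1,0.57
no.1,lateral_stem,Se,1,0.22
no.1,old_leaf,Se,1,0.41
no.1,young_leaf,Se,1,0.45
no.2,fibrous_root,Se,1,1.14
no.2,taproot,Se,1,0.36
no.2,main_stem,Se,1,0.45
no.2,lateral_stem,Se,1,0.13
no.2,old_leaf,Se,1,0.72
no.2,young_leaf,Se,1,0.11
no.3,fibrous_root,Se,1,1.00
no.3,taproot,Se,1,0.81
no.3,main_stem,Se,1,0.60
no.3,lateral_stem,Se,1,0.21
no.3,old_leaf,Se,1,0.46
no.3,young_leaf,Se,1,0.10
no.4,fibrous_root,Se,1,2.26
no.4,taproot,Se,1,1.68
no.4,main_stem,Se,1,1.04
no.4,lateral_stem,Se,1,0.22
no.4,old_leaf,Se,1,0.55
no.4,young_leaf,Se,1,0.10
no.5,fibrous_root,Se,1,0.87
no.5,taproot,Se,1,0.48
no.5,main_stem,Se,1,0.62
no.5,lateral_stem,Se,1,0.31
no.5,old_leaf,Se,1,0.33
no.5,young_leaf,Se,1,0.14
no.6,fibrous_root,Se,1,3.85
no.6,taproot,Se,1,2.29
no.6,main_stem,Se,1,0.63
no.6,lateral_stem,Se,1,0.81
no.6,old_leaf,Se,1,2.46
no.6,young_leaf,Se,1,1.38
no.7,fibrous_root,Se,1,2.65
no.7,taproot,Se,1,1.13
no.7,main_stem,Se,1,0.77
no.7,lateral_stem,Se,1,0.59
no.7,old_leaf,Se,1,1.28
no.7,young_leaf,Se,1,0.99
no.8,fibrous_root,Se,1,1.39
no.8,taproot,Se,1,0.64
no.8,main_stem,Se,1,0.46
no.8,lateral_stem,Se,1,0.59
no.8,old_leaf,Se,1,1.06
no.8,young_leaf,Se,1,0.14
no.9,fibrous_root,Se,1,2.64
no.9,taproot,Se,1,1.20
no.9,main_stem,Se,1,0.78
no.9,lateral_stem,Se,1,0.51
no.9,old_leaf,Se,1,0.59
no.9,young_leaf,Se,1,0.69
no.10,fibrous_root,Se,1,1.99
no.10,taproot,Se,1,0.66
no.10,main_stem,Se,1,0.45
no.10,lateral_stem,Se,1,0.48
no.10,old_leaf,Se,1,0.59
no.10,young_leaf,Se,1,0.20
no.11,fibrous_root,Se,1,0.67
no.11,taproot,Se,1,0.42
no.11,main_stem,Se,1,0.55
no.11,lateral_stem,Se,1,0.14
no.11,old_leaf,Se,1,0.48
no.11,young_leaf,Se,1,0.23
no.12,fibrous_root,Se,1,1.33
no.12,taproot,Se,1,0.52
no.12,main_stem,Se,1,0.68
no.12,lateral_stem,Se,1,0.62
no.12,old_leaf,Se,1,0.72
no.12,young_leaf,Se,1,0.09
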