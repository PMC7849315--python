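# Calibrated artifact constants (regenerate with scripts/calibrate_thresholds.py).
# A_thr_* are the relative-auxin (A/maxA) thresholds that trigger the
# meristem -> elongation transition, calibrated so that default steady states
# place the epidermal elongation onset at cell 11 on ammonium and cell 13 on
# nitrate.  DIV_thr / min_div_length set the division trigger; k_d is the
# passive lateral wall permeability coupling the epidermis and cortex files.
A_thr_ammonium: 0.3466
A_thr_nitrate: 0.5015
A_min_transition: 0.05
DIV_thr: 5.0
min_div_length: 7.0
k_d: 30.0
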