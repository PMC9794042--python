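# DERIVED default population model (EE) -- not the originally reported estimates.
# Typical values were produced by patchpk.calibrate.calibrate_theta, which tunes
# the typical-subject simulation to the published weekly geometric means
# (Cmax, AUC(0-168), Css(48-168) at weeks 1, 3, 12). Omegas are set from the
# published week-1 geometric CV% (clearance) and plausible phase-1 magnitudes
# (others). Regenerate with: patchpk calibrate --drug EE --out <file>
drug: EE
theta:
  CL: 107.71052957424467
  V: 2187.699531052343
  ka: 0.012186663817627189
  F: 0.3
  F_rel: 0.5333201526386123
  D1: 168.0
  D2: 0.0
  zero_route_fraction_rule: zero
  wk3_V_mult: 1.0
  wk3_CL_mult: 1.0
omega:
  CL: 0.29637131035163045
  V: 0.25
  ka: 0.3
sigma:
  kind: proportional
  prop: 0.15
  add: 0.0
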