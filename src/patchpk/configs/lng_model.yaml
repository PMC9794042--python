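# DERIVED default population model (LNG) -- not the originally reported estimates.
# Typical values were produced by patchpk.calibrate.calibrate_theta, which tunes
# the typical-subject simulation to the published weekly geometric means
# (Cmax, AUC(0-168), Css(48-168) at weeks 1, 3, 12). Omegas are set from the
# published week-1 geometric CV% (clearance) and plausible phase-1 magnitudes
# (others). Regenerate with: patchpk calibrate --drug LNG --out <file>
drug: LNG
theta:
  CL: 2.6993449033418218
  V: 80.32576040926992
  ka: 0.009089406282004294
  F: 0.27
  F_rel: 0.6488902837175237
  D1: 168.0
  D2: 2.0
  zero_route_fraction_rule: first
  wk3_V_mult: 0.7561098952924206
  wk3_CL_mult: 0.8034411197556635
omega:
  CL: 0.30851136469192325
  V: 0.2
  F_rel: 0.5
sigma:
  kind: proportional
  prop: 0.15
  add: 0.0
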