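# Example run configuration for `patchpk simulate --config examples/extended_regimen.yaml`.
# All defaults are spelled out; model_files may point at custom YAML models
# (paths relative to this file) and defaults to the packaged calibrated ones.
drugs: [EE, LNG]
model_files: {}
n_weeks: 12
patch_free_weeks: 1.0
amounts_mg: {EE: 2.3, LNG: 2.6}   # labelled patch content per application
n_subjects: 1000
seed: 20221227
weeks: [1, 3, 12]
out_dir: out/extended_regimen
sig_figures: 3
week_effect_mode: persist          # or week3_only
write_profiles: false
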