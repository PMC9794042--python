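"""Model-qualification diagnostics: goodness of fit and a VPC.

Fits the LNG model to a synthetic trial, prints weighted-residual summaries
(IWRES should look standard normal if the proportional-error model is right),
and runs a visual predictive check: the observed median concentration should
sit inside the band that 200 re-simulated trials put around their medians.
"""

import numpy as np

from patchpk import (
    FitSpec,
    ati_cl14_design,
    ati_cl14_regimen,
    default_model,
    fit_laplace,
    generate_trial,
    gof_diagnostics,
    vpc,
)

pop = default_model("LNG")
regimen = ati_cl14_regimen()
records = generate_trial(pop, ati_cl14_design("LNG"), regimen, seed=7)
fit = fit_laplace(records, FitSpec(drug="LNG", lloq=50.0), regimen, compute_rse=False)

gof = gof_diagnostics(fit, records)
print(f"GOF over {len(gof)} quantified records: "
      f"IWRES mean {gof['iwres'].mean():+.3f}, SD {gof['iwres'].std():.3f} "
      "(standard normal if the error model is adequate)")

table = vpc(fit, records, regimen, n_sim=200, seed=1)
inside = (
    (table["obs_p50"] >= table["sim_p50_lo"])
    & (table["obs_p50"] <= table["sim_p50_hi"])
)
print(f"VPC: observed median inside the simulated 90% band in "
      f"{inside.sum()}/{len(table)} time bins")
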