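"""Estimator behaviour: recovery, identifiability guards, VPC and GOF."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from patchpk.errors import IdentifiabilityError
from patchpk.estimation import (
    FitResult,
    FitSpec,
    fit_laplace,
    fit_two_stage,
    gof_diagnostics,
    laplace_objective,
    vpc,
)
from patchpk.population import PopulationModel, ResidualError
from patchpk.trial import ati_cl14_design, ati_cl14_regimen, generate_trial, rich_design


@pytest.fixture(scope="module")
def ee_dataset(ee_pop):
    reg = ati_cl14_regimen()
    data = generate_trial(ee_pop, ati_cl14_design("EE"), reg, seed=11)
    return data, reg


class TestTwoStage:
    def test_noise_free_rich_data_recovers_theta_exactly(self, ee_pop):
        quiet = PopulationModel(
            "EE", ee_pop.theta, {}, ResidualError("proportional", 0.0)
        )
        reg = ati_cl14_regimen()
        data = generate_trial(quiet, rich_design("EE", 4), reg, seed=1, noise_free=True)
        res = fit_two_stage(data, FitSpec(drug="EE"), reg, _perturbed(ee_pop, 1.3))
        for name in ("CL", "V", "ka", "F_rel"):
            got = getattr(res.estimates.theta, name)
            true = getattr(ee_pop.theta, name)
            assert got == pytest.approx(true, rel=1e-3), name
        assert all(v < 1e-3 for v in res.estimates.omega.values())

    def test_freeing_f_is_refused(self):
        with pytest.raises(IdentifiabilityError):
            FitSpec(drug="EE", free_F=True)

    def test_relabelling_equivariance(self, ee_dataset, ee_pop):
        data, reg = ee_dataset
        spec = FitSpec(drug="EE")
        a = fit_two_stage(data, spec, reg, ee_pop)
        relabeled = data.copy()
        mapping = {
            sid: f"Z{99 - i:02d}" for i, sid in enumerate(data["subject_id"].unique())
        }
        relabeled["subject_id"] = relabeled["subject_id"].map(mapping)
        b = fit_two_stage(relabeled, spec, reg, ee_pop)
        assert b.estimates.theta.CL == pytest.approx(a.estimates.theta.CL, rel=1e-9)
        assert b.estimates.omega["CL"] == pytest.approx(a.estimates.omega["CL"], rel=1e-9)

    def test_blq_logic_irrelevant_without_blq_records(self, ee_pop):
        reg = ati_cl14_regimen()
        data = generate_trial(ee_pop, ati_cl14_design("EE"), reg, seed=13)
        data = data[~data["blq"]].reset_index(drop=True)
        a = fit_two_stage(data, FitSpec(drug="EE", blq="drop"), reg, ee_pop)
        b = fit_two_stage(data, FitSpec(drug="EE", blq="lloq2", lloq=2.0), reg, ee_pop)
        assert a.estimates.theta == b.estimates.theta


class TestLaplace:
    def test_recovers_ee_model_from_one_trial(self, ee_pop):
        reg = ati_cl14_regimen()
        data = generate_trial(ee_pop, rich_design("EE", 50), reg, seed=1)
        res = fit_laplace(data, FitSpec(drug="EE"), reg, compute_rse=False)
        assert res.convergence["status"] == "converged"
        for name in ("CL", "V", "ka", "F_rel"):
            got = getattr(res.estimates.theta, name)
            true = getattr(ee_pop.theta, name)
            assert abs(np.log(got / true)) < np.log(1.15), name
        for name, true in ee_pop.omega.items():
            assert 0.5 * true < res.estimates.omega[name] < 1.5 * true, name

    def test_zero_iiv_data_shrinks_omega(self, ee_pop):
        reg = ati_cl14_regimen()
        quiet = PopulationModel(
            "EE", ee_pop.theta, {}, ResidualError("proportional", 0.1)
        )
        data = generate_trial(quiet, rich_design("EE", 20), reg, seed=2)
        init = PopulationModel(
            "EE", ee_pop.theta, {"CL": 0.3, "V": 0.3, "ka": 0.3}, quiet.sigma
        )
        res = fit_laplace(data, FitSpec(drug="EE"), reg, init=init, compute_rse=False)
        assert all(v < 0.05 for v in res.estimates.omega.values())

    def test_objective_prefers_truth_over_perturbation(self, ee_pop):
        reg = ati_cl14_regimen()
        data = generate_trial(ee_pop, rich_design("EE", 50), reg, seed=3)
        spec = FitSpec(drug="EE")
        perturbed = PopulationModel(
            "EE", dataclasses.replace(ee_pop.theta, CL=2 * ee_pop.theta.CL),
            ee_pop.omega, ee_pop.sigma,
        )
        assert laplace_objective(ee_pop, data, spec, reg) < laplace_objective(
            perturbed, data, spec, reg
        )

    def test_lng_smoke_recovers_clearance_and_week_effect(self, lng_pop):
        reg = ati_cl14_regimen()
        data = generate_trial(lng_pop, ati_cl14_design("LNG"), reg, seed=3)
        res = fit_laplace(data, FitSpec(drug="LNG"), reg, compute_rse=False)
        assert res.convergence["status"] == "converged"
        assert res.estimates.theta.CL == pytest.approx(lng_pop.theta.CL, rel=0.15)
        assert res.estimates.theta.wk3_CL_mult == pytest.approx(
            lng_pop.theta.wk3_CL_mult, rel=0.10
        )


def _perturbed(pop, factor):
    th = dataclasses.replace(
        pop.theta, CL=pop.theta.CL * factor, V=pop.theta.V / factor
    )
    return PopulationModel(pop.drug, th, pop.omega, pop.sigma)


def _fit_result_from(pop, spec, reg):
    return FitResult(
        estimates=pop, rse_pct={}, objective=0.0,
        convergence={"status": "assumed"}, eta=None, spec=spec, regimen=reg,
    )


class TestGof:
    def test_noise_free_fit_has_zero_residuals(self, ee_pop):
        reg = ati_cl14_regimen()
        quiet = PopulationModel(
            "EE", ee_pop.theta, {}, ResidualError("proportional", 0.0)
        )
        data = generate_trial(quiet, ati_cl14_design("EE"), reg, seed=4, noise_free=True)
        fit = _fit_result_from(
            PopulationModel("EE", ee_pop.theta, {}, ResidualError("proportional", 0.1)),
            FitSpec(drug="EE"), reg,
        )
        g = gof_diagnostics(fit, data)
        assert np.allclose(g["wres"], 0.0, atol=1e-9)
        assert np.allclose(g["dv"], g["pred"], rtol=1e-9)

    def test_weighted_residuals_standard_normal_under_true_model(self, ee_dataset, ee_pop):
        data, reg = ee_dataset
        spec = FitSpec(drug="EE")
        res = fit_laplace(data, spec, reg, compute_rse=False)
        g = gof_diagnostics(res, data)
        assert len(g) == (~data["blq"]).sum()
        ks = stats.kstest(g["iwres"], "norm")
        assert ks.pvalue > 0.01
        assert (g["pred"] > 0).all()


class TestVpc:
    def test_same_seed_identical_bands(self, ee_dataset, ee_pop):
        data, reg = ee_dataset
        fit = _fit_result_from(ee_pop, FitSpec(drug="EE", lloq=2.0), reg)
        a = vpc(fit, data, reg, n_sim=200, seed=21)
        b = vpc(fit, data, reg, n_sim=200, seed=21)
        pd.testing.assert_frame_equal(a, b)

    def test_self_consistency_median_inside_band(self, ee_dataset, ee_pop):
        data, reg = ee_dataset
        fit = _fit_result_from(ee_pop, FitSpec(drug="EE", lloq=2.0), reg)
        table = vpc(fit, data, reg, n_sim=300, seed=22)
        inside = (
            (table["obs_p50"] >= table["sim_p50_lo"])
            & (table["obs_p50"] <= table["sim_p50_hi"])
        )
        assert inside.mean() >= 0.85

    def test_gross_misfit_detected(self, ee_pop):
        reg = ati_cl14_regimen()
        times = ati_cl14_design("EE").sample_times[1:]  # drop the zero pre-dose
        rows = []
        for s in range(10):
            for t in times:
                rows.append({"subject_id": f"S{s}", "drug": "EE", "time_h": t,
                             "dv": 1e-3, "blq": False})
        data = pd.DataFrame(rows)
        fit = _fit_result_from(ee_pop, FitSpec(drug="EE", lloq=1e-6), reg)
        table = vpc(fit, data, reg, n_sim=200, seed=23)
        outside = (table["obs_p50"] < table["sim_p5_lo"]) | (
            table["obs_p50"] > table["sim_p95_hi"]
        )
        assert outside.all()
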