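"""Mixed-effects estimation of the population PK models from trial records.

Two estimators are provided:

* :func:`fit_two_stage` — per-subject weighted least squares on the log
  concentration scale, followed by log-scale (logit-scale for F_rel) means and
  variances across subjects.  Fast, robust, and the default initializer.
* :func:`fit_laplace` — maximum marginal likelihood with a Laplace
  approximation of the random-effect integral.  Inner modes are located by a
  damped Gauss-Newton iteration vectorized across subjects, and the inner
  Hessian uses the Gauss-Newton approximation (the FOCE-style curvature), so
  the objective is smooth and cheap enough for replicate recovery studies.

The residual model is proportional in exponential form, so the likelihood is
exactly Gaussian on the log scale: log y = log f(eta) + eps, eps ~ N(0, s^2).
Overall bioavailability F is structurally non-identifiable together with
F_rel and is always fixed (0.30 EE / 0.27 LNG), as is the 168-h zero-order
duration D1.  BLQ records are dropped by default (option: substitute LLOQ/2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .errors import IdentifiabilityError, InputError
from .population import (
    IIV_PARAMS,
    PopulationModel,
    ResidualError,
    _expit,
    _logit,
    individual_params,
)
from .structural import (
    DualRouteParams,
    Regimen,
    _select_by_week,
    dual_route_conc,
)

logger = logging.getLogger(__name__)

_ETA_ORDER = IIV_PARAMS  # random-effect ordering per drug


@dataclass(frozen=True)
class FitSpec:
    """Estimation settings: what is free, and how data are prepared."""

    drug: str
    fit_week3: bool | None = None   # default: LNG yes, EE no
    fit_D2: bool = False
    free_F: bool = False            # refused: F and F_rel are jointly non-identifiable
    blq: str = "drop"               # or "lloq2"
    lloq: float | None = None
    week_effect_mode: str = "persist"
    maxiter_outer: int = 300

    def __post_init__(self) -> None:
        if self.free_F:
            raise IdentifiabilityError(
                "overall bioavailability F cannot be estimated together with "
                "F_rel; F is fixed by design (0.30 EE / 0.27 LNG)"
            )
        if self.blq not in ("drop", "lloq2"):
            raise InputError("blq handling must be 'drop' or 'lloq2'")
        if self.fit_week3 is None:
            object.__setattr__(self, "fit_week3", self.drug == "LNG")


@dataclass
class FitResult:
    """Estimates, precision and convergence diagnostics of one fit."""

    estimates: PopulationModel
    rse_pct: dict[str, float]
    objective: float
    convergence: dict
    eta: pd.DataFrame | None = None     # per-subject empirical-Bayes modes
    spec: FitSpec | None = None
    regimen: Regimen | None = None

    def to_table(self) -> pd.DataFrame:
        """Parameter table: estimate, RSE%, transform, fixed/free flag."""
        th = self.estimates.theta
        rows = []
        for name, transform, fixed in _report_rows(self.estimates.drug, self.spec):
            if name.startswith("omega_"):
                val = self.estimates.omega.get(name.split("_", 1)[1], 0.0)
            elif name == "sigma_prop":
                val = self.estimates.sigma.prop
            else:
                val = getattr(th, name)
            rows.append(
                dict(parameter=name, estimate=val,
                     rse_pct=self.rse_pct.get(name, np.nan),
                     transform=transform, fixed=fixed)
            )
        return pd.DataFrame(rows)


def _report_rows(drug: str, spec: FitSpec | None):
    fit_wk3 = spec.fit_week3 if spec is not None else drug == "LNG"
    rows = [
        ("CL", "log", False), ("V", "log", False), ("ka", "log", False),
        ("F_rel", "logit", False), ("F", "none", True), ("D1", "none", True),
    ]
    if drug == "LNG":
        rows.append(("D2", "log", not (spec and spec.fit_D2)))
        rows.append(("wk3_V_mult", "log", not fit_wk3))
        rows.append(("wk3_CL_mult", "log", not fit_wk3))
    rows += [(f"omega_{p}", "log", False) for p in _ETA_ORDER[drug]]
    rows.append(("sigma_prop", "log", False))
    return rows


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

@dataclass
class _Prepped:
    ids: list[str]
    T: np.ndarray        # (n, m) padded times
    logY: np.ndarray     # (n, m) padded log observations
    mask: np.ndarray     # (n, m) True where a real observation exists
    n_obs: np.ndarray    # (n,)


def _prepare(data: pd.DataFrame, spec: FitSpec, min_obs: int = 1) -> _Prepped:
    df = data[data["drug"] == spec.drug].copy()
    if df.empty:
        raise InputError(f"no records for drug {spec.drug!r}")
    if spec.blq == "drop":
        df = df[~df["blq"]]
    else:
        if spec.lloq is None:
            raise InputError("blq='lloq2' requires the design LLOQ")
        df.loc[df["blq"], "dv"] = spec.lloq / 2.0
    df = df.dropna(subset=["dv"])
    groups, dropped = [], []
    for sid, g in df.groupby("subject_id", sort=True):
        if len(g) < min_obs:
            dropped.append(sid)
        else:
            groups.append((str(sid), g["time_h"].to_numpy(), g["dv"].to_numpy()))
    if dropped:
        logger.warning("excluding subjects with too few quantified records: %s", dropped)
        warnings.warn(f"excluded {len(dropped)} subject(s) with too few records")
    if not groups:
        raise InputError("no subject has enough quantified observations")
    m = max(len(t) for _, t, _ in groups)
    n = len(groups)
    T = np.zeros((n, m))
    logY = np.zeros((n, m))
    mask = np.zeros((n, m), dtype=bool)
    for i, (_, t, y) in enumerate(groups):
        T[i, : len(t)] = t
        logY[i, : len(t)] = np.log(y)
        mask[i, : len(t)] = True
    return _Prepped([g[0] for g in groups], T, logY, mask,
                    np.array([len(t) for _, t, _ in groups]))


# ---------------------------------------------------------------------------
# structural prediction with week-3 occasion effect
# ---------------------------------------------------------------------------

def _predict_conc(T, drug, dose_times, amounts_ng, CL, V, ka, F, F_rel, D1, D2,
                  wk3_V, wk3_CL, mode):
    base = dual_route_conc(T, dose_times, amounts_ng, drug, CL, V, ka, F, F_rel, D1, D2)
    if np.all(wk3_V == 1.0) and np.all(wk3_CL == 1.0) or mode == "off":
        return base
    scaled = dual_route_conc(
        T, dose_times, amounts_ng, drug, CL * wk3_CL, V * wk3_V, ka, F, F_rel, D1, D2
    )
    return _select_by_week(T, base, scaled, mode)


def _theta_to_subject_arrays(theta: DualRouteParams, drug: str, etas: np.ndarray):
    """Map (n, p) random effects to per-subject parameter arrays, shape (n, 1)."""
    names = _ETA_ORDER[drug]
    cols = {name: etas[:, j][:, None] for j, name in enumerate(names)}
    CL = theta.CL * np.exp(cols.get("CL", 0.0))
    V = theta.V * np.exp(cols.get("V", 0.0))
    ka = theta.ka * np.exp(cols.get("ka", 0.0))
    if "F_rel" in cols:
        F_rel = _expit(_logit(theta.F_rel) + cols["F_rel"])
    else:
        F_rel = np.full_like(CL, theta.F_rel)
    return CL, V, ka, F_rel


def _log_pred(theta: DualRouteParams, drug, dose_times, amounts_ng, T, etas, mode):
    CL, V, ka, F_rel = _theta_to_subject_arrays(theta, drug, etas)
    conc = _predict_conc(
        T, drug, dose_times, amounts_ng, CL, V, ka, theta.F, F_rel, theta.D1,
        theta.D2, theta.wk3_V_mult, theta.wk3_CL_mult, mode,
    )
    return np.log(np.maximum(conc, 1e-300))


# ---------------------------------------------------------------------------
# two-stage estimator
# ---------------------------------------------------------------------------

def fit_two_stage(
    data: pd.DataFrame,
    spec: FitSpec,
    regimen: Regimen,
    init: PopulationModel,
) -> FitResult:
    """Per-subject least squares, then across-subject moments.

    Each subject's CL, V, ka and F_rel (plus week-3 multipliers when fitted)
    are estimated on the log concentration scale; typical values are the
    transformed-scale means and omegas the transformed-scale SDs over the
    drug's random-effect set.  Needs >= 6 quantified observations per subject.
    """
    prep = _prepare(data, spec, min_obs=6)
    drug = spec.drug
    events = regimen.events_for(drug)
    dose_times = [e.t_app for e in events]
    amounts_ng = [e.amount * 1e6 for e in events]
    th0 = init.theta

    names = ["CL", "V", "ka", "F_rel"]
    if drug == "LNG" and spec.fit_week3:
        names += ["wk3_V_mult", "wk3_CL_mult"]
    if drug == "LNG" and spec.fit_D2:
        names += ["D2"]

    def unpack(x) -> DualRouteParams:
        upd = {}
        for name, xi in zip(names, x):
            upd[name] = _expit(xi) if name == "F_rel" else float(np.exp(xi))
        return replace(th0, **upd)

    x0 = np.array([
        _logit(th0.F_rel) if name == "F_rel" else np.log(getattr(th0, name))
        for name in names
    ])
    per_subj = []
    resid_ss, resid_n = 0.0, 0
    for i, sid in enumerate(prep.ids):
        t = prep.T[i, prep.mask[i]]
        ly = prep.logY[i, prep.mask[i]]

        def resid(x):
            p = unpack(x)
            lp = _log_pred(p, drug, dose_times, amounts_ng, t, np.zeros((1, len(_ETA_ORDER[drug]))), spec.week_effect_mode)[0]
            return ly - lp

        sol = least_squares(resid, x0, method="lm", xtol=1e-12, ftol=1e-12)
        per_subj.append(sol.x)
        resid_ss += float(np.sum(sol.fun**2))
        resid_n += len(ly)
    X = np.vstack(per_subj)
    mean_x = X.mean(axis=0)
    theta = unpack(mean_x)
    sd_x = X.std(axis=0, ddof=1) if len(X) > 1 else np.zeros(X.shape[1])
    omega = {
        p: float(sd_x[names.index(p)]) for p in _ETA_ORDER[drug] if p in names
    }
    dof = max(resid_n - X.size, 1)
    sigma = ResidualError("proportional", float(np.sqrt(resid_ss / dof)), 0.0)
    est = PopulationModel(drug, theta, omega, sigma)
    n = len(X)
    rse = {
        name: 100.0 * sd_x[j] / max(np.sqrt(n), 1.0)
        for j, name in enumerate(names)
    }
    eta = pd.DataFrame(
        X - mean_x, columns=names, index=pd.Index(prep.ids, name="subject_id")
    )[list(_ETA_ORDER[drug])]
    return FitResult(
        estimates=est, rse_pct=rse,
        objective=resid_n * np.log(max(sigma.prop, 1e-12) ** 2) + resid_ss / max(sigma.prop, 1e-12) ** 2,
        convergence={"status": "converged", "n_subjects": n},
        eta=eta, spec=spec, regimen=regimen,
    )


# ---------------------------------------------------------------------------
# Laplace marginal likelihood
# ---------------------------------------------------------------------------

class _Packing:
    """Transformed-scale packing of the outer parameter vector."""

    def __init__(self, spec: FitSpec, init: PopulationModel):
        self.spec = spec
        self.drug = spec.drug
        self.eta_names = list(_ETA_ORDER[self.drug])
        self.theta_names = ["CL", "V", "ka", "F_rel"]
        if self.drug == "LNG" and spec.fit_week3:
            self.theta_names += ["wk3_V_mult", "wk3_CL_mult"]
        if self.drug == "LNG" and spec.fit_D2:
            self.theta_names += ["D2"]
        self.init = init

    def pack(self, pop: PopulationModel) -> np.ndarray:
        th = pop.theta
        x = [
            _logit(th.F_rel) if n == "F_rel" else np.log(getattr(th, n))
            for n in self.theta_names
        ]
        x += [np.log(max(pop.omega.get(p, 0.3), 1e-3)) for p in self.eta_names]
        x.append(np.log(max(pop.sigma.prop, 1e-3)))
        return np.array(x)

    def unpack(self, x: np.ndarray) -> PopulationModel:
        nt = len(self.theta_names)
        upd = {}
        for n, xi in zip(self.theta_names, x[:nt]):
            upd[n] = float(_expit(xi)) if n == "F_rel" else float(np.exp(xi))
        theta = replace(self.init.theta, **upd)
        omega = {
            p: float(np.exp(xi))
            for p, xi in zip(self.eta_names, x[nt : nt + len(self.eta_names)])
        }
        sigma = ResidualError("proportional", float(np.exp(x[-1])), 0.0)
        return PopulationModel(self.drug, theta, omega, sigma)

    @property
    def names(self) -> list[str]:
        return (
            self.theta_names
            + [f"omega_{p}" for p in self.eta_names]
            + ["sigma_prop"]
        )


def _laplace_nll(pop, prep, dose_times, amounts_ng, mode, eta_state, inner_tol=1e-5):
    """Total Laplace-approximated -log marginal likelihood (constants dropped).

    ``eta_state`` is an (n, p) array of warm-start inner modes, updated in
    place across outer iterations.
    """
    drug = pop.drug
    p = len(_ETA_ORDER[drug])
    n, m = prep.T.shape
    omega = np.array([max(pop.omega.get(q, 0.0), 1e-6) for q in _ETA_ORDER[drug]])
    sig2 = max(pop.sigma.prop, 1e-6) ** 2
    W = prep.mask
    theta = pop.theta

    def logf(E):
        # exploration steps may overflow exp(eta); such points are rejected
        # by the backtracking line search, so the warnings are noise
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return _log_pred(theta, drug, dose_times, amounts_ng, prep.T, E, mode)

    def obj_vec(E):
        r = np.where(W, prep.logY - logf(E), 0.0)
        return 0.5 * np.sum(r * r, axis=1) / sig2 + 0.5 * np.sum(
            (E / omega) ** 2, axis=1
        )

    E = eta_state.copy()
    fE = obj_vec(E)
    delta = 1e-5
    J = np.empty((n, m, p))
    for _ in range(15):
        lf = logf(E)
        r = np.where(W, prep.logY - lf, 0.0)
        for d in range(p):
            Ed = E.copy()
            Ed[:, d] += delta
            J[:, :, d] = np.where(W, (logf(Ed) - lf) / delta, 0.0)
        JtJ = np.einsum("nmd,nme->nde", J, J) / sig2
        H = JtJ + np.eye(p) / omega**2
        grad = -np.einsum("nmd,nm->nd", J, r) / sig2 + E / omega**2
        step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        step = np.where(np.isfinite(step), np.clip(step, -4.0, 4.0), 0.0)
        if np.max(np.abs(step)) < inner_tol:
            break
        # per-subject backtracking
        tol = 1e-12 * (1.0 + np.abs(fE))
        scale = np.ones(n)
        f_new = fE
        for _ in range(10):
            E_new = np.clip(E - step * scale[:, None], -10.0, 10.0)
            f_new = obj_vec(E_new)
            worse = ~(f_new <= fE + tol)
            if not np.any(worse):
                break
            scale[worse] *= 0.5
        improved = f_new <= fE + tol
        E = np.where(improved[:, None], np.clip(E - step * scale[:, None], -10.0, 10.0), E)
        fE = np.where(improved, np.minimum(f_new, fE), fE)
        if not np.any(improved & (np.max(np.abs(step), axis=1) > inner_tol)):
            break
    eta_state[...] = E

    # curvature at the modes (Gauss-Newton)
    lf = logf(E)
    for d in range(p):
        Ed = E.copy()
        Ed[:, d] += delta
        J[:, :, d] = np.where(W, (logf(Ed) - lf) / delta, 0.0)
    H = np.einsum("nmd,nme->nde", J, J) / sig2 + np.eye(p) / omega**2
    sign, logdet = np.linalg.slogdet(H)
    nll = (
        np.sum(fE)
        + 0.5 * np.sum(logdet)
        + 0.5 * np.sum(prep.n_obs) * np.log(sig2)
        + prep.T.shape[0] * np.sum(np.log(omega))
    )
    return float(nll), E


def fit_laplace(
    data: pd.DataFrame,
    spec: FitSpec,
    regimen: Regimen,
    init: PopulationModel | None = None,
    compute_rse: bool = True,
) -> FitResult:
    """Maximize the Laplace-approximated marginal likelihood.

    ``init`` defaults to a two-stage fit of the same data.  Fixed by design:
    F, D1 and (unless freed) D2.  Reports RSEs from a finite-difference
    observed-information matrix on the transformed scale.
    """
    if init is None:
        base = PopulationModel(
            spec.drug, _default_init_theta(spec.drug),
            {p: 0.3 for p in _ETA_ORDER[spec.drug]}, ResidualError("proportional", 0.2),
        )
        init = fit_two_stage(data, spec, regimen, base).estimates
        init = replace(
            init,
            omega={p: min(max(v, 0.05), 1.0) for p, v in init.omega.items()},
        )
    prep = _prepare(data, spec, min_obs=1)
    events = regimen.events_for(spec.drug)
    dose_times = [e.t_app for e in events]
    amounts_ng = [e.amount * 1e6 for e in events]
    packing = _Packing(spec, init)
    x0 = packing.pack(init)
    p = len(_ETA_ORDER[spec.drug])
    eta_state = np.zeros((prep.T.shape[0], p))

    def objective(x):
        # cold-start the inner modes so the objective is a deterministic
        # function of x (warm starts would make finite differences noisy)
        pop = packing.unpack(x)
        eta0 = np.zeros_like(eta_state)
        nll, _ = _laplace_nll(
            pop, prep, dose_times, amounts_ng, spec.week_effect_mode, eta0
        )
        return nll

    bounds = [(-12.0, 12.0)] * len(x0)
    res = minimize(
        objective, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": spec.maxiter_outer, "ftol": 1e-10, "gtol": 1e-6,
                 "eps": 1e-5, "maxfun": 20000},
    )
    pop = packing.unpack(res.x)
    nll, E = _laplace_nll(
        pop, prep, dose_times, amounts_ng, spec.week_effect_mode, eta_state
    )
    rse = _rse_from_hessian(objective, res.x, packing) if compute_rse else {}
    eta = pd.DataFrame(
        E, columns=list(_ETA_ORDER[spec.drug]),
        index=pd.Index(prep.ids, name="subject_id"),
    )
    status = "converged" if res.success else "not_converged"
    if not res.success:
        logger.warning("Laplace fit did not converge: %s", res.message)
    return FitResult(
        estimates=pop, rse_pct=rse, objective=2.0 * nll,
        convergence={"status": status, "iterations": int(res.nit),
                     "message": str(res.message)},
        eta=eta, spec=spec, regimen=regimen,
    )


def laplace_objective(
    pop: PopulationModel, data: pd.DataFrame, spec: FitSpec, regimen: Regimen
) -> float:
    """-2 log marginal likelihood of a given model on given data."""
    prep = _prepare(data, spec, min_obs=1)
    events = regimen.events_for(spec.drug)
    eta0 = np.zeros((prep.T.shape[0], len(_ETA_ORDER[spec.drug])))
    nll, _ = _laplace_nll(
        pop, prep, [e.t_app for e in events], [e.amount * 1e6 for e in events],
        spec.week_effect_mode, eta0,
    )
    return 2.0 * nll


def _rse_from_hessian(objective, x: np.ndarray, packing: _Packing) -> dict[str, float]:
    """RSE% via central-difference Hessian of the NLL on the transformed scale."""
    q = len(x)
    h = 1e-4
    H = np.zeros((q, q))
    f0 = objective(x)
    fp = np.zeros(q)
    fm = np.zeros(q)
    for i in range(q):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        fp[i], fm[i] = objective(xp), objective(xm)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
    for i in range(q):
        for j in range(i + 1, q):
            xpp = x.copy(); xpp[[i, j]] += h
            xmm = x.copy(); xmm[[i, j]] -= h
            H[i, j] = H[j, i] = (
                objective(xpp) - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + objective(xmm)
            ) / (2 * h**2)
    rse = {}
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(q, np.nan)
    for name, s in zip(packing.names, se):
        if name == "F_rel":
            val = packing.unpack(x).theta.F_rel
            rse[name] = 100.0 * s * (1 - val)  # d(logit)->relative, delta method
        else:
            rse[name] = 100.0 * s  # log scale: SE(log) ~ relative SE
    return rse


def _default_init_theta(drug: str) -> DualRouteParams:
    if drug == "EE":
        return DualRouteParams(CL=100.0, V=2000.0, ka=0.05, F=0.30, F_rel=0.7,
                               zero_route_fraction_rule="zero")
    return DualRouteParams(CL=2.0, V=150.0, ka=0.02, F=0.27, F_rel=0.5, D2=24.0,
                           zero_route_fraction_rule="first")


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def gof_diagnostics(fit: FitResult, data: pd.DataFrame) -> pd.DataFrame:
    """Tidy goodness-of-fit table: dv, PRED, IPRED and weighted residuals.

    PRED is the typical-subject prediction (eta = 0); IPRED uses the
    empirical-Bayes modes from the fit.  Weighted residuals are log-scale
    residuals divided by sigma, so a well-specified proportional-error fit
    yields approximately standard-normal IWRES.
    """
    spec, regimen = fit.spec, fit.regimen
    prep = _prepare(data, spec, min_obs=1)
    events = regimen.events_for(spec.drug)
    dose_times = [e.t_app for e in events]
    amounts_ng = [e.amount * 1e6 for e in events]
    pnames = list(_ETA_ORDER[spec.drug])
    E = (
        fit.eta.reindex(prep.ids).fillna(0.0)[pnames].to_numpy()
        if fit.eta is not None
        else np.zeros((len(prep.ids), len(pnames)))
    )
    th = fit.estimates.theta
    lp_pop = _log_pred(th, spec.drug, dose_times, amounts_ng, prep.T,
                       np.zeros_like(E), spec.week_effect_mode)
    lp_ind = _log_pred(th, spec.drug, dose_times, amounts_ng, prep.T, E,
                       spec.week_effect_mode)
    sig = max(fit.estimates.sigma.prop, 1e-12)
    rows = []
    for i, sid in enumerate(prep.ids):
        sel = prep.mask[i]
        rows.append(pd.DataFrame({
            "subject_id": sid,
            "time_h": prep.T[i, sel],
            "dv": np.exp(prep.logY[i, sel]),
            "pred": np.exp(lp_pop[i, sel]),
            "ipred": np.exp(lp_ind[i, sel]),
            "wres": (prep.logY[i, sel] - lp_pop[i, sel]) / sig,
            "iwres": (prep.logY[i, sel] - lp_ind[i, sel]) / sig,
        }))
    return pd.concat(rows, ignore_index=True)


def vpc(
    fit: FitResult,
    data: pd.DataFrame,
    regimen: Regimen,
    n_sim: int = 200,
    seed: int = 0,
    pcts: Sequence[float] = (5.0, 50.0, 95.0),
    band: float = 90.0,
) -> pd.DataFrame:
    """Visual-predictive-check table.

    Simulates ``n_sim`` replicate trials at the observed design under the
    fitted model, computes the requested concentration percentiles per unique
    sampling time, and returns per time bin the observed percentiles together
    with the central ``band``% interval of each simulated percentile.
    """
    from .trial import SamplingDesign, generate_trial

    if n_sim < 200:
        raise InputError("vpc needs n_sim >= 200 replicates")
    spec = fit.spec
    df = data[(data["drug"] == spec.drug) & ~data["blq"]]
    times = np.unique(df["time_h"].to_numpy())
    n_subj = df["subject_id"].nunique()
    lloq = spec.lloq if spec.lloq is not None else 0.0
    design = SamplingDesign(n_subj, tuple(times), max(lloq, 1e-9))
    obs = df.groupby("time_h")["dv"].apply(
        lambda v: np.percentile(v, pcts)
    )
    sims = np.full((n_sim, len(times), len(pcts)), np.nan)
    rng_seeds = np.random.SeedSequence(seed).generate_state(n_sim) % (2**31 - 1)
    for r in range(n_sim):
        rep = generate_trial(
            fit.estimates, design, regimen, int(rng_seeds[r]),
            week_effect_mode=spec.week_effect_mode,
        )
        rep = rep[~rep["blq"]]
        for ti, t in enumerate(times):
            v = rep.loc[rep["time_h"] == t, "dv"]
            if len(v):
                sims[r, ti] = np.percentile(v, pcts)
    lo, hi = (100.0 - band) / 2.0, 100.0 - (100.0 - band) / 2.0
    rows = []
    for ti, t in enumerate(times):
        row = {"time_h": t}
        for pi, pc in enumerate(pcts):
            tag = f"p{pc:g}"
            row[f"obs_{tag}"] = obs.loc[t][pi]
            sim_vals = sims[:, ti, pi]
            sim_vals = sim_vals[np.isfinite(sim_vals)]
            row[f"sim_{tag}_lo"] = np.percentile(sim_vals, lo)
            row[f"sim_{tag}_mid"] = np.percentile(sim_vals, 50.0)
            row[f"sim_{tag}_hi"] = np.percentile(sim_vals, hi)
        rows.append(row)
    return pd.DataFrame(rows)
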