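"""Dual-route one-compartment transdermal PK models.

Both hormones delivered by the weekly patch are described by a one-compartment
disposition model fed by two absorption routes:

* ethinyl estradiol (EE): a zero-order infusion directly into the central
  compartment lasting the full wear period (``D1`` = 168 h), plus first-order
  absorption (rate constant ``ka``) from a depot that receives its share of the
  dose as a bolus at application time;
* levonorgestrel (LNG): a zero-order infusion into the central compartment
  (``D1`` = 168 h), plus a zero-order infusion of duration ``D2`` into a depot
  that drains into the central compartment first order.

Overall bioavailability ``F`` is fixed per drug (0.30 EE, 0.27 LNG) and split
between the routes by ``F_rel``.  For EE the zero-order route receives
``F_rel*F``; for LNG the first-order route receives ``F_rel*F``.  Multi-dose
profiles are linear superpositions of single-dose solutions; consecutive weekly
patches do not reset any state.

Internal units are hours, litres and nanograms; 1 ng/L equals 1 pg/mL, so
concentrations are reported in pg/mL without further conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, IntegrationError, ParameterError

WEEK_H = 168.0
DRUGS = ("EE", "LNG")

#: fixed overall bioavailability per drug
F_FIXED = {"EE": 0.30, "LNG": 0.27}
#: labelled patch content, mg
PATCH_CONTENT_MG = {"EE": 2.3, "LNG": 2.6}
#: nominal delivered amount per one-week wear, mg (30 / 120 ug per day x 7)
DELIVERED_MG = {"EE": 0.210, "LNG": 0.840}

_KA_K_RTOL = 1e-8  # switch to the ka -> k analytic limit below this


def _check_drug(drug: str) -> str:
    if drug not in DRUGS:
        raise InputError(f"unknown drug label {drug!r}; expected one of {DRUGS}")
    return drug


@dataclass(frozen=True)
class DualRouteParams:
    """Structural parameters of one individual.

    ``zero_route_fraction_rule`` records which route receives ``F_rel*F``:
    ``"zero"`` (EE convention) or ``"first"`` (LNG convention).
    """

    CL: float            # clearance, L/h
    V: float             # central volume, L
    ka: float            # first-order absorption rate constant, 1/h
    F: float             # overall bioavailability, fraction
    F_rel: float         # route-split fraction
    D1: float = WEEK_H   # zero-order central-input duration, h
    D2: float = 0.0      # zero-order depot-input duration, h (LNG only)
    zero_route_fraction_rule: str = "zero"
    wk3_V_mult: float = 1.0
    wk3_CL_mult: float = 1.0

    def __post_init__(self) -> None:
        if not (self.CL > 0 and self.V > 0):
            raise ParameterError(f"CL and V must be positive (CL={self.CL}, V={self.V})")
        if not self.ka > 0:
            raise ParameterError(f"ka must be positive (ka={self.ka})")
        if not (0 < self.F <= 1):
            raise ParameterError(f"F must lie in (0, 1] (F={self.F})")
        if not (0 <= self.F_rel <= 1):
            raise ParameterError(f"F_rel must lie in [0, 1] (F_rel={self.F_rel})")
        if not self.D1 > 0:
            raise ParameterError(f"D1 must be positive (D1={self.D1})")
        if self.D2 < 0:
            raise ParameterError(f"D2 must be non-negative (D2={self.D2})")
        if self.zero_route_fraction_rule not in ("zero", "first"):
            raise ParameterError(
                "zero_route_fraction_rule must be 'zero' or 'first'"
            )
        if not (self.wk3_V_mult > 0 and self.wk3_CL_mult > 0):
            raise ParameterError("week-3 multipliers must be positive")

    @property
    def k(self) -> float:
        """Elimination rate constant CL/V, 1/h."""
        return self.CL / self.V

    def route_fractions(self) -> tuple[float, float]:
        """(zero-order fraction of dose, first-order fraction of dose)."""
        if self.zero_route_fraction_rule == "zero":
            return self.F_rel * self.F, (1.0 - self.F_rel) * self.F
        return (1.0 - self.F_rel) * self.F, self.F_rel * self.F

    def at_week(self, week: int, mode: str = "persist") -> "DualRouteParams":
        """Parameters effective during the given week (1-based).

        The week-3 effect scales V and CL from week 3 onward (``persist``) or
        in week 3 only (``week3_only``); ``off`` disables it.
        """
        if week < 1:
            raise InputError(f"week index must be >= 1 (got {week})")
        active = (
            mode == "persist" and week >= 3
        ) or (mode == "week3_only" and week == 3)
        if not active or (self.wk3_V_mult == 1.0 and self.wk3_CL_mult == 1.0):
            return self
        return replace(
            self, V=self.V * self.wk3_V_mult, CL=self.CL * self.wk3_CL_mult
        )


@dataclass(frozen=True)
class DoseEvent:
    """One patch application."""

    t_app: float   # application time, h
    amount: float  # drug mass per patch, mg
    drug: str

    def __post_init__(self) -> None:
        if self.t_app < 0:
            raise InputError(f"application time must be >= 0 (got {self.t_app})")
        if not self.amount > 0:
            raise InputError(f"dose amount must be positive (got {self.amount})")
        _check_drug(self.drug)


@dataclass(frozen=True)
class Regimen:
    """Ordered patch applications plus a trailing patch-free period."""

    events: tuple[DoseEvent, ...]
    n_weeks: int
    patch_free_h: float = WEEK_H

    def __post_init__(self) -> None:
        if self.n_weeks < 1:
            raise InputError("n_weeks must be >= 1")
        object.__setattr__(self, "events", tuple(self.events))
        times = [e.t_app for e in self.events]
        if times != sorted(times):
            raise InputError("dose events must be sorted by application time")
        for drug in DRUGS:
            apps = [e.t_app for e in self.events if e.drug == drug]
            if any(abs(b - a - WEEK_H) > 1e-9 for a, b in zip(apps, apps[1:])):
                raise InputError(
                    f"consecutive weekly {drug} applications must be 168 h apart"
                )

    @property
    def horizon_h(self) -> float:
        return self.n_weeks * WEEK_H + self.patch_free_h

    def events_for(self, drug: str) -> tuple[DoseEvent, ...]:
        _check_drug(drug)
        return tuple(e for e in self.events if e.drug == drug)


def weekly_regimen(
    n_weeks: int = 12,
    drugs: Sequence[str] = DRUGS,
    amounts_mg: dict[str, float] | None = None,
    patch_free_weeks: float = 1.0,
) -> Regimen:
    """Weekly applications of the combination patch for ``n_weeks`` weeks."""
    amounts = dict(PATCH_CONTENT_MG if amounts_mg is None else amounts_mg)
    events = [
        DoseEvent(w * WEEK_H, amounts[d], d)
        for w in range(n_weeks)
        for d in drugs
    ]
    events.sort(key=lambda e: (e.t_app, e.drug))
    return Regimen(tuple(events), n_weeks, patch_free_weeks * WEEK_H)


@dataclass
class ConcProfile:
    """A (time, concentration) series for one subject, pg/mL."""

    drug: str
    times: np.ndarray
    conc: np.ndarray
    subject_id: str = "typical"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times.shape != self.conc.shape:
            raise InputError("times and conc must have identical shape")
        if np.any(np.diff(self.times) < 0):
            raise InputError("time grid must be monotone non-decreasing")

    def window(self, t_start: float, t_end: float) -> "ConcProfile":
        m = (self.times >= t_start - 1e-9) & (self.times <= t_end + 1e-9)
        return ConcProfile(self.drug, self.times[m], self.conc[m], self.subject_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "drug": self.drug,
                "time_h": self.times,
                "conc_pg_ml": self.conc,
            }
        )


def profiles_to_csv(profiles: Iterable[ConcProfile], path) -> None:
    pd.concat([p.to_frame() for p in profiles], ignore_index=True).to_csv(
        path, index=False
    )


def profiles_from_csv(path) -> list[ConcProfile]:
    df = pd.read_csv(path)
    out = []
    for (sid, drug), g in df.groupby(["subject_id", "drug"], sort=False):
        out.append(
            ConcProfile(drug, g["time_h"].to_numpy(), g["conc_pg_ml"].to_numpy(), str(sid))
        )
    return out


# ---------------------------------------------------------------------------
# closed-form single-dose kernels (broadcast over arrays)
# ---------------------------------------------------------------------------

def _zero_order_central_conc(t, R0, D, k, CL):
    """Concentration from a zero-order infusion into the central compartment.

    During the infusion (t <= D): (R0/CL)(1 - e^{-kt}); afterwards the
    accumulated amount washes out monoexponentially.  Vectorized; t < 0 -> 0.
    """
    t = np.asarray(t, dtype=float)
    te = np.minimum(np.maximum(t, 0.0), D)      # effective infusion exposure time
    rise = (R0 / CL) * -np.expm1(-k * te)
    decay = np.exp(-k * np.maximum(t - D, 0.0) * (t > D))
    return np.where(t > 0, rise * decay, 0.0)


def _bateman_cumulative(x, ka, k, V):
    """Integral from 0 to x of the unit-depot-bolus central concentration.

    Used to express the depot-infusion solution as R0d*(Phi(t) - Phi(t-D2)).
    Handles the ka -> k degeneracy by its analytic limit.
    """
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    ka = np.asarray(ka, dtype=float)
    k = np.asarray(k, dtype=float)
    near = np.abs(ka - k) < _KA_K_RTOL * k
    ka_safe = np.where(near, k * (1.0 + 1e-3), ka)
    pref = ka_safe / (V * (ka_safe - k))
    general = pref * (-np.expm1(-k * x) / k + np.expm1(-ka_safe * x) / ka_safe)
    # limit ka -> k of the cumulative: (1/(Vk)) (1 - e^{-kx}(1 + kx))
    limit = (1.0 - np.exp(-k * x) * (1.0 + k * x)) / (V * k)
    return np.where(near, limit, general)


def _bateman_conc(t, A0, ka, k, V):
    """Central concentration after a depot bolus A0 (Bateman equation)."""
    t = np.maximum(np.asarray(t, dtype=float), 0.0)
    ka = np.asarray(ka, dtype=float)
    k = np.asarray(k, dtype=float)
    near = np.abs(ka - k) < _KA_K_RTOL * k
    ka_safe = np.where(near, k * (1.0 + 1e-3), ka)
    general = (A0 * ka_safe) / (V * (ka_safe - k)) * (
        np.exp(-k * t) - np.exp(-ka_safe * t)
    )
    limit = A0 * k * t / V * np.exp(-k * t)
    return np.where(near, limit, general)


def _depot_infusion_conc(t, R0d, D2, ka, k, V):
    """Central concentration from a zero-order depot infusion of duration D2."""
    t = np.asarray(t, dtype=float)
    return R0d * (
        _bateman_cumulative(t, ka, k, V)
        - _bateman_cumulative(t - D2, ka, k, V)
    )


# spec-level operations on DualRouteParams -----------------------------------

def conc_zero_order_central(params: DualRouteParams, R0: float, D: float, t):
    """Concentration from a zero-order central infusion at rate R0 for D hours.

    Units follow R0: concentration is (mass unit of R0) per litre.
    """
    if R0 < 0:
        raise ParameterError("infusion rate must be >= 0")
    if not D > 0:
        raise ParameterError("infusion duration must be positive")
    return _zero_order_central_conc(t, R0, D, params.k, params.CL)


def conc_first_order_depot(params: DualRouteParams, A0: float, t):
    """Concentration after a depot bolus A0 absorbed first order (Bateman)."""
    if A0 < 0:
        raise ParameterError("depot amount must be >= 0")
    return _bateman_conc(t, A0, params.ka, params.k, params.V)


def conc_depot_infusion(params: DualRouteParams, R0d: float, D2: float, t):
    """Concentration from a zero-order infusion into the depot for D2 hours."""
    if R0d < 0:
        raise ParameterError("depot infusion rate must be >= 0")
    if R0d > 0 and not D2 > 0:
        raise ParameterError("depot infusion duration must be positive")
    if R0d == 0:
        return np.zeros_like(np.asarray(t, dtype=float))
    return _depot_infusion_conc(t, R0d, D2, params.ka, params.k, params.V)


# ---------------------------------------------------------------------------
# vectorized multi-dose superposition
# ---------------------------------------------------------------------------

def dual_route_conc(
    times,
    dose_times: Sequence[float],
    amounts_ng: Sequence[float],
    drug: str,
    CL, V, ka, F, F_rel, D1, D2,
):
    """Superposed central concentration (ng/L == pg/mL) for one parameter set.

    All parameters may be numpy arrays broadcastable against ``times`` (e.g.
    shape ``(n_subjects, 1)`` against a ``(n_times,)`` grid), which is how the
    population and estimation layers evaluate many subjects at once.
    """
    _check_drug(drug)
    times = np.asarray(times, dtype=float)
    k = CL / V
    if drug == "EE":
        frac_zero, frac_first = F_rel * F, (1.0 - F_rel) * F
    else:
        frac_zero, frac_first = (1.0 - F_rel) * F, F_rel * F
    conc = np.zeros(np.broadcast_shapes(np.shape(times), np.shape(k)))
    for t_app, amt in zip(dose_times, amounts_ng):
        trel = times - t_app
        R0 = frac_zero * amt / D1
        conc = conc + _zero_order_central_conc(trel, R0, D1, k, CL)
        if drug == "EE":
            A0 = frac_first * amt
            conc = conc + np.where(trel > 0, _bateman_conc(trel, A0, ka, k, V), 0.0)
        else:
            R0d = frac_first * amt / D2
            conc = conc + np.where(
                trel > 0, _depot_infusion_conc(trel, R0d, D2, ka, k, V), 0.0
            )
    return conc


def _week_index(t) -> np.ndarray:
    """1-based week of each absolute time; t = 0 belongs to week 1."""
    return np.floor(np.maximum(np.asarray(t, dtype=float), 0.0) / WEEK_H).astype(int) + 1


def _select_by_week(times, base, wk3, mode: str):
    if mode == "off":
        return base
    if mode == "persist":
        active = _week_index(times) >= 3
    elif mode == "week3_only":
        t = np.asarray(times, dtype=float)
        active = (t >= 2 * WEEK_H) & (t <= 3 * WEEK_H)
    else:
        raise InputError(f"unknown week-effect mode {mode!r}")
    return np.where(active, wk3, base)


def simulate_profile(
    params: DualRouteParams,
    regimen: Regimen,
    times,
    drug: str,
    subject_id: str = "typical",
    week_effect_mode: str = "persist",
) -> ConcProfile:
    """Closed-form multi-dose profile for one subject.

    The week-3 effect (LNG) acts as an occasion covariate: a time point that
    falls in week w is evaluated with the week-w parameter set applied to the
    whole dosing history.
    """
    _check_drug(drug)
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise InputError("time grid must be sorted")
    events = regimen.events_for(drug)
    dose_times = [e.t_app for e in events]
    amounts_ng = [e.amount * 1e6 for e in events]

    def _conc(p: DualRouteParams):
        return dual_route_conc(
            times, dose_times, amounts_ng, drug,
            p.CL, p.V, p.ka, p.F, p.F_rel, p.D1, p.D2,
        )

    base = _conc(params)
    p3 = params.at_week(3, "persist")
    if p3 is params or week_effect_mode == "off":
        conc = base
    else:
        conc = _select_by_week(times, base, _conc(p3), week_effect_mode)
    return ConcProfile(drug, times, conc, subject_id)


# ---------------------------------------------------------------------------
# ODE verification oracle
# ---------------------------------------------------------------------------

def _ode_conc(params: DualRouteParams, events, times, drug: str) -> np.ndarray:
    """Integrate depot+central amounts through the dosing schedule."""
    from scipy.integrate import solve_ivp

    k = params.k
    frac_zero, frac_first = params.route_fractions()
    # piecewise-constant input rates: breakpoints at starts/stops
    breaks = {0.0}
    rc_segments = []  # (start, stop, rate ng/h) into central
    rd_segments = []  # into depot (LNG)
    boluses = []      # (time, ng) into depot (EE)
    for e in events:
        amt = e.amount * 1e6
        rc_segments.append((e.t_app, e.t_app + params.D1, frac_zero * amt / params.D1))
        breaks.update((e.t_app, e.t_app + params.D1))
        if drug == "EE":
            boluses.append((e.t_app, frac_first * amt))
            breaks.add(e.t_app)
        else:
            rd_segments.append(
                (e.t_app, e.t_app + params.D2, frac_first * amt / params.D2)
            )
            breaks.update((e.t_app, e.t_app + params.D2))
    t_end = float(max(np.max(times), max(b for b in breaks)))
    grid = sorted(b for b in breaks if b <= t_end)
    if grid[-1] < t_end:
        grid.append(t_end)

    def rates_at(t):
        rc = sum(r for (a, b, r) in rc_segments if a <= t < b)
        rd = sum(r for (a, b, r) in rd_segments if a <= t < b)
        return rc, rd

    times = np.asarray(times, dtype=float)
    out = np.zeros_like(times)
    y = np.zeros(2)  # depot amount, central amount (ng)
    done = times <= 0.0
    for a, b in zip(grid, grid[1:]):
        for (tb, amt) in boluses:
            if abs(tb - a) < 1e-12:
                y[0] += amt
        rc, rd = rates_at(0.5 * (a + b))

        def rhs(t, y):
            return [rd - params.ka * y[0], rc + params.ka * y[0] - k * y[1]]

        sel = (~done) & (times > a) & (times <= b + 1e-12)
        t_eval = np.unique(np.append(np.clip(times[sel], a, b), b))
        sol = solve_ivp(
            rhs, (a, b), y, method="LSODA", rtol=1e-11, atol=1e-8, t_eval=t_eval
        )
        if not sol.success:
            raise IntegrationError(
                f"ODE integration failed on segment starting at t={a} h: {sol.message}"
            )
        out[sel] = np.interp(np.clip(times[sel], a, b), sol.t, sol.y[1]) / params.V
        done |= sel
        y = sol.y[:, -1]
    return out


def ode_oracle(
    params: DualRouteParams,
    regimen: Regimen,
    times,
    drug: str,
    subject_id: str = "typical",
    week_effect_mode: str = "persist",
) -> ConcProfile:
    """Numerical-integration reference for :func:`simulate_profile`.

    Uses the same occasion-covariate convention for the week-3 effect: the
    system is integrated once per parameter set and each output time takes the
    value from its week's set.
    """
    _check_drug(drug)
    times = np.asarray(times, dtype=float)
    events = regimen.events_for(drug)
    if not events:
        return ConcProfile(drug, times, np.zeros_like(times), subject_id)
    base = _ode_conc(params, events, times, drug)
    p3 = params.at_week(3, "persist")
    if p3 is params or week_effect_mode == "off":
        conc = base
    else:
        conc = _select_by_week(times, base, _ode_conc(p3, events, times, drug), week_effect_mode)
    return ConcProfile(drug, times, conc, subject_id)
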