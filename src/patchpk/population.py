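"""Population layer: interindividual variability and regimen-scale simulation.

A :class:`PopulationModel` couples the typical structural parameters with
log-normal interindividual variability (IIV) on the drug-specific random-effect
set — volume, clearance and ka for EE; volume, clearance and the route-split
fraction F_rel for LNG (F_rel varies on the logit scale so individual values
stay in [0, 1]) — plus a residual-error model used only when observations are
generated.  Extended-regimen simulation draws individuals, applies the week-3
occasion effect, and evaluates the closed-form superposition on an hourly grid
for each requested wear week with no residual noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError, ParameterError
from .structural import (
    WEEK_H,
    ConcProfile,
    DualRouteParams,
    Regimen,
    dual_route_conc,
    _select_by_week,
)

#: parameters carrying IIV in the paper-faithful models
IIV_PARAMS = {"EE": ("V", "CL", "ka"), "LNG": ("V", "CL", "F_rel")}
_TRANSFORM = {"CL": "log", "V": "log", "ka": "log", "F_rel": "logit"}


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class ResidualError:
    """Observation-noise model.

    ``proportional`` is multiplicative log-normal, dv = f*exp(prop*eps);
    ``additive`` is dv = f + add*eps (pg/mL); ``combined`` stacks both.
    """

    kind: str = "proportional"
    prop: float = 0.15
    add: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("proportional", "additive", "combined"):
            raise ParameterError(f"unknown residual-error kind {self.kind!r}")
        if self.prop < 0 or self.add < 0:
            raise ParameterError("residual-error magnitudes must be >= 0")

    @property
    def is_zero(self) -> bool:
        return self.prop == 0.0 and self.add == 0.0

    def apply(self, pred: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        dv = np.asarray(pred, dtype=float)
        if self.kind in ("proportional", "combined") and self.prop > 0:
            dv = dv * np.exp(self.prop * rng.standard_normal(dv.shape))
        if self.kind in ("additive", "combined") and self.add > 0:
            dv = dv + self.add * rng.standard_normal(dv.shape)
        return dv


@dataclass(frozen=True)
class PopulationModel:
    """Typical values, IIV standard deviations and residual error for one drug.

    ``omega`` maps parameter names to SDs on the transformed scale (log for
    CL/V/ka, logit for F_rel).  The week-3 multipliers live on ``theta``.
    """

    drug: str
    theta: DualRouteParams
    omega: Mapping[str, float] = field(default_factory=dict)
    sigma: ResidualError = field(default_factory=ResidualError)
    strict_iiv: bool = True

    def __post_init__(self) -> None:
        if self.drug not in IIV_PARAMS:
            raise InputError(f"unknown drug label {self.drug!r}")
        object.__setattr__(self, "omega", dict(self.omega))
        for name, sd in self.omega.items():
            if name not in _TRANSFORM:
                raise ParameterError(f"no IIV transform defined for {name!r}")
            if sd < 0:
                raise ParameterError(f"omega[{name}] must be >= 0")
            if self.strict_iiv and sd > 0 and name not in IIV_PARAMS[self.drug]:
                raise ParameterError(
                    f"{self.drug} carries IIV only on {IIV_PARAMS[self.drug]}"
                )


@dataclass(frozen=True)
class SubjectRealization:
    """One simulated individual: random effects and resulting parameters."""

    subject_id: str
    eta: Mapping[str, float]
    params: DualRouteParams


def individual_params(theta: DualRouteParams, eta: Mapping[str, float]) -> DualRouteParams:
    """Apply transformed-scale random effects to the typical parameters."""
    updates = {}
    for name, e in eta.items():
        base = getattr(theta, name)
        if _TRANSFORM[name] == "log":
            updates[name] = base * float(np.exp(e))
        else:
            updates[name] = float(_expit(_logit(base) + e))
    return replace(theta, **updates) if updates else theta


def draw_subjects(
    pop: PopulationModel, n: int, seed: int
) -> list[SubjectRealization]:
    """Draw ``n`` independent individuals, reproducibly for a fixed seed.

    Each subject consumes its own deterministic substream of the master seed,
    so results are invariant to how many subjects are drawn afterwards.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n)
    names = [p for p in ("CL", "V", "ka", "F_rel") if pop.omega.get(p, 0.0) > 0]
    out = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        eta = {name: float(pop.omega[name] * rng.standard_normal()) for name in names}
        out.append(
            SubjectRealization(f"S{i + 1:04d}", eta, individual_params(pop.theta, eta))
        )
    return out


def apply_week_effect(params: DualRouteParams, week: int, mode: str = "persist") -> DualRouteParams:
    """Parameters effective in the given week (week-3 V/CL occasion effect)."""
    return params.at_week(week, mode)


def week_grid(week: int) -> np.ndarray:
    """Hourly grid over the wear-week window, 169 points, endpoints inclusive."""
    return np.arange((week - 1) * WEEK_H, week * WEEK_H + 0.5, 1.0)


def simulate_population(
    pop: PopulationModel,
    regimen: Regimen,
    weeks: Sequence[int],
    n: int,
    seed: int,
    week_effect_mode: str = "persist",
) -> list[ConcProfile]:
    """Noise-free profiles for ``n`` drawn individuals over the requested weeks.

    Residual variability is never added here; IIV enters through the drawn
    parameters.  Output grids are hourly with 169 points per requested week.
    """
    weeks = sorted(set(int(w) for w in weeks))
    if any(w < 1 or w > regimen.n_weeks for w in weeks):
        raise InputError(
            f"requested weeks {weeks} outside regimen horizon 1..{regimen.n_weeks}"
        )
    subjects = draw_subjects(pop, n, seed)
    times = np.unique(np.concatenate([week_grid(w) for w in weeks]))
    return simulate_subjects(subjects, regimen, times, pop.drug, week_effect_mode)


def simulate_subjects(
    subjects: Sequence[SubjectRealization],
    regimen: Regimen,
    times: np.ndarray,
    drug: str,
    week_effect_mode: str = "persist",
) -> list[ConcProfile]:
    """Vectorized closed-form evaluation of many individuals on one grid."""
    events = regimen.events_for(drug)
    dose_times = [e.t_app for e in events]
    amounts_ng = [e.amount * 1e6 for e in events]
    times = np.asarray(times, dtype=float)

    def stack(attr, week):
        return np.array(
            [getattr(s.params.at_week(week, "persist"), attr) for s in subjects]
        )[:, None]

    def conc_at(week):
        return dual_route_conc(
            times, dose_times, amounts_ng, drug,
            stack("CL", week), stack("V", week), stack("ka", week),
            stack("F", week), stack("F_rel", week), stack("D1", week),
            stack("D2", week),
        )

    base = conc_at(1)
    any_effect = any(
        s.params.wk3_V_mult != 1.0 or s.params.wk3_CL_mult != 1.0 for s in subjects
    )
    if any_effect and week_effect_mode != "off":
        conc = _select_by_week(times, base, conc_at(3), week_effect_mode)
    else:
        conc = base
    return [
        ConcProfile(drug, times, conc[i], s.subject_id)
        for i, s in enumerate(subjects)
    ]
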