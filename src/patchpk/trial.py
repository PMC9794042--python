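"""Synthetic trial generator emulating the source study's cycle-2 PK design.

The original phase-1 study (ATI-CL14) sampled 18 patch-wearing subjects during
the first and third wear weeks of a 28-day cycle: immediately before each
application and 6, 12, 24, 48, 72, 120, 144 and 168 h afterwards, plus 174,
180, 192, 216 and 240 h after the third application — 23 samples per subject
once the shared window joins are deduplicated.  Assay lower limits of
quantification are 2 pg/mL (EE) and 50 pg/mL (LNG).  Those data are not
public, so this module generates statistically comparable observations from a
:class:`~patchpk.population.PopulationModel` for estimator testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .population import PopulationModel, draw_subjects, simulate_subjects
from .structural import WEEK_H, Regimen, _check_drug, weekly_regimen

#: within-week sampling offsets, h after a patch application
_WEEK_OFFSETS = (0.0, 6.0, 12.0, 24.0, 48.0, 72.0, 120.0, 144.0, 168.0)
#: additional offsets after the third (final) application
_POST_WEEK3_OFFSETS = (174.0, 180.0, 192.0, 216.0, 240.0)

LLOQ = {"EE": 2.0, "LNG": 50.0}


@dataclass(frozen=True)
class SamplingDesign:
    """Subject count, within-cycle sampling times and assay LLOQ."""

    n_subjects: int
    sample_times: tuple[float, ...]  # h from the cycle's first application
    lloq: float

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InputError("n_subjects must be >= 1")
        times = tuple(float(t) for t in self.sample_times)
        if list(times) != sorted(times) or (times and times[0] < 0):
            raise InputError("sample times must be sorted and non-negative")
        object.__setattr__(self, "sample_times", times)
        if not self.lloq > 0:
            raise InputError("lloq must be positive")


def ati_cl14_design(drug: str, n_subjects: int = 18) -> SamplingDesign:
    """The cycle-2 sampling design of the source trial: 23 samples/subject."""
    _check_drug(drug)
    week1 = _WEEK_OFFSETS
    week3 = tuple(2 * WEEK_H + o for o in _WEEK_OFFSETS + _POST_WEEK3_OFFSETS)
    times = tuple(sorted(set(week1) | set(week3)))
    return SamplingDesign(n_subjects, times, LLOQ[drug])


def ati_cl14_regimen(drugs: Sequence[str] = ("EE", "LNG")) -> Regimen:
    """Three weekly applications followed by a patch-free week (one cycle)."""
    return weekly_regimen(n_weeks=3, drugs=drugs, patch_free_weeks=1.0)


def rich_design(drug: str, n_subjects: int = 50) -> SamplingDesign:
    """A dense phase-1 style schedule used for parameter-recovery studies.

    Ten samples in each of the first three wear weeks plus washout samples
    after the final application (37 samples/subject); the washout points
    inform the first-order absorption rate constant.
    """
    _check_drug(drug)
    offsets = (0.0, 6.0, 12.0, 24.0, 48.0, 72.0, 96.0, 120.0, 144.0, 168.0)
    post = (174.0, 180.0, 192.0, 216.0, 240.0, 288.0, 336.0)
    times = set()
    for w in range(3):
        times.update(w * WEEK_H + o for o in offsets)
    times.update(2 * WEEK_H + o for o in post)
    return SamplingDesign(n_subjects, tuple(sorted(times)), LLOQ[drug])


def generate_trial(
    pop: PopulationModel,
    design: SamplingDesign,
    regimen: Regimen,
    seed: int,
    noise_free: bool = False,
    week_effect_mode: str = "persist",
) -> pd.DataFrame:
    """Simulate one trial: one observation record per subject and design time.

    Columns: subject_id, drug, time_h, dv (pg/mL; NaN when censored), blq.
    Residual error follows ``pop.sigma``; values below the LLOQ are censored
    with ``blq=True``.  Refuses a zero-noise sigma unless ``noise_free`` is
    set, since observed data must carry noise.
    """
    if max(design.sample_times) > regimen.horizon_h + 1e-9:
        raise InputError("regimen horizon does not cover the sampling design")
    if pop.sigma.is_zero and not noise_free:
        raise InputError(
            "residual error is zero; pass noise_free=True to generate "
            "noiseless records deliberately"
        )
    subjects = draw_subjects(pop, design.n_subjects, seed)
    times = np.asarray(design.sample_times, dtype=float)
    profiles = simulate_subjects(subjects, regimen, times, pop.drug, week_effect_mode)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD0E]))
    frames = []
    for prof in profiles:
        pred = prof.conc
        dv = pred.copy() if noise_free else pop.sigma.apply(pred, rng)
        blq = dv < design.lloq
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": prof.subject_id,
                    "drug": pop.drug,
                    "time_h": times,
                    "dv": np.where(blq, np.nan, dv),
                    "blq": blq,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_records_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, float_format="%.6g")


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["blq"] = df["blq"].astype(bool)
    return df


def write_nonmem_dataset(
    records: pd.DataFrame, regimen: Regimen, drug: str, path
) -> None:
    """NONMEM-style event records: dosing rows (EVID=1, AMT in ng) interleaved
    with observation rows (EVID=0, DV in pg/mL, MDV/BLQ flags)."""
    rows = []
    subjects = records["subject_id"].unique()
    for i, sid in enumerate(subjects, start=1):
        for e in regimen.events_for(drug):
            rows.append(
                dict(ID=i, TIME=e.t_app, AMT=e.amount * 1e6, RATE=0.0,
                     DV=".", EVID=1, MDV=1, BLQ=0)
            )
        sub = records[records["subject_id"] == sid]
        for _, r in sub.iterrows():
            rows.append(
                dict(ID=i, TIME=r["time_h"], AMT=0.0, RATE=0.0,
                     DV="." if r["blq"] else f"{r['dv']:.6g}",
                     EVID=0, MDV=int(bool(r["blq"])), BLQ=int(bool(r["blq"])))
            )
    df = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"], kind="stable")
    df.to_csv(path, index=False)
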