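"""Kill-fraction time courses from treated/control tumor volumes.

The fraction of tumor killed by treatment at time t is

    f_kill(t) = 1 - [V_i(t) / V_i(t0)] / [V_C(t) / V_C(t0)]

where V_i is the treated subject's volume, V_C the control reference
volume, and t0 the normalization day (treatment start).  Because both
ratios are growth-normalized, f_kill is invariant under rescaling either
series by a positive constant, is exactly 0 at t0, and is strictly below 1
whenever volumes are positive.  Negative values (treated outgrowing the
control) are retained: they carry information about when response onset
occurs.

The control reference V_C is the per-day mean of the control group; the
study compares groups, not paired animals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .io import TumorSeries


@dataclass(frozen=True)
class FkillSeries:
    """Derived kill-fraction time course for one subject.

    ``t0`` is the normalization day; ``times`` start at ``t0`` where the
    kill fraction is identically 0.  ``capped`` marks series whose values
    were clipped at 1 (predictions only; observed f_kill is always < 1).
    """

    subject_id: str
    t0: float
    times: tuple[float, ...]
    fkill: tuple[float, ...]
    capped: bool = False

    def __post_init__(self):
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "fkill", tuple(float(f) for f in self.fkill))
        if len(self.times) != len(self.fkill):
            raise DomainError("times and fkill must have equal length")
        if any(t < self.t0 for t in self.times):
            raise DomainError("all times must be >= t0")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise DomainError("times must be strictly increasing")
        if any(f > 1 + 1e-12 for f in self.fkill):
            raise DomainError("f_kill cannot exceed 1")
        if self.times and self.times[0] == self.t0 and self.fkill[0] != 0.0:
            raise DomainError("f_kill at t0 must be exactly 0")


def compute_fkill(treated: TumorSeries, control_reference: TumorSeries,
                  t0: float = 0.0) -> FkillSeries:
    """Growth-normalized kill fraction of ``treated`` against the control
    reference, for every measurement day >= ``t0`` shared by both series.

    ``t0`` must itself be a shared measurement day (no interpolation).
    """
    shared = sorted(set(treated.days) & set(control_reference.days))
    if t0 not in shared:
        raise DomainError(
            f"t0={t0} is not a shared measurement day of subject "
            f"{treated.subject_id!r} and the control reference"
        )
    vi0 = treated.volume_at(t0)
    vc0 = control_reference.volume_at(t0)
    times, fk = [], []
    for t in shared:
        if t < t0:
            continue
        if t == t0:
            f = 0.0
        else:
            f = 1.0 - (treated.volume_at(t) / vi0) / (control_reference.volume_at(t) / vc0)
        times.append(t)
        fk.append(f)
    return FkillSeries(subject_id=treated.subject_id, t0=t0,
                       times=tuple(times), fkill=tuple(fk))


def group_mean_series(series: list[TumorSeries]) -> pd.DataFrame:
    """Per-day arithmetic mean and sample SD (n-1) of a treatment group.

    All series must share the same measurement-day grid.  Returns a frame
    with columns day, mean_volume, sd_volume, n; SD is NaN when n = 1.
    """
    if not series:
        raise DomainError("empty group")
    grid = series[0].days
    off = [s.subject_id for s in series if s.days != grid]
    if off:
        raise DomainError(f"mismatched measurement days for subjects: {off}")
    vols = np.array([s.volumes for s in series], dtype=float)
    n = vols.shape[0]
    sd = vols.std(axis=0, ddof=1) if n > 1 else np.full(len(grid), np.nan)
    return pd.DataFrame({
        "day": grid,
        "mean_volume": vols.mean(axis=0),
        "sd_volume": sd,
        "n": n,
    })


def control_reference(controls: list[TumorSeries]) -> TumorSeries:
    """The synthetic 'average control' series: per-day mean volume of the
    control group, used as V_C in :func:`compute_fkill`."""
    if not controls:
        raise DomainError("control group is empty")
    stats = group_mean_series(controls)
    return TumorSeries(
        subject_id="control_mean",
        group="control",
        days=tuple(stats["day"]),
        volumes=tuple(stats["mean_volume"]),
    )


@dataclass(frozen=True)
class MechanisticParams:
    """Transport/kill parameters behind the quadratic response coefficient:
    F, drug flux across vessel walls; lambda_k, per-drug-mass cell death
    rate; V_T0, tumor volume at response onset (mm^3)."""

    flux_F: float
    death_rate_lambda_k: float
    v_T0: float

    def __post_init__(self):
        if self.flux_F <= 0 or self.death_rate_lambda_k <= 0 or self.v_T0 <= 0:
            raise DomainError("mechanistic parameters must be strictly positive")


def mechanistic_theta(p: MechanisticParams) -> float:
    """Closed-form quadratic response coefficient theta_f = F*lambda_k/(2*V_T0).

    A forward consistency check only; the pipeline never decomposes a
    fitted theta_f into these constituents.
    """
    return p.flux_F * p.death_rate_lambda_k / (2.0 * p.v_T0)
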