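"""Per-subject quadratic response fitting with onset-day optimization.

The response model is f_kill = theta_f * (t - t0)^2 for t >= t0, a
zero-intercept parabola in shifted time.  The onset day t0 — the first day
the tumor shows positive response — is unknown per subject and is chosen
by exhaustive search over the integer measurement days of the series
(excluding the last two, so at least two points remain to fit).  At each
candidate onset the slope has the closed form

    theta = sum(f * x) / sum(x^2),   x = (t - t0)^2

over the points with t > t0 and f_kill > 0; the candidate minimizing the
residual sum of squares wins, ties going to the earliest onset.

Subjects with fewer than three positive-response points get no R^2 or
p-value and are flagged ineligible, mirroring the study's exclusion of
animals that only began responding on the penultimate measurement day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .fkill import FkillSeries

_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class QuadraticFit:
    """Fitted quadratic response for one subject.

    ``theta_f`` is the response coefficient (per day^2), ``t0`` the fitted
    onset day (absent when no onset could be located), ``n_points`` the
    number of positive-response points used.  ``r_squared`` and ``p_value``
    are absent when fewer than three points were available.
    """

    subject_id: str
    theta_f: float
    t0: Optional[float]
    r_squared: Optional[float]
    p_value: Optional[float]
    n_points: int
    eligible: bool


def _zero_intercept_fit(f: np.ndarray, x: np.ndarray):
    """Closed-form zero-intercept OLS of f on x; returns (slope, rss)."""
    slope = float(f @ x) / float(x @ x)
    if slope < 0:
        slope = 0.0
    rss = float(((f - slope * x) ** 2).sum())
    return slope, rss


def fit_quadratic(fk: FkillSeries, t0_candidates=None) -> QuadraticFit:
    """Fit f_kill = theta_f*(t - t0)^2 with onset-day grid search.

    ``t0_candidates`` overrides the default grid (integer-valued
    measurement days except the last two).  Never raises on unresponsive
    subjects; they come back with ``eligible=False``.
    """
    t = np.asarray(fk.times, dtype=float)
    f = np.asarray(fk.fkill, dtype=float)
    if t0_candidates is None:
        t0_candidates = [d for d in fk.times[:-2] if float(d).is_integer()]

    best = None  # (rss, t0, theta, n_points, f_used, x_used)
    for c in t0_candidates:
        mask = (t > c) & (f > 0)
        n = int(mask.sum())
        if n < 2:
            continue
        x = (t[mask] - c) ** 2
        theta, rss = _zero_intercept_fit(f[mask], x)
        if best is None or rss < best[0] * (1 - _TIE_RTOL):
            best = (rss, float(c), theta, n, f[mask], x)

    if best is None:
        # fall back to single-point candidates so theta is still reported
        for c in t0_candidates:
            mask = (t > c) & (f > 0)
            if mask.sum() == 1:
                x = (t[mask] - c) ** 2
                theta, rss = _zero_intercept_fit(f[mask], x)
                best = (rss, float(c), theta, 1, f[mask], x)
                break
    if best is None:
        return QuadraticFit(fk.subject_id, theta_f=float("nan"), t0=None,
                            r_squared=None, p_value=None, n_points=0,
                            eligible=False)

    rss, t0, theta, n, f_used, x_used = best
    eligible = n >= 3 and theta > 0
    r2 = p = None
    if n >= 3:
        sst = float(((f_used - f_used.mean()) ** 2).sum())
        r2 = 1.0 - rss / sst if sst > 0 else (1.0 if rss == 0 else float("nan"))
        # F-test of the zero-intercept quadratic against the zero model
        ss0 = float((f_used ** 2).sum())
        if rss == 0:
            p = 0.0
        else:
            F = (ss0 - rss) / (rss / (n - 1))
            p = float(stats.f.sf(F, 1, n - 1)) if math.isfinite(F) else 0.0
    return QuadraticFit(fk.subject_id, theta_f=theta, t0=t0, r_squared=r2,
                        p_value=p, n_points=n, eligible=eligible)


def filter_eligible(fits: list[QuadraticFit]):
    """Split fits into (retained, excluded) by the >= 3 positive-response
    points rule, preserving order."""
    retained = [f for f in fits if f.n_points >= 3]
    excluded = [f for f in fits if f.n_points < 3]
    return retained, excluded
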