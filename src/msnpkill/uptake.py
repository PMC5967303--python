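"""Cross-subject uptake-response law: theta_f = A * exp(B * Si).

The quadratic response coefficients fitted per subject are regressed
against tumor silicon content (absolute mass %, the proxy for nanoparticle
accumulation).  The exponential law is fitted by nonlinear least squares
on the untransformed theta scale — not on log(theta) — because the
goodness of fit the analysis reports (R^2 about the mean theta) is defined
on that scale; a log-scale fit weights the small-theta subjects far more
heavily and lands on a visibly different curve.

The optimizer is a damped Gauss-Newton (Levenberg) iteration with the
analytic Jacobian of A*exp(B*Si), started at the closed-form log-linear
regression of ln(theta) on Si.  Only improving steps are accepted, so the
solution's residual sum of squares can never exceed the initializer's.
Convergence: relative RSS change below 1e-12, or 500 iterations (the
latter flags the fit method).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .exceptions import DomainError
from .fkill import FkillSeries

MAX_ITER = 500
RSS_RTOL = 1e-12


@dataclass(frozen=True)
class UptakeModel:
    """Fitted exponential uptake-response law.

    ``A`` has the units of theta_f (per day^2); ``B`` is per Si-mass-%
    unit.  ``r_squared`` is computed on the theta scale.  ``se_A``/``se_B``
    are asymptotic standard errors from the Gauss-Newton normal equations.
    """

    A: float
    B: float
    r_squared: float
    n_subjects: int
    fit_method: str
    residuals: tuple[float, ...] = field(default_factory=tuple)
    se_A: Optional[float] = None
    se_B: Optional[float] = None


def _model(si, A, B):
    return A * np.exp(B * si)


def loglinear_init(si: np.ndarray, theta: np.ndarray):
    """Closed-form initializer: OLS of ln(theta) on Si gives (A0, B0)."""
    B0, lnA0 = np.polyfit(si, np.log(theta), 1)
    return float(np.exp(lnA0)), float(B0)


def fit_exponential(si, theta, fit_method_tag: str = "gauss-newton") -> UptakeModel:
    """Fit theta = A*exp(B*Si) by damped Gauss-Newton least squares.

    Requires at least three (Si, theta) pairs with all theta positive
    (positivity is needed by the log-linear initializer).
    """
    si = np.asarray(si, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if si.shape != theta.shape or si.size < 3:
        raise DomainError("need >= 3 matched (Si, theta) pairs")
    if np.any(theta <= 0):
        raise DomainError("all theta must be positive for the exponential fit")

    A, B = loglinear_init(si, theta)
    r = theta - _model(si, A, B)
    rss = float(r @ r)
    lam = 1e-3
    converged = False
    for _ in range(MAX_ITER):
        e = np.exp(B * si)
        J = np.column_stack([e, A * si * e])  # d(model)/d(A,B)
        JtJ = J.T @ J
        g = J.T @ r
        step_ok = False
        for _ in range(50):
            M = JtJ + lam * np.diag(np.diag(JtJ))
            try:
                delta = np.linalg.solve(M, g)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            A_new, B_new = A + delta[0], B + delta[1]
            r_new = theta - _model(si, A_new, B_new)
            rss_new = float(r_new @ r_new)
            if np.isfinite(rss_new) and rss_new <= rss:
                step_ok = True
                break
            lam *= 10
        if not step_ok:
            break
        improvement = rss - rss_new
        A, B, r, rss = A_new, B_new, r_new, rss_new
        lam = max(lam / 10, 1e-12)
        if improvement <= RSS_RTOL * max(rss, 1e-300):
            converged = True
            break

    method = fit_method_tag if converged else fit_method_tag + ":max-iter"
    sst = float(((theta - theta.mean()) ** 2).sum())
    r2 = 1.0 - rss / sst if sst > 0 else 1.0
    se_A = se_B = None
    dof = si.size - 2
    if dof > 0:
        e = np.exp(B * si)
        J = np.column_stack([e, A * si * e])
        try:
            cov = np.linalg.inv(J.T @ J) * (rss / dof)
            se_A, se_B = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
        except np.linalg.LinAlgError:
            pass
    return UptakeModel(A=float(A), B=float(B), r_squared=r2,
                       n_subjects=int(si.size), fit_method=method,
                       residuals=tuple(float(v) for v in r),
                       se_A=se_A, se_B=se_B)


def confidence_interval(model: UptakeModel, param: str = "B",
                        level: float = 0.95) -> tuple[float, float]:
    """Wald confidence interval for ``A`` or ``B`` using the fit-reported
    standard error and the t quantile with n_subjects - 2 dof.  At the
    study's scale (a handful of animals) these intervals are wide — the
    honest statement of how fragile the cross-subject law is at small n."""
    if param not in ("A", "B"):
        raise DomainError("param must be 'A' or 'B'")
    se = model.se_B if param == "B" else model.se_A
    if se is None:
        raise DomainError("fit reported no standard errors")
    est = model.B if param == "B" else model.A
    q = float(stats.t.ppf(0.5 + level / 2, model.n_subjects - 2))
    return est - q * se, est + q * se


def predict_theta(model: UptakeModel, si: float) -> float:
    """Predicted response coefficient at a given tumor Si mass %."""
    return model.A * float(np.exp(model.B * si))


def predict_fkill_series(model: UptakeModel, si: float, t0: float,
                         times) -> FkillSeries:
    """Predicted kill-fraction time course theta(Si)*(t - t0)^2, capped at 1."""
    th = predict_theta(model, si)
    times = tuple(float(t) for t in times)
    raw = [th * (t - t0) ** 2 for t in times]
    capped = any(v > 1.0 for v in raw)
    fk = tuple(min(v, 1.0) for v in raw)
    return FkillSeries(subject_id=f"predicted(si={si:g})", t0=t0,
                       times=times, fkill=fk, capped=capped)


@dataclass(frozen=True)
class PredictionSet:
    """Pooled observed-vs-predicted kill fractions and their Pearson
    correlation; per-subject correlations kept for transparency."""

    subjects: tuple[str, ...]
    observed: tuple[float, ...]
    predicted: tuple[float, ...]
    pearson_r: float
    p_value: float
    per_subject_r: dict


def validate_predictions(observed: list[FkillSeries],
                         predicted: list[FkillSeries],
                         subject_ids=None) -> PredictionSet:
    """Pearson correlation between observed and model-predicted kill
    fractions, pooled over all subjects' post-onset days (t > t0).

    ``observed`` and ``predicted`` are matched element-wise and must share
    day grids.  Requires at least three pooled pairs.
    """
    if len(observed) != len(predicted):
        raise DomainError("observed/predicted lists must be matched")
    subject_ids = subject_ids or [o.subject_id for o in observed]
    subs, obs, pred = [], [], []
    per_subject = {}
    for sid, o, p in zip(subject_ids, observed, predicted):
        if o.times != p.times:
            raise DomainError(f"day grids differ for subject {sid!r}")
        so, sp = [], []
        for t, fo, fp in zip(o.times, o.fkill, p.fkill):
            if t > o.t0:
                subs.append(sid)
                obs.append(fo)
                pred.append(fp)
                so.append(fo)
                sp.append(fp)
        if len(so) >= 3 and np.std(so) > 0 and np.std(sp) > 0:
            per_subject[sid] = float(stats.pearsonr(so, sp).statistic)
    if len(obs) < 3:
        raise DomainError("need >= 3 pooled observed/predicted pairs")
    res = stats.pearsonr(obs, pred)
    return PredictionSet(subjects=tuple(subs), observed=tuple(obs),
                         predicted=tuple(pred),
                         pearson_r=float(res.statistic),
                         p_value=float(res.pvalue),
                         per_subject_r=per_subject)


def linear_baseline_r2(si, theta) -> float:
    """R^2 of a straight-line fit theta = a + b*Si; a sanity baseline for
    comparing against the exponential law."""
    si = np.asarray(si, dtype=float)
    theta = np.asarray(theta, dtype=float)
    b, a = np.polyfit(si, theta, 1)
    rss = float(((theta - (a + b * si)) ** 2).sum())
    sst = float(((theta - theta.mean()) ** 2).sum())
    return 1.0 - rss / sst if sst > 0 else 1.0
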