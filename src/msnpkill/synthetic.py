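"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator inverts the analysis chain: exponentially growing control
tumors, treated tumors that follow control kinetics until a subject-
specific onset day and then lose a quadratically growing kill fraction,
a cross-subject exponential law tying the response coefficient to tumor
silicon content, and linear standard-additions signal curves.  Every
latent quantity (Si, theta, onset day, growth rate) is returned as ground
truth, so parameter-recovery tests can close the loop.

One global seed drives a hierarchical seed tree (cohort -> subject), so
the same spec and seed reproduce the cohort bitwise and per-subject
streams do not interact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import GenerationError, ValidationError
from .gfaa import AdditionCurve
from .io import BiodistributionRecord, TumorSeries

KILL_CAP = 0.99  # generator-side cap keeping volumes positive


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for one synthetic study arm pair.

    Defaults (see :func:`table1_like_cohort`) mirror the study design:
    7 mice per group, measurements on days 0/3/7/8/9, ~500 mm^3 tumors at
    treatment start.  ``theta_law`` holds (A, B) of the exponential
    uptake-response law; ``t0_distribution`` weights candidate integer
    onset days; noise SDs are lognormal sigmas (multiplicative noise).
    """

    n_per_group: int = 7
    measurement_days: tuple[float, ...] = (0.0, 3.0, 7.0, 8.0, 9.0)
    control_v0: float = 500.0          # mm^3
    growth_rate: float = 0.12          # per day, exponential control growth
    theta_law: tuple[float, float] = (6.31e-4, 460.5)   # (A, B)
    si_range: tuple[float, float] = (0.001, 0.006)      # mass %
    t0_distribution: dict = field(
        default_factory=lambda: {0.0: 0.7, 3.0: 0.15, 7.0: 0.15})
    noise_sd_volume: float = 0.1       # lognormal sigma on volumes
    noise_sd_theta: float = 0.2        # lognormal sigma on theta
    gfaa_additions: tuple[float, ...] = (0.0, 0.002, 0.004, 0.008)
    gfaa_slope: float = 100.0          # signal units per concentration unit
    gfaa_noise_sd: float = 0.005       # signal units, additive gaussian
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1 or self.control_v0 <= 0 or self.growth_rate <= 0:
            raise ValidationError("cohort sizes, volumes and rates must be positive")
        days = self.measurement_days
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError("measurement_days must be strictly increasing")
        lo, hi = self.si_range
        if not (0 <= lo < hi <= 0.02):
            raise ValidationError("si_range must lie within [0, 0.02] mass %")
        if any(d not in days for d in self.t0_distribution):
            raise ValidationError("t0_distribution days must be measurement days")
        if self.gfaa_slope <= 0:
            raise ValidationError("gfaa_slope must be positive")


def table1_like_cohort(seed: int) -> CohortSpec:
    """A ready-made spec whose marginals resemble the study: Si uniform on
    [0.001, 0.006] mass %, theta spanning [0.001, 0.01] per day^2 (the
    default exponential law maps the Si range onto exactly that span)."""
    return CohortSpec(seed=int(seed))


def _control_volumes(spec: CohortSpec, days: np.ndarray) -> np.ndarray:
    return spec.control_v0 * np.exp(spec.growth_rate * days)


def simulate_cohort(spec: CohortSpec):
    """Generate one synthetic cohort.

    Returns ``(tumor_series, biodistribution, gfaa_curves, truth)`` where
    ``truth`` is a DataFrame of every latent (subject_id, si_true,
    theta_true, t0_true, growth_rate).  Control subjects grow
    exponentially; each treated subject follows control kinetics until its
    onset day and then carries kill fraction min(theta*(t-t0)^2, 0.99).
    Multiplicative lognormal measurement noise is applied to volumes last.
    """
    days = np.asarray(spec.measurement_days, dtype=float)
    root = np.random.SeedSequence(spec.seed)
    control_seeds, treated_seeds = root.spawn(2)
    ctrl_streams = control_seeds.spawn(spec.n_per_group)
    trt_streams = treated_seeds.spawn(spec.n_per_group)

    vc_ideal = _control_volumes(spec, days)

    series: list[TumorSeries] = []
    for i, ss in enumerate(ctrl_streams):
        rng = np.random.default_rng(ss)
        noise = np.exp(rng.normal(0.0, spec.noise_sd_volume, size=days.size)) \
            if spec.noise_sd_volume > 0 else np.ones(days.size)
        series.append(TumorSeries(f"CTRL {i + 1}", "control",
                                  tuple(days), tuple(vc_ideal * noise)))

    t0_days = np.array(sorted(spec.t0_distribution), dtype=float)
    t0_w = np.array([spec.t0_distribution[d] for d in t0_days], dtype=float)
    t0_w = t0_w / t0_w.sum()
    A, B = spec.theta_law

    biodist: list[BiodistributionRecord] = []
    curves: list[AdditionCurve] = []
    truth_rows = []
    for i, ss in enumerate(trt_streams):
        rng = np.random.default_rng(ss)
        sid = f"MSNP {i + 1}"
        si = float(rng.uniform(*spec.si_range))
        theta = A * np.exp(B * si)
        if spec.noise_sd_theta > 0:
            theta *= float(np.exp(rng.normal(0.0, spec.noise_sd_theta)))
        t0 = float(rng.choice(t0_days, p=t0_w))
        kill = np.where(days >= t0,
                        np.minimum(theta * (days - t0) ** 2, KILL_CAP), 0.0)
        vols = vc_ideal * (1.0 - kill)
        if spec.noise_sd_volume > 0:
            vols = vols * np.exp(rng.normal(0.0, spec.noise_sd_volume,
                                            size=days.size))
        if np.any(vols <= 0):
            bad = days[np.argmax(vols <= 0)]
            raise GenerationError(f"subject {sid}: non-positive volume at day {bad}")
        series.append(TumorSeries(sid, "nanoparticle", tuple(days), tuple(vols)))
        biodist.append(BiodistributionRecord(sid, "tumor", si))

        adds = np.asarray(spec.gfaa_additions, dtype=float)
        signal = spec.gfaa_slope * (si + adds)
        if spec.gfaa_noise_sd > 0:
            signal = signal + rng.normal(0.0, spec.gfaa_noise_sd, size=adds.size)
        curves.append(AdditionCurve(sid, "tumor", tuple(adds), tuple(signal)))
        truth_rows.append({"subject_id": sid, "si_true": si,
                           "theta_true": float(theta), "t0_true": t0,
                           "growth_rate": spec.growth_rate})

    truth = pd.DataFrame(truth_rows,
                         columns=["subject_id", "si_true", "theta_true",
                                  "t0_true", "growth_rate"])
    return series, biodist, curves, truth
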