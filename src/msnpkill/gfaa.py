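"""Standard-additions Si quantification and delivery efficiency (%ID).

Graphite-furnace atomic absorption signals from digested tissue are
matrix-sensitive, so each sample is quantified by the method of standard
additions: the sample is spiked with known Si increments, the signal is
regressed linearly on the added concentration, and the native
concentration is the magnitude of the x-intercept, b/m.  The standard
deviation of that estimate follows the usual x-intercept propagation

    sd = (s_yx / m) * sqrt(1/n + ybar^2 / (m^2 * sum((x - xbar)^2)))

with s_yx the residual standard error of the line.

Delivery efficiency converts a baseline-subtracted tissue Si mass % into
the percent of the injected Si dose recovered in that organ, using
strain-standard reference organ masses (per-animal organ masses are not
measured in this design).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .exceptions import DomainError, QuantificationError, ValidationError
from .io import BiodistributionRecord, StudyConfig


@dataclass(frozen=True)
class AdditionCurve:
    """One sample's signal-vs-added-concentration curve.

    Additions share one concentration unit (declared by the data file and
    carried through unchanged); signals are instrument absorbance in
    arbitrary units.
    """

    sample_id: str
    tissue: str
    additions: tuple[float, ...]
    signals: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "additions", tuple(float(a) for a in self.additions))
        object.__setattr__(self, "signals", tuple(float(s) for s in self.signals))
        if len(self.additions) != len(self.signals) or len(self.additions) < 3:
            raise ValidationError(
                f"sample {self.sample_id!r}: need >= 3 matched (addition, signal) points"
            )
        if 0.0 not in self.additions:
            raise ValidationError(f"sample {self.sample_id!r}: additions must include 0")
        if any(a < 0 for a in self.additions):
            raise ValidationError(f"sample {self.sample_id!r}: negative addition")
        if len(set(self.additions)) < 2:
            raise ValidationError(f"sample {self.sample_id!r}: additions all equal")


@dataclass(frozen=True)
class SiEstimate:
    """Standard-additions concentration estimate for one sample, in the
    same unit as the additions, with its propagated SD and the fitted
    line's slope/intercept."""

    sample_id: str
    concentration: float
    sd: float
    slope: float
    intercept: float


def standard_additions(curve: AdditionCurve) -> SiEstimate:
    """Quantify native Si in one sample from its additions curve.

    Fits signal = m*addition + b by OLS; the concentration is b/m.  A
    non-positive slope means the signal does not increase with added Si
    and the sample cannot be quantified.
    """
    x = np.asarray(curve.additions, dtype=float)
    y = np.asarray(curve.signals, dtype=float)
    m, b = np.polyfit(x, y, 1)
    if m <= 0:
        raise QuantificationError(
            f"sample {curve.sample_id!r}: fitted slope {m:g} <= 0; "
            "signal must increase with added Si"
        )
    n = x.size
    resid = y - (m * x + b)
    rss = float(resid @ resid)
    s_yx = np.sqrt(rss / (n - 2)) if n > 2 else 0.0
    sxx = float(((x - x.mean()) ** 2).sum())
    sd = (s_yx / m) * np.sqrt(1.0 / n + y.mean() ** 2 / (m ** 2 * sxx))
    return SiEstimate(sample_id=curve.sample_id,
                      concentration=float(b / m), sd=float(sd),
                      slope=float(m), intercept=float(b))


class NetSi(NamedTuple):
    """Baseline-subtracted Si mass % with a below-baseline flag."""

    value: float
    below_baseline: bool


def subtract_baseline(record: BiodistributionRecord, config: StudyConfig) -> NetSi:
    """Subtract the organ's naturally-occurring Si baseline.

    Negative nets (measurement below the untreated-tissue baseline) are
    reported as-is with a flag; delivery-efficiency math treats them as 0.
    """
    if record.organ not in config.control_baseline:
        raise DomainError(f"no control baseline configured for organ {record.organ!r}")
    net = record.si_mass_percent - config.control_baseline[record.organ]
    return NetSi(value=net, below_baseline=net < 0)


def delivery_efficiency(net_si_mass_percent: float, organ: str,
                        config: StudyConfig) -> float:
    """Percent of the injected Si dose recovered in one organ.

    organ Si mass = (net mass % / 100) * reference organ mass;
    %ID = 100 * organ Si mass / total injected Si mass.  Negative nets
    (below baseline) contribute 0.
    """
    if organ not in config.organ_reference_masses:
        raise DomainError(f"no reference mass configured for organ {organ!r}")
    injected = config.injected_si_mass
    if injected <= 0:
        raise DomainError("injected Si mass must be positive")
    net = max(net_si_mass_percent, 0.0)
    organ_si_mg = (net / 100.0) * config.organ_reference_masses[organ] * 1000.0  # g -> mg
    return 100.0 * organ_si_mg / injected
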