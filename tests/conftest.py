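import numpy as np
import pytest

from msnpkill import TumorSeries


@pytest.fixture
def control_series():
    """Exponentially growing control, 500 mm^3 at day 0, rate 0.12/day."""
    days = (0.0, 3.0, 7.0, 8.0, 9.0)
    return TumorSeries("CTRL 1", "control", days,
                       tuple(500.0 * np.exp(0.12 * d) for d in days))


@pytest.fixture
def study_config():
    from msnpkill import default_study_config
    return default_study_config()


def make_treated(control: TumorSeries, theta: float, t0: float,
                 subject_id: str = "T1") -> TumorSeries:
    """Treated series following control kinetics with kill fraction
    theta*(t - t0)^2 after onset; the analytic inverse of compute_fkill."""
    vols = []
    for d, vc in zip(control.days, control.volumes):
        kill = theta * (d - t0) ** 2 if d >= t0 else 0.0
        vols.append(vc * (1.0 - min(kill, 0.99)))
    return TumorSeries(subject_id, "nanoparticle", control.days, tuple(vols))
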