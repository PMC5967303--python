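"""Tabular input/output, study configuration, and the packaged
tumor-response fixture.

All tables are comma-separated with a header row, decimal points, UTF-8.
Silicon content is always expressed as absolute mass percent of tissue
(0.00372 means 0.00372%); no function in this package converts to or from
fractional scale.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .exceptions import FormatError, ValidationError

VALID_GROUPS = frozenset({"control", "free_drug", "nanoparticle"})
VALID_ORGANS = frozenset({"tumor", "liver", "spleen", "kidney"})

TUMOR_COLUMNS = ("subject_id", "group", "day", "volume_mm3")
BIODIST_COLUMNS = ("subject_id", "organ", "si_mass_percent")
GFAA_COLUMNS = ("sample_id", "tissue", "addition_si", "signal")


@dataclass(frozen=True)
class TumorSeries:
    """One subject's tumor volume time course.

    Days are relative to treatment start (day 0 = first dose) and may be
    non-integer for synthetic data; volumes are mm^3.
    """

    subject_id: str
    group: str
    days: tuple[float, ...]
    volumes: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "days", tuple(float(d) for d in self.days))
        object.__setattr__(self, "volumes", tuple(float(v) for v in self.volumes))
        if self.group not in VALID_GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r} for subject {self.subject_id!r}; "
                f"expected one of {sorted(VALID_GROUPS)}"
            )
        if len(self.days) != len(self.volumes) or len(self.days) < 1:
            raise ValidationError(
                f"subject {self.subject_id!r}: days and volumes must have equal "
                f"length >= 1"
            )
        if any(d < 0 for d in self.days):
            raise ValidationError(f"subject {self.subject_id!r}: negative day")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValidationError(
                f"subject {self.subject_id!r}: days must be strictly increasing"
            )
        if any(v <= 0 for v in self.volumes):
            raise ValidationError(
                f"subject {self.subject_id!r}: volumes must be positive"
            )

    def volume_at(self, day: float) -> float:
        for d, v in zip(self.days, self.volumes):
            if d == day:
                return v
        raise KeyError(f"day {day} not in series for {self.subject_id!r}")


@dataclass(frozen=True)
class BiodistributionRecord:
    """Absolute Si mass percent measured in one organ of one subject."""

    subject_id: str
    organ: str
    si_mass_percent: float

    def __post_init__(self):
        if self.organ not in VALID_ORGANS:
            raise ValidationError(
                f"unknown organ {self.organ!r}; expected one of {sorted(VALID_ORGANS)}"
            )
        if not (0 <= self.si_mass_percent < 1):
            raise ValidationError(
                f"si_mass_percent {self.si_mass_percent} outside [0, 1) mass % "
                f"for subject {self.subject_id!r}"
            )


@dataclass(frozen=True)
class StudyConfig:
    """Dosing and organ-reference constants for delivery-efficiency math.

    ``si_fraction`` is the silicon mass fraction of the particle (0.3936
    for these MSNPs); ``organ_reference_masses`` are strain-standard organ
    masses in grams used when per-animal masses were not measured;
    ``control_baseline`` holds mean naturally-occurring Si mass % per organ.
    """

    particle_mass_per_dose: float = 1.0  # mg
    n_doses: int = 4
    si_fraction: float = 0.3936
    organ_reference_masses: dict[str, float] = field(default_factory=dict)
    control_baseline: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.si_fraction <= 1):
            raise ValidationError("si_fraction must be in (0, 1]")
        if self.n_doses < 1:
            raise ValidationError("n_doses must be >= 1")
        if self.particle_mass_per_dose <= 0:
            raise ValidationError("particle_mass_per_dose must be positive")
        if any(m <= 0 for m in self.organ_reference_masses.values()):
            raise ValidationError("organ reference masses must be positive")

    @property
    def injected_si_mass(self) -> float:
        """Total injected Si mass (mg) over the course of treatment."""
        return self.si_fraction * self.particle_mass_per_dose * self.n_doses


def read_tumor_table(path) -> list[TumorSeries]:
    """Read a tumor volume table into one day-sorted series per subject.

    Required columns: subject_id, group, day, volume_mm3.  Rows may appear
    in any order; duplicate (subject, day) rows are rejected.
    """
    df = pd.read_csv(path)
    for col in TUMOR_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"tumor table {path}: missing column {col!r}")
    bad = df.index[df["volume_mm3"] <= 0]
    if len(bad):
        # +2: 1-based rows plus the header line
        raise ValidationError(
            f"tumor table {path}: non-positive volume at row {bad[0] + 2}"
        )
    out = []
    for (sid, grp), sub in df.groupby(["subject_id", "group"], sort=True):
        sub = sub.sort_values("day")
        if sub["day"].duplicated().any():
            raise ValidationError(f"tumor table {path}: duplicate day for {sid!r}")
        out.append(
            TumorSeries(
                subject_id=str(sid),
                group=str(grp),
                days=tuple(sub["day"]),
                volumes=tuple(sub["volume_mm3"]),
            )
        )
    return out


def write_tumor_table(series: list[TumorSeries], path) -> None:
    rows = [
        {"subject_id": s.subject_id, "group": s.group, "day": d, "volume_mm3": v}
        for s in series
        for d, v in zip(s.days, s.volumes)
    ]
    pd.DataFrame(rows, columns=list(TUMOR_COLUMNS)).to_csv(path, index=False)


def read_biodistribution_table(path) -> list[BiodistributionRecord]:
    df = pd.read_csv(path)
    for col in BIODIST_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"biodistribution table {path}: missing column {col!r}")
    return [
        BiodistributionRecord(str(r.subject_id), str(r.organ), float(r.si_mass_percent))
        for r in df.itertuples()
    ]


def write_biodistribution_table(records: list[BiodistributionRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records],
                 columns=list(BIODIST_COLUMNS)).to_csv(path, index=False)


def read_gfaa_table(path):
    """Read standard-additions raw data into one AdditionCurve per sample."""
    from .gfaa import AdditionCurve

    df = pd.read_csv(path)
    for col in GFAA_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"GFAA table {path}: missing column {col!r}")
    curves = []
    for (sid, tissue), sub in df.groupby(["sample_id", "tissue"], sort=True):
        sub = sub.sort_values("addition_si")
        curves.append(
            AdditionCurve(
                sample_id=str(sid),
                tissue=str(tissue),
                additions=tuple(sub["addition_si"]),
                signals=tuple(sub["signal"]),
            )
        )
    return curves


def write_gfaa_table(curves, path) -> None:
    rows = [
        {"sample_id": c.sample_id, "tissue": c.tissue, "addition_si": a, "signal": s}
        for c in curves
        for a, s in zip(c.additions, c.signals)
    ]
    pd.DataFrame(rows, columns=list(GFAA_COLUMNS)).to_csv(path, index=False)


def read_study_config(path) -> StudyConfig:
    """Load a StudyConfig from YAML (keys particle_mass_per_dose_mg,
    n_doses, si_fraction, organ_reference_masses, control_baseline)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return StudyConfig(
            particle_mass_per_dose=float(raw["particle_mass_per_dose_mg"]),
            n_doses=int(raw["n_doses"]),
            si_fraction=float(raw["si_fraction"]),
            organ_reference_masses={k: float(v) for k, v in raw["organ_reference_masses"].items()},
            control_baseline={k: float(v) for k, v in raw["control_baseline"].items()},
        )
    except KeyError as exc:
        raise FormatError(f"study config {path}: missing key {exc}") from exc


def default_study_config() -> StudyConfig:
    """The packaged default configuration (1 mg particles x 4 doses,
    39.36% Si, BALB/c strain-standard organ masses)."""
    with resources.files("msnpkill._fixtures").joinpath("study_config.yml").open() as fh:
        raw = yaml.safe_load(fh)
    return StudyConfig(
        particle_mass_per_dose=float(raw["particle_mass_per_dose_mg"]),
        n_doses=int(raw["n_doses"]),
        si_fraction=float(raw["si_fraction"]),
        organ_reference_masses={k: float(v) for k, v in raw["organ_reference_masses"].items()},
        control_baseline={k: float(v) for k, v in raw["control_baseline"].items()},
    )


def load_table1_fixture():
    """The published per-mouse tumor response table for the MSNP group.

    Returns ``(records, fits)`` where ``records`` are the seven tumor Si
    measurements and ``fits`` the corresponding quadratic response
    coefficients.  Two mice responded only on the final two measurement
    days; their onset day, p-value and R^2 are absent and they carry
    ``eligible=False``.  ``n_points`` for the responding mice reflects the
    four post-onset measurement days of the study schedule.
    """
    from .response import QuadraticFit

    path = resources.files("msnpkill._fixtures").joinpath("table1.csv")
    with path.open() as fh:
        df = pd.read_csv(fh)
    records, fits = [], []
    for r in df.itertuples():
        records.append(
            BiodistributionRecord(str(r.mouse), "tumor", float(r.si_mass_percent))
        )
        n_points = int(r.n_points)
        fits.append(
            QuadraticFit(
                subject_id=str(r.mouse),
                theta_f=float(r.theta_f),
                t0=None if pd.isna(r.t0) else float(r.t0),
                r_squared=None if pd.isna(r.r_squared) else float(r.r_squared),
                p_value=None if pd.isna(r.p_value) else float(r.p_value),
                n_points=n_points,
                eligible=n_points >= 3,
            )
        )
    return records, fits


@dataclass
class FitReport:
    """Aggregated pipeline output: per-subject quadratic fits, the
    cross-subject uptake model, validation correlation, and provenance."""

    fits: list
    uptake: Optional[object] = None
    validation_r: Optional[float] = None
    validation_p: Optional[float] = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "fits": [dataclasses.asdict(f) for f in self.fits],
            "uptake": None if self.uptake is None else dataclasses.asdict(self.uptake),
            "validation_r": self.validation_r,
            "validation_p": self.validation_p,
            "provenance": self.provenance,
        }
        return d

    def write(self, directory) -> None:
        """Write report.json (machine-readable) and report.txt (human)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
        with open(directory / "report.txt", "w") as fh:
            fh.write(self.render_text())

    def render_text(self) -> str:
        lines = ["per-subject quadratic response fits",
                 "subject_id theta_f t0 n_points r_squared p_value eligible"]
        for f in self.fits:
            lines.append(
                f"{f.subject_id} {f.theta_f!r} {f.t0!r} {f.n_points} "
                f"{f.r_squared!r} {f.p_value!r} {f.eligible}"
            )
        if self.uptake is not None:
            u = self.uptake
            lines += ["", "uptake model theta = A*exp(B*Si)",
                      f"A {u.A!r}", f"B {u.B!r}", f"r_squared {u.r_squared!r}",
                      f"n_subjects {u.n_subjects}", f"fit_method {u.fit_method}"]
        if self.validation_r is not None:
            lines += ["", f"validation pearson r {self.validation_r!r} "
                          f"p {self.validation_p!r}"]
        if self.provenance:
            lines += ["", "provenance"]
            lines += [f"{k} {v}" for k, v in sorted(self.provenance.items())]
        return "\n".join(lines) + "\n"

    @classmethod
    def read(cls, directory) -> "FitReport":
        from .response import QuadraticFit
        from .uptake import UptakeModel

        with open(Path(directory) / "report.json") as fh:
            d = json.load(fh)
        fits = [QuadraticFit(**f) for f in d["fits"]]
        uptake = None
        if d["uptake"] is not None:
            u = dict(d["uptake"])
            u["residuals"] = tuple(u["residuals"])
            uptake = UptakeModel(**u)
        return cls(
            fits=fits,
            uptake=uptake,
            validation_r=d["validation_r"],
            validation_p=d["validation_p"],
            provenance=d["provenance"],
        )
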