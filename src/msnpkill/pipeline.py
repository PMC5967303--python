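"""End-to-end orchestration of the analysis stages.

Each ``run_*`` function is a complete pipeline stage operating on files:
it reads the delimited inputs, calls the library, and writes result
tables plus a provenance block sufficient to re-execute identically.
The CLI and the numbered analysis drivers are thin wrappers over these.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .exceptions import ConfigurationError, QuantificationError
from .fkill import FkillSeries, compute_fkill, control_reference
from .gfaa import delivery_efficiency, standard_additions, subtract_baseline
from .io import (FitReport, StudyConfig, default_study_config,
                 load_table1_fixture, read_biodistribution_table,
                 read_gfaa_table, read_tumor_table, write_biodistribution_table,
                 write_gfaa_table, write_tumor_table)
from .response import filter_eligible, fit_quadratic
from .synthetic import CohortSpec, simulate_cohort, table1_like_cohort
from .uptake import (fit_exponential, linear_baseline_r2, predict_fkill_series,
                     validate_predictions)

log = logging.getLogger("msnpkill")


@dataclass
class RunConfig:
    """Paths, flags and seed for one pipeline run; recorded in every report."""

    out_dir: Path
    tumor_table: Optional[Path] = None
    biodist_table: Optional[Path] = None
    gfaa_table: Optional[Path] = None
    study_config: Optional[StudyConfig] = None
    include_excluded_mice: bool = False
    reference_subject: Optional[str] = None
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def provenance(self) -> dict:
        # hash covers only settings that affect the computation, not
        # where the results land
        keyable = {k: str(v) for k, v in dataclasses.asdict(self).items()
                   if k not in ("extras", "out_dir")}
        digest = hashlib.sha256(
            json.dumps(keyable, sort_keys=True).encode()).hexdigest()[:16]
        return {"seed": self.seed, "config_hash": digest,
                "version": __version__}


def run_simulate(spec: CohortSpec, out_dir) -> Path:
    """Generate a synthetic cohort and write its four tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series, biodist, curves, truth = simulate_cohort(spec)
    write_tumor_table(series, out_dir / "tumors.csv")
    write_biodistribution_table(biodist, out_dir / "biodist.csv")
    write_gfaa_table(curves, out_dir / "gfaa.csv")
    truth.to_csv(out_dir / "truth.csv", index=False)
    log.info("simulated cohort (seed=%d) -> %s", spec.seed, out_dir)
    return out_dir


def run_fit_response(cfg: RunConfig) -> FitReport:
    """Kill-fraction computation and per-subject quadratic fits.

    Requires both a control and a nanoparticle group in the tumor table.
    Writes response_fits.csv and a report pair under ``cfg.out_dir``.
    """
    if cfg.tumor_table is None:
        raise ConfigurationError("fit-response needs a tumor table")
    series = read_tumor_table(cfg.tumor_table)
    controls = [s for s in series if s.group == "control"]
    treated = [s for s in series if s.group == "nanoparticle"]
    if not controls or not treated:
        raise ConfigurationError(
            "tumor table must contain both control and nanoparticle groups"
        )
    if cfg.reference_subject is not None:
        ref = next((s for s in controls if s.subject_id == cfg.reference_subject),
                   None)
        if ref is None:
            raise ConfigurationError(
                f"reference subject {cfg.reference_subject!r} not in control group")
    else:
        ref = control_reference(controls)
    fits = []
    for s in treated:
        fk = compute_fkill(s, ref, t0=0.0)
        fit = fit_quadratic(fk)
        log.info("subject %s: onset t0=%s theta=%s n=%d eligible=%s",
                 s.subject_id, fit.t0, fit.theta_f, fit.n_points, fit.eligible)
        fits.append(fit)
    report = FitReport(fits=fits, provenance=cfg.provenance())
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([dataclasses.asdict(f) for f in fits]).to_csv(
        out / "response_fits.csv", index=False)
    report.write(out)
    return report


def run_fit_uptake(cfg: RunConfig) -> FitReport:
    """Cross-subject exponential uptake-response fit, with optional
    prediction validation when the tumor table is also supplied.

    Needs a quadratic-fit table (response_fits.csv) under ``extras`` or an
    in-memory list of fits, plus the biodistribution table, with at least
    three matched eligible subjects.
    """
    fits = cfg.extras.get("fits")
    if fits is None:
        fits_path = cfg.extras.get("fits_table")
        if fits_path is None:
            raise ConfigurationError("fit-uptake needs a quadratic-fit table")
        from .response import QuadraticFit
        df = pd.read_csv(fits_path)
        fits = [
            QuadraticFit(
                subject_id=str(r.subject_id), theta_f=float(r.theta_f),
                t0=None if pd.isna(r.t0) else float(r.t0),
                r_squared=None if pd.isna(r.r_squared) else float(r.r_squared),
                p_value=None if pd.isna(r.p_value) else float(r.p_value),
                n_points=int(r.n_points), eligible=bool(r.eligible))
            for r in df.itertuples()
        ]
    if cfg.biodist_table is None:
        raise ConfigurationError("fit-uptake needs a biodistribution table")
    biodist = read_biodistribution_table(cfg.biodist_table)
    si_by_subject = {b.subject_id: b.si_mass_percent
                     for b in biodist if b.organ == "tumor"}
    pool = fits if cfg.include_excluded_mice else filter_eligible(fits)[0]
    matched = [(f, si_by_subject[f.subject_id]) for f in pool
               if f.subject_id in si_by_subject and f.theta_f > 0]
    if len(matched) < 3:
        raise ConfigurationError(
            f"only {len(matched)} matched subjects with positive theta; need >= 3")
    si = [m[1] for m in matched]
    theta = [m[0].theta_f for m in matched]
    model = fit_exponential(si, theta)
    log.info("uptake law: A=%g B=%g R2=%.4f (n=%d, %s)", model.A, model.B,
             model.r_squared, model.n_subjects, model.fit_method)

    report = FitReport(fits=list(fits), uptake=model,
                       provenance=cfg.provenance())
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {"A": model.A, "B": model.B, "r_squared": model.r_squared,
               "n_subjects": model.n_subjects, "fit_method": model.fit_method}
    if cfg.extras.get("linear_baseline"):
        summary["linear_baseline_r_squared"] = linear_baseline_r2(si, theta)
    pd.DataFrame([summary]).to_csv(out / "uptake_model.csv", index=False)

    # validation against observed time courses, if tumors are available
    if cfg.tumor_table is not None:
        series = read_tumor_table(cfg.tumor_table)
        controls = [s for s in series if s.group == "control"]
        treated = {s.subject_id: s for s in series if s.group == "nanoparticle"}
        ref = control_reference(controls)
        observed, predicted, sids, rows = [], [], [], []
        for f, si_val in matched:
            if f.subject_id not in treated or f.t0 is None:
                continue
            full = compute_fkill(treated[f.subject_id], ref, t0=0.0)
            post = [(t, fo) for t, fo in zip(full.times, full.fkill) if t > f.t0]
            if not post:
                continue
            times = tuple(t for t, _ in post)
            obs = FkillSeries(f.subject_id, t0=f.t0, times=times,
                              fkill=tuple(fo for _, fo in post))
            pred = predict_fkill_series(model, si_val, t0=f.t0, times=times)
            observed.append(obs)
            predicted.append(pred)
            sids.append(f.subject_id)
            for t, fo, fp in zip(obs.times, obs.fkill, pred.fkill):
                rows.append({"subject_id": f.subject_id, "day": t,
                             "observed_fkill": fo, "predicted_fkill": fp})
        if len(observed) >= 1:
            pset = validate_predictions(observed, predicted, subject_ids=sids)
            report.validation_r = pset.pearson_r
            report.validation_p = pset.p_value
            pd.DataFrame(rows).to_csv(out / "predictions.csv", index=False)
            log.info("validation: pooled pearson r=%.3f p=%.2g",
                     pset.pearson_r, pset.p_value)
    report.write(out)
    return report


def run_gfaa(cfg: RunConfig) -> pd.DataFrame:
    """Standard-additions quantification and (if biodistribution data are
    present) the per-organ delivery-efficiency table.

    A curve that cannot be quantified produces an error row; the rest of
    the run is unaffected.
    """
    if cfg.gfaa_table is None:
        raise ConfigurationError("gfaa needs a standard-additions table")
    config = cfg.study_config or default_study_config()
    curves = read_gfaa_table(cfg.gfaa_table)
    rows = []
    for c in curves:
        try:
            est = standard_additions(c)
            rows.append({"sample_id": est.sample_id, "tissue": c.tissue,
                         "si_concentration": est.concentration, "sd": est.sd,
                         "slope": est.slope, "intercept": est.intercept,
                         "error": ""})
        except QuantificationError as exc:
            log.warning("sample %s: %s", c.sample_id, exc)
            rows.append({"sample_id": c.sample_id, "tissue": c.tissue,
                         "si_concentration": float("nan"), "sd": float("nan"),
                         "slope": float("nan"), "intercept": float("nan"),
                         "error": str(exc)})
    estimates = pd.DataFrame(rows)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    estimates.to_csv(out / "si_estimates.csv", index=False)

    if cfg.biodist_table is not None:
        records = read_biodistribution_table(cfg.biodist_table)
        id_rows = []
        for r in records:
            net = subtract_baseline(r, config)
            pid = delivery_efficiency(net.value, r.organ, config)
            id_rows.append({"subject_id": r.subject_id, "organ": r.organ,
                            "net_si_mass_percent": net.value,
                            "percent_id": pid,
                            "flags": "below_baseline" if net.below_baseline else ""})
        pd.DataFrame(id_rows).to_csv(out / "percent_id.csv", index=False)
    return estimates


def run_demo(out_dir, seed: int = 0) -> dict:
    """Single-command end-to-end reproduction on fixture + synthetic data.

    Fits the exponential uptake law to the published per-mouse table, then
    simulates a study-scale cohort, reruns the whole pipeline on it, and
    returns the headline numbers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # published table: exclusion + exponential fit
    records, fits = load_table1_fixture()
    retained, excluded = filter_eligible(fits)
    si = {r.subject_id: r.si_mass_percent for r in records}
    model = fit_exponential([si[f.subject_id] for f in retained],
                            [f.theta_f for f in retained])
    fixture = {"n_retained": len(retained), "n_excluded": len(excluded),
               "A": model.A, "B": model.B, "r_squared": model.r_squared}
    log.info("published-table fit: R2=%.4f A=%.3g B=%.1f",
             model.r_squared, model.A, model.B)

    # synthetic cohort end-to-end
    sim_dir = run_simulate(table1_like_cohort(seed), out / "synthetic")
    resp = run_fit_response(RunConfig(out_dir=out / "response",
                                      tumor_table=sim_dir / "tumors.csv",
                                      seed=seed))
    up_cfg = RunConfig(out_dir=out / "uptake",
                       tumor_table=sim_dir / "tumors.csv",
                       biodist_table=sim_dir / "biodist.csv",
                       seed=seed, extras={"fits": resp.fits})
    up = run_fit_uptake(up_cfg)
    gfaa_est = run_gfaa(RunConfig(out_dir=out / "gfaa",
                                  gfaa_table=sim_dir / "gfaa.csv",
                                  biodist_table=sim_dir / "biodist.csv",
                                  seed=seed))
    result = {
        "fixture": fixture,
        "synthetic": {
            "n_fits": len(resp.fits),
            "uptake_A": up.uptake.A, "uptake_B": up.uptake.B,
            "uptake_r_squared": up.uptake.r_squared,
            "validation_r": up.validation_r,
            "n_gfaa_samples": int(len(gfaa_est)),
        },
    }
    with open(out / "demo_summary.json", "w") as fh:
        json.dump(result, fh, indent=1)
    return result
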