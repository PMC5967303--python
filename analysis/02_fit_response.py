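"""Kill-fraction computation and per-subject quadratic response fits.

Each treated subject's volume course is normalized against the control-
group mean, converted to a kill-fraction series, and fitted with
f_kill = theta_f*(t - t0)^2 over an onset-day grid.  Subjects whose
response begins too late to leave three positive points are flagged
ineligible — the same rule that excluded two of seven animals in the
original cohort.
"""

from pathlib import Path

import pandas as pd

from msnpkill.pipeline import RunConfig, run_fit_response

SEED = 42
IN = Path("results/synthetic")
OUT = Path("results/response")


def main():
    report = run_fit_response(RunConfig(out_dir=OUT, seed=SEED,
                                        tumor_table=IN / "tumors.csv"))
    fits = pd.read_csv(OUT / "response_fits.csv")
    truth = pd.read_csv(IN / "truth.csv")
    merged = fits.merge(truth, on="subject_id")
    eligible = merged[merged.eligible]
    rel = (eligible.theta_f - eligible.theta_true).abs() / eligible.theta_true
    print(merged[["subject_id", "theta_f", "theta_true", "t0", "t0_true",
                  "n_points", "eligible"]].to_string(index=False))
    print(f"\n{len(eligible)}/{len(merged)} subjects eligible; median "
          f"relative error of theta among them: {rel.median():.1%}")
    print(f"onset day recovered exactly for "
          f"{(eligible.t0 == eligible.t0_true).sum()}/{len(eligible)} eligible subjects")
    print(f"wrote response_fits.csv, report.json/.txt -> {OUT}/")


if __name__ == "__main__":
    main()
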