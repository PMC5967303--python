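# msnpkill

Pharmacodynamic analysis linking nanoparticle uptake in tumors to
chemotherapy efficacy, for preclinical (mouse xenograft / syngeneic)
studies where drug is delivered by mesoporous silica nanoparticles
(MSNPs) and particle accumulation is measured as elemental silicon.

## The problem and the model

In a treated animal the fraction of tumor killed by treatment is defined
against the control group's growth,

    f_kill(t) = 1 − [V_i(t) / V_i(t0)] / [V_C(t) / V_C(t0)],

where V_i is the treated tumor volume, V_C the control-group mean volume,
and t0 the treatment start.  For carriers that release drug at a nearly
constant rate, the early-time response is quadratic,

    f_kill = θ_f · (t − t₀)²,      θ_f = F·λ_k / (2·V_T,0),

with θ_f the per-subject response coefficient (per day²), t₀ the onset
day of positive response, F the drug flux across vessel walls, λ_k the
cell-death rate and V_T,0 the tumor volume at onset.  Across subjects the
coefficient follows an exponential law in tumor silicon content (absolute
mass %, the proxy for MSNP accumulation):

    θ_f = A · e^{B·Si}.

The package implements the full chain: kill-fraction computation,
per-subject quadratic fitting with integer-day onset optimization and an
eligibility filter (≥ 3 positive-response points), θ-scale nonlinear
least squares for (A, B), prediction validation by pooled Pearson
correlation, GFAA standard-additions Si quantification with
delivery-efficiency (%ID) bookkeeping, and a synthetic-cohort generator
that inverts the whole chain for parameter-recovery studies.

## Worked example

The packaged per-mouse fixture holds the seven published (Si, θ_f) rows.
Two mice responded only on the last two measurement days, leaving too few
points for a fit; the exponential law is fitted to the remaining five:

```sh
$ msnpkill demo --out demo/ --seed 1
published table: 5 retained / 2 excluded; exponential fit R2=0.8170 (A=1.76e-05, B=1664.4)
synthetic cohort: B_hat=332.0 R2=0.860 validation r=0.940
```

The first line is the reproducible headline: on the five retained pairs,
θ-scale nonlinear least squares gives R² = 0.817 for θ_f = A·e^{B·Si} —
treatment efficacy grows exponentially with tumor particle uptake.  The
second line is the same pipeline run end-to-end on a freshly simulated
study-scale cohort (7 mice/group, measurement days 0/3/7/8/9); with only
a handful of animals the fitted exponent is highly variable between
seeds, which is exactly the small-sample fragility the synthetic cohorts
are there to quantify (see `docs/methods.md`).

The numbered drivers under `analysis/` run the same stages as a narrative
sequence, writing tables under `results/`:

```sh
python analysis/01_simulate_cohort.py   # synthetic cohort + ground truth
python analysis/02_fit_response.py      # kill fractions, quadratic fits
python analysis/03_fit_uptake.py        # exponential law, validation r
python analysis/04_gfaa_quant.py        # standard additions, %ID
```

Library use mirrors the CLI:

```python
from msnpkill import load_table1_fixture, filter_eligible, fit_exponential

records, fits = load_table1_fixture()
retained, excluded = filter_eligible(fits)          # 5 kept, 2 removed
si = {r.subject_id: r.si_mass_percent for r in records}
model = fit_exponential([si[f.subject_id] for f in retained],
                        [f.theta_f for f in retained])
print(model.r_squared)                              # 0.8170
```

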