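# burrowacc

Accelerometry-based behaviour classification and workload statistics
for fossorial cooperative breeders.

Strictly subterranean social mammals — Damaraland mole-rats are the
motivating system — cannot be observed directly in the wild, so their
cooperative workload (digging the shared foraging-tunnel network) is
measured with collar-mounted tri-axial accelerometers. This package
implements the full analysis chain for such deployments, for
behavioural ecologists asking how work is divided within groups:

1. **I/O & windowing** (`acc_io`) — read 25 Hz logger CSVs, split on
   gaps, cut into 2-s windows (50 samples per axis), attach
   ground-truth behaviour labels from video-annotated intervals;
2. **Signal features** (`signal_features`) — overall dynamic body
   acceleration (ODBA; per window, Σ over samples and axes of
   |a − runmean₁₀(a)|), posture (mean z, with mean z < 4.9 ms⁻² = half
   gravity marking an upright "vertical eating" posture), and a frozen
   50-feature vector per window;
3. **Classification** (`behavior_model`) — gradient-boosted trees over
   a 14-behaviour ethogram, grouped into four analysis categories
   (rest / excavate / move / other), evaluated with
   leave-individuals-out cross-validation;
4. **Ethogram derivatives** (`ethogram`) — bouts, walk-around
   (movement bouts > 5 s with no excavation in the prior minute),
   vertical-eating proportions, and per-individual-day time budgets;
5. **Growth** (`growth`) — an individual growth index: the residual
   from a sex-specific penalized-spline surface of juvenile mass gain;
6. **Statistics** (`stats`) — Hartigan's dip test of unimodality
   (bootstrap null), repeatability (intra-class correlation with a
   boundary-corrected likelihood-ratio test), gamma-log and
   beta-binomial-logit mixed models with a group random intercept
   (adaptive Gauss–Hermite), and task-specialization correlations;
7. **Synthetic data** (`simulate`) — a generator that plants known
   breeder/group-size/sex/age/growth effects in behaviour schedules
   and raw signal, so every stage above is testable end to end.

The central scientific contrasts follow the form

  g(E[y_i]) = β₀ + β₁·status_i + β₂·groupsize_c + β₃·status×groupsize
              + β₄·sex_i + u_group,   u_group ~ N(0, σ²),

with a gamma/log model for ODBA and beta-binomial/logit models for
time-budget proportions; a negative β₃ for excavation means breeders
do proportionally less digging as groups grow.

## Worked example

Simulate a full study population at the daily-budget level and run the
breeder-contrast model, repeatability and the dip test:

```python
from burrowacc.simulate import PopulationConfig, make_population, simulate_budgets
from burrowacc.stats import fit_glmm, workload_design, repeatability, dip_test

meta, captures, truth = make_population(PopulationConfig(seed=42))
budgets = simulate_budgets(meta, seed=42)

design = workload_design(budgets, meta)
fit = fit_glmm(design, "n_excavate",
               ["status", "group_size_c", "status_x_gs", "sex_male"],
               "group_id", "betabinom", trials="n_total")
print(fit.coef_table().round(3).to_string(index=False))

nb = budgets[budgets.individual_id.isin(meta.loc[~meta.breeder, "individual_id"])]
r = repeatability(nb["prop_excavate"], nb["individual_id"])
x = nb.groupby("individual_id")["prop_excavate"].mean().to_numpy()
d = dip_test(x, n_boot=2000, seed=0)
```

Output:

```
        term   beta    se       z     p
 (Intercept) -2.260 0.062 -36.221 0.000
      status -0.580 0.097  -5.989 0.000
group_size_c -0.005 0.017  -0.309 0.757
 status_x_gs -0.076 0.030  -2.573 0.010
    sex_male -0.180 0.065  -2.782 0.005
repeatability r_rpt = 0.34 (LRT = 366.9, p < 0.001)
dip D = 0.027, p = 0.98 (n = 81)
```

Reading it: non-breeders spend expit(−2.26) ≈ 9% of their time
excavating; breeders carry a −0.58 logit deficit at average group size
that deepens by −0.076 per extra group member (the planted generator
truths are −0.542 and −0.066, inside the intervals); males dig less
than females. Daily digging effort is individually repeatable
(r ≈ 0.34) but its distribution across non-breeders is unimodal
(dip p = 0.98) — individual variation, not discrete worker castes.

A command-line layer wraps the same functions
(`burrowacc simulate|train|predict|budgets|stats ...`).

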