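# cellquant

Reusable, tested implementations of four quantification procedures that are
usually run as one-off analysis notebooks in cell-migration and invasion
studies:

1. **3D collagen-invasion quantification** from confocal z-stacks — an
   intensity-profile method with no segmentation: subtract the Otsu
   threshold, sum intensity over *x*, *y* to a z-profile, co-align profiles
   of a plate on their maxima by zero-padding, place an invasion horizon
   above the shared cell-layer peak, and report per image the proportion of
   total intensity beyond the horizon, with one-way ANOVA across condition
   groups.
2. **Migration-track statistics** for random-migration and wound-healing
   assays: per-cell mean speed (path length / elapsed time), directionality
   ratio (net displacement / path length), wound persistence (mean cosine of
   step angles to the wound normal), box-and-whisker summaries with
   adjacent-value whiskers, and ANOVA with Holm-adjusted contrasts against a
   reference (starved) condition.
3. **mRNA half-life estimation** from actinomycin-D chases: comparative-Ct
   (2^−ΔΔCt) relative quantification against a reference gene, and ordinary
   least squares of log expression on time, *t*½ = ln 2 / *k*, with a pooled
   interaction test for equal decay slopes across conditions.
4. **Median-split survival comparison**: dichotomize a patient cohort at the
   median marker expression, Kaplan–Meier curves per group, Mantel–Haenszel
   log-rank test, and hazard ratio HR = (O₁/E₁)/(O₀/E₀) of high- over
   low-expression patients with a 95 % CI on the log scale.

Every pipeline ships with a matching synthetic-data generator with known
ground truth (invasion phantoms, persistent random walks, exponential decay
on the Ct scale, two-group proportional-hazards cohorts), so each method is
validated end to end by parameter recovery. See `docs/methods.md` for the
models and conventions.

## Worked example

Simulate a 720-patient cohort in which high marker expression truly halves
the hazard (HR = 0.5), then run the median-split analysis:

```python
from cellquant import synthetic, survival

cohort = synthetic.gen_survival_cohort(synthetic.SurvivalSimSpec(seed=1))
res = survival.run_survival_pipeline(cohort)
print(res["n_low"], res["n_high"])                      # 360 360
print(round(res["hazard_ratio"], 4))                    # 0.5237
print(round(res["hr_ci_low"], 4), round(res["hr_ci_high"], 4))  # 0.4319 0.635
print(round(res["chi_square"], 2))                      # 46.09
```

The estimated hazard ratio 0.52 (95 % CI 0.43–0.64) recovers the generating
value 0.5; the log-rank χ² of 46.09 on 1 df (p ≈ 10⁻¹¹) correctly flags the
survival advantage of the high-expression group.

Half-life recovery from a simulated 8-hour actinomycin-D chase with a true
2 h half-life, 0.1-cycle Ct noise and triplicates:

```python
from cellquant import synthetic, qpcr

ct = synthetic.gen_decay_course(synthetic.DecaySimSpec(seed=1))
rel = qpcr.delta_delta_ct(ct, target_gene="reln", reference_gene="actin",
                          calibrator="t0")
fit = qpcr.fit_half_life(qpcr.build_decay_course(rel))
print(round(fit.half_life, 3), round(fit.r_squared, 4))  # 1.993 0.9993
```

Invasion phantoms (5 % vs 50 % of cell intensity displaced into the
collagen) run through the full stack pipeline:

```python
from cellquant import synthetic, invasion

stacks, labels = [], []
for i, (f, g) in enumerate([(0.05, "control")] * 3 + [(0.5, "egf")] * 3):
    spec = synthetic.InvasionPhantomSpec(invaded_fraction=f, seed=50 + i)
    stack, _ = synthetic.gen_invasion_stack(spec)
    stacks.append(stack); labels.append(g)
table, anova, aligned = invasion.quantify_stacks(stacks, labels)
print(table.groupby("group")["invasion_value"].mean().round(4))
# control    0.0502
# egf        0.5007
```

The group means recover the generated fractions to three decimals and the
ANOVA separates the groups (p ≈ 2×10⁻¹¹).

A `cellquant` console script exposes the same pipelines
(`simulate stack|tracks|decay|cohort`, `invade`, `tracks`, `decay`,
`survive`); every text output is written deterministically, so re-running a
subcommand on the same inputs and seed reproduces the files byte for byte.

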