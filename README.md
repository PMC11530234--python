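# circadiff

Differential circadian rhythmicity analysis for two-group time-course
expression data and wearable streams.

## The problem

Peripheral circadian clocks (for example in cultured fibroblasts) can be
synchronized by blood serum, and the question of interest is whether two
conditions — such as serum from young versus old donors — drive *different*
sets of genes to oscillate, and whether genes rhythmic under both
conditions differ in their rhythm parameters.  Answering this needs three
ingredients, all provided here:

1. **Cosinor regression.**  Each series is modelled as
   `y(t) = M + A·cos(2π(t − φ)/τ) + ε` with a fixed period τ = 24 h, where
   `M` is the MESOR (rhythm-adjusted mean), `A ≥ 0` the amplitude and `φ`
   the acrophase (peak time in hours).  The model is linear in
   `(cos ωt, sin ωt)` and is fit by ordinary least squares; rhythmicity is
   tested with the 2-df zero-amplitude F-test.

2. **Four-model weighted-BIC classification.**  For each gene, four nested
   Gaussian models are fit to the pooled data of both groups: rhythmic in
   *neither* group, in the *young group only*, the *old group only*, or
   *both*.  BIC values are converted to Schwarz weights
   `w_i = exp(−ΔBIC_i/2)/Σ_j exp(−ΔBIC_j/2)`; a gene is classified when one
   model's weight exceeds 0.75.

3. **Joint differential fit.**  For genes of interest, a joint nonlinear
   model `y = (k + k₁G) + (α + α₁G)·cos(ω(t − φ − φ₁G))` with group
   indicator `G` estimates the young-group parameters and the
   old-minus-young differences `(k₁, α₁, φ₁)` directly, with Wald tests for
   each difference and Benjamini–Hochberg adjustment across genes per
   statistic.  Phase differences are wrapped to (−12, 12] h: positive =
   delay of the old group.

On top of these, the package provides the seven gene-subset filters used
as enrichment-tool input (decreased/increased MESOR, phase advance/delay,
loss/gain of rhythmicity, rhythmic in both), the |log₂ FC| effect-size
screens, a three-round per-gene heatmap normalization, a wearable-stream
chain (minute aggregation → per-subject 24-h cosinor → exact Wilcoxon
rank-sum tests for MESOR/amplitude and a bootstrap two-sample Kuiper test
for the circular acrophase), and a synthetic-data generator that emulates
the two-group serum-entrainment design (4 donors per group, samples every
2 h from 32 to 58 h) with full ground truth.

## Worked example

```python
from circadiff import (PipelineConfig, SimulationConfig,
                       generate_expression_dataset, run_pipeline, subset_filters)

config = SimulationConfig(n_genes=120, seed=11)
dataset, truth = generate_expression_dataset(config)
report = run_pipeline(dataset, PipelineConfig())
print(report["rhythm_class"].value_counts().to_string())
```

prints

```
rhythm_class
rhythmic_both          30
rhythmic_young_only    30
rhythmic_old_only      30
arrhythmic             29
unclassified            1
```

i.e. of the 120 simulated genes (30 per true class), all but one are
assigned their generating class at the 0.75 weight cutoff; one gene's
evidence is split and stays unclassified.  Inspecting a gene that was
simulated with a 2-h phase delay in the old group:

```python
gene = truth.loc[truth["has_delta_phase"], "gene_id"].iloc[0]
row = report.loc[gene]
print(f"{gene}: class={row['rhythm_class']}")
print(f"  young phase = {row['phase_young']:.2f} h, old phase = {row['phase_old']:.2f} h")
print(f"  d_phase = {row['d_phase']:+.2f} h (q = {row['q_d_phase']:.2e})")
```

```
gene_00003: class=rhythmic_both
  young phase = 16.75 h, old phase = 18.59 h
  d_phase = +1.84 h (q = 5.15e-05)
```

The gene is called rhythmic in both groups and its estimated phase
difference (+1.84 h, a delay) is significant after BH adjustment —
recovering the injected 2-h delay to within sampling noise.  The subset
filters on the same report,

```python
print({k: int(v.sum()) for k, v in subset_filters(report).items()})
```

```
{'decreased_mesor': 0, 'increased_mesor': 8, 'phase_advance': 0, 'phase_delay': 7,
 'loss_of_rhythmicity': 30, 'gain_of_rhythmicity': 30, 'rhythmic_both': 30}
```

pick up the genes carrying injected MESOR shifts (+0.5, hence `increased`)
and phase delays, and exactly the 30 young-only / 30 old-only genes as
losing / gaining rhythmicity.

The same pipeline is available from the shell:

```sh
circadiff simulate --seed 7 --genes 400 --out-dir sim
circadiff classify --matrix sim/matrix.tsv --annotation sim/annotation.tsv --out-dir out
circadiff wearables --input stream.csv --seed 1 --out-dir wear
```

`classify` writes the per-gene report TSV, one plain-text gene list per
subset (ready as enrichment-tool input), the normalized heatmap matrix and
a run log.

## Applying to real data

The pipeline consumes a genes × samples TSV of log₁₀(1 + normalized count)
values plus a sample-annotation TSV (`sample_id`, `group` ∈ {young, old},
`donor`, `timepoint_hr`); any normalized RNA-seq time course laid out this
way — e.g. a download of a serum-entrainment experiment from GEO —
can be run through `circadiff classify` unchanged.  The synthetic
generator exists so that every stage is testable without a download.
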