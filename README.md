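# toxclass

Transcriptome-based classification of toxicant classes from in-vitro
expression profiling, built around the workflow used to separate histone
deacetylase inhibitors (HDACi) from mercury compounds in stem-cell test
systems:

1. **Contrasts** — every treated array is reduced to its log2 difference
   against the mean of its matched untreated controls from the same
   experiment (paired design); this simple subtraction doubles as a batch
   correction. A location/scale empirical-Bayes batch adjustment (the
   ComBat model) is included for comparison views.
2. **Differential expression** — per compound, a one-sample moderated
   *t*-test of the mean contrast against zero, with the per-probe variance
   s²_g shrunk toward an empirical-Bayes prior:
   s̃² = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g), p values FDR-adjusted by
   Benjamini–Hochberg. A probe is significant when linear |FC| > 1.5 and
   adjusted p < 0.05; a gene is deregulated when ≥ 1 annotated probe is
   significant; a **consensus gene** is deregulated in the same direction
   by ≥ 4 compounds of a class.
3. **Classification** — a linear soft-margin SVM in contrast space. Per
   training split: keep the 100 highest-variance probe sets *within the
   training set*, tune the cost over C = 2⁻⁵ … 2², fit, and calibrate class
   probabilities with a Platt-style logistic map p = 1/(1+exp(A·f + B)) on
   the decision values f = w·x + b. Validation leaves out whole compounds
   (all replicates): a compound is called class A when the mean of its
   replicate probabilities exceeds 0.5.
4. **Panel minimization** — the 100-probe start panel, ordered by
   descending variance, is reduced one probe at a time from the
   low-variance end; each panel size is revalidated by leave-one-out and
   leave-two-out runs to find the smallest panel with acceptable
   predictivity.
5. **TF networks** — pairwise Kraskov k-nearest-neighbour mutual
   information (k = 9), CLR background correction, top-0.1 % edge
   retention restricted to transcription factors, greedy-modularity
   communities, Fruchterman–Reingold layout and hypergeometric gene-set
   overlays.

A synthetic-data module generates study-shaped datasets (12 compounds in
two classes × 4 replicates with one extra replicate for two compounds,
35 shared controls, 2 measurement batches, class-shared plus
compound-private signatures), so the whole pipeline runs and is tested
without any downloads.

## Worked example

```python
from toxclass.simulate import SyntheticConfig, generate_dataset
from toxclass.preprocess import subtract_controls
from toxclass.classify import leave_n_out
from toxclass import degs

expr, meta, annot, truth = generate_dataset(SyntheticConfig(seed=1))
contrasts = subtract_controls(expr, meta)

res = leave_n_out(contrasts, meta, n=1, seed=1)
print(f"leave-one-out: {sum(r.correct for r in res.records)}/12 compounds correct")
for r in res.records[:3]:
    print(f"  {r.compound:12s} mean P(HDACi-like) = {r.mean_probability:.3f} -> {r.call}")

table = degs.moderated_t(contrasts, meta)
calls = degs.call_degs(table, annot)
hdaci = [c for c in meta.compounds if meta.class_of(c) == "CLASS_A"]
up, down = degs.consensus_genes(calls, hdaci, "CLASS_A", m=4)
print(f"consensus genes (>=4 of 6 class-A compounds): {len(up)} up, {len(down)} down")
```

prints

```
leave-one-out: 12/12 compounds correct
  HgBr2        mean P(HDACi-like) = 0.080 -> CLASS_B
  HgCl2        mean P(HDACi-like) = 0.079 -> CLASS_B
  MeHg         mean P(HDACi-like) = 0.153 -> CLASS_B
consensus genes (>=4 of 6 class-A compounds): 115 up, 123 down
```

Each left-out compound is predicted by a classifier that never saw any of
its replicates; the probabilities are the calibrated P(class A) averaged
over the four replicate arrays. The consensus counts are the genes the
moderated-t/BH/fold-change rule calls in the same direction for at least
four of the six class-A compounds.

The same stages are available from the shell:

```bash
toxclass simulate --out run/ --seed 1
toxclass preprocess --expr run/expression.tsv --meta run/metadata.tsv --out run/contrasts.tsv
toxclass degs --contrasts run/contrasts.tsv --meta run/metadata.tsv \
    --annot run/annotation.tsv --out run/
toxclass crossval --contrasts run/contrasts.tsv --meta run/metadata.tsv \
    --n 1 --n 2 --out run/cv.json
toxclass run-all --out run/ --seed 1   # orchestrated end-to-end run
```

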