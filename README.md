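# sensisig

**sensisig** implements a signature-discovery pipeline for cell-based
prediction of skin sensitizers from transcriptomics. Allergic contact
dermatitis is triggered by chemical haptens, and regulatory pressure to
replace animal tests (such as the murine local lymph node assay) has driven
the development of in-vitro alternatives in which a dendritic-cell-like cell
line is stimulated with panels of sensitizing and non-sensitizing chemicals
and its transcriptional response is used as the readout. Single surface
markers such as CD86 lack predictive power (typically ~50% sensitivity even
at 100% specificity), so the assay's discriminatory ability has to come from
a multi-gene biomarker signature.

The package is aimed at computational biologists building or auditing such
assays. It provides, as a tested and reusable library plus CLI:

- **dataio** — TSV expression-matrix / sample-annotation I/O, dataset
  assembly, QC bookkeeping (dropping whole outlier compounds and single
  faulty arrays), and an advisory PCA/MAD outlier-compound screen.
- **simulate** — a seeded generator of synthetic stimulation studies
  (sensitizers with potency-graded shared effects, compound-idiosyncratic
  programs, vehicle controls, replicate noise, optional outlier compounds),
  with ground truth for recovery tests.
- **diffexpr** — per-transcript one-way ANOVA filters (two-class and
  per-compound) with Benjamini–Hochberg FDR and candidate selection.
- **elimination** — the core algorithm: backward elimination of analytes
  scored by the Kullback–Leibler divergence of leave-one-out cross-validated
  linear-SVM class probabilities, with breakpoint detection.
- **validation** — stratified compound-level 70/30 resampling that re-derives
  the signature on training data only and scores held-out compounds by
  ROC/AUC; per-gene call frequencies; single-marker baseline screen.
- **reporting** — PCA with held-out projection, row z-scoring, hierarchical
  leaf ordering for heatmaps, KLD-trajectory and ROC plots.

## The method

Given a log2 expression matrix with classes *sensitizer* / *non-sensitizer*
(vehicle controls excluded), candidate analytes are first selected by
one-way ANOVA p-value. Backward elimination then proceeds: with *N*
analytes in play, each analyte *j* is left out in turn, a linear soft-margin
SVM is evaluated by leave-one-out cross-validation on the other *N−1*, and
the divergence

&nbsp;&nbsp;&nbsp;&nbsp;KLD = −(1/S) Σₛ ln p̂ₛ(true class)

is recorded, where p̂ₛ is the Platt-calibrated out-of-fold probability of
sample *s*'s true class. The analyte whose removal yields the smallest KLD
contributes the least non-redundant information and is eliminated; the loop
repeats with *N−1* analytes. The KLD trajectory falls while redundant
analytes are removed and rises once informative ones start to go; the global
minimum is the **breakpoint**, and the analytes remaining there are the
**prediction signature**. The selection procedure (not a fixed signature) is
validated by repeated stratified compound-level 70/30 splits: the signature
is re-derived from scratch on each training set, an SVM is trained on it,
and the held-out compounds' samples are scored by the area under the ROC
curve.

## Worked example

```python
import numpy as np
from sensisig import (SynthConfig, generate_dataset, compute_gene_stats,
                      select_candidates, backward_eliminate, run_validation)

cfg = SynthConfig(n_genes=200, n_informative=12, n_sens_compounds=8,
                  n_nonsens_compounds=8, n_controls_per_vehicle=3, seed=11)
ds, truth = generate_dataset(cfg)
print(f"dataset: {ds.n_genes} genes x {ds.n_samples} samples")

stats = compute_gene_stats(ds)
cands = select_candidates(stats, "two_group", top_k=25)
trace = backward_eliminate(ds, cands)
res = run_validation(ds, n_iter=5, top_k=25, seed=1)
```

Output:

```
dataset: 200 genes x 54 samples ({'sensitizer': 24, 'non_sensitizer': 24, 'vehicle_control': 6})
candidates: 25 analytes, smallest p = 2.47e-14
elimination: breakpoint after 8 steps, signature of 17 genes (6/12 truly informative), KLD 0.0906 -> 0.0669
validation: per-iteration AUC [0.944 0.917 0.889 1.    0.861], mean AUC = 0.922
most re-selected genes: {'G00197': 80.0, 'G00026': 60.0, 'G00076': 60.0}
```

Reading the numbers: 25 ANOVA-filtered candidates are pruned for 8 steps
before the cross-validated KLD reaches its minimum (0.091 → 0.067), leaving
a 17-gene signature that includes 6 of the 12 genes the generator made truly
class-informative (the rest of the separation is carried by correlated
idiosyncratic structure, as in real stimulation data). Five resampling
iterations on this small 16-compound panel give a mean held-out AUC of 0.92;
the call frequencies say how often each gene re-entered the re-derived
signatures.

The same workflows are available from the shell:

```bash
sensisig simulate --preset study-design --seed 1 --out data/
sensisig discover --expression data/expression.tsv --annotation data/annotation.tsv \
                  --top-k 50 --out discovery/
sensisig validate --expression data/expression.tsv --annotation data/annotation.tsv \
                  --n-iter 20 --top-k 50 --seed 1 --out validation/
```

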