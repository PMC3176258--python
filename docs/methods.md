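# Methods

This note documents the models, algorithms and numerical choices behind
`sensisig`, in the spirit of a statistical package's model documentation:
what is computed, under which assumptions, with which defaults, and what the
synthetic-data tests do and do not establish.

## Data model

A dataset is a log2-scale, normalized genes × samples expression matrix
paired with a per-sample annotation (compound, class, vehicle, replicate,
potency). Normalization (e.g. RMA for microarrays) is upstream of this
package; all operations assume finite log-scale intensities. Vehicle
controls carry reserved compound ids (`VEHICLE_DMSO`, `VEHICLE_WATER`) and
are excluded from all two-class operations by default — the two classes are
the chemicals, not chemical-vs-control (a config flag
`include_controls_as_nonsens` reverses this for the ANOVA filter). Potency
labels (extreme/strong/moderate/weak) follow the LLNA convention for
sensitizers and are annotation only; no stage conditions on them.

QC bookkeeping is explicit: `remove_samples` drops whole compounds (all
replicates) and individually named samples, logging per-class counts, and
never touches retained values. `flag_outlier_compounds` is an advisory
screen for compounds whose profiles would dominate the dataset: samples are
projected on the top *k* principal components (default 5), each sample's
distance from the grand centroid is converted to a robust z-score
(median/MAD with the 1.4826 normal-consistency factor), and a compound's
score is the median over its replicates, flagged above a threshold (default
6). The rule is deliberately conservative and advisory-only because the
decision to drop a compound is a judgment call; "feasible rank" for *k* is
interpreted dimensionally (min(#samples−1, #genes)) so that degenerate but
well-shaped inputs score 0 rather than erroring.

## Synthetic-data generator

The generator emulates a chemical-stimulation study: by default 20
sensitizing + 20 non-sensitizing compounds in triplicate plus 12 DMSO and 12
water control replicates (144 samples), at a desk-scale 2000 genes. All on
log2 scale, drawn from one seeded RNG stream in a fixed order:

1. gene baselines ~ N(7.0, 1.5²) — typical microarray log2 intensity spread;
2. a shared sensitizer axis on `n_informative` random genes (default 100 ≈
   5% of genes) with loadings ±|N(1, 0.25²)|, scaled per compound by its
   potency class: defaults {extreme 2.0, strong 1.5, moderate 1.0, weak 0.6}
   log2 units, assigned round-robin (a `study_table` mode reproduces the
   4/4/8/4 class sizes of a typical 20-sensitizer reference panel);
3. a compound-idiosyncratic program for *every* compound (both classes):
   5% of genes shifted by N(0, 0.4²) — this makes class separation genuinely
   depend on the informative axis and mimics the compound heterogeneity seen
   in real stimulation profiles;
4. replicate noise N(0, 0.3²) per sample; controls are baseline plus noise;
5. optional per-compound multipliers on the whole effect vector, emulating
   the occasional extreme-outlier compound.

Effect magnitudes are stand-ins chosen so a desk-scale run separates classes
without being trivial; no quantitative effect-size estimates for real
stimulation biology were available to calibrate them. Consequently, passing
recovery tests show the *pipeline* behaves correctly on data with this
structure — shared class axis, idiosyncratic heterogeneity, i.i.d. Gaussian
noise — not that it would achieve the same operating characteristics on real
arrays, which add probe-level artifacts, batch effects, correlated noise and
non-Gaussian tails the generator does not model.

## ANOVA filtering

Per gene, classic equal-variance one-way fixed-effects ANOVA: the two-group
form (sensitizer vs non-sensitizer; F(1, n−2), identical to the squared
pooled-variance t) and the multi-group form across every compound group
(F(k−1, n−k); vehicle tokens are their own groups). A textual description of
the multi-group comparison is implemented as one-way across stimulations; a
two-factor layout (e.g. compound × vehicle) is not implemented. Totally flat
genes get p = 1; perfect separation with zero within-group variance gets the
p floor (1e-300) to keep values in (0, 1]. Benjamini–Hochberg q-values come
from `statsmodels.stats.multitest`. Candidate selection uses raw p by
default (q optional), sorted ascending with deterministic gene-id
tie-breaks; both a p threshold (≤, valid range (0, 1]) and `top_k` are
supported — at desk scale `top_k` is the practical choice because thresholds
calibrated for ~30,000-transcript arrays (~1e-6) are meaningless at 2000
genes.

## SVM and calibration

The classifier is the standard linear soft-margin SVM (L2-regularized hinge
loss) at cost C = 1, with per-gene z-scaling from training statistics and
the intercept carried as an augmented constant feature, i.e. exactly the
objective of liblinear's `LinearSVC(loss="hinge")`. A linear kernel at the
library-default cost is the only tractable choice given the elimination
loop's O(N²·S) model fits, and is standard for p ≫ n expression panels.

The solver is a deterministic cyclic dual coordinate descent compiled with
numba. The elimination loop performs on the order of 10⁵–10⁶ leave-one-out
fits; a general-purpose library fit carries ~30× too much per-call overhead
for that loop, so the package owns the inner solver and the test suite
verifies it against `sklearn.svm.LinearSVC` on the same objective (weights
agree to 1e-6).

Leave-one-out cross-validation exploits the KKT conditions: a left-out
sample with zero dual weight (a non-support vector) does not change the
optimum, so only support-vector folds are refit, warm-started from the
full-data solution. For this shortcut to be exact, z-scaling is computed
once per LOOCV pass from all samples of the pass rather than per fold — the
same convention as calling R's `e1071::svm` on a pre-scaled matrix. The
scaling statistics use only samples inside the pass (training samples of the
enclosing split), so no held-out validation data leaks in. A
compound-level LOOCV (leaving out all replicates of a compound together) is
available via `level="compound"`.

Decision values are calibrated to probabilities by Platt scaling,
p = 1/(1+exp(A·d+B)), fitted by Newton iterations on the regularized
log-loss with Platt's smoothed targets ((N₊+1)/(N₊+2) and 1/(N₋+2)). One
calibration is fitted per LOOCV pass on the collected out-of-fold decision
values — cheaper and more stable than per-fold calibration, and it uses only
out-of-fold information. Smoothing caps attainable confidence near
(n+1)/(n+2) per class, which matters when interpreting "all probabilities
≥ 0.9"-style checks at small n. Probabilities are clipped to
[1e-6, 1−1e-6] so the divergence stays finite on separable data.

## Elimination objective and breakpoint

The recorded score is the mean Kullback–Leibler divergence between the
one-hot true-label distribution and the calibrated LOOCV prediction, which
reduces to the mean negative log predicted probability of the true class
(natural log): KLD = −(1/S) Σ ln p̂ₛ. This definition is the one consistent
with the observed dynamics — the score *falls* as uninformative analytes are
removed (cross-validated predictions sharpen) and *rises* past the
breakpoint as information is lost. An alternative scoring, the symmetrized
KL divergence between class-conditional Gaussians fitted to the decision
values (a separation measure, maximized instead of minimized), is provided
as `variant="gaussian"` for sensitivity analysis.

At each step all N candidate removals are evaluated and the argmin is
eliminated; ties break to the lexicographically smallest gene id, making the
whole trace deterministic given (dataset, candidate order, cost). `floor`
(default 1) stops the loop when that many analytes remain, producing the
full trajectory. `chunk > 1` removes the k best-scoring analytes per step, a
labeled approximation for very large candidate sets; the default 1 is the
exact algorithm. The breakpoint is the step achieving the global minimum
recorded score, ties resolving to the latest step (the smaller signature);
the signature is everything not yet eliminated there.

LOOCV solver tolerance inside the elimination loop is 1e-3 on the maximal
projected gradient (decision values stable to ~3e-3, far below what the KLD
ranking needs), with a 2000-sweep cap; `train_classifier` uses 1e-8.

## Resampling validation

Compounds (never individual replicates) are split per class, uniformly at
random under a per-iteration seed derived from the master seed via
`SeedSequence([seed, iteration])`: round(0.7·class size) to training (round
half up) with at least one test compound forced per class. Each iteration
re-runs the entire selection on the training samples only — ANOVA filter,
candidate selection, backward elimination, breakpoint (or a fixed panel size
via `signature_mode="fixed"`, for studies that standardize the signature
size) — then trains an SVM on the training samples restricted to the
signature and scores the held-out samples' decision values by ROC/AUC
(sensitizer positive; AUC equals the Mann–Whitney concordance with half
credit for ties, via scikit-learn). Aggregates are the mean AUC and per-gene
call frequencies (percent of iterations whose signature contains the gene).
Per-iteration sensitivity/specificity/accuracy are additionally reported at
a fixed operating point: the threshold maximizing Youden's J on the
*training* LOOCV decision values, applied unchanged to the held-out scores
(ties resolve toward the more specific point).
A leakage test perturbs held-out expression values and asserts the derived
signature is unchanged.

The single-marker baseline mirrors one-biomarker assays: per compound, a
two-sided pooled-variance t test of its replicates against the
matching-vehicle control replicates, called positive when p < α (default
0.05) and the marker is elevated; sensitivity/specificity are computed over
compounds. At α = 0.05 null compounds fire at roughly α/2 (elevated half of
a 5% false-positive rate), so small panels show occasional baseline false
positives — the expected behavior of the t-test screen, not a defect.

## Reporting

PCA centers genes on the fitting samples (unit-variance scaling optional and
off by default, the common expression-PCA convention), takes components from
the SVD, and fixes signs so each component's largest-magnitude loading is
positive. Held-out samples are centered with the *model's* statistics and
projected on its loadings, so projecting the fitting samples reproduces
their scores exactly. Heatmap export z-scores each gene row to mean 0 and
population (divide-by-n) sd 1 — constant rows become zeros with a warning —
and orders rows by agglomerative clustering (default average linkage,
Euclidean distance on the z-scored rows; correlation distance optional).
Figures are exported as TSVs of coordinates/orderings plus rendered PNGs, so
tests assert on data rather than pixels.

## Problem sizes and determinism

Default test and acceptance problem sizes are desk-scale: 2000-gene study
designs, 50–100 candidate analytes in elimination, 5 validation iterations.
These keep the full suite around a minute on one CPU while exercising every
code path at the study's sample layout (144 samples; 38 compounds after
dropping two). All randomness flows from explicit seeds (generator configs,
split master seeds), and every CLI run writes a manifest with its config and
SHA-256 input checksums, so any artifact can be regenerated exactly.

## Known limitations

- The generator's Gaussian, gene-independent noise understates the
  correlated structure of real arrays; call frequencies and AUCs on
  synthetic data are therefore optimistic relative to real studies.
- The elimination loop is exact but O(N²) in candidates; thousands of
  candidates require `chunk > 1` or substantial compute.
- Platt calibration with a single global fit assumes the out-of-fold
  decision values share one scale; per-fold calibration is not implemented.
- The multi-group ANOVA is one-way across stimulations; factorial designs
  (compound × vehicle) are out of scope.
- The Youden operating point is chosen on training LOOCV scores without
  uncertainty quantification; confidence intervals on AUC or the point
  metrics (e.g. bootstrap) are not provided.
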