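# Methods

## Problem setting

Cytosine methylation (5-methyl-cytosine, mostly at CpG dinucleotides) is
strongly conditioned on the local sequence context. `methylpred` predicts the
methylation state of a candidate cytosine from a fixed-length window centred
on it: 41 bp for curated benchmark-style collections, 201 bp for windows cut
around CpG sites called from single-cell bisulfite sequencing read counts.
The predictor is a binary kernel classifier over a 612-dimensional encoding
of the window.

## Feature encoding

Each window of length l+1 is described by four concatenated blocks
(84 + 30 + 312 + 186 = 612 values; the block ledger is part of the public
API so downstream reports can attribute features to their extractor).

**k-gram counts (84).** Overlapping occurrence counts of all 1-, 2- and
3-mers, each block in lexicographic order (A<C<G<T). Counts are raw by
default; a per-window normalisation flag exists but is off, since all
windows in one dataset share a length and scaling is then immaterial.

**Multivariate mutual information (30).** Base, adjacent-pair and
adjacent-triple frequencies are computed from overlapping windows, with
pairs and triples collapsed to their sorted (unordered) representatives:
10 canonical 2-tuples and 20 canonical 3-tuples. Each pair tuple contributes
f(N1,N2) ln[f(N1,N2)/(f(N1)f(N2))]; each triple contributes a directed
three-term decomposition (see the module docstring) that is *not* the
symmetric interaction-information identity — the asymmetric form, evaluated
on the sorted tuple, is retained deliberately as part of the method being
implemented. Conventions: 0·ln(·) = 0 and any term with a zero denominator
contributes 0, so features are always finite; natural logarithms throughout.
A pseudocount option exists and is off by default.

**DWT band statistics (312).** The window is first mapped to an l×6
physicochemical matrix: each adjacent dinucleotide looks up six structural
properties (Twist, Tilt, Roll, Shift, Slide, Rise; shipped as a plain-text
table satisfying reverse-complement symmetry, overridable for alternative
property sets). Each property column is decomposed by a 4-level discrete
wavelet cascade; per level we keep max/min/mean/population-std of the detail
band, the same four statistics of the approximation band, and the first five
approximation coefficients (zero-padded on the right when the band is
shorter), i.e. 13 per level, 52 per property. Numerical choices: Haar (db1)
wavelet by default — it makes the analytic invariants (zero detail on
constant tracks, dyadic energy conservation) exact — with db4 available;
symmetric boundary padding; both are config keys echoed into saved feature
files. The "first five" slot is taken from every level's approximation
rather than only the deepest one, because the 4+4+5-per-level arithmetic
requires it.

**Pseudo-composition autocovariance (186).** For property column i,
p(i,λ) = Σ_{n=1}^{L−λ} (PC_i(n) − mean_i)(PC_i(n+λ) − mean_i) for
λ = 0..30. The raw sum is kept (no division by L−λ or the variance); λ=0 is
then exactly L times the population variance. The upper limit is written in
terms of the actual track length L so that 201-bp windows reuse the same lag
range; for 41-bp windows (L = 40) this reduces to the canonical form. L must
exceed λ_max, so windows must be at least λ_max+2 long.

## Dataset assembly

Sites from read-count tables are labeled by read majority after discarding
sites with fewer than 4 reads; exact ties (methylated == unmethylated reads)
are discarded as ambiguous — a deliberate conservative choice, since a
majority rule defines no label for them. Windows are cut with the cytosine
centred (flank 20 or 100); out-of-bounds windows and non-C centres are
skipped and reported. Strand is assumed '+' unless a per-site strand list is
supplied with reverse-complementing enabled.

Redundancy handling is exact: within-class duplicate sequences collapse to
the first occurrence, and a sequence present in both classes is removed from
both. Similarity-threshold clustering (CD-HIT style) is not reimplemented; a
hook accepts an externally produced representative list.

Class imbalance is corrected with SMOTE in the 612-D feature space:
x_new = x + u(x_nn − x), u ~ U[0,1], with x_nn one of the k = 5 nearest
minority neighbours by Euclidean distance. Interpolation happens on feature
vectors, not sequences (discrete-sequence interpolation is undefined), so
synthetic rows carry no sequence — which is sufficient because synthetic
rows only ever train (below). Balanced output keeps every original row
unchanged and flags generated rows `origin="synthetic"`.

## Classifier

The primary model is a sparse Bayesian kernel classifier (relevance vector
machine): a logistic-linear model over a Gaussian kernel basis (one basis
per training point plus a bias), independent zero-mean Gaussian priors per
weight, and per-weight prior precisions re-estimated by type-II maximum
likelihood. The logistic likelihood is handled by a Laplace approximation
recomputed each cycle with damped Newton/IRLS (warm-started between cycles).
Basis functions are pruned when their precision exceeds 1e9; iteration stops
when the maximum relative change of the retained precisions falls below
1e-6 or at the cap of 5000 cycles (non-convergence is recorded on the model
and warned about, and the model is still returned).

Numerical safeguards worth documenting: the bias keeps a fixed weak prior
(precision 1e-6) and is never pruned or re-estimated — re-estimating it
diverges on balanced data where the optimal bias is ~0; and bases that are
numerically dead (weight below 1e-8, or well-determinedness factor γ ≤ 1e-5
with weight ≤ 1e-4) are pruned directly, because their precisions would
otherwise drift toward the threshold arbitrarily slowly without affecting
the decision function.

Features are standardised to train-set zero mean/unit variance before the
kernel (the four blocks differ by orders of magnitude in scale; Gaussian
kernels are scale-sensitive), and the kernel width defaults to the median
pairwise distance of the standardised training rows; both are recorded in
the serialized model. Scores are posterior positive-class probabilities
through the logistic link; hard labels use a 0.5 threshold (configurable —
AUC is computed from raw scores and is threshold-free).

The interchangeable alternative is a soft-margin Gaussian-kernel SVM
(delegated to scikit-learn, with Platt-calibrated probabilities) exposing
the identical fit/predict contract, so every protocol accepts either model.

## Validation protocols and metrics

*Target-jackknife cross-validation*: leave-one-out restricted to real
samples. Each real sample is held out once and predicted by a model trained
on everything else, including SMOTE rows; synthetic rows are never tested.
Predictions are pooled into a single confusion matrix (matching
single-number reporting) rather than averaged per round.

*Chromosome-parity holdout*: records on chromosomes 1, 3, 5, 7, 9, 11 train
and those on 2, 4, 6, 8, 10, 12 test; all other chromosomes are excluded
and reported.

Metrics: ACC, SN, SP, and MCC from the pooled confusion matrix (MCC = 0
when its denominator vanishes), plus the ROC curve over all thresholds and
its AUC with the Mann-Whitney tie convention (tied scores count one half),
which makes AUC stable under permutation of equal scores.

## Feature selection

Features are ranked once by the absolute weights of a linear-kernel SVM fit
on the standardised table (one score per feature; recursive elimination is
available as an optional mode). Nested prefixes of the ranking are evaluated
with an injectable cross-validation accuracy function; the evaluated prefix
sizes default to every dimension up to 200 and a stride of 10 beyond, an
affordable-resolution choice that is overridable to all 612. The selected
prefix maximises the accuracy curve (ties break toward fewer features), and
the report includes how many chosen features come from each block. Constant
or numerically constant columns are excluded from standardisation and scored
zero.

## Synthetic data generator

The generator emulates the two-class window datasets: positives carry a
short consensus motif planted immediately 3' of the central C (per-position
match probability 0.9, motif CGCGG by default) and a +0.10 shift in G+C
fraction; negatives are background-only (uniform base composition). The GC
shift perturbs the physicochemical tracks, so all four feature blocks carry
signal — which is what makes feature selection exercisable on synthetic
data. All windows are odd-length with a forced central C, and generation is
deterministic given the seed. Default condition sizes are 200 positives +
200 negatives of 41 bp. A companion mode embeds the same windows into a toy
multi-chromosome genome with read-count site records consistent with the
labels, so extraction, labeling and the holdout split can be tested end to
end. The generator does not model bisulfite conversion errors, read-depth
biases, CpG-density gradients, or genomic repeat structure; passing tests
therefore demonstrate correctness of the pipeline and recoverability of a
planted signal, not expected accuracy on real methylomes.

## Problem sizes used in the shipped checks

The end-to-end checks run the full 612-D + sparse-Bayes target-jackknife on
400 windows (200+200), i.e. 400 training rounds per evaluation — the same
protocol shape as the full-scale experiments at a desk-friendly size; the
headline external-dataset experiments (2426-round jackknife on 787+1639
windows; hundreds of thousands of scBS-seq sites) are structurally identical
and can be reproduced by supplying those datasets through the same file
dialects.

## Known limitations

- The three-tuple information decomposition is asymmetric in its arguments;
  the sorted canonical order fixes the convention but other orders would
  give different values.
- Exact-duplicate removal is not a substitute for similarity clustering;
  near-duplicate windows can still inflate cross-validation estimates.
- SMOTE rows have features but no sequences, so sequence-level exports of
  balanced datasets list only real windows.
- The relevance-vector fit scales cubically in the active basis size; for
  datasets beyond a few thousand rows the SVM alternative or holdout
  validation is the practical choice.
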