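# Methods

## The mixture model

Each phosphopeptide `i` carries two observations: a log-abundance vector
`x_i` over `S` samples, with an observation mask `m_i` (TMT coverage is
stochastic per run, so whole run-blocks of `m_i` are typically missing
together), and an 11-residue sequence window centered on the
phosphoacceptor (S, T, or Y).  The model is a `K`-component mixture in which
component `c` has

* a diagonal-covariance Gaussian over samples, mean `mu_c`, variances
  `sigma2_c` (floored at 1e-6 to keep the likelihood bounded), and
* a sequence model over windows (one of two, below),

tied by mixing weights `pi` on the simplex.  The E-step score is

```
s(i,c) = log pi_c + sum_{s : m_is = 1} log N(x_is | mu_cs, sigma2_cs) + w * w_seq(i,c)
```

and responsibilities are the row-wise softmax of `s`.  Because the
covariance is diagonal, the Gaussian factorizes over samples and the
marginal likelihood of the observed entries is exact — no imputation enters
the E-step.  A peptide with no observed samples is assigned by prior and
sequence alone.

The M-step refits `mu`, `sigma2` with responsibility-and-mask-weighted
moments, `pi` as responsibility column means, and the per-cluster sequence
state from the soft assignments.  Missing cells are then refreshed as the
responsibility-weighted mix of cluster centers, `sum_c R_ic * mu_cs`; this
completed matrix is an output (`imputed_`), not an input to the next E-step.

**Weight semantics.**  `w` multiplies only the sequence term.  At `w = 0`
the model is exactly a diagonal-covariance Gaussian mixture on abundance
(verified against scikit-learn's `GaussianMixture` from the same
initialization); as `w -> inf` assignments follow the sequence scores alone.
The magnitude of `w` is arbitrary — sequence scores and data log-likelihoods
live on different scales — so `quantify_weight_influence` locates a fit
between its two extremes by refitting at `w = 0` and at a very large `w`
and reporting Frobenius distances between Hungarian-aligned responsibility
matrices.

**Initialization.**  Missing cells are completed by iterative
soft-thresholded SVD (rank cap 5 by default, matching the rank used by the
PCA-completion baseline), and k-means on the completed matrix provides hard
starting labels.  The k-means seed derives from `random_state`; everything
after initialization is deterministic.

**Convergence.**  EM stops when the total log-likelihood
`sum_i logsumexp_c s(i,c)` increases by less than `tol` (default 1e-4,
`max_iter` 500).  At `w = 0` the trace is non-decreasing by the standard EM
guarantee.  With `w > 0` the sequence M-step (a weighted-count refit, not an
exact maximizer of the mixed objective) is heuristic, so monotonicity is not
guaranteed in theory, though the trace converges rapidly in practice; the
test suite asserts monotonicity in the Gaussian regime and convergence in
the mixed regime.

**Empty clusters.**  A component whose responsibility mass vanishes is
reseeded from the worst-fit peptides (lowest total log-likelihood), keeping
`K` fixed, with a warning.

## Sequence models

**PAM250.**  The `n x n` matrix `P` of pairwise window similarities under
the standard PAM250 substitution matrix (embedded as a constant, verified
against Biopython in the tests) is computed once; padded positions
contribute zero.  The cluster score is the linear map `w = (1/n) P v`, i.e.
the `v`-weighted mean similarity of each peptide to the cluster, normalized
by the dataset size `n` (not the cluster mass — the score is deliberately
linear in `v`).

**Continuous binomial enrichment.**  From the one-hot tensor `T`
(peptide x amino-acid x position), weighted counts `k = T^T v` and the
pseudocounted dataset background `G` (pseudocount 1/20 per residue per
position, which also keeps `1 - G` strictly inside the Beta domain) give the
cumulative probability matrix

```
M = I_{1-G}(||v||_1 - k, k + 1)
```

with the boundary `k = ||v||_1` set to 1 analytically and `M` floored at
1e-10 before logs.  For integer `k` this is exactly the binomial CDF
`P(X <= k)` at rate `G` (asserted to 10 significant digits against direct
summation); fractional `k` arises from soft assignments.  A peptide's score
is `sum_positions log M[residue, position]` over its non-padded residues.

## Motifs and kinase inference

A cluster PSSM is built from responsibility-weighted counts -> pseudocounted
per-position frequencies -> log2 -> minus the identically-constructed
all-peptide background, so the all-peptide "cluster" gives exactly the zero
matrix, and any per-column normalization constant cancels in the
subtraction.  Information content per position is `log2(20) - H(column)`
bits, computed from the cluster frequencies; the cumulative enrichment of a
model sums totals over its cluster PSSMs.

Kinase ranking compares the PSSM with each PSPL on the shared 20 x 9 grid
(positions -5..-1, +1..+4; the phosphoacceptor column is fixed by the PSPL
assay and excluded).  Raw PSPL intensities are put on the enrichment scale
by dividing each column by its mean and log2-transforming; a matrix that
already contains non-positive entries is taken to be enrichment-scaled and
passed through (this makes a PSSM used as its own "PSPL" a distance-0
match).  Both matrices are clipped at zero from below — only enrichment is
compared — and the distance is the Frobenius norm of the difference, ranked
ascending with name tie-breaks.  The shuffle control permutes flanking PSSM
columns (center fixed), which preserves column sums, amino-acid marginals
and total bits while destroying positional structure; a positional match
shows up as shuffled distances exceeding the unshuffled one.

## Imputation benchmark

For each peptide, iteration `t` hides `t` of its observed TMT runs,
cumulatively (runs are drawn without replacement per peptide, so iteration 2
hides a second run on top of the first).  Peptides observed in fewer than 7
runs are excluded first — a benchmark parameter independent of the model-fit
filter (default: discard peptides seen in < 2 runs).  A fresh model is fit
to each masked dataset; hidden cells are predicted by the peptide's
hard-assigned cluster center (soft mixing available as an option) and scored
by MSE against the held-out truth, alongside per-peptide mean, constant
zero, per-peptide minimum (computed but excluded from default reports — it
is drastically worse), and rank-5 PCA completion baselines.
`cluster_fit_mse` separately measures intra-cluster tightness: the MSE
between 2,000 sampled peptides (or all, if fewer) and their assigned
centers.

## Association

Cluster centers (samples x clusters) are standardized column-wise — L1
penalties are scale-sensitive — and regressed on a binary phenotype with
L1-regularized logistic regression (liblinear).  The regularization strength
is chosen by mean stratified-cross-validated AUC over a log grid
(1e-2..1e2, 9 points) unless fixed; reported ROC/AUC is the mean over
stratified folds (default 5, seeded), and coefficients come from a final
fit on all samples.  Mann-Whitney U tests are two-sided per cluster with
Bonferroni adjustment `p_adj = min(1, p * K)` and flags at 0.05 / 0.001.
PCA of centers is mean-centered with a deterministic sign convention (the
largest-magnitude loading of each component is positive).

## Synthetic data

The generator draws what the model assumes: cluster templates with
cluster-level offsets spaced `mean_separation * noise_sd` apart plus
per-sample jitter of half that scale; peptide abundances are template plus
i.i.d. Gaussian noise.  Sequences are sampled per flanking position as the
cluster's preferred residue with probability `motif_strength`, else from the
(default uniform) background; the center is a cluster-specific S/T/Y.
Missingness hides whole peptide x run blocks at rate `missing_frac`, never
leaving a peptide with zero observed runs.  `independent_motifs=True` draws
the sequence partition independently of the abundance partition — the
regime where the weight genuinely trades fit MSE against motif information;
with the default aligned partitions all weights recover the same clustering.
`phenotype_effect` shifts cluster-0 templates in the second half of samples,
giving a binary phenotype with known direction.

Defaults (300 peptides, 24 samples in 6 runs, 3 clusters, 4-sigma
separation, unit noise, motif strength 0.7, 25% hidden blocks) are the
package's documented study conditions: separations at which a mixture model
should succeed, missingness heavy enough to exercise the run-block
machinery.  `kinase_motif_cluster` samples windows position-wise with
probability proportional to `exp(strength * PSPL score)` for kinase-recovery
experiments, and `random_pspl` draws gamma-distributed decoy specificity
profiles dominated by one or two residues per position, as real profiles
are.

What the generator does **not** emulate: MS intensity physics, ionization
bias, ratio compression, peptide-level abundance offsets, or correlated
noise across samples.  Tests passing on this generator demonstrate that the
algorithms behave as designed under their own model assumptions — not that
real cohort data satisfy those assumptions.

## Numerical and design choices

* Amino-acid axis order is fixed alphabetical `ACDEFGHIKLMNPQRSTVWY`.
* Windows store positions -5..+5 (the common 11-mer convention); kinase
  matching uses the PSPL design grid -5..-1, +1..+4.
* Nonstandard residues (U, X, B, Z, J, O) become padding with a warning —
  no substitution or specificity column exists for them; lowercase input is
  upper-cased.
* Duplicate phosphosite rows (same protein + site label) are rejected at
  load; distinct peptide forms of one site need distinct site labels.
* Mixing weights are standard EM column means of responsibilities,
  initialized by the k-means partition — required for a well-defined
  mixture likelihood.
* The mixed-weight default used in synthetic experiments is `w = 5` with the
  binomial method: at the generator's scales (24 samples, unit noise,
  ~10 flanking positions with log-probability differences of order 1) this
  puts the weighted sequence term and the data term in the same magnitude
  range, the regime between the two extremes.
* Cross-fit cluster comparisons align labels by Hungarian assignment
  maximizing responsibility-column overlap; labels are otherwise arbitrary.
* The acceptance script runs every stage at the sizes above (200-300
  peptides, 24 samples, K = 3), completing in seconds while leaving all
  effects far from threshold.

## Known limitations

* The E-step uses observed-dimension marginal likelihoods; iterative
  imputation feeds only the completed-matrix output, not the likelihood.
  An alternative reading — imputing before the E-step and using full
  vectors — would couple the Gaussian term to the imputation; the marginal
  form was chosen for exactness.
* With `w > 0` the combined objective has no EM monotonicity guarantee (see
  above).
* Out-of-sample `transform`/`impute` is supported for the binomial sequence
  method only; the PAM250 score is defined through the training-set pairwise
  matrix.
* Kinase inference compares motifs only; kinase-substrate specificity driven
  by docking, co-localization, or phosphosite-binding domains is invisible
  to it.
* No automatic selection of `n_clusters` or `weight`; sweep them with the
  benchmark utilities.
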