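# ddmc — dual data and motif clustering of phosphoproteomic data

Mass-spectrometry phosphoproteomics measures thousands of phosphosites across
samples, but the data are hard to mine: coverage is stochastic per TMT
(tandem mass tag) run, so missingness is heavy and block-structured, and the
measurements report substrates, not the kinases acting on them.  `ddmc`
clusters phosphopeptides **simultaneously** on two signals:

* their **abundance pattern** across samples, modeled per cluster as a
  multivariate Gaussian with diagonal covariance, with missing cells handled
  natively (the likelihood uses only observed dimensions, and missing values
  are re-imputed from cluster centers each iteration); and
* their **phosphosite sequence motif** (an 11-mer window centered on the
  phospho-S/T/Y), scored either by mean PAM250 similarity to the cluster or
  by a continuous binomial enrichment model.

Fitting is expectation-maximization on the combined objective

```
s(i,c) = log pi_c + sum_{observed s} log N(x_is | mu_cs, sigma2_cs) + w * w_seq(i,c)
```

where the weight `w` trades the two sources off: `w = 0` is a plain Gaussian
mixture on abundance; very large `w` clusters on sequence alone.  The
binomial sequence score generalizes integer count enrichment to soft cluster
assignments through the regularized incomplete Beta function,
`M = I_{1-G}(||v||_1 - k, k + 1)`, with `k` the responsibility-weighted
amino-acid/position counts and `G` the dataset background.

Around the core model the package provides, for analysts of TMT
phosphoproteome cohorts:

* cluster **motif PSSMs** (background-subtracted log2 enrichment), their
  information content in bits, and **upstream-kinase ranking** against
  experimental PSPL (position-scanning peptide library) specificity
  profiles, with a position-shuffling control;
* an **imputation benchmark** that hides whole TMT runs cumulatively and
  compares cluster-center imputation against mean / zero / minimum / PCA
  matrix-completion baselines;
* **cluster–phenotype association**: L1-regularized logistic regression on
  cluster centers with cross-validated ROC/AUC, per-cluster Mann-Whitney U
  tests with Bonferroni correction, and PCA of the centers;
* a **synthetic-data generator** with full ground truth (cluster labels,
  templates, motifs, phenotype) emulating cluster-structured abundance,
  cluster-specific motifs, and block missingness by run.

The estimator follows scikit-learn conventions (`fit`, `predict`,
`transform`, `get_params`, fitted attributes with trailing underscores) and
composes with sklearn tooling.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score

from ddmc import DDMC, SynthSpec, generate, encode_sequences, cluster_pssm, rank_kinases
from ddmc.synth import random_pspl

# 300 synthetic phosphopeptides, 24 samples in 6 TMT runs, 3 clusters,
# 4-sigma mean separation, cluster-specific motifs, 25% of runs missing
ds, truth = generate(SynthSpec(seed=0))
model = DDMC(n_clusters=3, weight=5.0, seq_method="binomial", random_state=0).fit(ds)

print(f"converged in {model.n_iter_} iterations; "
      f"ARI vs ground truth = {adjusted_rand_score(truth.labels, model.labels_):.3f}")
print(f"fraction of cells imputed: {1 - ds.mask.mean():.2f}")

tensor = encode_sequences(ds)
pssm = cluster_pssm(tensor, model.responsibilities_, 0)
collection = [random_pspl(f"KIN{i}", seed=i) for i in range(5)]
for kinase, dist in rank_kinases(pssm, collection)[:3]:
    print(f"  {kinase}: distance {dist:.2f}")
```

prints

```
converged in 2 iterations; ARI vs ground truth = 1.000
fraction of cells imputed: 0.24
  KIN4: distance 10.62
  KIN2: distance 11.51
  KIN3: distance 11.53
```

The adjusted Rand index of 1.0 says the mixed-weight fit recovered the
generating partition exactly despite a quarter of the peptide-run blocks
being hidden; the kinase list ranks candidate upstream kinases by Frobenius
distance between the cluster's motif and each specificity profile (lower is
a better match — here against random decoy profiles, so distances are large
and close together).

A command-line interface wraps the same pipeline for shell use:

```bash
ddmc simulate --seed 3 --out synth/
ddmc fit --table synth/table.csv --runs synth/runs.csv --clusters 3 --weight 5 --out model/
ddmc motifs --model model/ --out pssms/
ddmc kinases --model model/ --pspl pspl_dir/ --shuffle-control 100 --out rankings.csv
ddmc impute-benchmark --table synth/table.csv --runs synth/runs.csv --clusters 3 \
    --weights 0,5 --iterations 2 --min-runs-present 3 --out mse.csv
ddmc associate --model model/ --labels labels.csv --phenotype status --out assoc/
```

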