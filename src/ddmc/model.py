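"""Dual data and motif clustering (DDMC): an EM mixture model over abundance and sequence.

Each cluster is a multivariate Gaussian with diagonal covariance over the
sample dimensions (one dimension per sample) combined with a sequence model
(PAM250 mean distance or continuous binomial enrichment) over the peptide
windows.  The E-step sums the abundance log-likelihood — evaluated over a
peptide's *observed* samples only, which the diagonal covariance lets us do
exactly — the mixing-weight log-prior, and the sequence score scaled by a
user weight:

    s(i, c) = log pi_c + sum_{observed s} log N(x_is | mu_cs, sigma2_cs)
              + weight * w_seq(i, c)

With weight = 0 the model reduces to a Gaussian mixture on abundance alone;
with a very large weight clustering is driven by the sequence motifs.  The
M-step refits Gaussian parameters, mixing weights, and the per-cluster
sequence state from the soft assignments, and missing cells are re-imputed
each iteration as the responsibility-weighted mix of cluster centers.
Initialization completes the matrix by soft-thresholded SVD and runs k-means.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .data import PhosphoDataset, SequenceWindow, encode_sequences
from .impute import soft_impute
from .sequence import BinomialSeqModel, Pam250SeqModel

VARIANCE_FLOOR = 1e-6
EMPTY_CLUSTER_EPS = 1e-8


def _gaussian_loglik(X, mask, means, variances):
    """(n_peptides, n_clusters) log N over observed dimensions only."""
    n, _ = X.shape
    K = means.shape[0]
    out = np.empty((n, K))
    for c in range(K):
        var = variances[c]
        ll = -0.5 * (np.log(2.0 * np.pi * var) + (X - means[c]) ** 2 / var)
        out[:, c] = (ll * mask).sum(axis=1)
    return out


def hungarian_cluster_map(R_ref: np.ndarray, R_other: np.ndarray) -> np.ndarray:
    """Permutation p maximizing responsibility overlap: cluster c of `other` -> p[c] of `ref`.

    Cluster labels are arbitrary across fits; overlap is the inner product of
    responsibility columns, maximized by Hungarian assignment.
    """
    overlap = R_ref.T @ R_other  # (K_ref, K_other)
    ref_idx, other_idx = linear_sum_assignment(-overlap)
    p = np.empty(R_other.shape[1], dtype=int)
    p[other_idx] = ref_idx
    return p


class DDMC(BaseEstimator, ClusterMixin):
    """Dual data/motif mixture-model clustering of phosphopeptides.

    Parameters
    ----------
    n_clusters : int
        Number of mixture components.
    weight : float
        Non-negative factor scaling the sequence log-likelihood term in the
        E-step.  0 gives an abundance-only Gaussian mixture; very large
        values cluster essentially on sequence.
    seq_method : {"binomial", "pam250"}
        Sequence-cluster scoring method.
    tol : float
        EM stops when the total log-likelihood increases by less than this.
    max_iter : int
        Maximum EM iterations.
    init_rank : int
        Rank cap for the soft-impute completion used before k-means
        initialization.
    random_state : int or None
        Seeds k-means initialization; the rest of the fit is deterministic.

    Attributes
    ----------
    means_ : ndarray (n_clusters, n_samples)
        Gaussian cluster centers.
    variances_ : ndarray (n_clusters, n_samples)
        Diagonal covariances (floored at 1e-6).
    mixing_ : ndarray (n_clusters,)
        Mixture weights (simplex).
    responsibilities_ : ndarray (n_peptides, n_clusters)
        Posterior membership probabilities; rows sum to 1.
    labels_ : ndarray (n_peptides,)
        Hard assignments (argmax responsibility).
    log_likelihood_trace_ : list of float
        Total log-likelihood at each EM iteration.
    imputed_ : ndarray (n_peptides, n_samples)
        Abundance matrix with missing cells replaced by the
        responsibility-weighted mix of cluster centers.
    """

    def __init__(
        self,
        n_clusters: int = 3,
        weight: float = 0.0,
        seq_method: str = "binomial",
        tol: float = 1e-4,
        max_iter: int = 500,
        init_rank: int = 5,
        random_state=None,
    ):
        self.n_clusters = n_clusters
        self.weight = weight
        self.seq_method = seq_method
        self.tol = tol
        self.max_iter = max_iter
        self.init_rank = init_rank
        self.random_state = random_state

    # ------------------------------------------------------------------ setup

    def _validate(self, ds: PhosphoDataset):
        if not isinstance(ds, PhosphoDataset):
            raise TypeError("DDMC.fit expects a PhosphoDataset")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_clusters > ds.n_peptides:
            raise ValueError("n_clusters exceeds the number of peptides")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.seq_method not in ("binomial", "pam250"):
            raise ValueError(f"unknown seq_method {self.seq_method!r}")

    def _make_seq_model(self, ds):
        tensor = encode_sequences(ds)
        if self.seq_method == "binomial":
            return BinomialSeqModel(tensor)
        return Pam250SeqModel(tensor)

    def _initial_labels(self, completed):
        rng = np.random.default_rng(self.random_state)
        for _ in range(5):
            seed = int(rng.integers(0, 2**31 - 1))
            km = KMeans(n_clusters=self.n_clusters, n_init=10, random_state=seed)
            labels = km.fit_predict(completed)
            if len(np.unique(labels)) == self.n_clusters:
                return labels
        raise RuntimeError("k-means initialization kept producing empty clusters")

    # ------------------------------------------------------------------ steps

    def _score_matrix(self, X, mask):
        """Combined per-peptide, per-cluster log scores s(i, c)."""
        S = _gaussian_loglik(X, mask, self.means_, self.variances_)
        S += np.log(self.mixing_)[None, :]
        if self.weight > 0:
            seq = np.column_stack([self._seq.score(st) for st in self.seq_states_])
            S += self.weight * seq
        return S

    def _e_step(self, X, mask):
        S = self._score_matrix(X, mask)
        norm = logsumexp(S, axis=1)
        if not np.all(np.isfinite(norm)):
            bad = int(np.argmax(~np.isfinite(norm)))
            worst = int(np.argmin(S[bad]))
            raise FloatingPointError(
                f"non-finite log-likelihood for peptide {bad} (worst cluster {worst})"
            )
        R = np.exp(S - norm[:, None])
        return R, float(norm.sum())

    def _rescue_empty(self, R, X, mask):
        """Reinitialize clusters that lost all responsibility mass.

        The worst-fit peptides (lowest total log-likelihood under the current
        model) are hard-assigned to the empty cluster so n_clusters is
        preserved.
        """
        col_mass = R.sum(axis=0)
        empties = np.flatnonzero(col_mass < EMPTY_CLUSTER_EPS)
        if empties.size == 0:
            return R
        S = self._score_matrix(X, mask)
        fit_quality = logsumexp(S, axis=1)
        order = np.argsort(fit_quality)
        n_seed = max(1, R.shape[0] // (10 * self.n_clusters))
        used = 0
        for c in empties:
            warnings.warn(f"cluster {c} emptied; reseeding from worst-fit peptides")
            rows = order[used : used + n_seed]
            used += n_seed
            R[rows] = 0.0
            R[rows, c] = 1.0
        return R

    def _m_step(self, X, mask, R):
        Rm = R.T @ mask  # (K, n_samples) responsibility mass per observed cell
        safe = np.maximum(Rm, 1e-12)
        self.means_ = (R.T @ (X * mask)) / safe
        sq = np.empty_like(self.means_)
        for c in range(self.n_clusters):
            d2 = (X - self.means_[c]) ** 2
            sq[c] = (R[:, c][:, None] * d2 * mask).sum(axis=0)
        self.variances_ = np.maximum(sq / safe, VARIANCE_FLOOR)
        self.mixing_ = np.maximum(R.mean(axis=0), 1e-12)
        self.mixing_ /= self.mixing_.sum()
        if self.weight > 0:
            self.seq_states_ = [self._seq.fit_cluster(R[:, c]) for c in range(self.n_clusters)]

    def _update_missing(self, X, mask, R):
        expected = R @ self.means_
        return np.where(mask, X, expected)

    # ------------------------------------------------------------------ API

    def fit(self, ds: PhosphoDataset, y=None):
        """Run EM to convergence on a phosphopeptide dataset."""
        self._validate(ds)
        X, mask = ds.abundance, ds.mask
        self._seq = self._make_seq_model(ds)
        self.sequences_ = list(ds.sequences)
        self.sample_names_ = list(ds.sample_names)
        self.peptide_ids_ = list(ds.peptide_ids)

        completed = soft_impute(X, mask, rank=min(self.init_rank, min(X.shape)))
        labels = self._initial_labels(completed)
        R = np.zeros((ds.n_peptides, self.n_clusters))
        R[np.arange(ds.n_peptides), labels] = 1.0
        self.seq_states_ = [None] * self.n_clusters
        self._m_step(X, mask, R)

        trace = []
        prev_ll = -np.inf
        self.converged_ = False
        for it in range(self.max_iter):
            R, ll = self._e_step(X, mask)
            R = self._rescue_empty(R, X, mask)
            trace.append(ll)
            self._m_step(X, mask, R)
            if ll - prev_ll < self.tol and it > 0:
                self.converged_ = True
                prev_ll = ll
                break
            prev_ll = ll

        self.responsibilities_ = R
        self.labels_ = R.argmax(axis=1)
        self.log_likelihood_trace_ = trace
        self.n_iter_ = len(trace)
        self.imputed_ = self._update_missing(X, mask, R)
        return self

    def predict(self, ds: PhosphoDataset = None) -> np.ndarray:
        """Hard cluster labels (training data if ``ds`` is omitted)."""
        if ds is None:
            return self.labels_
        return self.transform(ds).argmax(axis=1)

    def transform(self, ds: PhosphoDataset = None) -> np.ndarray:
        """Responsibility matrix for ``ds`` (training responsibilities if omitted).

        For new data the sequence term uses the training-set background and
        per-cluster states, so windows must share the training window length.
        """
        if ds is None:
            return self.responsibilities_
        X, mask = ds.abundance, ds.mask
        S = _gaussian_loglik(X, mask, self.means_, self.variances_)
        S += np.log(self.mixing_)[None, :]
        if self.weight > 0:
            if self.seq_method == "binomial":
                new_seq = BinomialSeqModel(encode_sequences(ds))
                new_seq.background = self._seq.background
                seq = np.column_stack([new_seq.score(M) for M in self.seq_states_])
            else:
                raise NotImplementedError(
                    "out-of-sample transform is only supported for seq_method='binomial'"
                )
            S += self.weight * seq
        return np.exp(S - logsumexp(S, axis=1)[:, None])

    def fit_predict(self, ds: PhosphoDataset, y=None) -> np.ndarray:
        return self.fit(ds).labels_

    def cluster_centers(self) -> np.ndarray:
        """(n_samples, n_clusters) matrix: column c is cluster c's signal across samples."""
        return self.means_.T

    def impute(self, ds: PhosphoDataset = None) -> np.ndarray:
        """Completed abundance matrix: observed cells kept, missing cells from centers."""
        if ds is None:
            return self.imputed_
        R = self.transform(ds)
        return np.where(ds.mask, ds.abundance, R @ self.means_)

    def seq_scores(self) -> np.ndarray:
        """(n_peptides, n_clusters) sequence log-scores under the fitted states."""
        if self.weight > 0:
            return np.column_stack([self._seq.score(st) for st in self.seq_states_])
        # states were never fit; fit them from final responsibilities
        states = [self._seq.fit_cluster(self.responsibilities_[:, c]) for c in range(self.n_clusters)]
        return np.column_stack([self._seq.score(st) for st in states])


def quantify_weight_influence(ds: PhosphoDataset, fitted: DDMC, large_weight: float = 1e6):
    """How far a clustering sits between its abundance-only and sequence-only extremes.

    Refits the model at weight 0 and at ``large_weight`` (same seed and
    cluster count), Hungarian-aligns cluster labels to the fitted model, and
    returns the Frobenius norms (||R_fit - R_weight0||_F, ||R_fit - R_large||_F).
    """
    norms = []
    for w in (0.0, large_weight):
        other = DDMC(**{**fitted.get_params(), "weight": w}).fit(ds)
        p = hungarian_cluster_map(fitted.responsibilities_, other.responsibilities_)
        aligned = np.empty_like(other.responsibilities_)
        aligned[:, p] = other.responsibilities_
        norms.append(float(np.linalg.norm(fitted.responsibilities_ - aligned)))
    return tuple(norms)


# ------------------------------------------------------------------ persistence


def save_model(model: DDMC, out_dir):
    """Serialize a fitted model to a directory of delimited matrices + JSON metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = model.sample_names_
    pd.DataFrame(model.means_, columns=cols).to_csv(out / "means.csv", index=False)
    pd.DataFrame(model.variances_, columns=cols).to_csv(out / "variances.csv", index=False)
    pd.DataFrame(model.responsibilities_).to_csv(out / "responsibilities.csv", index=False)
    pd.DataFrame({"mixing": model.mixing_}).to_csv(out / "mixing.csv", index=False)
    pd.DataFrame(model.imputed_, columns=cols).to_csv(out / "imputed.csv", index=False)
    pd.DataFrame(
        {
            "protein": [p for p, _ in model.peptide_ids_],
            "site": [s for _, s in model.peptide_ids_],
            "sequence": [w.residues for w in model.sequences_],
            "cluster": model.labels_,
        }
    ).to_csv(out / "peptides.csv", index=False)
    meta = {
        "params": model.get_params(),
        "log_likelihood_trace": model.log_likelihood_trace_,
        "converged": bool(model.converged_),
        "n_iter": int(model.n_iter_),
        "sample_names": cols,
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_model(model_dir) -> DDMC:
    """Rebuild a fitted DDMC (parameters and outputs) from :func:`save_model` output."""
    d = Path(model_dir)
    meta = json.loads((d / "metadata.json").read_text())
    model = DDMC(**meta["params"])
    model.means_ = pd.read_csv(d / "means.csv").to_numpy()
    model.variances_ = pd.read_csv(d / "variances.csv").to_numpy()
    model.responsibilities_ = pd.read_csv(d / "responsibilities.csv").to_numpy()
    model.mixing_ = pd.read_csv(d / "mixing.csv")["mixing"].to_numpy()
    model.imputed_ = pd.read_csv(d / "imputed.csv").to_numpy()
    pep = pd.read_csv(d / "peptides.csv")
    model.peptide_ids_ = list(zip(pep["protein"], pep["site"]))
    model.sequences_ = [SequenceWindow(s, len(s) // 2) for s in pep["sequence"]]
    model.labels_ = pep["cluster"].to_numpy()
    model.sample_names_ = meta["sample_names"]
    model.log_likelihood_trace_ = meta["log_likelihood_trace"]
    model.converged_ = meta["converged"]
    model.n_iter_ = meta["n_iter"]
    return model
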