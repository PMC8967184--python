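"""Sequence-cluster scoring: PAM250 mean distance and continuous binomial enrichment.

Two interchangeable ways to score how well a peptide's sequence window fits a
cluster whose membership is soft (a responsibility vector ``v`` in [0,1]^n):

* **PAM250** — precompute the n x n matrix ``P`` of pairwise window
  similarities under the PAM250 substitution matrix; the cluster score of
  peptide ``a`` is the ``v``-weighted mean similarity ``w = (1/n) P v``.
* **Binomial enrichment** — form the responsibility-weighted amino-acid count
  matrix ``k = (T^T v)^T`` from the one-hot sequence tensor ``T``, and score
  each (residue, position) cell by the cumulative probability of observing at
  most ``k`` occurrences in ``||v||_1`` draws at the background rate ``G``.
  Because responsibilities are fractional, the binomial CDF is extended to
  continuous counts through the regularized incomplete Beta function
  ``M = I_{1-G}(||v||_1 - k, k + 1)``; for integer counts this equals the
  ordinary binomial CDF exactly.  A peptide's cluster score is the sum of
  ``log M`` over its residues.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betainc

from .data import AA_ORDER, SequenceTensor, encode_sequences

# Standard PAM250 substitution matrix (log-odds, quarter-bit units), rows and
# columns in AA_ORDER ("ACDEFGHIKLMNPQRSTVWY").  Embedded so scoring never
# depends on an external lookup at run time.
PAM250 = np.array([
    #  A   C   D   E   F   G   H   I   K   L   M   N   P   Q   R   S   T   V   W   Y
    [  2, -2,  0,  0, -3,  1, -1, -1, -1, -2, -1,  0,  1,  0, -2,  1,  1,  0, -6, -3],  # A
    [ -2, 12, -5, -5, -4, -3, -3, -2, -5, -6, -5, -4, -3, -5, -4,  0, -2, -2, -8,  0],  # C
    [  0, -5,  4,  3, -6,  1,  1, -2,  0, -4, -3,  2, -1,  2, -1,  0,  0, -2, -7, -4],  # D
    [  0, -5,  3,  4, -5,  0,  1, -2,  0, -3, -2,  1, -1,  2, -1,  0,  0, -2, -7, -4],  # E
    [ -3, -4, -6, -5,  9, -5, -2,  1, -5,  2,  0, -3, -5, -5, -4, -3, -3, -1,  0,  7],  # F
    [  1, -3,  1,  0, -5,  5, -2, -3, -2, -4, -3,  0,  0, -1, -3,  1,  0, -1, -7, -5],  # G
    [ -1, -3,  1,  1, -2, -2,  6, -2,  0, -2, -2,  2,  0,  3,  2, -1, -1, -2, -3,  0],  # H
    [ -1, -2, -2, -2,  1, -3, -2,  5, -2,  2,  2, -2, -2, -2, -2, -1,  0,  4, -5, -1],  # I
    [ -1, -5,  0,  0, -5, -2,  0, -2,  5, -3,  0,  1, -1,  1,  3,  0,  0, -2, -3, -4],  # K
    [ -2, -6, -4, -3,  2, -4, -2,  2, -3,  6,  4, -3, -3, -2, -3, -3, -2,  2, -2, -1],  # L
    [ -1, -5, -3, -2,  0, -3, -2,  2,  0,  4,  6, -2, -2, -1,  0, -2, -1,  2, -4, -2],  # M
    [  0, -4,  2,  1, -3,  0,  2, -2,  1, -3, -2,  2,  0,  1,  0,  1,  0, -2, -4, -2],  # N
    [  1, -3, -1, -1, -5,  0,  0, -2, -1, -3, -2,  0,  6,  0,  0,  1,  0, -1, -6, -5],  # P
    [  0, -5,  2,  2, -5, -1,  3, -2,  1, -2, -1,  1,  0,  4,  1, -1, -1, -2, -5, -4],  # Q
    [ -2, -4, -1, -1, -4, -3,  2, -2,  3, -3,  0,  0,  0,  1,  6,  0, -1, -2,  2, -4],  # R
    [  1,  0,  0,  0, -3,  1, -1, -1,  0, -3, -2,  1,  1, -1,  0,  2,  1, -1, -2, -3],  # S
    [  1, -2,  0,  0, -3,  0, -1,  0,  0, -2, -1,  0,  0, -1, -1,  1,  3,  0, -5, -3],  # T
    [  0, -2, -2, -2, -1, -1, -2,  4, -2,  2,  2, -2, -1, -2, -2, -1,  0,  4, -6, -2],  # V
    [ -6, -8, -7, -7,  0, -7, -3, -5, -3, -2, -4, -4, -6, -5,  2, -2, -5, -6, 17,  0],  # W
    [ -3,  0, -4, -4,  7, -5,  0, -1, -4, -1, -2, -2, -5, -4, -4, -3, -3, -2,  0, 10],  # Y
], dtype=float)

#: Laplace-style pseudocount added per amino acid per position when estimating
#: background frequencies (keeps 1-G strictly inside the Beta domain).
DEFAULT_PSEUDOCOUNT = 1.0 / len(AA_ORDER)

#: Floor applied to cumulative probabilities before taking logs.
M_FLOOR = 1e-10


def _as_tensor(tensor_or_windows) -> SequenceTensor:
    if isinstance(tensor_or_windows, SequenceTensor):
        return tensor_or_windows
    return encode_sequences(tensor_or_windows)


def pam250_pairwise(tensor_or_windows) -> np.ndarray:
    """All-pairs PAM250 window similarity matrix (symmetric, n x n).

    ``P[a, b]`` sums PAM250(residue_a, residue_b) over positions where both
    windows carry a standard residue; padded positions contribute 0.
    """
    T = _as_tensor(tensor_or_windows).data
    n, _, n_pos = T.shape
    P = np.zeros((n, n))
    for k in range(n_pos):
        Ak = T[:, :, k]  # (n, 20)
        P += Ak @ PAM250 @ Ak.T
    return P


def pam250_cluster_score(P: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Mean PAM250 similarity from each peptide to a soft cluster: w = (1/n) P v.

    The normalization is by the dataset size ``n`` (not the cluster mass), so
    the score is linear in ``v``.
    """
    v = np.asarray(v, dtype=float)
    if v.shape[0] != P.shape[0]:
        raise ValueError("responsibility vector length does not match P")
    return (P @ v) / P.shape[0]


def binomial_background(tensor_or_windows, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """Background relative frequencies G (20 x positions) over the whole dataset.

    G[j, k] = (count of amino acid j at position k + pseudocount) /
              (non-padded peptides at k + 20 * pseudocount).
    Columns over represented residues sum to 1; entries stay strictly inside
    (0, 1) thanks to the pseudocount.
    """
    T = _as_tensor(tensor_or_windows).data
    counts = T.sum(axis=0)  # (20, n_pos)
    denom = counts.sum(axis=0, keepdims=True) + len(AA_ORDER) * pseudocount
    return (counts + pseudocount) / denom


def continuous_binomial_cdf(k, n_eff, G):
    """P(X <= k) for X ~ Binomial(n_eff, G), extended to non-integer k and n_eff.

    Evaluates the regularized incomplete Beta function I_{1-G}(n_eff - k, k+1)
    elementwise; the boundary k >= n_eff (first Beta argument <= 0) is the
    limit value 1 and is handled analytically.
    """
    k = np.asarray(k, dtype=float)
    n_eff = float(n_eff)
    G = np.asarray(G, dtype=float)
    a = n_eff - k
    with np.errstate(invalid="ignore"):
        M = betainc(np.where(a > 0, a, 1.0), k + 1.0, 1.0 - G)
    return np.where(a > 0, M, 1.0)


class BinomialSeqModel:
    """Continuous binomial enrichment scoring of cluster sequence motifs.

    Holds the one-hot tensor and dataset background; per-cluster state is the
    cumulative-probability matrix ``M`` returned by :meth:`fit_cluster`.
    """

    def __init__(self, tensor_or_windows, pseudocount: float = DEFAULT_PSEUDOCOUNT):
        self.tensor = _as_tensor(tensor_or_windows)
        self.background = binomial_background(self.tensor, pseudocount)

    def fit_cluster(self, v: np.ndarray) -> np.ndarray:
        """Weighted counts -> cumulative probability matrix M for one cluster."""
        v = np.asarray(v, dtype=float)
        T = self.tensor.data
        if v.shape[0] != T.shape[0]:
            raise ValueError("responsibility vector length does not match tensor")
        n_eff = v.sum()
        if n_eff <= 0:
            raise ValueError("empty cluster: responsibility mass is zero")
        k = np.einsum("ijk,i->jk", T, v)
        # fractional counts can exceed n_eff by rounding error only
        k = np.minimum(k, n_eff)
        M = continuous_binomial_cdf(k, n_eff, self.background)
        return np.maximum(M, M_FLOOR)

    def score(self, M: np.ndarray) -> np.ndarray:
        """Per-peptide cluster log-probability: sum of log M over the peptide's residues."""
        return np.einsum("ijk,jk->i", self.tensor.data, np.log(M))


class Pam250SeqModel:
    """PAM250 mean-distance scoring; pairwise matrix computed once at construction."""

    def __init__(self, tensor_or_windows):
        self.tensor = _as_tensor(tensor_or_windows)
        self.P = pam250_pairwise(self.tensor)

    def fit_cluster(self, v: np.ndarray) -> np.ndarray:
        # cluster state is the responsibility vector itself
        return np.asarray(v, dtype=float)

    def score(self, v: np.ndarray) -> np.ndarray:
        return pam250_cluster_score(self.P, v)
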