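"""Cluster motifs (PSSMs), information content, and upstream-kinase ranking.

A cluster PSSM summarizes a soft cluster's sequence preferences: the one-hot
tensor is weighted by the cluster's responsibilities to give per-position
amino-acid frequencies, which are log2-transformed and background-subtracted
(background = the identically-constructed matrix over *all* peptides).
Positive scores mark enriched residues, negative scores depleted ones, and
the all-peptide cluster gives exactly the zero matrix.

Candidate upstream kinases are ranked by the Frobenius distance between a
cluster PSSM and each experimental PSPL specificity profile, comparing only
positive enrichment on the shared 20 x 9 grid (positions -5..-1, +1..+4; the
phosphoacceptor column is fixed by the PSPL assay and excluded).  A
position-shuffling control quantifies how much of a match is positional
rather than compositional.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import AA_ORDER, PSPL_POSITIONS, PSPLMatrix, SequenceTensor
from .sequence import DEFAULT_PSEUDOCOUNT


@dataclass
class PSSM:
    """Position-specific scoring matrix: 20 x positions log2 enrichment vs background.

    ``frequencies`` keeps the pseudocounted per-position amino-acid
    probabilities the scores were derived from (needed for information
    content).
    """

    scores: np.ndarray  # (20, n_positions)
    positions: tuple
    frequencies: np.ndarray = None
    cluster_id: int = None

    def column(self, position: int) -> np.ndarray:
        return self.scores[:, self.positions.index(position)]


def _weighted_frequencies(tensor: SequenceTensor, v: np.ndarray, pseudocount: float) -> np.ndarray:
    counts = np.einsum("ijk,i->jk", tensor.data, np.asarray(v, dtype=float))
    denom = counts.sum(axis=0, keepdims=True) + len(AA_ORDER) * pseudocount
    return (counts + pseudocount) / denom


def cluster_pssm(
    tensor: SequenceTensor,
    R: np.ndarray,
    cluster: int,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PSSM:
    """Background-subtracted log2 enrichment PSSM for one soft cluster.

    Weighted counts (tensor weighted by the cluster's responsibility column)
    are turned into pseudocounted per-position frequencies, log2-transformed,
    and the all-peptide background matrix (same construction, v = 1) is
    subtracted.
    """
    R = np.asarray(R, dtype=float)
    v = R[:, cluster] if R.ndim == 2 else R
    if v.sum() <= 0:
        raise ValueError(f"cluster {cluster}: total responsibility is zero")
    freq = _weighted_frequencies(tensor, v, pseudocount)
    bg = _weighted_frequencies(tensor, np.ones(tensor.n_peptides), pseudocount)
    scores = np.log2(freq) - np.log2(bg)
    return PSSM(scores=scores, positions=tuple(tensor.positions), frequencies=freq, cluster_id=cluster)


def pssm_from_windows(windows, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> "PSSM":
    """PSSM of a peptide set against a uniform background (no dataset context).

    Used for stand-alone motifs such as one built from a kinase's validated
    substrate windows.
    """
    from .data import encode_sequences

    tensor = encode_sequences(windows)
    freq = _weighted_frequencies(tensor, np.ones(tensor.n_peptides), pseudocount)
    scores = np.log2(freq) - np.log2(1.0 / len(AA_ORDER))
    return PSSM(scores=scores, positions=tuple(tensor.positions), frequencies=freq)


def pssm_information_bits(pssm: PSSM) -> tuple:
    """Shannon information content per position and its total, in bits.

    Per position: log2(20) - H(column frequencies).  A uniform column carries
    0 bits; a deterministic one carries log2(20) ~ 4.32 bits.  The cumulative
    enrichment of a model is the sum of totals over its cluster PSSMs.
    """
    freq = pssm.frequencies
    if freq is None:
        raise ValueError("PSSM lacks frequency matrix; information content undefined")
    f = np.asarray(freq, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(f), 0.0)
    entropy = -plogp.sum(axis=0)
    per_position = np.log2(len(AA_ORDER)) - entropy
    return per_position, float(per_position.sum())


def pspl_to_enrichment(pspl: PSPLMatrix) -> np.ndarray:
    """Put a PSPL on the log2-enrichment scale of cluster PSSMs.

    Raw PSPL matrices are positive phosphorylation intensities: each position
    column is divided by its mean and log2-transformed, so a residue preferred
    over the column average scores positive — directly comparable to a
    background-subtracted PSSM column.  A matrix containing non-positive
    entries is taken to be on the log2-enrichment scale already and is
    returned unchanged.
    """
    scores = np.asarray(pspl.scores, dtype=float)
    if np.any(scores <= 0):
        return scores
    return np.log2(scores / scores.mean(axis=0, keepdims=True))


def _pssm_on_pspl_grid(pssm: PSSM) -> np.ndarray:
    try:
        idx = [pssm.positions.index(p) for p in PSPL_POSITIONS]
    except ValueError as e:
        raise ValueError(
            f"PSSM positions {pssm.positions} do not cover the PSPL grid {PSPL_POSITIONS}"
        ) from e
    return pssm.scores[:, idx]


def kinase_distance(pssm: PSSM, pspl: PSPLMatrix) -> float:
    """Frobenius distance between positive enrichment of a cluster PSSM and a PSPL.

    Both matrices are restricted to the shared 20 x 9 grid and clipped at zero
    from below (only enriched residues are compared); lower is a better match.
    """
    a = np.clip(_pssm_on_pspl_grid(pssm), 0.0, None)
    b = np.clip(pspl_to_enrichment(pspl), 0.0, None)
    return float(np.linalg.norm(a - b))


def rank_kinases(pssm: PSSM, collection, restrict_class: str = None) -> list:
    """Rank a PSPL collection by ascending distance to a cluster PSSM.

    Ties break deterministically by kinase name.  ``restrict_class`` limits
    the ranking to kinases of one phosphoacceptor class ("S/T" or "Y").
    """
    if not collection:
        raise ValueError("empty PSPL collection")
    cands = [p for p in collection if restrict_class is None or p.phosphoacceptor_class == restrict_class]
    ranked = sorted(((kinase_distance(pssm, p), p.kinase_name) for p in cands))
    return [(name, dist) for dist, name in ranked]


def shuffle_positions(pssm: PSSM, seed=None) -> PSSM:
    """Uniformly permute the flanking position columns; the phosphoacceptor stays put.

    The column multiset — hence column sums, amino-acid marginals, and total
    information content — is unchanged; only positional structure is destroyed.
    """
    positions = list(pssm.positions)
    flank = [i for i, p in enumerate(positions) if p != 0]
    if len(flank) < 2:
        raise ValueError("need at least two flanking positions to shuffle")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(flank))
    new_scores = pssm.scores.copy()
    new_scores[:, flank] = pssm.scores[:, [flank[j] for j in perm]]
    new_freq = None
    if pssm.frequencies is not None:
        new_freq = pssm.frequencies.copy()
        new_freq[:, flank] = pssm.frequencies[:, [flank[j] for j in perm]]
    return PSSM(scores=new_scores, positions=pssm.positions, frequencies=new_freq, cluster_id=pssm.cluster_id)


def shuffle_control_distances(pssm: PSSM, pspl: PSPLMatrix, n_shuffles: int = 100, seed=None) -> np.ndarray:
    """Kinase distances of ``n_shuffles`` independent position shuffles of a PSSM."""
    rng = np.random.default_rng(seed)
    return np.array(
        [kinase_distance(shuffle_positions(pssm, rng.integers(2**31 - 1)), pspl) for _ in range(n_shuffles)]
    )


def write_pssm(pssm: PSSM, path):
    """Export a PSSM as CSV (rows = amino acids, columns = signed positions)."""
    path = Path(path)
    df = pd.DataFrame(pssm.scores, index=list(AA_ORDER), columns=[str(p) for p in pssm.positions])
    df.to_csv(path)
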