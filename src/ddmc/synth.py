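"""Synthetic phosphopeptide datasets with known ground truth.

Emulates the statistical structure the mixture model assumes: cluster-wise
Gaussian abundance across samples, cluster-specific sequence motifs, and
block missingness by TMT run.  Every downstream module is testable against
the generator's ground truth without any external download.

What it does *not* emulate: MS intensity physics, ionization bias, ratio
compression, or peptide-level abundance offsets — passing tests show the
algorithms behave as designed under their own model assumptions, not that
real spectra behave this way.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .data import (
    AA_ORDER,
    PHOSPHOACCEPTORS,
    PSPL_POSITIONS,
    PhosphoDataset,
    PSPLMatrix,
    SequenceWindow,
)


@dataclass
class SynthSpec:
    """Generator settings with field-realistic defaults.

    Abundance: cluster template means are spread ``mean_separation`` noise
    standard deviations apart (cluster-level offsets plus per-sample jitter),
    peptides add i.i.d. Gaussian noise.  Sequences: each cluster prefers one
    residue per flanking position with probability ``motif_strength`` (the
    rest uniform over the alphabet).  Missingness: whole peptide x run blocks
    are hidden at rate ``missing_frac``, never leaving a peptide with zero
    observed runs.  ``phenotype_effect`` shifts cluster-0 peptides in the
    second half of samples, creating a binary phenotype with ground truth.
    """

    n_peptides: int = 300
    n_samples: int = 24
    n_runs: int = 6
    n_clusters: int = 3
    mean_separation: float = 4.0
    noise_sd: float = 1.0
    motif_strength: float = 0.7
    missing_frac: float = 0.25
    phenotype_effect: float = 0.0
    window_length: int = 11
    independent_motifs: bool = False
    background: np.ndarray = None  # optional non-uniform residue background
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.missing_frac < 1):
            raise ValueError("missing_frac must be in [0, 1)")
        if self.n_clusters > self.n_peptides:
            raise ValueError("more clusters than peptides")
        if self.n_samples % self.n_runs:
            raise ValueError("n_samples must divide evenly into n_runs")


@dataclass
class GroundTruth:
    """Everything the generator knows: labels, templates, motifs, phenotype."""

    labels: np.ndarray  # abundance cluster per peptide
    motif_labels: np.ndarray  # sequence cluster per peptide (== labels unless crossed)
    templates: np.ndarray  # (n_clusters, n_samples)
    preferred_residues: list  # per cluster: dict position -> residue
    phenotype: np.ndarray = None  # per-sample binary labels, if an effect was requested
    spec: dict = field(default_factory=dict)


def _sample_windows(rng, n, labels, spec: SynthSpec):
    half = spec.window_length // 2
    flanks = [p for p in range(-half, half + 1) if p != 0]
    bg = spec.background if spec.background is not None else np.full(len(AA_ORDER), 1 / len(AA_ORDER))
    bg = np.asarray(bg, dtype=float)
    bg = bg / bg.sum()
    centers = sorted(PHOSPHOACCEPTORS)
    prefs = []
    for _ in range(spec.n_clusters):
        prefs.append(
            {
                **{p: AA_ORDER[rng.integers(len(AA_ORDER))] for p in flanks},
                0: centers[rng.integers(len(centers))],
            }
        )
    windows = []
    for i in range(n):
        pref = prefs[labels[i]]
        chars = []
        for p in range(-half, half + 1):
            if p == 0:
                chars.append(pref[0])
            elif rng.random() < spec.motif_strength:
                chars.append(pref[p])
            else:
                chars.append(AA_ORDER[rng.choice(len(AA_ORDER), p=bg)])
        windows.append(SequenceWindow("".join(chars), half))
    return windows, prefs


def generate(spec: SynthSpec):
    """Draw a dataset and its ground truth; bit-identical for a given seed."""
    rng = np.random.default_rng(spec.seed)
    K, n, S = spec.n_clusters, spec.n_peptides, spec.n_samples

    # balanced-ish random cluster assignment, every cluster non-empty
    labels = np.concatenate([np.arange(K), rng.integers(0, K, size=n - K)])
    rng.shuffle(labels)

    sep = spec.mean_separation * spec.noise_sd
    offsets = (np.arange(K) - (K - 1) / 2.0) * sep
    templates = offsets[:, None] + rng.normal(0.0, sep / 2.0, size=(K, S))

    phenotype = None
    if spec.phenotype_effect:
        phenotype = np.array(["A"] * (S // 2) + ["B"] * (S - S // 2))
        templates = templates.copy()
        templates[0, phenotype == "B"] += spec.phenotype_effect * spec.noise_sd

    abundance = templates[labels] + rng.normal(0.0, spec.noise_sd, size=(n, S))

    if spec.independent_motifs:
        motif_labels = np.concatenate([np.arange(K), rng.integers(0, K, size=n - K)])
        rng.shuffle(motif_labels)
    else:
        motif_labels = labels.copy()
    windows, prefs = _sample_windows(rng, n, motif_labels, spec)

    cols_per_run = S // spec.n_runs
    sample_names = [f"sample{j}" for j in range(S)]
    run_map = {sample_names[j]: f"run{j // cols_per_run}" for j in range(S)}
    mask = np.ones((n, S), dtype=bool)
    if spec.missing_frac > 0:
        hide = rng.random((n, spec.n_runs)) < spec.missing_frac
        keep_one = hide.all(axis=1)
        if keep_one.any():  # never hide every run of a peptide
            keep_runs = rng.integers(0, spec.n_runs, size=int(keep_one.sum()))
            hide[np.flatnonzero(keep_one), keep_runs] = False
        for r in range(spec.n_runs):
            cols = slice(r * cols_per_run, (r + 1) * cols_per_run)
            mask[hide[:, r], cols] = False

    ds = PhosphoDataset(
        abundance=np.where(mask, abundance, 0.0),
        mask=mask,
        sequences=windows,
        run_map=run_map,
        peptide_ids=[(f"GENE{i}", f"{windows[i].residues[spec.window_length // 2]}{i}-p") for i in range(n)],
        sample_names=sample_names,
    )
    truth = GroundTruth(
        labels=labels,
        motif_labels=motif_labels,
        templates=templates,
        preferred_residues=prefs,
        phenotype=phenotype,
        spec={k: v for k, v in asdict(spec).items() if not isinstance(v, np.ndarray)},
    )
    return ds, truth


def random_pspl(name: str, seed=None, concentration: float = 0.3, phosphoacceptor_class: str = "S/T") -> PSPLMatrix:
    """A synthetic kinase specificity profile with a few strongly preferred residues.

    Columns are gamma-distributed positive intensities; a small
    ``concentration`` makes each position dominated by one or two residues,
    as real specificity profiles are.
    """
    rng = np.random.default_rng(seed)
    scores = rng.gamma(concentration, 1.0, size=(len(AA_ORDER), len(PSPL_POSITIONS))) + 1e-3
    scores /= scores.mean(axis=0, keepdims=True)
    return PSPLMatrix(kinase_name=name, scores=scores, phosphoacceptor_class=phosphoacceptor_class)


def kinase_motif_cluster(pspl: PSPLMatrix, n_peptides: int, strength: float = 1.0, seed=None) -> list:
    """Sample sequence windows from a kinase's specificity profile.

    Flanking residues are drawn position-wise with probability proportional
    to exp(strength * PSPL score); strength 0 gives uniform sampling, large
    strength concentrates on each position's preferred residue.  The center
    is drawn from the kinase's phosphoacceptor class; position +5 (outside
    the PSPL design) is uniform.
    """
    rng = np.random.default_rng(seed)
    half = 5
    centers = "Y" if pspl.phosphoacceptor_class == "Y" else "ST"
    windows = []
    for _ in range(n_peptides):
        chars = []
        for p in range(-half, half + 1):
            if p == 0:
                chars.append(centers[rng.integers(len(centers))])
            elif p in PSPL_POSITIONS:
                col = pspl.scores[:, PSPL_POSITIONS.index(p)]
                logits = strength * col
                probs = np.exp(logits - logits.max())
                probs /= probs.sum()
                chars.append(AA_ORDER[rng.choice(len(AA_ORDER), p=probs)])
            else:
                chars.append(AA_ORDER[rng.integers(len(AA_ORDER))])
        windows.append(SequenceWindow("".join(chars), half))
    return windows
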