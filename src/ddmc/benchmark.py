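"""Artificial-missingness imputation benchmark and model-fit diagnostics.

The benchmark hides whole TMT runs: for each peptide, iteration ``t`` hides
``t`` randomly chosen observed runs (cumulative — iteration 2 hides a second
run on top of the first), the hidden values are imputed by each method, and
the mean squared error against the true values is reported per method and
iteration.  Because a TMT run is the unit of stochastic coverage in
multiplexed MS, hiding runs (rather than individual cells) mirrors real
missingness structure.

Baselines: per-peptide observed mean, constant zero, per-peptide observed
minimum (dramatically worse; excluded from default reports), and matrix
completion by PCA.  The model-based method imputes each hidden cell with the
peptide's assigned cluster center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import PhosphoDataset, filter_min_runs
from .impute import pca_complete
from .model import DDMC

#: Baselines reported by default ("minimum" is available but far worse).
DEFAULT_BASELINES = ("mean", "zero", "pca")


@dataclass
class MaskedExperiment:
    """A dataset with extra runs hidden, plus the held-out truth.

    ``held_out`` maps peptide row -> array of column indices hidden in this
    iteration's cumulative mask; true values live in the source dataset.
    """

    masked_ds: PhosphoDataset
    held_out: dict
    iteration: int

    def held_out_cells(self):
        """Iterate (row, col) pairs of all held-out cells."""
        for i, cols in self.held_out.items():
            for j in cols:
                yield i, j


def make_masked_experiments(
    ds: PhosphoDataset,
    n_iterations: int,
    min_runs_present: int = 7,
    seed=None,
) -> list:
    """Build the cumulative run-hiding experiments.

    Peptides observed in fewer than ``min_runs_present`` runs are discarded
    first (a benchmark threshold, separate from the model-fit filter).  At
    iteration ``t``, each peptide has ``t`` of its observed runs hidden; runs
    are drawn without replacement per peptide, so the sets are cumulative
    across iterations.  Peptides that would lose every observed run are
    excluded with a warning.
    """
    if n_iterations < 0:
        raise ValueError("n_iterations must be >= 0")
    ds = filter_min_runs(ds, min_runs_present)
    if n_iterations == 0:
        return []
    obs_runs = ds.runs_observed()
    droppable = obs_runs.sum(axis=1) > n_iterations
    if not droppable.all():
        warnings.warn(
            f"{int((~droppable).sum())} peptides would lose all observed runs; excluded"
        )
        ds = ds.subset(np.flatnonzero(droppable))
        obs_runs = ds.runs_observed()

    rng = np.random.default_rng(seed)
    run_cols = ds.run_columns()
    run_ids = list(run_cols)
    # per peptide, a fixed random order of its observed runs
    orders = []
    for i in range(ds.n_peptides):
        observed = [r for k, r in enumerate(run_ids) if obs_runs[i, k]]
        orders.append(rng.permutation(observed))

    experiments = []
    for t in range(1, n_iterations + 1):
        mask = ds.mask.copy()
        held = {}
        for i, order in enumerate(orders):
            cols = np.concatenate([run_cols[r] for r in order[:t]])
            cols = cols[ds.mask[i, cols]]  # only cells actually observed
            mask[i, cols] = False
            held[i] = cols
        masked = PhosphoDataset(
            abundance=np.where(mask, ds.abundance, 0.0),
            mask=mask,
            sequences=list(ds.sequences),
            run_map=dict(ds.run_map),
            peptide_ids=list(ds.peptide_ids),
            sample_names=list(ds.sample_names),
        )
        experiments.append(MaskedExperiment(masked_ds=masked, held_out=held, iteration=t))
    return experiments


def impute_baseline(masked_ds: PhosphoDataset, method: str, rank: int = 5) -> np.ndarray:
    """Complete a masked dataset with a baseline strategy.

    ``mean``/``minimum`` use each peptide's observed statistic, ``zero``
    fills constant 0, ``pca`` runs rank-``rank`` matrix completion.
    """
    X, mask = masked_ds.abundance, masked_ds.mask
    if method == "zero":
        return np.where(mask, X, 0.0)
    if method in ("mean", "minimum"):
        nobs = mask.sum(axis=1)
        if method == "mean":
            stat = np.divide((X * mask).sum(axis=1), nobs, out=np.zeros(len(X)), where=nobs > 0)
        else:
            stat = np.where(nobs > 0, np.where(mask, X, np.inf).min(axis=1), 0.0)
        return np.where(mask, X, stat[:, None])
    if method == "pca":
        return pca_complete(X, mask, rank=rank)
    raise ValueError(f"unknown imputation method {method!r}")


def ddmc_impute(masked_ds: PhosphoDataset, model: DDMC, assignment: str = "hard") -> np.ndarray:
    """Impute hidden cells with the fitted model's cluster centers.

    ``hard`` uses each peptide's assigned cluster center; ``soft`` mixes
    centers by responsibility.
    """
    if assignment == "hard":
        pred = model.means_[model.labels_]
    elif assignment == "soft":
        pred = model.responsibilities_ @ model.means_
    else:
        raise ValueError("assignment must be 'hard' or 'soft'")
    return np.where(masked_ds.mask, masked_ds.abundance, pred)


def imputation_mse(source_ds: PhosphoDataset, experiment: MaskedExperiment, completed: np.ndarray) -> float:
    """MSE over the experiment's held-out cells between truth and a completed matrix."""
    completed = np.asarray(completed)
    if completed.shape != source_ds.abundance.shape:
        raise ValueError("completed matrix shape mismatch")
    errs = []
    for i, j in experiment.held_out_cells():
        if not np.isfinite(completed[i, j]):
            raise ValueError(f"missing prediction for held-out cell ({i}, {j})")
        errs.append((completed[i, j] - source_ds.abundance[i, j]) ** 2)
    return float(np.mean(errs))


def run_imputation_benchmark(
    ds: PhosphoDataset,
    n_clusters: int,
    weight: float,
    n_iterations: int = 5,
    min_runs_present: int = 7,
    seq_method: str = "binomial",
    baselines=DEFAULT_BASELINES,
    assignment: str = "hard",
    seed=None,
):
    """Full benchmark: per-method, per-iteration MSE table (dict of dicts).

    Fits a fresh model on each masked dataset (the model never sees the
    held-out values) and compares against the baseline strategies.
    """
    experiments = make_masked_experiments(ds, n_iterations, min_runs_present, seed)
    results = {m: {} for m in ("ddmc", *baselines)}
    # source rows aligned with the (threshold-filtered, possibly trimmed) experiments
    source = filter_min_runs(ds, min_runs_present)
    if experiments and experiments[0].masked_ds.n_peptides != source.n_peptides:
        ids = {pid: i for i, pid in enumerate(source.peptide_ids)}
        rows = [ids[pid] for pid in experiments[0].masked_ds.peptide_ids]
        source = source.subset(np.asarray(rows))
    for exp in experiments:
        model = DDMC(
            n_clusters=n_clusters, weight=weight, seq_method=seq_method, random_state=seed
        ).fit(exp.masked_ds)
        results["ddmc"][exp.iteration] = imputation_mse(source, exp, ddmc_impute(exp.masked_ds, model, assignment))
        for m in baselines:
            results[m][exp.iteration] = imputation_mse(source, exp, impute_baseline(exp.masked_ds, m))
    return results


def cluster_fit_mse(model: DDMC, ds: PhosphoDataset, n_sample: int = 2000, seed=None) -> float:
    """Average MSE between randomly sampled peptides and their assigned cluster centers.

    Samples ``n_sample`` peptides without replacement (all peptides, with a
    warning, if fewer exist) and averages the squared deviation of each
    peptide's observed values from its hard-assigned center.
    """
    rng = np.random.default_rng(seed)
    n = ds.n_peptides
    if n_sample > n:
        warnings.warn(f"n_sample={n_sample} exceeds {n} peptides; using all")
        rows = np.arange(n)
    else:
        rows = rng.choice(n, size=n_sample, replace=False)
    centers = model.means_[model.labels_[rows]]
    mses = []
    for r, c in zip(rows, centers):
        obs = ds.mask[r]
        if obs.any():
            mses.append(float(np.mean((ds.abundance[r, obs] - c[obs]) ** 2)))
    return float(np.mean(mses))
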