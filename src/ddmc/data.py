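"""Data model and I/O for phosphopeptide tables, TMT-run structure, and PSPL matrices.

A phosphopeptide table has one row per phosphosite: a protein identifier, a
site label (e.g. ``S1943-p``), an 11-residue sequence window centered on the
phosphoacceptor, and one log-abundance column per sample.  Samples belong to
TMT (tandem mass tag) runs; coverage is stochastic per run, so missingness is
block-structured by run.  PSPL (position-scanning peptide library) matrices
are experimental kinase specificity profiles: 20 amino acids by 9 flanking
positions (-5..-1, +1..+4; the central phosphoacceptor is fixed by the assay).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Fixed amino-acid axis order used by every tensor and matrix in the package.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Padding character for windows truncated at protein termini.
PAD = "-"

#: Residues that can carry the phosphate.
PHOSPHOACCEPTORS = frozenset("STY")

#: Nonstandard residues mapped to padding (no substitution/specificity column exists).
NONSTANDARD = frozenset("UXBZJO")

#: Flanking positions covered by a PSPL assay (the 180 = 20 x 9 library design).
PSPL_POSITIONS = (-5, -4, -3, -2, -1, 1, 2, 3, 4)


@dataclass(frozen=True)
class SequenceWindow:
    """A fixed-length, ungapped residue window centered on a phosphoacceptor.

    Parameters
    ----------
    residues
        String over the 20-letter alphabet plus ``-`` padding at the edges.
    center_index
        0-based index of the phosphoacceptor (must be S, T, or Y).
    """

    residues: str
    center_index: int

    def __post_init__(self):
        if len(self.residues) % 2 == 0:
            raise ValueError(f"window length must be odd, got {len(self.residues)}")
        if self.center_index != len(self.residues) // 2:
            raise ValueError("phosphoacceptor must sit at the window center")
        if self.residues[self.center_index] not in PHOSPHOACCEPTORS:
            raise ValueError(
                f"center residue {self.residues[self.center_index]!r} is not S/T/Y "
                f"in window {self.residues!r}"
            )
        bad = set(self.residues) - set(AA_ORDER) - {PAD}
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in window {self.residues!r}")
        # '-' only at the edges: strip and check the interior is contiguous
        if PAD in self.residues.strip(PAD):
            raise ValueError(f"internal padding in window {self.residues!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, offset: int) -> str:
        """Residue at a signed offset from the phosphoacceptor ('-' if padded)."""
        i = self.center_index + offset
        if i < 0 or i >= len(self.residues):
            return PAD
        return self.residues[i]


def clean_window(raw: str, length: int = 11) -> str:
    """Upper-case a raw window, map nonstandard residues to padding, pad/validate length."""
    s = str(raw).strip().upper()
    mapped = []
    for ch in s:
        if ch in NONSTANDARD:
            warnings.warn(
                f"nonstandard residue {ch!r} treated as padding in window {raw!r}",
                stacklevel=2,
            )
            mapped.append(PAD)
        else:
            mapped.append(ch)
    s = "".join(mapped)
    if len(s) != length:
        raise ValueError(f"window {raw!r} has length {len(s)}, expected {length}")
    return s


@dataclass
class PhosphoDataset:
    """Peptide x sample abundance matrix with missingness mask and sequence windows.

    Attributes
    ----------
    abundance : ndarray (n_peptides, n_samples)
        Log-transformed intensities; entries where ``mask`` is False are
        meaningless (kept as 0.0).
    mask : ndarray of bool, same shape
        True where a value was observed.
    sequences : list of SequenceWindow
        One window per row.
    run_map : dict sample -> run identifier
        Every sample belongs to exactly one TMT run.
    peptide_ids : list of (protein, site) tuples
    sample_names : list of str
    """

    abundance: np.ndarray
    mask: np.ndarray
    sequences: list
    run_map: dict
    peptide_ids: list
    sample_names: list = field(default=None)

    def __post_init__(self):
        self.abundance = np.asarray(self.abundance, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.abundance.shape != self.mask.shape:
            raise ValueError("abundance and mask shapes differ")
        if len(self.sequences) != self.abundance.shape[0]:
            raise ValueError("row count does not match number of sequences")
        if self.sample_names is None:
            self.sample_names = [f"sample{j}" for j in range(self.abundance.shape[1])]
        if len(self.sample_names) != self.abundance.shape[1]:
            raise ValueError("sample_names length mismatch")
        missing_runs = [s for s in self.sample_names if s not in self.run_map]
        if missing_runs:
            raise ValueError(f"samples without a TMT run: {missing_runs}")
        if len(self.peptide_ids) != self.abundance.shape[0]:
            raise ValueError("peptide_ids length mismatch")
        # zero out unobserved cells so downstream masked arithmetic is safe
        self.abundance = np.where(self.mask, self.abundance, 0.0)

    @property
    def n_peptides(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[1]

    @property
    def runs(self) -> list:
        seen = {}
        for s in self.sample_names:
            seen.setdefault(self.run_map[s], None)
        return list(seen)

    def run_columns(self) -> dict:
        """Map run identifier -> array of column indices belonging to that run."""
        out = {}
        for j, s in enumerate(self.sample_names):
            out.setdefault(self.run_map[s], []).append(j)
        return {r: np.asarray(cols) for r, cols in out.items()}

    def runs_observed(self) -> np.ndarray:
        """Boolean (n_peptides, n_runs) matrix: peptide observed in run (>=1 sample)."""
        cols = self.run_columns()
        out = np.zeros((self.n_peptides, len(cols)), dtype=bool)
        for k, (_, idx) in enumerate(cols.items()):
            out[:, k] = self.mask[:, idx].any(axis=1)
        return out

    def subset(self, rows: np.ndarray) -> "PhosphoDataset":
        rows = np.asarray(rows)
        return PhosphoDataset(
            abundance=self.abundance[rows].copy(),
            mask=self.mask[rows].copy(),
            sequences=[self.sequences[i] for i in np.atleast_1d(rows)],
            run_map=dict(self.run_map),
            peptide_ids=[self.peptide_ids[i] for i in np.atleast_1d(rows)],
            sample_names=list(self.sample_names),
        )

    def copy(self) -> "PhosphoDataset":
        return self.subset(np.arange(self.n_peptides))

    def to_frame(self, values: np.ndarray = None) -> pd.DataFrame:
        """Export as a phosphopeptide table (NaN where unobserved unless values given)."""
        if values is None:
            values = np.where(self.mask, self.abundance, np.nan)
        df = pd.DataFrame(values, columns=self.sample_names)
        df.insert(0, "sequence", [w.residues for w in self.sequences])
        df.insert(0, "site", [site for _, site in self.peptide_ids])
        df.insert(0, "protein", [prot for prot, _ in self.peptide_ids])
        return df


@dataclass
class SequenceTensor:
    """One-hot peptide x amino-acid x position encoding of sequence windows.

    ``data[i, j, k]`` is 1 when peptide ``i`` carries amino acid ``AA_ORDER[j]``
    at signed position ``positions[k]``, and 0 elsewhere; padded positions are
    all-zero across the amino-acid axis.
    """

    data: np.ndarray  # (n_peptides, 20, n_positions)
    positions: tuple

    @property
    def n_peptides(self) -> int:
        return self.data.shape[0]

    def decode(self, i: int) -> str:
        """Recover the residue string of peptide ``i`` ('-' at padded positions)."""
        out = []
        for k in range(self.data.shape[2]):
            col = self.data[i, :, k]
            out.append(AA_ORDER[int(np.argmax(col))] if col.any() else PAD)
        return "".join(out)


def encode_sequences(ds_or_windows, positions=None) -> SequenceTensor:
    """One-hot encode sequence windows over a signed position range.

    Parameters
    ----------
    ds_or_windows
        A :class:`PhosphoDataset` or a list of :class:`SequenceWindow`.
    positions
        Iterable of signed offsets from the phosphoacceptor; defaults to the
        full window (-5..+5 for 11-mers).
    """
    windows = ds_or_windows.sequences if isinstance(ds_or_windows, PhosphoDataset) else list(ds_or_windows)
    if not windows:
        raise ValueError("no sequence windows to encode")
    if positions is None:
        half = len(windows[0]) // 2
        positions = range(-half, half + 1)
    positions = tuple(int(p) for p in positions)
    data = np.zeros((len(windows), len(AA_ORDER), len(positions)))
    for i, w in enumerate(windows):
        for k, p in enumerate(positions):
            res = w.residue_at(p)
            if res != PAD:
                data[i, AA_INDEX[res], k] = 1.0
    return SequenceTensor(data=data, positions=positions)


def filter_min_runs(ds: PhosphoDataset, min_runs: int) -> PhosphoDataset:
    """Keep peptides observed in at least ``min_runs`` distinct TMT runs.

    Peptides detected in too few runs carry little cross-run signal and are
    discarded before model fitting (default practice: drop single-run peptides).
    Row order is preserved; applying the filter twice equals applying it once.
    """
    if min_runs < 1:
        raise ValueError("min_runs must be >= 1")
    n_runs_obs = ds.runs_observed().sum(axis=1)
    keep = np.flatnonzero(n_runs_obs >= min_runs)
    if keep.size == 0:
        raise ValueError(
            f"no peptides observed in >= {min_runs} runs; lower the threshold"
        )
    if keep.size == ds.n_peptides:
        return ds
    return ds.subset(keep)


def _parse_id(protein, site) -> tuple:
    return (str(protein).strip(), str(site).strip())


def load_phospho_table(
    path,
    run_map_path=None,
    *,
    delimiter=None,
    protein_col="protein",
    site_col="site",
    sequence_col="sequence",
    window_length=11,
) -> PhosphoDataset:
    """Load a delimited phosphopeptide table (and sample->run map) from disk.

    The table needs ``protein``, ``site`` and ``sequence`` columns plus one
    numeric column per sample.  Blank/NaN cells become unobserved entries in
    the mask.  Windows are upper-cased and validated (S/T/Y at the center);
    rows with malformed windows raise with the offending peptide ids listed.

    ``run_map_path`` points to a two-column table (sample, run); if omitted,
    all samples are placed in a single run.
    """
    path = Path(path)
    sep = delimiter if delimiter is not None else ("\t" if path.suffix in (".tsv", ".txt") else ",")
    df = pd.read_csv(path, sep=sep)
    for col in (protein_col, site_col, sequence_col):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    sample_cols = [c for c in df.columns if c not in (protein_col, site_col, sequence_col)]
    if not sample_cols:
        raise ValueError("no sample columns found")

    ids = [_parse_id(p, s) for p, s in zip(df[protein_col], df[site_col])]
    dupes = pd.Series(ids)[pd.Series(ids).duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicated peptide ids: {list(dupes)}")

    windows, bad = [], []
    for pid, raw in zip(ids, df[sequence_col]):
        try:
            s = clean_window(raw, length=window_length)
            windows.append(SequenceWindow(s, len(s) // 2))
        except ValueError as e:
            bad.append((pid, str(e)))
    if bad:
        msg = "; ".join(f"{p[0]} {p[1]}: {err}" for p, err in bad[:10])
        raise ValueError(f"{len(bad)} malformed sequence windows: {msg}")

    values = df[sample_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    mask = np.isfinite(values)

    if run_map_path is not None:
        rm = pd.read_csv(Path(run_map_path), sep=sep if delimiter is not None else None, engine="python")
        run_map = dict(zip(rm.iloc[:, 0].astype(str), rm.iloc[:, 1].astype(str)))
    else:
        run_map = {c: "run1" for c in sample_cols}

    return PhosphoDataset(
        abundance=np.nan_to_num(values),
        mask=mask,
        sequences=windows,
        run_map=run_map,
        peptide_ids=ids,
        sample_names=sample_cols,
    )


def write_phospho_table(ds: PhosphoDataset, path, values=None, cluster_labels=None):
    """Write a dataset back to a delimited table (NaN for unobserved cells).

    ``values`` may be a completed abundance matrix (e.g. after imputation);
    ``cluster_labels`` appends a cluster assignment column.
    """
    path = Path(path)
    df = ds.to_frame(values)
    if cluster_labels is not None:
        df["cluster"] = np.asarray(cluster_labels)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df.to_csv(path, sep=sep, index=False)


def write_run_map(ds: PhosphoDataset, path):
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    pd.DataFrame(
        {"sample": ds.sample_names, "run": [ds.run_map[s] for s in ds.sample_names]}
    ).to_csv(path, sep=sep, index=False)


@dataclass
class PSPLMatrix:
    """Experimental kinase specificity profile: 20 amino acids x 9 flanking positions."""

    kinase_name: str
    scores: np.ndarray  # (20, 9) over PSPL_POSITIONS
    phosphoacceptor_class: str = "S/T"  # "S/T" or "Y"

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(AA_ORDER), len(PSPL_POSITIONS)):
            raise ValueError(
                f"PSPL {self.kinase_name!r}: expected shape "
                f"{(len(AA_ORDER), len(PSPL_POSITIONS))}, got {self.scores.shape}"
            )
        if not np.all(np.isfinite(self.scores)):
            raise ValueError(f"PSPL {self.kinase_name!r} contains non-finite entries")


def _read_pspl_file(path: Path) -> PSPLMatrix:
    df = pd.read_csv(path, sep="\t" if path.suffix in (".tsv", ".txt") else ",", index_col=0)
    try:
        cols = [int(c) for c in df.columns]
    except ValueError as e:
        raise ValueError(f"{path}: position columns must be signed integers") from e
    if tuple(cols) != PSPL_POSITIONS:
        raise ValueError(f"{path}: expected position columns {PSPL_POSITIONS}, got {tuple(cols)}")
    rows = [str(r).strip().upper() for r in df.index]
    if sorted(rows) != sorted(AA_ORDER):
        raise ValueError(f"{path}: rows must be the 20 standard amino acids")
    scores = df.to_numpy(dtype=float)[[rows.index(a) for a in AA_ORDER]]
    name = path.stem
    acceptor = "Y" if name.upper().endswith("_Y") else "S/T"
    return PSPLMatrix(kinase_name=name, scores=scores, phosphoacceptor_class=acceptor)


def load_pspl_collection(path) -> list:
    """Load kinase PSPL matrices from a file or a directory of CSV/TSV files.

    Each file: rows = 20 amino acids, columns = signed positions -5..-1, +1..+4,
    kinase name taken from the file stem.  Names must be unique.
    """
    path = Path(path)
    files = sorted(path.glob("*.csv")) + sorted(path.glob("*.tsv")) if path.is_dir() else [path]
    if not files:
        raise ValueError(f"no PSPL files found under {path}")
    matrices = [_read_pspl_file(f) for f in files]
    names = [m.kinase_name for m in matrices]
    if len(set(names)) != len(names):
        raise ValueError("duplicate kinase names in PSPL collection")
    return matrices


def write_pspl(pspl: PSPLMatrix, path):
    path = Path(path)
    df = pd.DataFrame(pspl.scores, index=list(AA_ORDER), columns=[str(p) for p in PSPL_POSITIONS])
    df.to_csv(path, sep="\t" if path.suffix in (".tsv", ".txt") else ",")
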