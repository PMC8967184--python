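import numpy as np
import pytest

from ddmc import PhosphoDataset, SequenceWindow, SynthSpec, generate


def make_windows(strings):
    return [SequenceWindow(s, len(s) // 2) for s in strings]


@pytest.fixture
def toy_windows():
    # three 11-mers with distinct flank composition
    return make_windows(
        [
            "AAAAASAAAAA",
            "PKLMRTQWERA",
            "--CDESFGHI-",
        ]
    )


@pytest.fixture
def tiny_dataset():
    """4 peptides x 6 samples in 3 runs, one missing block."""
    windows = make_windows(
        ["AAAAASAAAAA", "PKLMRTQWERA", "--CDESFGHI-", "GGGGGYGGGGG"]
    )
    mask = np.ones((4, 6), dtype=bool)
    mask[1, 2:4] = False  # peptide 1 missing run B entirely
    mask[3, 0:2] = False
    abundance = np.arange(24, dtype=float).reshape(4, 6)
    samples = [f"s{j}" for j in range(6)]
    run_map = {"s0": "A", "s1": "A", "s2": "B", "s3": "B", "s4": "C", "s5": "C"}
    return PhosphoDataset(
        abundance=np.where(mask, abundance, 0.0),
        mask=mask,
        sequences=windows,
        run_map=run_map,
        peptide_ids=[(f"P{i}", f"S{i}-p") for i in range(4)],
        sample_names=samples,
    )


@pytest.fixture(scope="session")
def synth_default():
    """Default-condition synthetic dataset with ground truth (shared, read-only)."""
    return generate(SynthSpec(seed=7))


@pytest.fixture(scope="session")
def synth_complete():
    """Fully observed synthetic dataset (no missing blocks)."""
    return generate(SynthSpec(missing_frac=0.0, seed=11))
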