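import numpy as np
import pytest

from seqrs_kit import (
    LabeledSequenceSet,
    OccupancySimConfig,
    make_matched_negatives,
    simulate_occupancy_sites,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def occupancy_with_matched_negatives(
    n: int = 200, window_len: int = 50, motif: str = "A" * 12,
    jitter: int = 5, seed: int = 1, shuffle_order: int = 0,
) -> LabeledSequenceSet:
    """Planted-motif positives plus per-sequence composition-matched shuffles
    as negatives — the standard validation setup for the occupancy model."""
    cfg = OccupancySimConfig(
        n_positive=n, n_negative=0, window_len=window_len,
        motif=motif, plant_offset_jitter=jitter, seed=seed,
    )
    pos = simulate_occupancy_sites(cfg)
    negs = make_matched_negatives(pos.sequences, order=shuffle_order, seed=seed + 7_001)
    seqs = list(pos.sequences) + list(negs)
    labels = np.r_[np.ones(n, int), np.zeros(n, int)]
    centers = np.full(2 * n, window_len // 2, dtype=int)
    return LabeledSequenceSet(seqs, labels, centers)


@pytest.fixture(scope="session")
def labeled_occupancy():
    return occupancy_with_matched_negatives()
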