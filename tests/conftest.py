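import numpy as np
import pytest

from era3d.genome import GenomeModel
from era3d.intervals import IntervalSet


@pytest.fixture
def toy_genome():
    return GenomeModel({"chr1": 100, "chr2": 50})


@pytest.fixture
def kb10_genome():
    return GenomeModel({"chr1": 10_000})


def mask_from_set(s: IntervalSet) -> dict[str, np.ndarray]:
    """Per-base boolean coverage mask: the oracle for interval algebra."""
    masks = {c: np.zeros(L, dtype=bool) for c, L in s.genome.chromosomes.items()}
    for chrom, start, end in s:
        masks[chrom][start:end] = True
    return masks


def set_from_mask(masks: dict[str, np.ndarray], genome: GenomeModel,
                  name: str = "oracle") -> IntervalSet:
    """Minimal sorted interval set covering exactly the masked bases."""
    records = []
    for chrom, mask in masks.items():
        padded = np.concatenate(([False], mask, [False]))
        diff = np.diff(padded.astype(np.int8))
        for s, e in zip(np.flatnonzero(diff == 1), np.flatnonzero(diff == -1)):
            records.append((chrom, int(s), int(e)))
    return IntervalSet.from_records(records, genome, name=name)


def random_interval_set(rng: np.random.Generator, genome: GenomeModel,
                        max_intervals: int = 20) -> IntervalSet:
    records = []
    for chrom, L in genome.chromosomes.items():
        for _ in range(int(rng.integers(0, max_intervals + 1))):
            start = int(rng.integers(0, L - 1))
            end = int(rng.integers(start + 1, min(start + L // 4 + 2, L) + 1))
            records.append((chrom, start, end))
    return IntervalSet.from_records(records, genome, name="random")
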