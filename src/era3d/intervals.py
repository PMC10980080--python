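"""Interval algebra for genomic feature tracks.

All coordinates are 0-based, half-open (BED convention). The operations
mirror the bedtools-style idiom used when pooling published Hi-C feature
annotations (domains, loop anchors, boundaries): collapse overlaps so each
base is counted once, pool datasets across cell types, report coverage
statistics, and subset one track by overlap with another, emitting each
query record at most once.

Bookended intervals (end of one equals start of the next) are merged, the
default of ``bedtools merge``; this affects region counts and is pinned by
tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import InputError, ParseError
from .genome import GenomeModel

logger = logging.getLogger(__name__)

Interval = tuple[str, int, int]


@dataclass
class IntervalSet:
    """A named set of genomic intervals on a genome model.

    ``data`` maps chromosome name to an ``(n, 2)`` int64 array of
    ``[start, end)`` rows. Rows are kept in the order supplied; call
    :meth:`merge` (or :func:`merge_intervals`) to obtain the sorted,
    non-overlapping normal form.
    """

    name: str
    genome: GenomeModel
    data: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls,
        records: Iterable[Interval],
        genome: GenomeModel,
        name: str = "",
        validate: bool = True,
    ) -> "IntervalSet":
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in records:
            if validate:
                _validate_interval(chrom, start, end, genome)
            per_chrom.setdefault(chrom, []).append((int(start), int(end)))
        data = {
            c: np.asarray(rows, dtype=np.int64).reshape(-1, 2)
            for c, rows in per_chrom.items()
        }
        return cls(name=name, genome=genome, data=data)

    def __len__(self) -> int:
        return sum(arr.shape[0] for arr in self.data.values())

    def __iter__(self) -> Iterator[Interval]:
        for chrom in self.genome.names:
            for start, end in self.data.get(chrom, _EMPTY):
                yield chrom, int(start), int(end)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return list(self) == list(other)

    @property
    def coverage(self) -> int:
        """Total covered base pairs, Σ(end − start) over records as stored."""
        return int(
            sum((arr[:, 1] - arr[:, 0]).sum() for arr in self.data.values())
        )

    def sizes(self) -> np.ndarray:
        """Region sizes in bp, genome order."""
        parts = [
            self.data[c][:, 1] - self.data[c][:, 0]
            for c in self.genome.names
            if c in self.data
        ]
        if not parts:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(parts)

    def merge(self, name: str | None = None) -> "IntervalSet":
        return merge_intervals(self, name=name)

    def to_bed(self, path: str | Path) -> None:
        write_bed(self, path)


_EMPTY = np.empty((0, 2), dtype=np.int64)


def _validate_interval(chrom: str, start: int, end: int, genome: GenomeModel) -> None:
    if chrom not in genome:
        raise InputError(f"interval on unknown chromosome {chrom!r}")
    if not (0 <= start < end <= genome.length(chrom)):
        raise InputError(
            f"invalid interval {chrom}:{start}-{end} "
            f"(chromosome length {genome.length(chrom)})"
        )


def read_bed(path: str | Path, genome: GenomeModel, name: str | None = None) -> IntervalSet:
    """Read a BED-like file (3+ tab-separated columns) into an IntervalSet.

    Records on unknown chromosomes or with out-of-bounds/inverted
    coordinates are rejected; the number rejected is logged. Lines that
    cannot be parsed at all raise :class:`ParseError` with the line number.
    """
    records: list[Interval] = []
    rejected = 0
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("expected >=3 tab-separated columns", line=i)
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(
                    f"non-integer coordinates {parts[1]!r}, {parts[2]!r}", line=i
                ) from None
            if chrom not in genome or not (0 <= start < end <= genome.length(chrom)):
                rejected += 1
                continue
            records.append((chrom, start, end))
    if rejected:
        logger.warning("read_bed(%s): rejected %d invalid record(s)", path, rejected)
    return IntervalSet.from_records(
        records, genome, name=name or Path(path).stem, validate=False
    )


def write_bed(s: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in s:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def merge_intervals(s: IntervalSet, name: str | None = None) -> IntervalSet:
    """Collapse overlapping and bookended intervals per chromosome.

    Returns the minimal sorted set covering exactly the same base pairs:
    the normal form every coverage computation in era3d expects.
    """
    merged: dict[str, np.ndarray] = {}
    for chrom, arr in s.data.items():
        if arr.shape[0] == 0:
            continue
        arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
        out: list[list[int]] = [[int(arr[0, 0]), int(arr[0, 1])]]
        for start, end in arr[1:]:
            if start <= out[-1][1]:  # overlap or bookended
                out[-1][1] = max(out[-1][1], int(end))
            else:
                out.append([int(start), int(end)])
        merged[chrom] = np.asarray(out, dtype=np.int64)
    return IntervalSet(name=name if name is not None else s.name,
                       genome=s.genome, data=merged)


def pool_datasets(sets: Sequence[IntervalSet], name: str) -> IntervalSet:
    """Merged union of several interval sets sharing one genome model.

    This is the "pooled" track construction: concatenate all records from
    all cell-type datasets, then collapse overlaps so any given region is
    counted only once.
    """
    if not sets:
        raise InputError("pool_datasets requires at least one interval set")
    genome = sets[0].genome
    for s in sets[1:]:
        if s.genome is not genome and s.genome != genome:
            raise InputError("pool_datasets: interval sets on different genomes")
    data: dict[str, list[np.ndarray]] = {}
    for s in sets:
        for chrom, arr in s.data.items():
            data.setdefault(chrom, []).append(arr)
    combined = IntervalSet(
        name=name,
        genome=genome,
        data={c: np.concatenate(parts) for c, parts in data.items()},
    )
    return merge_intervals(combined, name=name)


@dataclass(frozen=True)
class CoverageStats:
    """Summary of a merged track: region count, median size, coverage, % genome."""

    n_regions: int
    median_size: float | None  # bp; None when the set is empty
    coverage: int  # bp
    proportion: float  # percent of genome covered, 0-100

    def as_dict(self) -> dict:
        return {
            "n_regions": self.n_regions,
            "median_size": self.median_size,
            "coverage": self.coverage,
            "proportion": self.proportion,
        }


def coverage_stats(s: IntervalSet, genome: GenomeModel | None = None) -> CoverageStats:
    """Number of regions, median region size (bp), coverage (bp) and
    proportion of the genome covered (%), for a merged interval set.

    The median uses the average-of-middle-two convention for even counts
    and is reported as ``None`` for an empty set.
    """
    genome = genome or s.genome
    sizes = s.sizes()
    n = sizes.size
    median = float(np.median(sizes)) if n else None
    cov = int(sizes.sum())
    return CoverageStats(
        n_regions=n,
        median_size=median,
        coverage=cov,
        proportion=100.0 * cov / genome.total_length,
    )


def intersect_unique(a: IntervalSet, b: IntervalSet, name: str | None = None) -> IntervalSet:
    """Records of ``a`` having >=1 bp overlap with any record of ``b``.

    Each record of ``a`` is written at most once regardless of how many
    ``b`` regions it overlaps (``bedtools intersect -u`` semantics), and
    ``a``'s records are reported as given, never merged with each other.
    """
    if a.genome is not b.genome and a.genome != b.genome:
        raise InputError("intersect_unique: interval sets on different genomes")
    b_merged = merge_intervals(b)
    out: dict[str, np.ndarray] = {}
    for chrom, arr in a.data.items():
        bm = b_merged.data.get(chrom)
        if bm is None or arr.shape[0] == 0:
            continue
        starts, ends = bm[:, 0], bm[:, 1]
        # a-record [s, e) overlaps some merged b-interval iff the first
        # b-interval with end > s exists and starts before e.
        idx = np.searchsorted(ends, arr[:, 0], side="right")
        keep = (idx < len(starts)) & (starts[np.minimum(idx, len(starts) - 1)] < arr[:, 1])
        if keep.any():
            out[chrom] = arr[keep]
    return IntervalSet(
        name=name if name is not None else f"{a.name}_in_{b.name}",
        genome=a.genome,
        data=out,
    )
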