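"""Genome binning, per-bin feature density, and Spearman correlation.

The central statistic of the package: split the genome into fixed-size bins
(20 kb, 50 kb or 100 kb are the conventional choices), compute in every bin
the fraction of sequence covered by each feature track (a 3D-genome feature
such as pooled domains, or a class of genes), and correlate track densities
pairwise across all genome-wide bins with Spearman's rank correlation.

Bins are pooled across chromosomes ("global" correlation); the last bin of
each chromosome may be shorter and enters with its true length as the
density denominator. Zero-density bins are included — dropping them would
bias rank correlations between sparse tracks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConstantInputError, InputError
from .genome import GenomeModel
from .intervals import IntervalSet, merge_intervals


@dataclass(frozen=True)
class BinGrid:
    """Consecutive fixed-size bins tiling a genome.

    The union of bins equals the genome: every chromosome of length L gets
    ceil(L / bin_size) bins, the last truncated at the chromosome end.
    """

    genome: GenomeModel
    bin_size: int
    bins: pd.DataFrame  # columns: chrom, start, end

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def lengths(self) -> np.ndarray:
        return (self.bins["end"] - self.bins["start"]).to_numpy()


def make_bins(genome: GenomeModel, bin_size: int) -> BinGrid:
    if bin_size <= 0:
        raise InputError(f"bin_size must be positive, got {bin_size}")
    rows = []
    for chrom, length in genome.chromosomes.items():
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    bins = pd.concat(rows, ignore_index=True)
    return BinGrid(genome=genome, bin_size=bin_size, bins=bins)


def _cumulative_coverage(arr: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Covered bp in [0, x) for each x in points, for merged intervals arr."""
    if arr.shape[0] == 0:
        return np.zeros(len(points), dtype=np.int64)
    starts, ends = arr[:, 0], arr[:, 1]
    lengths = ends - starts
    cum = np.concatenate(([0], np.cumsum(lengths)))
    # number of intervals starting strictly before x
    i = np.searchsorted(starts, points, side="right")
    covered = cum[i]
    # subtract the part of the last-started interval lying at or beyond x
    has_prev = i > 0
    prev_end = ends[np.maximum(i - 1, 0)]
    overshoot = np.where(has_prev, np.maximum(prev_end - points, 0), 0)
    return covered - overshoot


def bin_density(grid: BinGrid, track: IntervalSet) -> np.ndarray:
    """Per-bin covered fraction of ``track`` on ``grid``.

    The track is collapsed to its merged normal form first, so each base
    contributes once. Conservation: sum(fraction * bin length) equals the
    merged track's total coverage.
    """
    if track.genome != grid.genome:
        raise InputError("bin_density: track and grid on different genomes")
    merged = merge_intervals(track)
    frac = np.zeros(grid.n_bins, dtype=float)
    for chrom, sub in grid.bins.groupby("chrom", sort=False):
        arr = merged.data.get(chrom)
        if arr is None:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cov = _cumulative_coverage(arr, ends) - _cumulative_coverage(arr, starts)
        frac[sub.index] = cov / (ends - starts)
    return frac


@dataclass
class BinDensityTable:
    """Per-bin covered fractions for a collection of named tracks."""

    grid: BinGrid
    densities: pd.DataFrame  # one column per track, index aligned to grid.bins

    @classmethod
    def from_tracks(cls, grid: BinGrid, tracks: Sequence[IntervalSet]) -> "BinDensityTable":
        cols = {t.name: bin_density(grid, t) for t in tracks}
        return cls(grid=grid, densities=pd.DataFrame(cols))

    def add_track(self, track: IntervalSet) -> None:
        self.densities[track.name] = bin_density(self.grid, track)

    @property
    def track_names(self) -> list[str]:
        return list(self.densities.columns)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.grid.bins.reset_index(drop=True), self.densities], axis=1)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n: int


def spearman(x: np.ndarray, y: np.ndarray) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    rho is the Pearson correlation of the rank-transformed vectors; the
    two-sided p value comes from the t approximation on n-2 degrees of
    freedom, appropriate for the thousands of bins of a genome-wide grid.
    Constant input is an error, not a silent zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("spearman: x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise InputError("spearman: need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError("spearman: correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return SpearmanResult(rho=float(rho), p=float(p), n=len(x))


@dataclass(frozen=True)
class CorrelationResult:
    track_a: str
    track_b: str
    rho: float  # NaN when undefined (constant track)
    p: float
    n: int
    bin_size: int
    significant: bool
    error: str | None = None


def correlation_matrix(
    table: BinDensityTable,
    tracks: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> tuple[list[CorrelationResult], pd.DataFrame]:
    """All pairwise Spearman correlations between track densities.

    Returns the long-format results (one row per unordered pair) and a
    symmetric rho matrix ready for heatmap plotting (diagonal 1). Pairs
    involving a constant track carry NaN and the error message rather than
    aborting the whole matrix.
    """
    names = list(tracks) if tracks is not None else table.track_names
    if len(names) < 2:
        raise InputError("correlation_matrix: need at least 2 tracks")
    results: list[CorrelationResult] = []
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            try:
                r = spearman(table.densities[a].to_numpy(), table.densities[b].to_numpy())
                res = CorrelationResult(
                    track_a=a, track_b=b, rho=r.rho, p=r.p, n=r.n,
                    bin_size=table.grid.bin_size, significant=r.p < alpha,
                )
            except ConstantInputError as exc:
                res = CorrelationResult(
                    track_a=a, track_b=b, rho=float("nan"), p=float("nan"),
                    n=table.grid.n_bins, bin_size=table.grid.bin_size,
                    significant=False, error=str(exc),
                )
            results.append(res)
            mat.loc[a, b] = mat.loc[b, a] = res.rho
    return results, mat


def correlation_results_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    """Long-format TSV-ready table (track_a, track_b, bin_size, rho, p, n)."""
    return pd.DataFrame(
        {
            "track_a": [r.track_a for r in results],
            "track_b": [r.track_b for r in results],
            "bin_size": [r.bin_size for r in results],
            "rho": [r.rho for r in results],
            "p": [r.p for r in results],
            "n": [r.n for r in results],
            "significant": [r.significant for r in results],
        }
    )
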