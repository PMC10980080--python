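"""Expression pipeline: normalization, aggregation and group comparisons.

Counts are normalized with the median-of-ratios method (the DESeq2 size
factor): per gene, the geometric mean across samples is taken over genes
with all-nonzero counts, and a sample's factor is the median across those
genes of count / geometric mean. This corrects for sequencing depth and
RNA composition without assuming most genes change.

Normalized counts are averaged per tissue and then per tissue category
(germ layers, germ line, brain; a tissue may belong to several categories,
e.g. cortex and cerebellum count in both ectoderm and brain). Groups of
genes — evolutionary eras or intergenic controls — are compared with the
two-sided Mann-Whitney U test (tie- and continuity-corrected normal
approximation), Benjamini-Hochberg corrected across the comparisons
requested in one run. Reported p values are floored at 2.225e-308, the
smallest positive normal double. A log10 display transform adds the
smallest nonzero value to every argument so zeros remain plottable;
summaries (mean, SEM, median) are always computed on untransformed values.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InputError, NormalizationError, TransformError

logger = logging.getLogger(__name__)

P_FLOOR = 2.225e-308  # smallest positive normal double; reported floor


@dataclass
class ExpressionMatrix:
    """Gene x sample count matrix with sample->tissue and category maps.

    ``categories`` maps a category name to the tissues it aggregates;
    tissues may appear in more than one category.
    """

    counts: pd.DataFrame  # genes x samples, non-negative
    sample_to_tissue: dict[str, str]
    categories: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise InputError("expression counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.sample_to_tissue]
        if missing:
            raise InputError(f"samples without tissue assignment: {missing[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def tissues(self) -> list[str]:
        return sorted(set(self.sample_to_tissue.values()))

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        counts_path: str | Path,
        sample_map_path: str | Path,
        categories: Mapping[str, Sequence[str]],
    ) -> "ExpressionMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        smap = pd.read_csv(sample_map_path, sep="\t", names=["sample", "tissue"],
                           comment="#")
        return cls(
            counts=counts,
            sample_to_tissue=dict(zip(smap["sample"], smap["tissue"])),
            categories={k: list(v) for k, v in categories.items()},
        )


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample (column).

    Only genes with nonzero counts in every sample contribute; if no such
    gene exists the normalization is undefined.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.size == 0:
        raise NormalizationError("size_factors: empty count matrix")
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise NormalizationError(
            "size_factors: no gene has nonzero counts in every sample"
        )
    sub = mat[all_nonzero]
    log_geo_mean = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo_mean)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample's counts by its median-of-ratios size factor."""
    factors = size_factors(matrix.counts)
    return ExpressionMatrix(
        counts=matrix.counts / factors,
        sample_to_tissue=matrix.sample_to_tissue,
        categories=matrix.categories,
    )


def aggregate_by_category(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Mean normalized count per gene per tissue category.

    Per gene: first the mean over each tissue's samples, then the mean of
    those tissue means over the category's tissues. Tissues shared between
    categories contribute to each.
    """
    if not matrix.categories:
        raise ConfigError("aggregate_by_category: no categories configured")
    tissue_means: dict[str, pd.Series] = {}
    for tissue in set(matrix.sample_to_tissue.values()):
        samples = [s for s, t in matrix.sample_to_tissue.items() if t == tissue]
        tissue_means[tissue] = matrix.counts[samples].mean(axis=1)
    out = {}
    for category, tissues in matrix.categories.items():
        if not tissues:
            raise ConfigError(f"category {category!r} has no tissues")
        missing = [t for t in tissues if t not in tissue_means]
        if missing:
            raise ConfigError(
                f"category {category!r} references unknown tissues {missing}"
            )
        out[category] = pd.concat(
            [tissue_means[t] for t in tissues], axis=1
        ).mean(axis=1)
    return pd.DataFrame(out)


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sem: float
    median: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    """One Mann-Whitney comparison between two gene groups in one category."""

    group_a: str
    group_b: str
    category: str
    u_statistic: float
    p: float
    p_adjusted: float
    summary_a: GroupSummary
    summary_b: GroupSummary


def _summary(values: np.ndarray) -> GroupSummary:
    n = len(values)
    return GroupSummary(
        mean=float(np.mean(values)),
        sem=float(np.std(values, ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        median=float(np.median(values)),
        n=n,
    )


def compare_groups(
    values: pd.DataFrame | pd.Series,
    grouping: Mapping[str, str],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[GroupComparison]:
    """Pairwise Mann-Whitney U tests between gene groups, BH-corrected.

    ``values`` is a per-gene Series or a genes x categories DataFrame;
    ``grouping`` maps gene id to its group label (era or control class).
    By default all unordered group pairs are compared in every category;
    the BH family is the full set of comparisons of this one call.
    Empty or singleton-missing groups are skipped with a warning.
    """
    if isinstance(values, pd.Series):
        values = values.to_frame(name=values.name or "value")
    groups: dict[str, list[str]] = {}
    for gene, label in grouping.items():
        if gene in values.index:
            groups.setdefault(label, []).append(gene)
    labels = [g for g in groups if groups[g]]
    if pairs is None:
        pairs = list(itertools.combinations(labels, 2))
    raw: list[tuple[str, str, str, float, float, GroupSummary, GroupSummary]] = []
    for category in values.columns:
        col = values[category]
        for a, b in pairs:
            if a not in groups or b not in groups:
                logger.warning("compare_groups: skipping (%s, %s): empty group", a, b)
                continue
            va = col.loc[groups[a]].to_numpy(dtype=float)
            vb = col.loc[groups[b]].to_numpy(dtype=float)
            u, p = stats.mannwhitneyu(
                va, vb, alternative="two-sided", method="asymptotic"
            )
            raw.append((a, b, category, float(u), float(p), _summary(va), _summary(vb)))
    if not raw:
        return []
    adjusted = benjamini_hochberg(np.array([r[4] for r in raw]))
    return [
        GroupComparison(
            group_a=a, group_b=b, category=cat, u_statistic=u,
            p=max(p, P_FLOOR), p_adjusted=max(float(padj), P_FLOOR),
            summary_a=sa, summary_b=sb,
        )
        for (a, b, cat, u, p, sa, sb), padj in zip(raw, adjusted)
    ]


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p values, monotone and capped at 1."""
    return stats.false_discovery_control(p, method="bh")


def comparisons_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """TSV-ready long table of group comparisons."""
    return pd.DataFrame(
        {
            "group_a": [c.group_a for c in comparisons],
            "group_b": [c.group_b for c in comparisons],
            "category": [c.category for c in comparisons],
            "U": [c.u_statistic for c in comparisons],
            "p": [c.p for c in comparisons],
            "p_adj": [c.p_adjusted for c in comparisons],
            "mean_a": [c.summary_a.mean for c in comparisons],
            "sem_a": [c.summary_a.sem for c in comparisons],
            "median_a": [c.summary_a.median for c in comparisons],
            "n_a": [c.summary_a.n for c in comparisons],
            "mean_b": [c.summary_b.mean for c in comparisons],
            "sem_b": [c.summary_b.sem for c in comparisons],
            "median_b": [c.summary_b.median for c in comparisons],
            "n_b": [c.summary_b.n for c in comparisons],
        }
    )


def length_decile_stratify(
    lengths: Mapping[str, int],
    values: pd.Series,
    grouping: Mapping[str, str],
    n_quantiles: int = 10,
) -> pd.DataFrame:
    """Per-length-decile, per-group expression summaries.

    Deciles are taken over the pooled gene set by coding length, ties
    broken by rank order so decile sizes differ by at most one. Returns a
    table (decile, group, mean, sem, median, n) with a ``degenerate`` flag
    when all lengths are identical (deciles then carry no information).
    """
    genes = [g for g in values.index if g in lengths and g in grouping]
    if len(genes) < n_quantiles:
        raise InputError(
            f"length_decile_stratify: need >= {n_quantiles} genes, got {len(genes)}"
        )
    lens = np.array([lengths[g] for g in genes], dtype=float)
    degenerate = bool(np.all(lens == lens[0]))
    if degenerate:
        logger.warning("length_decile_stratify: all lengths identical; "
                       "deciles are degenerate")
    order = np.argsort(lens, kind="stable")
    ranks = np.empty(len(genes), dtype=int)
    ranks[order] = np.arange(len(genes))
    deciles = ranks * n_quantiles // len(genes)
    rows = []
    frame = pd.DataFrame(
        {
            "value": values.loc[genes].to_numpy(dtype=float),
            "decile": deciles,
            "group": [grouping[g] for g in genes],
        }
    )
    for (decile, group), sub in frame.groupby(["decile", "group"], sort=True):
        s = _summary(sub["value"].to_numpy())
        rows.append(
            {
                "decile": int(decile), "group": group, "mean": s.mean,
                "sem": s.sem, "median": s.median, "n": s.n,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def log10_display(values: np.ndarray | pd.Series) -> np.ndarray:
    """log10 with the zero-handling rule: add the smallest nonzero value
    to every argument. Strictly increasing in the input; display only."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise InputError("log10_display: negative values")
    nonzero = arr[arr > 0]
    if nonzero.size == 0:
        raise TransformError("log10_display: all values are zero")
    m = nonzero.min()
    return np.log10(arr + m)
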