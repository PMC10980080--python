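"""Phylostratigraphic gene-age assignment from homology hit tables.

A gene's minimal evolutionary age is the age of the most distant species in
which a sufficiently similar protein is found: each species on the query
lineage maps to one of 31 phylostrata (PS 1 = cellular organisms, the most
ancient; PS 31 = restricted to the query species). An isoform's
phylostratum is the minimum PS among its homology hits passing the e-value
cutoff (strictly below 1e-3 by default); a gene is represented by the
longest of its oldest isoforms. Phylostrata are grouped into eras with
either a five-era scheme (Ancient PS 1-3, Metazoan PS 4-7, Chordate
PS 8-17, Mammal PS 18-22, Primate PS 23-31) or the four-era scheme used
when comparing against synteny-based ages (Early PS 1-13, Vertebrate
PS 14-17, Mammal PS 18-22, Primate PS 23-31).

Hit tables are inputs here: running the underlying similarity searches is
out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyComparisonError, InputError

logger = logging.getLogger(__name__)

N_PHYLOSTRATA = 31

HIT_COLUMNS = ["gene_id", "isoform_id", "species", "evalue"]


@dataclass(frozen=True)
class Taxonomy:
    """Ordered lineage taxonomy: species -> phylostratum (1..31).

    The query species must map to the youngest phylostratum (31). Node ages
    in million years are optional annotation and unused by assignment.
    """

    species_to_ps: dict[str, int]
    query_species: str
    node_ages_mya: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.species_to_ps:
            raise ConfigError("taxonomy is empty")
        for sp, ps in self.species_to_ps.items():
            if not (1 <= ps <= N_PHYLOSTRATA):
                raise ConfigError(f"species {sp!r} maps to invalid phylostratum {ps}")
        if self.species_to_ps.get(self.query_species) != N_PHYLOSTRATA:
            raise ConfigError(
                f"query species {self.query_species!r} must map to PS {N_PHYLOSTRATA}"
            )

    def resolve(self, species: str) -> int:
        try:
            return self.species_to_ps[species]
        except KeyError:
            raise InputError(f"species {species!r} not in taxonomy") from None

    @classmethod
    def from_tsv(cls, path: str | Path, query_species: str) -> "Taxonomy":
        """Read a species<TAB>phylostratum[<TAB>mya] table."""
        df = pd.read_csv(path, sep="\t", comment="#",
                         names=["species", "phylostratum", "mya"],
                         usecols=[0, 1, 2], engine="python")
        ages = {}
        for _, row in df.iterrows():
            if pd.notna(row.get("mya")):
                ages.setdefault(int(row["phylostratum"]), float(row["mya"]))
        return cls(
            species_to_ps=dict(zip(df["species"], df["phylostratum"].astype(int))),
            query_species=query_species,
            node_ages_mya=ages,
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sp, ps in self.species_to_ps.items():
                mya = self.node_ages_mya.get(ps, "")
                fh.write(f"{sp}\t{ps}\t{mya}\n")


@dataclass(frozen=True)
class EraScheme:
    """A total map from phylostrata 1..31 to named evolutionary eras."""

    name: str
    boundaries: tuple[tuple[str, int, int], ...]  # (label, ps_lo, ps_hi) inclusive

    def __post_init__(self) -> None:
        covered = sorted(
            ps for _, lo, hi in self.boundaries for ps in range(lo, hi + 1)
        )
        if covered != list(range(1, N_PHYLOSTRATA + 1)):
            raise ConfigError(f"era scheme {self.name!r} is not total over PS 1..31")

    @property
    def labels(self) -> list[str]:
        """Era labels ordered oldest to youngest."""
        return [label for label, _, _ in self.boundaries]

    def era_of(self, ps: int) -> str:
        if not (1 <= ps <= N_PHYLOSTRATA):
            raise InputError(f"phylostratum {ps} out of range 1..{N_PHYLOSTRATA}")
        for label, lo, hi in self.boundaries:
            if lo <= ps <= hi:
                return label
        raise AssertionError("unreachable: scheme is total")

    def rank(self, era: str) -> int:
        """0 for the oldest era, increasing toward the youngest."""
        try:
            return self.labels.index(era)
        except ValueError:
            raise InputError(f"unknown era {era!r} in scheme {self.name!r}") from None


FIVE_ERA = EraScheme(
    "five_era",
    (
        ("Ancient", 1, 3),
        ("Metazoan", 4, 7),
        ("Chordate", 8, 17),
        ("Mammal", 18, 22),
        ("Primate", 23, 31),
    ),
)

FOUR_ERA = EraScheme(
    "four_era",
    (
        ("Early", 1, 13),
        ("Vertebrate", 14, 17),
        ("Mammal", 18, 22),
        ("Primate", 23, 31),
    ),
)

SCHEMES = {s.name: s for s in (FIVE_ERA, FOUR_ERA)}


@dataclass(frozen=True)
class GeneRecord:
    """One gene or isoform with coordinates, protein length and age labels."""

    gene_id: str
    isoform_id: str
    chrom: str
    start: int
    end: int
    protein_length: int | None = None
    phylostratum: int | None = None
    era: str | None = None
    annotated: bool = True

    @property
    def length(self) -> int:
        return self.end - self.start


def load_hit_table(path: str | Path, taxonomy: Taxonomy) -> pd.DataFrame:
    """Read a TSV hit table (gene_id, isoform_id, species, evalue).

    Hits on species absent from the taxonomy are rejected at load time.
    """
    df = pd.read_csv(path, sep="\t", comment="#", names=HIT_COLUMNS, dtype={
        "gene_id": str, "isoform_id": str, "species": str, "evalue": float,
    })
    unknown = ~df["species"].isin(taxonomy.species_to_ps)
    if unknown.any():
        bad = sorted(df.loc[unknown, "species"].unique())
        raise InputError(f"hit table contains unresolvable species: {bad[:5]}")
    if (df["evalue"] < 0).any():
        raise InputError("hit table contains negative e-values")
    return df


def filter_proteins(
    isoforms: Iterable[GeneRecord], min_aa: int = 40, max_aa: int = 4000
) -> list[GeneRecord]:
    """Keep isoforms with min_aa <= protein length < max_aa.

    Short proteins cannot be assigned a lineage restriction level reliably;
    extremely long ones are removed for parity with the boundary convention
    '< 40 AA removed, >= 4,000 AA removed'. Records without a length are
    rejected with a warning.
    """
    kept: list[GeneRecord] = []
    n_short = n_long = n_missing = 0
    for rec in isoforms:
        if rec.protein_length is None:
            n_missing += 1
            continue
        if rec.protein_length < min_aa:
            n_short += 1
        elif rec.protein_length >= max_aa:
            n_long += 1
        else:
            kept.append(rec)
    if n_short or n_long or n_missing:
        logger.info(
            "filter_proteins: removed %d short (<%d AA), %d long (>=%d AA), "
            "%d missing-length",
            n_short, min_aa, n_long, max_aa, n_missing,
        )
    if n_missing:
        logger.warning("filter_proteins: %d record(s) had no protein length", n_missing)
    return kept


def assign_phylostratum(
    hits: pd.DataFrame, taxonomy: Taxonomy, evalue_cutoff: float = 1e-3
) -> int:
    """Minimal phylostratum among hits passing the e-value cutoff.

    The most distant (most ancient) species with a hit whose e-value is
    strictly below the cutoff determines the age. Self-species hits carry
    no lineage information and are ignored; with no qualifying non-self
    hit the isoform is restricted to the query species (PS 31).
    """
    if evalue_cutoff <= 0:
        raise ConfigError(f"evalue_cutoff must be positive, got {evalue_cutoff}")
    if len(hits) == 0:
        return N_PHYLOSTRATA
    passing = hits[
        (hits["evalue"] < evalue_cutoff)
        & (hits["species"] != taxonomy.query_species)
    ]
    if len(passing) == 0:
        return N_PHYLOSTRATA
    return int(min(taxonomy.resolve(sp) for sp in passing["species"]))


def select_representative(isoforms: Sequence[GeneRecord]) -> GeneRecord:
    """The longest of the oldest isoforms of one gene.

    Oldest = minimal phylostratum number; among those, maximal protein
    length; equal lengths break ties by lexicographically smallest
    isoform id, so the choice is deterministic.
    """
    if not isoforms:
        raise InputError("select_representative: no isoforms given")
    return min(
        isoforms,
        key=lambda r: (r.phylostratum, -(r.protein_length or 0), r.isoform_id),
    )


def map_to_era(ps: int, scheme: EraScheme) -> str:
    return scheme.era_of(ps)


def assign_ages(
    isoforms: Sequence[GeneRecord],
    hits: pd.DataFrame,
    taxonomy: Taxonomy,
    evalue_cutoff: float = 1e-3,
) -> pd.DataFrame:
    """Per-gene age table from per-isoform hit lists.

    Assigns each isoform its minimal phylostratum, picks the longest of the
    oldest isoforms per gene, and labels it under both era schemes. Returns
    a DataFrame with columns gene_id, isoform_id, phylostratum, era_five,
    era_four.
    """
    by_isoform = dict(tuple(hits.groupby("isoform_id", sort=False))) if len(hits) else {}
    empty = hits.iloc[0:0] if len(hits) else pd.DataFrame(columns=HIT_COLUMNS)
    aged: dict[str, list[GeneRecord]] = {}
    for rec in isoforms:
        ps = assign_phylostratum(
            by_isoform.get(rec.isoform_id, empty), taxonomy, evalue_cutoff
        )
        aged.setdefault(rec.gene_id, []).append(replace(rec, phylostratum=ps))
    rows = []
    for gene_id, recs in aged.items():
        rep = select_representative(recs)
        rows.append(
            {
                "gene_id": gene_id,
                "isoform_id": rep.isoform_id,
                "phylostratum": rep.phylostratum,
                "era_five": FIVE_ERA.era_of(rep.phylostratum),
                "era_four": FOUR_ERA.era_of(rep.phylostratum),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "isoform_id", "phylostratum",
                                       "era_five", "era_four"])


@dataclass(frozen=True)
class MethodComparison:
    """Per-gene and summary comparison of two era assignments."""

    per_gene: pd.DataFrame  # gene_id, era_a, era_b, cls
    n: int
    fraction_same: float
    fraction_younger_by_a: float
    fraction_younger_by_b: float
    fraction_oldest_a: float
    fraction_oldest_b: float


def compare_age_methods(
    ages_a: Mapping[str, str],
    ages_b: Mapping[str, str],
    era_order: Sequence[str],
) -> MethodComparison:
    """Gene-by-gene comparison of two era assignments on their shared genes.

    Classes: ``same`` when both methods give the same era; ``younger_by_a``
    when method a places the gene in a later (younger) era than method b;
    ``younger_by_b`` for the converse. Era rank follows ``era_order``
    (oldest first). Also reports each method's fraction of genes in the
    oldest era.
    """
    common = sorted(set(ages_a) & set(ages_b))
    if not common:
        raise EmptyComparisonError("compare_age_methods: no shared genes")
    logger.info("compare_age_methods: %d shared genes", len(common))
    order = {era: i for i, era in enumerate(era_order)}
    rows = []
    for g in common:
        ra, rb = order[ages_a[g]], order[ages_b[g]]
        cls = "same" if ra == rb else ("younger_by_a" if ra > rb else "younger_by_b")
        rows.append((g, ages_a[g], ages_b[g], cls))
    per_gene = pd.DataFrame(rows, columns=["gene_id", "era_a", "era_b", "cls"])
    n = len(per_gene)
    counts = per_gene["cls"].value_counts()
    oldest = era_order[0]
    return MethodComparison(
        per_gene=per_gene,
        n=n,
        fraction_same=counts.get("same", 0) / n,
        fraction_younger_by_a=counts.get("younger_by_a", 0) / n,
        fraction_younger_by_b=counts.get("younger_by_b", 0) / n,
        fraction_oldest_a=(per_gene["era_a"] == oldest).mean(),
        fraction_oldest_b=(per_gene["era_b"] == oldest).mean(),
    )


def era_counts(ages: pd.DataFrame, scheme: EraScheme = FIVE_ERA,
               column: str = "era_five") -> pd.Series:
    """Number of genes per era, ordered oldest to youngest."""
    counts = ages[column].value_counts()
    return pd.Series({era: int(counts.get(era, 0)) for era in scheme.labels})
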