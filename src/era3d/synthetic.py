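"""Synthetic genomes, era-labeled genes, feature tracks, hit tables and
count matrices for exercising the full analysis pipeline without any
external download.

The generator plants known structure so downstream modules can be checked
for parameter recovery:

* genes carry a planted evolutionary-era label and non-overlapping
  coordinates on a toy genome, with soft-masked (lowercase) repeat-like
  patches in the intergenic sequence;
* feature tracks are built from fixed-size candidate windows kept with
  era-weighted Bernoulli odds, so the enrichment of a track around genes
  of a chosen era is a tunable multiplier (1 = no association);
* homology hit tables place, for every gene, its most distant sub-cutoff
  hit in a phylostratum consistent with the planted era, plus closer hits
  and above-cutoff decoys that a correct assignment must ignore;
* expression counts are negative-binomial with a per-era mean, a
  lognormal per-gene effect and lognormal per-sample depth factors, so
  both the size-factor normalization and the era gradient are testable.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ages import FIVE_ERA, GeneRecord, Taxonomy, N_PHYLOSTRATA, HIT_COLUMNS
from .errors import ConfigError, SizingError
from .expression import ExpressionMatrix
from .genome import GenomeModel
from .intervals import IntervalSet, merge_intervals
from .orfs import reverse_complement

ERAS = FIVE_ERA.labels  # Ancient, Metazoan, Chordate, Mammal, Primate

# era -> inclusive phylostratum range, from the five-era scheme
ERA_PS_RANGE = {label: (lo, hi) for label, lo, hi in FIVE_ERA.boundaries}

#: Tissue categories used by default: three germ layers, the germ line and
#: the brain; cortex and cerebellum belong to both ectoderm and brain.
DEFAULT_CATEGORIES: dict[str, list[str]] = {
    "ectoderm": ["cortex", "cerebellum", "skin"],
    "mesoderm": ["heart", "muscle"],
    "endoderm": ["liver", "lung"],
    "ovary": ["ovary"],
    "testis": ["testis"],
    "brain": ["cortex", "cerebellum", "amygdala"],
}

#: Default per-era expression means (counts). Ancient and primate anchor a
#: roughly log-linear gradient between the extremes typical of adult-tissue
#: mean counts; intermediates interpolate.
DEFAULT_EXPRESSION_MEANS: dict[str, float] = {
    "Ancient": 2700.0,
    "Metazoan": 1200.0,
    "Chordate": 550.0,
    "Mammal": 260.0,
    "Primate": 120.0,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    ``genes_per_era`` sets how many genes carry each planted era label;
    ``track_enrichment`` gives the per-era odds multiplier for feature
    track placement (1 everywhere = null track); ``expression_means`` the
    per-era negative-binomial mean and ``dispersion`` its overdispersion
    (var = mu + dispersion * mu^2).
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrA": 5_000_000, "chrB": 5_000_000}
    )
    genes_per_era: dict[str, int] = field(
        default_factory=lambda: {era: 100 for era in ERAS}
    )
    gene_length_log_mean: float = float(np.log(2000.0))  # lognormal, bp
    gene_length_log_sigma: float = 0.5
    min_gene_length: int = 150
    track_enrichment: dict[str, float] = field(
        default_factory=lambda: {era: 1.0 for era in ERAS}
    )
    track_window: int = 1000  # bp, candidate-window size for track placement
    track_base_coverage: float = 0.25  # marginal keep probability at odds 1
    expression_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXPRESSION_MEANS)
    )
    dispersion: float = 0.5
    gene_effect_sigma: float = 0.5  # lognormal per-gene expression scatter
    depth_sigma: float = 0.2  # lognormal per-sample depth scatter
    samples_per_tissue: int = 3
    categories: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CATEGORIES.items()}
    )
    mask_fraction: float = 0.2  # fraction of intergenic sequence soft-masked
    seed: int = 0

    def __post_init__(self) -> None:
        for era, n in self.genes_per_era.items():
            if n < 0:
                raise ConfigError(f"genes_per_era[{era!r}] must be >= 0, got {n}")
        for era, m in self.track_enrichment.items():
            if m <= 0:
                raise ConfigError(f"track_enrichment[{era!r}] must be > 0, got {m}")
        if self.dispersion <= 0:
            raise ConfigError(f"dispersion must be > 0, got {self.dispersion}")
        if not (0 < self.track_base_coverage < 1):
            raise ConfigError("track_base_coverage must be in (0, 1)")
        if not (0 <= self.mask_fraction < 1):
            raise ConfigError("mask_fraction must be in [0, 1)")


@dataclass
class SyntheticGenome:
    """Output of :func:`gen_genome`: coordinates, labels and sequence."""

    genome: GenomeModel
    genes: list[GeneRecord]
    sequence: dict[str, str] | None  # soft-masked; None when not requested
    mask: IntervalSet  # soft-masked (repeat-like) intervals

    def gene_intervals(self, era: str | None = None, name: str | None = None) -> IntervalSet:
        """Gene spans as an interval set, optionally restricted to one era."""
        recs = [g for g in self.genes if era is None or g.era == era]
        label = name or (f"{era}_genes" if era else "genes")
        return IntervalSet.from_records(
            [(g.chrom, g.start, g.end) for g in recs], self.genome, name=label
        )

    @property
    def planted_eras(self) -> dict[str, str]:
        return {g.gene_id: g.era for g in self.genes}


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def gen_genome(spec: SyntheticSpec, with_sequence: bool = True) -> SyntheticGenome:
    """Generate a toy genome with non-overlapping, era-labeled genes.

    Gene lengths are lognormal (rounded to whole codons); placement is
    uniform with rejection of overlaps. Era labels are assigned in a
    seed-shuffled order. When ``with_sequence`` is set, random ACGT
    sequence is produced with ``mask_fraction`` of the intergenic part
    soft-masked in patches (lowercase), leaving unmasked intergenic
    sequence between genes.
    """
    rng = np.random.default_rng(spec.seed)
    genome = GenomeModel(dict(spec.chrom_lengths))
    n_total = sum(spec.genes_per_era.values())

    labels = [era for era in ERAS for _ in range(spec.genes_per_era.get(era, 0))]
    # eras absent from the five-era scheme are appended deterministically
    for era, n in spec.genes_per_era.items():
        if era not in ERAS:
            labels.extend([era] * n)
    rng.shuffle(labels)

    lengths = np.exp(
        rng.normal(spec.gene_length_log_mean, spec.gene_length_log_sigma, n_total)
    )
    lengths = np.maximum(lengths.astype(np.int64), spec.min_gene_length)
    lengths = (lengths // 3) * 3  # whole codons
    if lengths.sum() > 0.5 * genome.total_length:
        raise SizingError(
            f"requested {lengths.sum()} bp of genes on a {genome.total_length} bp "
            "genome; genes may cover at most half the genome"
        )

    chrom_names = genome.names
    chrom_lens = np.array([genome.length(c) for c in chrom_names], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    placed: list[tuple[str, int, int]] = []
    for length in lengths:
        ok = False
        for _ in range(1000):
            ci = int(rng.choice(len(chrom_names), p=chrom_p))
            chrom = chrom_names[ci]
            limit = genome.length(chrom) - int(length)
            if limit <= 0:
                continue
            start = int(rng.integers(limit))
            end = start + int(length)
            if any(s < end and start < e for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((start, end))
            placed.append((chrom, start, end))
            ok = True
            break
        if not ok:
            raise SizingError(
                f"could not place a gene of {length} bp after 1000 tries; "
                "genome too small or too crowded"
            )

    genes = [
        GeneRecord(
            gene_id=f"g{i:05d}",
            isoform_id=f"g{i:05d}.t1",
            chrom=chrom,
            start=start,
            end=end,
            protein_length=(end - start) // 3,
            era=labels[i],
        )
        for i, (chrom, start, end) in enumerate(placed)
    ]

    sequence: dict[str, str] | None = None
    mask_records: list[tuple[str, int, int]] = []
    if with_sequence:
        sequence = {}
        for chrom in chrom_names:
            L = genome.length(chrom)
            arr = _BASES[rng.integers(0, 4, L)]
            gene_iv = sorted(occupied[chrom])
            # soft-mask random intergenic patches (repeat-like sequence)
            target = int(spec.mask_fraction * L)
            masked = 0
            guard = 0
            while masked < target and guard < 10_000:
                guard += 1
                patch_len = int(rng.integers(200, 2000))
                start = int(rng.integers(max(L - patch_len, 1)))
                end = start + patch_len
                if any(s < end and start < e for s, e in gene_iv):
                    continue
                arr[start:end] |= 0x20  # lowercase
                mask_records.append((chrom, start, end))
                masked += patch_len
            sequence[chrom] = arr.tobytes().decode("ascii")
    mask = merge_intervals(
        IntervalSet.from_records(mask_records, genome, name="softmask")
    )
    return SyntheticGenome(genome=genome, genes=genes, sequence=sequence, mask=mask)


def gen_feature_track(
    genes: Sequence[GeneRecord],
    genome: GenomeModel,
    enrichment: dict[str, float],
    seed: int,
    window: int = 1000,
    base_coverage: float = 0.25,
    name: str = "track",
) -> IntervalSet:
    """Feature track with tunable per-era enrichment.

    The genome is tiled into candidate windows of ``window`` bp. A window
    overlapping a gene of era e is kept with probability derived from
    multiplying the base odds by ``enrichment[e]`` (the largest multiplier
    wins where genes of several eras overlap one window); background
    windows are kept at ``base_coverage``. Kept windows are merged. With
    all multipliers equal to 1 the track is independent of every era.
    """
    for era, m in enrichment.items():
        if m <= 0:
            raise ConfigError(f"enrichment[{era!r}] must be > 0, got {m}")
    rng = np.random.default_rng(seed)
    base_odds = base_coverage / (1.0 - base_coverage)
    records: list[tuple[str, int, int]] = []
    for chrom in genome.names:
        L = genome.length(chrom)
        n_win = (L + window - 1) // window
        mult = np.ones(n_win, dtype=float)
        for g in genes:
            if g.chrom != chrom:
                continue
            m = enrichment.get(g.era, 1.0)
            lo = g.start // window
            hi = (g.end - 1) // window + 1
            mult[lo:hi] = np.maximum(mult[lo:hi], m) if m >= 1 else np.where(
                mult[lo:hi] == 1.0, m, mult[lo:hi]
            )
        odds = base_odds * mult
        p = odds / (1.0 + odds)
        keep = rng.random(n_win) < p
        for wi in np.flatnonzero(keep):
            start = int(wi) * window
            records.append((chrom, start, min(start + window, L)))
    track = IntervalSet.from_records(records, genome, name=name)
    return merge_intervals(track, name=name)


def toy_taxonomy() -> Taxonomy:
    """A 31-phylostratum lineage with one species per stratum.

    Anchor species follow the usual representatives (E. coli for the
    cellular-organisms stratum, sponge for metazoans, lancelet for
    chordates, platypus for mammals, lemur for primates); the remaining
    strata get placeholder species names. Homo sapiens is the query
    species at PS 31.
    """
    anchors = {
        1: "Escherichia coli",
        4: "Amphimedon queenslandica",
        8: "Branchiostoma floridae",
        14: "Danio rerio",
        18: "Ornithorhynchus anatinus",
        23: "Lemur catta",
        31: "Homo sapiens",
    }
    species_to_ps = {
        anchors.get(ps, f"species_ps{ps:02d}"): ps
        for ps in range(1, N_PHYLOSTRATA + 1)
    }
    return Taxonomy(species_to_ps=species_to_ps, query_species="Homo sapiens")


def species_for_phylostratum(taxonomy: Taxonomy) -> dict[int, str]:
    """First species listed for each phylostratum."""
    out: dict[int, str] = {}
    for sp, ps in taxonomy.species_to_ps.items():
        out.setdefault(ps, sp)
    return out


def gen_hit_table(
    genes: Sequence[GeneRecord],
    taxonomy: Taxonomy,
    seed: int,
    evalue_cutoff: float = 1e-3,
    decoy_rate: float = 0.5,
    n_closer_hits: int = 2,
) -> pd.DataFrame:
    """Homology hit table consistent with each gene's planted era.

    For every gene the most distant sub-cutoff hit falls at a phylostratum
    drawn uniformly within the planted era's range, accompanied by closer
    sub-cutoff hits. With probability ``decoy_rate`` a decoy hit in a more
    distant stratum is added with an e-value at or above the cutoff; a
    correct assignment must ignore it. Genes whose drawn stratum is the
    query stratum get only a self-species hit.
    """
    by_ps = species_for_phylostratum(taxonomy)
    missing = [ps for ps in range(1, N_PHYLOSTRATA + 1) if ps not in by_ps]
    if missing:
        raise ConfigError(f"taxonomy lacks species for phylostrata {missing}")
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, str, float]] = []

    def sub_cutoff_evalue() -> float:
        return 10.0 ** -rng.uniform(4.0, 50.0)

    for g in genes:
        if g.era not in ERA_PS_RANGE:
            raise ConfigError(f"gene {g.gene_id} has unknown planted era {g.era!r}")
        lo, hi = ERA_PS_RANGE[g.era]
        anchor_ps = int(rng.integers(lo, hi + 1))
        if anchor_ps < N_PHYLOSTRATA:
            rows.append(
                (g.gene_id, g.isoform_id, by_ps[anchor_ps], sub_cutoff_evalue())
            )
            closer = rng.integers(anchor_ps + 1, N_PHYLOSTRATA + 1, n_closer_hits)
            for ps in closer:
                rows.append(
                    (g.gene_id, g.isoform_id, by_ps[int(ps)], sub_cutoff_evalue())
                )
        else:
            rows.append(
                (g.gene_id, g.isoform_id, taxonomy.query_species, sub_cutoff_evalue())
            )
        if anchor_ps > 1 and rng.random() < decoy_rate:
            decoy_ps = int(rng.integers(1, anchor_ps))
            decoy_evalue = float(10.0 ** rng.uniform(np.log10(evalue_cutoff), 1.0))
            rows.append((g.gene_id, g.isoform_id, by_ps[decoy_ps], decoy_evalue))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def gen_expression(genes: Sequence[GeneRecord], spec: SyntheticSpec) -> ExpressionMatrix:
    """Negative-binomial count matrix with planted per-era means.

    Counts for gene g in sample s are NB with mean
    mu_era(g) * gene_effect(g) * depth(s) and dispersion ``spec.dispersion``
    (var = mu + dispersion * mu^2). Gene effects and sample depths are
    lognormal. The tissue->category map of the spec is attached.
    """
    rng = np.random.default_rng(spec.seed + 1)  # independent of gen_genome draws
    tissues = sorted({t for ts in spec.categories.values() for t in ts})
    samples = [f"{t}_{i}" for t in tissues for i in range(spec.samples_per_tissue)]
    sample_to_tissue = {f"{t}_{i}": t for t in tissues
                        for i in range(spec.samples_per_tissue)}
    if not genes:
        counts = pd.DataFrame(
            np.empty((0, len(samples))), index=pd.Index([], name="gene_id"),
            columns=samples,
        )
        return ExpressionMatrix(counts, sample_to_tissue,
                                {k: list(v) for k, v in spec.categories.items()})
    for g in genes:
        if g.era not in spec.expression_means:
            raise ConfigError(f"no expression mean configured for era {g.era!r}")
    mu_era = np.array([spec.expression_means[g.era] for g in genes])
    gene_effect = np.exp(rng.normal(0.0, spec.gene_effect_sigma, len(genes)))
    depth = np.exp(rng.normal(0.0, spec.depth_sigma, len(samples)))
    mu = np.outer(mu_era * gene_effect, depth)
    r = 1.0 / spec.dispersion  # NB number of failures; p = r / (r + mu)
    counts = rng.negative_binomial(r, r / (r + mu))
    frame = pd.DataFrame(
        counts.astype(float),
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
        columns=samples,
    )
    return ExpressionMatrix(frame, sample_to_tissue,
                            {k: list(v) for k, v in spec.categories.items()})


# ---------------------------------------------------------------------------
# Controlled sequence for ORF-scanner validation


def build_orf_construct(n_codons: int) -> str:
    """ATG + (n_codons - 1) CTT codons + TAA.

    The CTT interior contains no ATG or stop codon in any frame on either
    strand, so a construct of n_codons >= threshold yields exactly one ORF
    and a shorter one yields none.
    """
    if n_codons < 1:
        raise ConfigError("construct needs at least the start codon")
    return "ATG" + "CTT" * (n_codons - 1) + "TAA"


def gen_orf_test_sequence(
    n_orfs: int = 50,
    n_decoys: int = 50,
    orf_codons: int = 40,
    decoy_codons: int = 39,
    chrom_length: int = 1_000_000,
    chrom: str = "chrT",
    seed: int = 0,
) -> tuple[GenomeModel, dict[str, str], list[tuple[int, int, str]]]:
    """A soft-masked chromosome with known embedded ORFs and decoys.

    The background is lowercase (repeat-like) random sequence, invisible
    to the intergenic scanner; each construct is an uppercase island, half
    of them embedded in reverse complement (minus strand). Returns the
    genome, sequence and the expected (start, end, strand) spans of the
    compliant ORFs only.
    """
    rng = np.random.default_rng(seed)
    seq = bytearray((_BASES[rng.integers(0, 4, chrom_length)] | 0x20).tobytes())
    constructs = [(build_orf_construct(orf_codons), True) for _ in range(n_orfs)]
    constructs += [(build_orf_construct(decoy_codons), False) for _ in range(n_decoys)]
    order = rng.permutation(len(constructs))
    expected: list[tuple[int, int, str]] = []
    cursor = 0
    gap_budget = chrom_length - sum(len(c) for c, _ in constructs)
    min_gap = 10
    n_slots = len(constructs) + 1
    if gap_budget < min_gap * n_slots:
        raise SizingError("chromosome too short for the requested constructs")
    for k, idx in enumerate(order):
        construct, compliant = constructs[idx]
        remaining = len(order) - k
        max_gap = gap_budget - min_gap * remaining
        gap = int(rng.integers(min_gap, max(max_gap // remaining, min_gap + 1)))
        gap_budget -= gap
        cursor += gap
        minus = bool(rng.random() < 0.5)
        piece = reverse_complement(construct) if minus else construct
        seq[cursor:cursor + len(piece)] = piece.encode("ascii")
        if compliant:
            expected.append((cursor, cursor + len(piece), "-" if minus else "+"))
        cursor += len(piece)
    genome = GenomeModel({chrom: chrom_length})
    expected.sort()
    return genome, {chrom: seq.decode("ascii")}, expected
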