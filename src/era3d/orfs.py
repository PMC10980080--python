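"""Intergenic control sequences: Igen ORFs and length-matched Non-ORFs.

Igen ORFs are potential protein-coding sequences in the non-genic,
non-repetitive part of a genome: a methionine (ATG) codon followed by at
least 40 non-stop codons (the Met counted among them) and a stop codon
(TAA/TAG/TGA), giving a minimum span of 41 codons = 123 bp. They carry no
expression evidence and serve as the coding-capacity control for
protein-coding genes. Igen Non-ORFs are intergenic windows matched exactly
to the ORF length distribution that do not begin with ATG and are free to
contain stop codons.

Repeat-like sequence is encoded as lowercase (soft-masking); ORFs and
Non-ORFs must lie wholly in uppercase sequence, outside any excluded
intervals (genes, previously picked controls), and contain no N.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError, ParseError, SizingError
from .genome import GenomeModel
from .intervals import IntervalSet, merge_intervals

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGTNacgtn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IgenOrf:
    """A maximal intergenic ORF: ATG ... first in-frame stop."""

    chrom: str
    start: int  # genomic, 0-based half-open, strand-independent span
    end: int
    strand: str  # '+' or '-'
    codon_count: int  # non-stop codons including the initial Met

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_bed_fields(self) -> tuple:
        return (self.chrom, self.start, self.end,
                f"orf_{self.chrom}_{self.start}", self.codon_count, self.strand)


@dataclass(frozen=True)
class IgenNonOrf:
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _check_alphabet(seq: str, chrom: str) -> None:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ParseError(
            f"chromosome {chrom!r}: non-DNA characters {sorted(bad)[:5]}"
        )


def _eligible_mask(seq: str, exclusions: np.ndarray | None) -> np.ndarray:
    """Positions usable for controls: uppercase ACGT outside exclusions."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    upper = (arr >= ord("A")) & (arr <= ord("Z"))
    not_n = arr != ord("N")
    mask = upper & not_n
    if exclusions is not None:
        for start, end in exclusions:
            mask[start:end] = False
    return mask


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def _scan_plus_strand(seq: str, min_codons: int) -> list[tuple[int, int, int]]:
    """Maximal ORFs on the given (already oriented) sequence.

    Returns (start, end, codon_count) in local coordinates, end past the
    stop codon. For each frame, extend from the first ATG to the first
    in-frame stop; ATGs nested inside an open ORF are not reported
    separately, preventing double counting of the same region.
    """
    found: list[tuple[int, int, int]] = []
    n = len(seq)
    for frame in range(3):
        orf_start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos:pos + 3]
            if codon in STOP_CODONS:
                if orf_start is not None:
                    codons = (pos - orf_start) // 3
                    if codons >= min_codons:
                        found.append((orf_start, pos + 3, codons))
                    orf_start = None
            elif codon == START_CODON and orf_start is None:
                orf_start = pos
        # an open ORF at segment end lacks a stop codon: not reported
    return found


def find_intergenic_orfs(
    sequence: Mapping[str, str],
    genome: GenomeModel,
    exclusions: IntervalSet | None = None,
    min_codons: int = 40,
) -> list[IgenOrf]:
    """Six-frame scan for maximal ORFs in eligible intergenic sequence.

    Scans both strands and all three frames of every maximal run of
    uppercase, non-N sequence outside ``exclusions``. An ORF must start
    with ATG, end at its first in-frame stop, and contain at least
    ``min_codons`` non-stop codons (Met included in the count).
    """
    excl = merge_intervals(exclusions) if exclusions is not None else None
    out: list[IgenOrf] = []
    for chrom in genome.names:
        seq = sequence.get(chrom)
        if seq is None:
            continue
        if len(seq) != genome.length(chrom):
            raise InputError(
                f"sequence length {len(seq)} != genome length "
                f"{genome.length(chrom)} for {chrom!r}"
            )
        _check_alphabet(seq, chrom)
        excl_arr = excl.data.get(chrom) if excl is not None else None
        mask = _eligible_mask(seq, excl_arr)
        for run_start, run_end in _runs(mask):
            segment = seq[run_start:run_end]
            for s, e, codons in _scan_plus_strand(segment, min_codons):
                out.append(IgenOrf(chrom, run_start + s, run_start + e, "+", codons))
            rc = reverse_complement(segment)
            seg_len = run_end - run_start
            for s, e, codons in _scan_plus_strand(rc, min_codons):
                out.append(
                    IgenOrf(chrom, run_start + seg_len - e,
                            run_start + seg_len - s, "-", codons)
                )
    out.sort(key=lambda o: (o.chrom, o.start, o.end, o.strand))
    return out


def sample_non_orfs(
    sequence: Mapping[str, str],
    genome: GenomeModel,
    lengths: Sequence[int],
    exclusions: IntervalSet | None = None,
    seed: int = 0,
    max_tries_per_length: int = 10_000,
) -> list[IgenNonOrf]:
    """Sample intergenic windows matching a requested length multiset.

    Each requested length yields exactly one window, rejection-sampled
    until it lies wholly in eligible sequence, does not overlap exclusions
    or previously placed windows, and does not begin with ATG on the plus
    strand. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    excl = merge_intervals(exclusions) if exclusions is not None else None
    # eligible runs are kept up to date: placing a window splits its run,
    # so overlap with previous picks is impossible by construction
    runs: list[tuple[str, int, int]] = []
    for chrom in genome.names:
        seq = sequence.get(chrom)
        if seq is None:
            continue
        _check_alphabet(seq, chrom)
        excl_arr = excl.data.get(chrom) if excl is not None else None
        runs.extend((chrom, rs, re) for rs, re in _runs(_eligible_mask(seq, excl_arr)))

    out: list[IgenNonOrf] = []
    for length in lengths:
        if length <= 0:
            raise InputError(f"non-ORF length must be positive, got {length}")
        ok = False
        for _ in range(max_tries_per_length):
            counts = np.array([re - rs - length + 1 for _, rs, re in runs])
            counts = np.maximum(counts, 0)
            total = int(counts.sum())
            if total == 0:
                raise SizingError(f"no eligible window of length {length}")
            cum = np.cumsum(counts)
            pick = int(rng.integers(total))
            slot = int(np.searchsorted(cum, pick, side="right"))
            chrom, rs, re = runs[slot]
            start = rs + pick - (int(cum[slot - 1]) if slot else 0)
            end = start + length
            if sequence[chrom][start:start + 3].upper() == START_CODON:
                continue
            runs[slot:slot + 1] = [r for r in
                                   [(chrom, rs, start), (chrom, end, re)]
                                   if r[2] > r[1]]
            out.append(IgenNonOrf(chrom, start, end))
            ok = True
            break
        if not ok:
            raise SizingError(
                f"could not place non-ORF of length {length} after "
                f"{max_tries_per_length} tries"
            )
    return out


def orfs_to_intervals(orfs: Sequence[IgenOrf], genome: GenomeModel,
                      name: str = "igen_orfs") -> IntervalSet:
    return IntervalSet.from_records(
        [(o.chrom, o.start, o.end) for o in orfs], genome, name=name
    )


def non_orfs_to_intervals(non_orfs: Sequence[IgenNonOrf], genome: GenomeModel,
                          name: str = "igen_non_orfs") -> IntervalSet:
    return IntervalSet.from_records(
        [(o.chrom, o.start, o.end) for o in non_orfs], genome, name=name
    )


def write_orfs_bed(orfs: Sequence[IgenOrf], path: str | Path) -> None:
    """6-column BED with the codon count in the score column."""
    with open(path, "w") as fh:
        for o in orfs:
            fh.write("\t".join(str(f) for f in o.to_bed_fields()) + "\n")


def write_non_orfs_bed(non_orfs: Sequence[IgenNonOrf], path: str | Path) -> None:
    with open(path, "w") as fh:
        for o in non_orfs:
            fh.write(f"{o.chrom}\t{o.start}\t{o.end}\n")
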