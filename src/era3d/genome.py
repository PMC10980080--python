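"""Genome model: named chromosomes with lengths.

A :class:`GenomeModel` is the coordinate system every interval set, bin grid
and sequence in era3d is validated against. Chromosome-size tables use the
two-column ``name<TAB>length`` convention of ``samtools faidx`` / UCSC
``chrom.sizes`` files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError, ParseError


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosome names and lengths (bp).

    Parameters
    ----------
    chromosomes
        Mapping of chromosome name to length in base pairs. Insertion order
        is preserved and used for all per-chromosome iteration.
    """

    chromosomes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.chromosomes.items():
            if not isinstance(length, int) or length <= 0:
                raise ConfigError(
                    f"chromosome {name!r} has non-positive length {length}"
                )

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(self.chromosomes.values())

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def length(self, name: str) -> int:
        try:
            return self.chromosomes[name]
        except KeyError:
            raise ConfigError(f"unknown chromosome {name!r}") from None

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeModel":
        """Read a ``name<TAB>length`` chromosome-sizes table."""
        chroms: dict[str, int] = {}
        with open(path) as fh:
            for i, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ParseError("expected 'name<TAB>length'", line=i)
                name = parts[0]
                try:
                    length = int(parts[1])
                except ValueError:
                    raise ParseError(
                        f"non-integer length {parts[1]!r}", line=i
                    ) from None
                if name in chroms:
                    raise ParseError(f"duplicate chromosome {name!r}", line=i)
                chroms[name] = length
        return cls(chroms)

    def to_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chromosomes.items():
                fh.write(f"{name}\t{length}\n")
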