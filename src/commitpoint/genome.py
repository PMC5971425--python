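"""Genome assembly model: chromosome names and lengths.

The assembly is the universe for coordinate validation and for region
randomization. It is read from a UCSC-style two-column ``chrom.sizes``
file (name, length).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator


@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered set of chromosomes with lengths in bp.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length)`` pairs. Names must be unique and
        lengths positive.
    """

    chromosomes: tuple[tuple[str, int], ...]
    _lengths: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in assembly")
        for name, length in self.chromosomes:
            if length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "_lengths", dict(self.chromosomes))

    @classmethod
    def from_items(cls, items: Iterable[tuple[str, int]]) -> "GenomeAssembly":
        return cls(tuple((str(n), int(l)) for n, l in items))

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeAssembly":
        """Read a two-column (name, length) chrom.sizes file."""
        items: list[tuple[str, int]] = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
                try:
                    length = int(fields[1])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from exc
                items.append((fields[0], length))
        return cls.from_items(items)

    def to_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chromosomes:
                fh.write(f"{name}\t{length}\n")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in assembly") from None

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)
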