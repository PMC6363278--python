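"""Toy genome description used throughout the package.

Coordinates are 0-based, half-open (BED convention) everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Genome:
    """An ordered set of chromosomes with a native bin size.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length_bp)`` pairs. Lengths must be positive
        and divisible by ``bin_size``; names must be unique.
    bin_size
        Native bin size in bp for binned tracks built on this genome.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int = 10_000

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes))
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            if length % self.bin_size != 0:
                raise ValueError(
                    f"chromosome {name} length {length} not divisible by bin_size {self.bin_size}"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str) -> int:
        return self.length(chrom) // self.bin_size


def default_genome() -> Genome:
    """4 chromosomes x 30 Mb at 10-kb bins: large enough for Mb-scale domains."""
    return Genome(tuple((f"chr{i}", 30_000_000) for i in range(1, 5)), bin_size=10_000)
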