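"""Physical/genetic genome models used by the forward-genetics simulator.

A :class:`GenomeModel` carries, per chromosome, a physical length in bp and a
genetic length in Morgans.  The genetic length drives the Poisson crossover
count in meiosis (Haldane model, no interference); the physical length is the
coordinate system for variants, windows and candidate regions.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Chromosome:
    """One chromosome: name, physical size (bp) and genetic size (Morgans)."""

    name: str
    length_bp: int
    length_morgans: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"chromosome {self.name!r}: length_bp must be > 0")
        if self.length_morgans < 0:
            raise ValueError(f"chromosome {self.name!r}: length_morgans must be >= 0")


@dataclass(frozen=True)
class GenomeModel:
    """An ordered collection of chromosomes with unique names."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes)

    def __contains__(self, name: object) -> bool:
        return name in self.names

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}")

    @property
    def total_bp(self) -> int:
        return sum(c.length_bp for c in self.chromosomes)


# Approximate SL3.0-scale chromosome sizes (bp) for the 12 tomato chromosomes.
_TOMATO_CHROM_BP = {
    "ch01": 98_543_444,
    "ch02": 55_340_444,
    "ch03": 70_787_664,
    "ch04": 66_470_942,
    "ch05": 65_875_088,
    "ch06": 49_751_636,
    "ch07": 68_045_021,
    "ch08": 65_866_657,
    "ch09": 72_482_091,
    "ch10": 65_527_505,
    "ch11": 56_302_525,
    "ch12": 67_145_203,
}


def tomato_genome(cm_per_mb: float = 1.5) -> GenomeModel:
    """Twelve-chromosome tomato-like genome preset.

    Genetic lengths assume a uniform ``cm_per_mb`` recombination rate
    (default 1.5 cM/Mb, ~1210 cM genome-wide, in the range of published
    tomato linkage maps).  The linear cM<->bp assumption is deliberate:
    crossover positions are drawn uniformly on the physical map.
    """
    chroms = tuple(
        Chromosome(name, bp, round(bp * cm_per_mb * 1e-8, 4))
        for name, bp in _TOMATO_CHROM_BP.items()
    )
    return GenomeModel(chroms)
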