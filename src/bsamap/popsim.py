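"""Forward-genetics simulator for bulked-segregant mapping-by-sequencing.

Simulates the study design end to end: an EMS-mutagenized line carrying one
causal recessive variant plus a genome-wide background of induced SNPs is
backcrossed to the non-mutagenized parent; the BC1F1 (heterozygous at every
EMS variant) is selfed to give a BC1F2 population; plants are phenotyped,
bulked by phenotype, and each bulk is pool-sequenced to per-site allele
depths.

Meiosis uses the Haldane model: the crossover count per chromosome is Poisson
with mean equal to the chromosome's genetic length in Morgans, and crossover
positions are uniform on the physical map.  Pooled sequencing draws each read
from a uniformly chosen chromosome copy in the bulk and flips the reported
allele with the per-read error probability.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeModel

MUTANT = "mutant"
WILDTYPE = "wildtype"
MUTANT_PHENOTYPE = "mutant_phenotype"
WT_LIKE = "wt_like"
MUTANT_BULK = "mutant_bulk"
WT_LIKE_BULK = "wt_like_bulk"

_TRANSITION_ALT = {"G": "A", "C": "T", "A": "G", "T": "C"}
_TRANSVERSION_ALTS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide variant with an optional causal flag."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    is_causal: bool = False


class EmsVariantSet:
    """A sorted, position-unique set of EMS-induced SNVs with exactly one causal.

    Variants are stored sorted by (chrom, pos); positions are unique per
    chromosome and ref != alt for every record.
    """

    def __init__(self, variants: Iterable[Variant]):
        vs = sorted(variants, key=lambda v: (v.chrom, v.pos))
        seen: set[tuple[str, int]] = set()
        n_causal = 0
        for v in vs:
            if v.ref == v.alt:
                raise ValueError(f"variant {v.chrom}:{v.pos} has ref == alt")
            key = (v.chrom, v.pos)
            if key in seen:
                raise ValueError(f"duplicate variant position {v.chrom}:{v.pos}")
            seen.add(key)
            n_causal += v.is_causal
        if n_causal != 1:
            raise ValueError(f"expected exactly one causal variant, got {n_causal}")
        self.variants: tuple[Variant, ...] = tuple(vs)
        by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for i, v in enumerate(self.variants):
            idx, pos = by_chrom.setdefault(v.chrom, ([], []))
            idx.append(i)
            pos.append(v.pos)
        self._index_by_chrom = {
            c: (np.asarray(idx, dtype=np.int64), np.asarray(pos, dtype=np.int64))
            for c, (idx, pos) in by_chrom.items()
        }

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[Variant]:
        return iter(self.variants)

    def __getitem__(self, i: int) -> Variant:
        return self.variants[i]

    @property
    def causal(self) -> Variant:
        return next(v for v in self.variants if v.is_causal)

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._index_by_chrom)

    def chrom_index(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(row indices, positions) of this chromosome's variants."""
        return self._index_by_chrom[chrom]


def simulate_ems_variants(
    genome: GenomeModel,
    n_background: int,
    causal: tuple[str, int, str, str],
    seed: int | None = None,
    transition_fraction: float = 0.98,
) -> EmsVariantSet:
    """Draw ``n_background`` EMS SNVs plus the given causal variant.

    Background positions are uniform on the physical genome (chromosomes
    weighted by bp length); position collisions are resolved by resampling.
    The substitution spectrum defaults to 98% G/C->A/T transitions, the
    canonical EMS signature; the causal variant is taken verbatim.
    """
    if n_background < 0:
        raise ValueError("n_background must be >= 0")
    c_chrom, c_pos, c_ref, c_alt = causal
    chrom = genome.chromosome(c_chrom)  # raises KeyError if unknown
    if not 1 <= c_pos <= chrom.length_bp:
        raise ValueError(
            f"causal position {c_pos} outside chromosome {c_chrom} "
            f"(length {chrom.length_bp})"
        )
    rng = np.random.default_rng(seed)
    lengths = np.array([c.length_bp for c in genome.chromosomes], dtype=float)
    weights = lengths / lengths.sum()
    occupied = {(c_chrom, c_pos)}
    variants = [Variant(c_chrom, c_pos, c_ref, c_alt, is_causal=True)]
    for _ in range(n_background):
        while True:
            ci = int(rng.choice(len(genome.chromosomes), p=weights))
            ch = genome.chromosomes[ci]
            pos = int(rng.integers(1, ch.length_bp + 1))
            if (ch.name, pos) not in occupied:
                break
        occupied.add((ch.name, pos))
        if rng.random() < transition_fraction:
            ref = "G" if rng.random() < 0.5 else "C"
            alt = _TRANSITION_ALT[ref]
        else:
            ref = "ACGT"[int(rng.integers(4))]
            alt = _TRANSVERSION_ALTS[ref][int(rng.integers(2))]
        variants.append(Variant(ch.name, pos, ref, alt))
    return EmsVariantSet(variants)


class Haplotype:
    """One chromosome copy as parental-origin segments tiling [1, length].

    ``ends[i]`` is the (1-based, inclusive) last position of segment ``i``;
    ``origins[i]`` is ``"mutant"`` or ``"wildtype"``.
    """

    __slots__ = ("ends", "origins", "_ends_arr", "_mut_arr")

    def __init__(self, ends: Sequence[int], origins: Sequence[str]):
        if len(ends) != len(origins) or not ends:
            raise ValueError("ends and origins must be equal-length, non-empty")
        if any(b >= a for a, b in zip(ends[1:], ends[:-1])):
            raise ValueError("segment ends must be strictly increasing")
        self.ends = tuple(int(e) for e in ends)
        self.origins = tuple(origins)
        self._ends_arr = np.asarray(self.ends, dtype=np.int64)
        self._mut_arr = np.asarray([o == MUTANT for o in self.origins], dtype=bool)

    def origin_at(self, pos: int) -> str:
        return self.origins[bisect.bisect_left(self.ends, pos)]

    def mutant_mask(self, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: does this copy carry the mutant haplotype at each pos."""
        idx = np.searchsorted(self._ends_arr, positions, side="left")
        return self._mut_arr[idx]


@dataclass
class Individual:
    """A BC1F2 plant: two haplotypes per chromosome plus a phenotype."""

    haplotypes: dict[str, tuple[Haplotype, Haplotype]]
    phenotype: str

    def genotype_at(self, chrom: str, pos: int) -> int:
        """Mutant-allele dosage (0, 1 or 2) at a position."""
        pair = self.haplotypes[chrom]
        return sum(h.origin_at(pos) == MUTANT for h in pair)


def _gamete(rng: np.random.Generator, length_bp: int, length_morgans: float) -> Haplotype:
    """One meiotic product of the BC1F1 heterozygote for one chromosome."""
    k = int(rng.poisson(length_morgans)) if length_morgans > 0 else 0
    start = MUTANT if rng.random() < 0.5 else WILDTYPE
    other = WILDTYPE if start == MUTANT else MUTANT
    if k == 0:
        return Haplotype((length_bp,), (start,))
    breaks = rng.integers(1, length_bp, size=k)
    vals, counts = np.unique(breaks, return_counts=True)
    vals = vals[counts % 2 == 1]  # coincident crossovers cancel
    if vals.size == 0:
        return Haplotype((length_bp,), (start,))
    ends = np.append(vals, length_bp)
    origins = tuple(start if i % 2 == 0 else other for i in range(ends.size))
    return Haplotype(ends.tolist(), origins)


def make_bc1f2(
    variants: EmsVariantSet,
    n: int,
    genome: GenomeModel,
    seed: int | None = None,
    penetrance: float = 1.0,
) -> list[Individual]:
    """Self the BC1F1 heterozygote to produce ``n`` BC1F2 individuals.

    The BC1F1 is heterozygous at every EMS variant, so each BC1F2 haplotype
    is a mosaic of whole-chromosome "mutant" and "wildtype" parental
    segments produced by simulated meiosis.  Phenotype is recessive: only
    plants homozygous for the causal variant express the mutant phenotype
    (subject to ``penetrance``, default fully penetrant).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= penetrance <= 1.0:
        raise ValueError("penetrance must be in [0, 1]")
    rng = np.random.default_rng(seed)
    causal = variants.causal
    pop: list[Individual] = []
    for _ in range(n):
        haps = {
            c.name: (
                _gamete(rng, c.length_bp, c.length_morgans),
                _gamete(rng, c.length_bp, c.length_morgans),
            )
            for c in genome.chromosomes
        }
        ind = Individual(haplotypes=haps, phenotype=WT_LIKE)
        if ind.genotype_at(causal.chrom, causal.pos) == 2:
            if penetrance >= 1.0 or rng.random() < penetrance:
                ind.phenotype = MUTANT_PHENOTYPE
        pop.append(ind)
    return pop


def select_bulks(
    pop: Sequence[Individual], n_per_bulk: int, seed: int | None = None
) -> tuple[list[Individual], list[Individual]]:
    """Sample phenotype-selected bulks without replacement.

    Returns ``(mutant_bulk, wt_like_bulk)``.  Raises if either phenotype
    class has fewer than ``n_per_bulk`` members, naming the failing class.
    """
    if n_per_bulk < 0:
        raise ValueError("n_per_bulk must be >= 0")
    rng = np.random.default_rng(seed)
    mut = [i for i in pop if i.phenotype == MUTANT_PHENOTYPE]
    wt = [i for i in pop if i.phenotype == WT_LIKE]
    if len(mut) < n_per_bulk:
        raise ValueError(
            f"{MUTANT_BULK}: only {len(mut)} {MUTANT_PHENOTYPE} individuals "
            f"available, need {n_per_bulk}"
        )
    if len(wt) < n_per_bulk:
        raise ValueError(
            f"{WT_LIKE_BULK}: only {len(wt)} {WT_LIKE} individuals "
            f"available, need {n_per_bulk}"
        )
    mut_idx = rng.choice(len(mut), size=n_per_bulk, replace=False)
    wt_idx = rng.choice(len(wt), size=n_per_bulk, replace=False)
    return [mut[i] for i in mut_idx], [wt[i] for i in wt_idx]


@dataclass
class BulkCounts:
    """Per-variant pooled sequencing counts for one bulk.

    Arrays are aligned with the order of the :class:`EmsVariantSet` the
    counts were simulated from.
    """

    label: str
    depth: np.ndarray
    alt_count: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.alt_count = np.asarray(self.alt_count, dtype=np.int64)
        if self.depth.shape != self.alt_count.shape:
            raise ValueError("depth and alt_count must have the same shape")
        if (self.alt_count < 0).any() or (self.alt_count > self.depth).any():
            raise ValueError("require 0 <= alt_count <= depth")


def carrier_matrix(bulk: Sequence[Individual], variants: EmsVariantSet) -> np.ndarray:
    """Boolean (n_variants, 2*n_individuals) matrix: copy carries the alt allele.

    Every EMS variant rides the mutant parental haplotype (the BC1F1 is
    heterozygous at all of them), so a chromosome copy carries the alt allele
    at a site exactly when its parental origin there is "mutant".
    """
    out = np.zeros((len(variants), 2 * len(bulk)), dtype=bool)
    for chrom in variants.chroms:
        idx, pos = variants.chrom_index(chrom)
        for j, ind in enumerate(bulk):
            pair = ind.haplotypes[chrom]
            for h, hap in enumerate(pair):
                out[idx, 2 * j + h] = hap.mutant_mask(pos)
    return out


def simulate_pooled_reads(
    bulk: Sequence[Individual],
    variants: EmsVariantSet,
    mean_depth: float = 32.0,
    error_rate: float = 0.002,
    seed: int | None = None,
    label: str = "bulk",
) -> BulkCounts:
    """Pool-sequence a bulk: per-site Poisson depth, reads from random copies.

    Per variant, depth ~ Poisson(mean_depth); each read is drawn from a
    uniformly chosen chromosome copy in the bulk, reports the alt allele if
    that copy carries it, and is flipped with probability ``error_rate``.
    """
    if not bulk:
        raise ValueError("bulk is empty")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    carriers = carrier_matrix(bulk, variants)
    n_copies = carriers.shape[1]
    depths = rng.poisson(mean_depth, size=len(variants))
    alts = np.zeros(len(variants), dtype=np.int64)
    for i, d in enumerate(depths):
        if d == 0:
            continue
        copy_idx = rng.integers(0, n_copies, size=d)
        alt_reads = carriers[i, copy_idx]
        if error_rate > 0:
            alt_reads = alt_reads ^ (rng.random(d) < error_rate)
        alts[i] = int(alt_reads.sum())
    return BulkCounts(label=label, depth=depths, alt_count=alts)


def inject_introgression_block(
    variants: EmsVariantSet,
    counts: Sequence[BulkCounts],
    interval: tuple[str, int, int],
    af_both_bulks: float,
    seed: int | None = None,
    genome: GenomeModel | None = None,
) -> tuple[BulkCounts, ...]:
    """Overwrite alt fractions inside an interval in every bulk.

    Models a fixed divergent block (e.g. a wild-relative introgression) that
    shows the same high alt fraction in both bulks regardless of phenotype:
    each affected site's alt count is redrawn as Binomial(depth,
    ``af_both_bulks``).  An empty interval (start > end) is a no-op.
    """
    chrom, start, end = interval
    known = set(variants.chroms) | (set(genome.names) if genome is not None else set())
    if chrom not in known:
        raise ValueError(f"interval chromosome {chrom!r} not in the simulated genome")
    if genome is not None:
        length = genome.chromosome(chrom).length_bp
        if start > length or end < 1:
            raise ValueError(f"interval {start}-{end} outside chromosome {chrom}")
    if not 0.0 <= af_both_bulks <= 1.0:
        raise ValueError("af_both_bulks must be in [0, 1]")
    if start > end:
        return tuple(counts)
    rng = np.random.default_rng(seed)
    idx, pos = variants.chrom_index(chrom) if chrom in variants.chroms else (
        np.empty(0, dtype=np.int64),
        np.empty(0, dtype=np.int64),
    )
    hit = idx[(pos >= start) & (pos <= end)]
    out = []
    for bc in counts:
        alt = bc.alt_count.copy()
        alt[hit] = rng.binomial(bc.depth[hit], af_both_bulks)
        out.append(BulkCounts(label=bc.label, depth=bc.depth.copy(), alt_count=alt))
    return tuple(out)


_GENOTYPE_CODE = {2: "hom_mut", 1: "het", 0: "hom_wt"}


def marker_genotype_table(
    pop: Sequence[Individual],
    chrom: str,
    positions: Sequence[int],
    missing_rate: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Genotype a population at marker positions, KASP-style.

    Returns a DataFrame with one row per individual: a ``phenotype`` column
    plus one column per marker position (sorted), coded hom_mut/het/hom_wt,
    with optional uniform missingness.
    """
    rng = np.random.default_rng(seed)
    positions = sorted(int(p) for p in positions)
    rows = []
    for ind in pop:
        row: dict[str, object] = {"phenotype": ind.phenotype}
        for p in positions:
            if missing_rate > 0 and rng.random() < missing_rate:
                row[str(p)] = "missing"
            else:
                row[str(p)] = _GENOTYPE_CODE[ind.genotype_at(chrom, p)]
        rows.append(row)
    return pd.DataFrame(rows, columns=["phenotype"] + [str(p) for p in positions])
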