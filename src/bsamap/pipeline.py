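"""End-to-end simulation -> scan orchestration at the study design.

The default preset mirrors the mapping design: a 12-chromosome tomato-like
genome, ~1300 background EMS SNPs plus one causal G>T at ch12:2,751,259,
216 BC1F2 plants, phenotype-selected bulks of 38, pooled sequencing at mean
depth 32 with 0.002 per-read error, a 10-100 read-depth window, and a
10-SNP sliding-window scan called at AF_mut > 0.95 / AF_wt < 0.4.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import afscan, popsim, variant_io
from .genome import GenomeModel, tomato_genome


@dataclass
class SimulationPreset:
    """All knobs of one simulated mapping experiment."""

    genome: GenomeModel = field(default_factory=tomato_genome)
    causal: tuple[str, int, str, str] = ("ch12", 2_751_259, "G", "T")
    n_background: int = 1300
    n_plants: int = 216
    n_per_bulk: int = 38
    mean_depth: float = 32.0
    error_rate: float = 0.002
    penetrance: float = 1.0
    min_depth: int = 10
    max_depth: int = 100
    window_snps: int = 10
    t_high: float = 0.95
    t_low: float = 0.4


def default_preset(**overrides) -> SimulationPreset:
    return replace(SimulationPreset(), **overrides)


@dataclass
class ScanResult:
    """Everything one simulated experiment produced."""

    preset: SimulationPreset
    variants: popsim.EmsVariantSet
    population: list
    table: variant_io.VariantTable
    track: pd.DataFrame
    windows: pd.DataFrame
    regions: list
    causal_window: pd.Series | None

    @property
    def causal_window_af_mut(self) -> float:
        return float(self.causal_window["af_mut"])

    @property
    def causal_window_af_wt(self) -> float:
        return float(self.causal_window["af_wt"])

    @property
    def causal_in_region(self) -> bool:
        return any(r.contains_causal for r in self.regions)


def simulate_bulk_table(
    seed: int, preset: SimulationPreset | None = None
) -> tuple[variant_io.VariantTable, popsim.EmsVariantSet, list]:
    """Simulate one experiment down to the two-bulk variant table (unfiltered)."""
    p = preset or SimulationPreset()
    ss = np.random.SeedSequence(seed)
    s_var, s_pop, s_bulk, s_mut, s_wt = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(5)
    )
    variants = popsim.simulate_ems_variants(p.genome, p.n_background, p.causal, seed=s_var)
    pop = popsim.make_bc1f2(variants, p.n_plants, p.genome, seed=s_pop, penetrance=p.penetrance)
    mut_bulk, wt_bulk = popsim.select_bulks(pop, p.n_per_bulk, seed=s_bulk)
    mut_counts = popsim.simulate_pooled_reads(
        mut_bulk, variants, p.mean_depth, p.error_rate, seed=s_mut,
        label=popsim.MUTANT_BULK,
    )
    wt_counts = popsim.simulate_pooled_reads(
        wt_bulk, variants, p.mean_depth, p.error_rate, seed=s_wt,
        label=popsim.WT_LIKE_BULK,
    )
    table = variant_io.VariantTable.from_counts(variants, wt_counts, mut_counts)
    return table, variants, pop


def scan_simulation(seed: int, preset: SimulationPreset | None = None) -> ScanResult:
    """Run one simulated experiment end to end: simulate, filter, scan, call."""
    p = preset or SimulationPreset()
    table, variants, pop = simulate_bulk_table(seed, p)
    filtered = variant_io.filter_depth(table, p.min_depth, p.max_depth)
    track = afscan.af_track(filtered)
    windows = afscan.sliding_window_mean(track, window_snps=p.window_snps)
    causal = variants.causal
    regions = afscan.call_candidate_regions(
        windows, t_high=p.t_high, t_low=p.t_low, causal=(causal.chrom, causal.pos)
    )
    cw = afscan.window_at(windows, causal.chrom, causal.pos)
    return ScanResult(
        preset=p, variants=variants, population=pop, table=filtered,
        track=track, windows=windows, regions=regions, causal_window=cw,
    )
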