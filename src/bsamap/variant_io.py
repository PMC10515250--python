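"""Two-bulk variant tables: VCF round trip and the study's variant filters.

The in-memory container is a pandas DataFrame wrapped in
:class:`VariantTable`, one row per biallelic SNV with per-bulk read depth and
alt-read count.  Bulk order is fixed as (wt_like, mutant).  Coordinates are
1-based throughout (VCF convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .genome import GenomeModel
from .popsim import BulkCounts, EmsVariantSet

log = logging.getLogger(__name__)

BULK_ORDER = ("wt_like", "mutant")
COLUMNS = ["chrom", "pos", "ref", "alt", "wt_depth", "wt_alt", "mut_depth", "mut_alt"]

_BASES = frozenset("ACGT")
_TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


@dataclass
class VariantTable:
    """Sorted table of biallelic SNVs with per-bulk allele depths."""

    df: pd.DataFrame
    n_skipped: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        df = self.df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        for bulk in ("wt", "mut"):
            bad = df[f"{bulk}_alt"] > df[f"{bulk}_depth"]
            if bad.any():
                raise ValueError("alt_count exceeds depth in some rows")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_counts(
        cls,
        variants: EmsVariantSet,
        wt_counts: BulkCounts,
        mut_counts: BulkCounts,
    ) -> "VariantTable":
        """Assemble a table from simulated pooled counts (wt_like, mutant)."""
        if len(wt_counts.depth) != len(variants) or len(mut_counts.depth) != len(variants):
            raise ValueError("counts are not aligned with the variant set")
        df = pd.DataFrame(
            {
                "chrom": [v.chrom for v in variants],
                "pos": [v.pos for v in variants],
                "ref": [v.ref for v in variants],
                "alt": [v.alt for v in variants],
                "wt_depth": wt_counts.depth,
                "wt_alt": wt_counts.alt_count,
                "mut_depth": mut_counts.depth,
                "mut_alt": mut_counts.alt_count,
                "is_causal": [v.is_causal for v in variants],
            }
        )
        return cls(df)


def read_bulk_vcf(path: str) -> VariantTable:
    """Read a two-sample VCF with per-allele depths into a :class:`VariantTable`.

    The two samples are mapped to (wt_like, mutant) by name when the samples
    are called ``wt_like`` and ``mutant``, otherwise positionally (first =
    wt_like).  Multi-allelic records are split into one row per SNV alt;
    non-SNV alleles are skipped and counted in ``n_skipped`` (also logged).
    Records lacking an AD-like per-allele depth raise, naming the record.
    """
    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    if len(samples) == 0:
        raise ValueError(f"{path}: VCF has zero samples; expected two bulks")
    if len(samples) != 2:
        raise ValueError(f"{path}: expected exactly 2 samples, found {len(samples)}")
    if set(samples) == set(BULK_ORDER):
        wt_name, mut_name = BULK_ORDER
    else:
        wt_name, mut_name = samples
    has_causal_info = "CAUSAL" in vf.header.info
    rows = []
    n_skipped = 0
    for rec in vf:
        alts = rec.alts or ()
        if rec.ref is None or len(rec.ref) != 1 or rec.ref.upper() not in _BASES:
            n_skipped += max(1, len(alts))
            continue
        ads = {}
        for name in (wt_name, mut_name):
            ad = rec.samples[name].get("AD")
            if ad is None or all(a is None for a in ad):
                raise ValueError(
                    f"{path}: record {rec.chrom}:{rec.pos} sample {name} has no AD field"
                )
            ads[name] = [0 if a is None else int(a) for a in ad]
        for ai, alt in enumerate(alts):
            if alt is None or len(alt) != 1 or alt.upper() not in _BASES:
                n_skipped += 1
                continue
            row = {"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref.upper(), "alt": alt.upper()}
            for prefix, name in (("wt", wt_name), ("mut", mut_name)):
                ad = ads[name]
                dp = rec.samples[name].get("DP")
                row[f"{prefix}_depth"] = int(dp) if dp is not None else sum(ad)
                row[f"{prefix}_alt"] = ad[ai + 1] if ai + 1 < len(ad) else 0
            row["is_causal"] = (
                bool(rec.info.get("CAUSAL", False)) if has_causal_info else False
            )
            rows.append(row)
    vf.close()
    if n_skipped:
        log.info("read_bulk_vcf: skipped %d non-SNV allele(s) in %s", n_skipped, path)
    df = pd.DataFrame(rows, columns=COLUMNS + ["is_causal"])
    return VariantTable(df, n_skipped=n_skipped)


def write_bulk_vcf(
    table: VariantTable,
    path: str,
    genome: GenomeModel | None = None,
    params: dict | None = None,
) -> None:
    """Write a VariantTable as VCF 4.2 with AD and DP per bulk sample.

    Tool name and any ``params`` (e.g. simulation seed) are recorded as
    header meta lines.
    """
    header = pysam.VariantHeader()
    header.add_meta("source", "bsamap")
    for k, v in (params or {}).items():
        header.add_meta(f"bsamap_{k}", str(v))
    contigs = (
        genome.names if genome is not None else list(dict.fromkeys(table.df["chrom"]))
    )
    for name in contigs:
        if genome is not None:
            header.contigs.add(name, length=genome.chromosome(name).length_bp)
        else:
            header.contigs.add(name)
    header.info.add("CAUSAL", 0, "Flag", "Known causal variant (simulation truth)")
    header.formats.add("AD", "R", "Integer", "Per-allele read depth")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    for sample in BULK_ORDER:
        header.add_sample(sample)
    vf = pysam.VariantFile(path, "w", header=header)
    has_causal = "is_causal" in table.df.columns
    for row in table.df.itertuples(index=False):
        rec = vf.new_record(
            contig=row.chrom, start=row.pos - 1, stop=row.pos, alleles=(row.ref, row.alt)
        )
        if has_causal and bool(getattr(row, "is_causal", False)):
            rec.info["CAUSAL"] = True
        rec.samples["wt_like"]["AD"] = (int(row.wt_depth - row.wt_alt), int(row.wt_alt))
        rec.samples["wt_like"]["DP"] = int(row.wt_depth)
        rec.samples["mutant"]["AD"] = (int(row.mut_depth - row.mut_alt), int(row.mut_alt))
        rec.samples["mutant"]["DP"] = int(row.mut_depth)
        vf.write(rec)
    vf.close()


def filter_depth(
    table: VariantTable,
    min_depth: int = 10,
    max_depth: int = 100,
    per_bulk: bool = True,
) -> VariantTable:
    """Keep SNVs whose read depth lies in [min_depth, max_depth] (inclusive).

    By default the bound is applied per bulk and both bulks must pass (the
    conservative reading of a depth-window filter on two pools); with
    ``per_bulk=False`` the bound applies to the summed depth instead.
    """
    if min_depth > max_depth:
        raise ValueError("min_depth must be <= max_depth")
    df = table.df
    if per_bulk:
        keep = (
            df["wt_depth"].between(min_depth, max_depth)
            & df["mut_depth"].between(min_depth, max_depth)
        )
    else:
        keep = (df["wt_depth"] + df["mut_depth"]).between(min_depth, max_depth)
    return VariantTable(df[keep].reset_index(drop=True), n_skipped=table.n_skipped)


def filter_substitution_class(table: VariantTable, mode: str = "all") -> VariantTable:
    """Restrict by substitution class: ``all`` (identity) or ``transitions_only``.

    The default is ``all``: the EMS spectrum is transition-dominated, but a
    causal transversion must survive the filter.
    """
    if mode == "all":
        return VariantTable(table.df.copy(), n_skipped=table.n_skipped)
    if mode != "transitions_only":
        raise ValueError(f"unknown substitution filter mode {mode!r}")
    df = table.df
    keep = [
        (r, a) in _TRANSITIONS for r, a in zip(df["ref"], df["alt"])
    ]
    return VariantTable(df[keep].reset_index(drop=True), n_skipped=table.n_skipped)
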