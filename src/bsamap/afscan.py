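"""Bulk allele-frequency scan: per-SNP AFs, 10-SNP sliding windows, regions.

The scan statistic is the fraction of reads carrying the mutant allele at
each site in each bulk, smoothed as the arithmetic mean over a sliding
window of a fixed number of SNPs (windows never span chromosomes).  A window
is causal-like when the mutant-bulk mean exceeds ``t_high`` while the
wt-like-bulk mean stays below ``t_low`` (strict inequalities); passing
windows that overlap or touch merge into candidate regions whose bounds are
the bp positions of the outermost member SNPs (1-based closed).

A dAF column (mutant minus wt-like AF) is emitted for plotting only; region
calling uses exclusively the dual-threshold rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import VariantTable


def allele_frequency(alt_count, depth):
    """alt_count / depth; requires depth >= 1 (filter zero-depth sites first)."""
    alt = np.asarray(alt_count, dtype=float)
    dep = np.asarray(depth, dtype=float)
    if (dep < 1).any():
        raise ValueError("allele_frequency requires depth >= 1 at every site")
    out = alt / dep
    return float(out) if out.ndim == 0 else out


def af_track(table: VariantTable) -> pd.DataFrame:
    """Per-variant AF table: chrom, pos, af_wt, af_mut, daf (and is_causal)."""
    df = table.df
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"],
            "af_wt": allele_frequency(df["wt_alt"], df["wt_depth"]),
            "af_mut": allele_frequency(df["mut_alt"], df["mut_depth"]),
        }
    )
    out["daf"] = out["af_mut"] - out["af_wt"]
    if "is_causal" in df.columns:
        out["is_causal"] = df["is_causal"].to_numpy()
    return out


def sliding_window_mean(
    track: pd.DataFrame, window_snps: int = 10, step: int = 1
) -> pd.DataFrame:
    """Mean AF per bulk over sliding windows of ``window_snps`` SNPs.

    One window per start offset at the given step, per chromosome;
    chromosomes with fewer SNPs than the window emit no windows.  The window
    midpoint is the mean bp of its member SNPs; start_pos/end_pos are the
    outermost member SNP positions.
    """
    if window_snps < 1:
        raise ValueError("window_snps must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    frames = []
    for chrom, g in track.groupby("chrom", sort=True):
        g = g.sort_values("pos", kind="mergesort")
        n = len(g)
        if n < window_snps:
            continue
        pos = g["pos"].to_numpy(dtype=float)
        cs_pos = np.concatenate([[0.0], np.cumsum(pos)])
        cs_mut = np.concatenate([[0.0], np.cumsum(g["af_mut"].to_numpy(dtype=float))])
        cs_wt = np.concatenate([[0.0], np.cumsum(g["af_wt"].to_numpy(dtype=float))])
        starts = np.arange(0, n - window_snps + 1, step)
        w = window_snps
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start_idx": starts,
                    "n_snps": w,
                    "start_pos": pos[starts].astype(np.int64),
                    "end_pos": pos[starts + w - 1].astype(np.int64),
                    "mid_bp": (cs_pos[starts + w] - cs_pos[starts]) / w,
                    "af_wt": (cs_wt[starts + w] - cs_wt[starts]) / w,
                    "af_mut": (cs_mut[starts + w] - cs_mut[starts]) / w,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "chrom", "start_idx", "n_snps", "start_pos", "end_pos",
                "mid_bp", "af_wt", "af_mut",
            ]
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class CandidateRegion:
    """A genomic interval supported by causal-like smoothed-AF windows."""

    chrom: str
    start: int  # 1-based, closed
    end: int
    n_windows: int
    min_af_mut: float
    max_af_wt: float
    passes_dual: bool = True
    contains_causal: bool | None = None


def call_candidate_regions(
    windows: pd.DataFrame,
    t_high: float = 0.95,
    t_low: float = 0.4,
    rule: str = "dual",
    causal: tuple[str, int] | None = None,
) -> list[CandidateRegion]:
    """Merge threshold-passing windows into candidate regions.

    ``rule="dual"`` (default): a window passes iff mean AF_mut > t_high AND
    mean AF_wt < t_low — the published detection rule.  ``rule="mutant_only"``
    passes on AF_mut > t_high alone, which is how a divergent introgression
    block (high AF in both bulks) surfaces for inspection before ranking
    demotes it.  Overlapping or adjacent passing windows merge; region bounds
    are the outermost member-SNP positions.  When the causal (chrom, pos) is
    known, each region is flagged for containing it.
    """
    if not (0.0 < t_low < t_high < 1.0):
        raise ValueError("need 0 < t_low < t_high < 1")
    if rule not in ("dual", "mutant_only"):
        raise ValueError(f"unknown rule {rule!r}")
    dual = (windows["af_mut"] > t_high) & (windows["af_wt"] < t_low)
    passing = dual if rule == "dual" else (windows["af_mut"] > t_high)
    regions: list[CandidateRegion] = []
    for chrom, g in windows[passing].groupby("chrom", sort=True):
        g = g.sort_values("start_idx", kind="mergesort")
        run: list[int] = []
        run_end_idx = -2
        for i in g.index:
            w_start = int(windows.at[i, "start_idx"])
            w_end = w_start + int(windows.at[i, "n_snps"]) - 1
            if w_start <= run_end_idx + 1 and run:
                run.append(i)
                run_end_idx = max(run_end_idx, w_end)
            else:
                if run:
                    regions.append(_make_region(windows, run, chrom, dual, causal))
                run = [i]
                run_end_idx = w_end
        if run:
            regions.append(_make_region(windows, run, chrom, dual, causal))
    return regions


def _make_region(windows, members, chrom, dual, causal) -> CandidateRegion:
    sub = windows.loc[members]
    start = int(sub["start_pos"].min())
    end = int(sub["end_pos"].max())
    contains = None
    if causal is not None:
        contains = causal[0] == chrom and start <= causal[1] <= end
    return CandidateRegion(
        chrom=chrom,
        start=start,
        end=end,
        n_windows=len(members),
        min_af_mut=float(sub["af_mut"].min()),
        max_af_wt=float(sub["af_wt"].max()),
        passes_dual=bool(dual[members].any()),
        contains_causal=contains,
    )


def rank_regions(regions: list[CandidateRegion]) -> list[CandidateRegion]:
    """Order candidate regions, strongest causal evidence first.

    Dual-rule regions precede mutant-only detections (a block with high AF
    in both bulks is penalized by its wt-like AF); then descending minimum
    mutant-bulk AF, ascending maximum wt-like AF, descending window support,
    and genomic order as the final tie-break.
    """
    return sorted(
        regions,
        key=lambda r: (
            not r.passes_dual,
            -r.min_af_mut,
            r.max_af_wt,
            -r.n_windows,
            r.chrom,
            r.start,
        ),
    )


def window_at(
    windows: pd.DataFrame, chrom: str, pos: int, strict: bool = False
) -> pd.Series | None:
    """The window containing ``pos`` whose midpoint is nearest to it.

    Falls back to the nearest window on the chromosome when no window span
    contains the position (unless ``strict``), and returns None when the
    chromosome has no windows at all.
    """
    g = windows[windows["chrom"] == chrom]
    if g.empty:
        return None
    hit = g[(g["start_pos"] <= pos) & (g["end_pos"] >= pos)]
    if hit.empty:
        if strict:
            return None
        hit = g
    return hit.loc[(hit["mid_bp"] - pos).abs().idxmin()]
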