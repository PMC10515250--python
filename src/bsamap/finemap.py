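"""Recombinant fine mapping over a marker scaffold, plus the segregation test.

Phenotypically mutant individuals in a recessive-trait F2-type population are
inferred homozygous mutant at the causal locus, so any marker genotype other
than hom_mut reveals a recombination event between marker and causal site.
Marker-wise recombinant counts delimit the candidate interval: the causal
position lies in the maximal run of zero-recombinant markers, strictly
between the nearest flanking markers that show recombinants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GENOTYPE_CODES = frozenset({"hom_mut", "het", "hom_wt", "missing"})


def read_marker_tsv(path: str, phenotype_col: str = "phenotype") -> pd.DataFrame:
    """Load an individuals x markers genotype matrix from TSV.

    The header row carries marker positions; one column holds phenotypes.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if phenotype_col not in df.columns:
        raise ValueError(f"{path}: no {phenotype_col!r} column")
    return df


def count_recombinants(
    data: pd.DataFrame,
    selected_phenotype: str = "mutant_phenotype",
    phenotype_col: str = "phenotype",
) -> pd.Series:
    """Per-marker recombinant counts among phenotype-selected individuals.

    A selected (recessive-class, hence inferred hom_mut) individual is a
    recombinant at a marker when its genotype there is not hom_mut;
    heterozygous calls count (one crossover), missing calls are excluded.
    Markers are the non-phenotype columns, ordered by numeric position.
    """
    sel = data[data[phenotype_col] == selected_phenotype]
    if sel.empty:
        raise ValueError(
            f"no individuals with phenotype {selected_phenotype!r}"
        )
    markers = [c for c in data.columns if c != phenotype_col]
    try:
        markers = sorted(markers, key=lambda c: float(c))
    except (TypeError, ValueError):
        pass  # non-positional marker names: keep the given column order
    bad = set(np.unique(data[markers].to_numpy())) - GENOTYPE_CODES
    if bad:
        raise ValueError(f"invalid genotype codes: {sorted(bad)}")
    counts = {}
    for m in markers:
        g = sel[m]
        informative = g != "missing"
        counts[m] = int((g[informative] != "hom_mut").sum())
    return pd.Series(counts, name="recombinants")


@dataclass(frozen=True)
class FinemapResult:
    """Recombinant counts and the inferred causal interval.

    ``left_flank``/``right_flank`` are the positions of the nearest markers
    with recombinants (the interval is open at them); ``None`` means the
    interval runs to the chromosome end.  ``zero_markers`` is the maximal
    run of zero-recombinant markers containing the causal site.
    """

    counts: pd.Series
    zero_markers: tuple[str, ...]
    left_flank: str | None
    right_flank: str | None
    resolved: bool
    diagnostic: str = ""

    def contains(self, pos: float) -> bool:
        """Is a position inside the open interval (flank, flank)?"""
        if not self.zero_markers:
            return False
        left = float(self.left_flank) if self.left_flank is not None else -np.inf
        right = float(self.right_flank) if self.right_flank is not None else np.inf
        return left < pos < right


def infer_interval(counts: pd.Series) -> FinemapResult:
    """Locate the causal interval as the maximal zero-recombinant marker run.

    With ties, the longest run wins (first on the chromosome if equal).
    All-zero counts span every marker but are flagged unresolved; all-nonzero
    counts yield an empty interval with a diagnostic.
    """
    if len(counts) < 2:
        raise ValueError("need at least two markers")
    vals = counts.to_numpy()
    markers = list(counts.index)
    runs = []
    i = 0
    while i < len(vals):
        if vals[i] == 0:
            j = i
            while j + 1 < len(vals) and vals[j + 1] == 0:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    if not runs:
        return FinemapResult(
            counts=counts, zero_markers=(), left_flank=None, right_flank=None,
            resolved=False,
            diagnostic="all markers show recombinants; no zero-recombinant interval",
        )
    i, j = max(runs, key=lambda r: r[1] - r[0])
    left = markers[i - 1] if i > 0 else None
    right = markers[j + 1] if j < len(markers) - 1 else None
    unresolved = left is None and right is None
    return FinemapResult(
        counts=counts,
        zero_markers=tuple(markers[i : j + 1]),
        left_flank=left,
        right_flank=right,
        resolved=not unresolved,
        diagnostic=(
            "unresolved: zero recombinants at every marker" if unresolved else ""
        ),
    )


def chi_square_segregation(
    n_mutant: int, n_wt: int, expected_ratio: tuple[float, float] = (1, 3)
) -> tuple[float, int, float]:
    """Pearson chi-square goodness of fit against a phenotypic ratio.

    Defaults to the 1:3 (mutant:wild-type) expectation of a monogenic
    recessive trait in an F2-type generation.  Returns (statistic, df, p).
    """
    if n_mutant < 0 or n_wt < 0:
        raise ValueError("counts must be >= 0")
    total = n_mutant + n_wt
    if total == 0:
        raise ValueError("total count must be > 0")
    ratio = np.asarray(expected_ratio, dtype=float)
    expected = total * ratio / ratio.sum()
    stat, p = stats.chisquare([n_mutant, n_wt], f_exp=expected)
    return float(stat), 1, float(p)
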