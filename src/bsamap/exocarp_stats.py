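"""Downstream exocarp summaries: DEG filtering, category accounting,
fold-change and t-test helpers, and cell-wall composition calculators.

Differential-expression testing itself is out of scope — log2 fold changes
and q-values arrive as inputs; this module applies the threshold filter
(|log2FC| >= 1, q < 0.05, FPKM > 5 in at least one genotype), counts genes
per manually assigned functional category, and computes the pectin/
hemicellulose ratio diagnostics used for cutin-embedded polysaccharides:
RGI branching (Ara+Gal)/Rha, pectin linearity GalA/(Rha+Ara+Gal), Xyl/Man,
the degree of methyl esterification (mol methanol per 100 mol uronic acid)
and the degree of acetylation (mass acetic acid per mass polysaccharide).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEG_COLUMNS = ["gene_id", "function", "category", "log2fc", "q"]


def filter_degs(
    records: pd.DataFrame,
    lfc_cut: float = 1.0,
    q_cut: float = 0.05,
    fpkm_cut: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the DEG thresholds; return (up, down) tables.

    Keeps records with |log2fc| >= lfc_cut AND q < q_cut AND, when
    ``fpkm_wt``/``fpkm_mut`` columns are present, FPKM strictly greater than
    ``fpkm_cut`` in at least one genotype.  Up means log2fc > 0
    (mutant over wild type).
    """
    df = records
    keep = (df["log2fc"].abs() >= lfc_cut) & (df["q"] < q_cut)
    if "fpkm_wt" in df.columns and "fpkm_mut" in df.columns:
        keep &= (df["fpkm_wt"] > fpkm_cut) | (df["fpkm_mut"] > fpkm_cut)
    kept = df[keep]
    up = kept[kept["log2fc"] > 0].reset_index(drop=True)
    down = kept[kept["log2fc"] < 0].reset_index(drop=True)
    return up, down


def count_by_category(records: pd.DataFrame) -> dict[str, int]:
    """Exact gene counts per functional category label.

    Raises on missing/empty category labels, listing the offending genes.
    """
    if records.empty:
        return {}
    cat = records["category"]
    bad = cat.isna() | (cat.astype(str).str.strip() == "")
    if bad.any():
        genes = records.loc[bad, "gene_id"].tolist()
        raise ValueError(f"records without a category label: {genes}")
    return cat.value_counts().to_dict()


def fold_change(value_ref: float, value_alt: float) -> tuple[float, str]:
    """Reporting-style fold change: max/min rounded to one decimal + direction.

    Direction is relative to the reference: the alt value is a ``reduction``
    (alt < ref), an ``increase`` (alt > ref) or ``none`` (equal).
    """
    if value_ref <= 0 or value_alt <= 0:
        raise ValueError("fold_change requires positive values")
    fold = max(value_ref, value_alt) / min(value_ref, value_alt)
    if value_alt < value_ref:
        direction = "reduction"
    elif value_alt > value_ref:
        direction = "increase"
    else:
        direction = "none"
    return round(fold, 1), direction


def two_sample_t(a, b) -> tuple[float, int, float]:
    """Classic pooled-variance Student's t, two-sided.

    Each group is either raw values (array-like) or a (mean, sd, n) summary
    triple; the two routes agree on matched inputs.  Both groups constant
    and equal means -> (0, df, 1) by convention.
    """

    def as_summary(g):
        if isinstance(g, tuple) and len(g) == 3 and np.isscalar(g[0]):
            mean, sd, n = g
            if n < 2:
                raise ValueError("need n >= 2 per group")
            if sd < 0:
                raise ValueError("SD must be >= 0")
            return float(mean), float(sd), int(n)
        vals = np.asarray(g, dtype=float)
        if vals.size < 2:
            raise ValueError("need n >= 2 per group")
        return float(vals.mean()), float(vals.std(ddof=1)), int(vals.size)

    m1, s1, n1 = as_summary(a)
    m2, s2, n2 = as_summary(b)
    df = n1 + n2 - 2
    if s1 == 0.0 and s2 == 0.0:
        if m1 == m2:
            return 0.0, df, 1.0
        return math.copysign(math.inf, m1 - m2), df, 0.0
    t, p = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return float(t), df, float(p)


@dataclass(frozen=True)
class SugarProfile:
    """Monosaccharide composition (mol%) plus esterification measurements.

    ``methanol_mol`` and ``uronic_mol`` are mole amounts on a shared scale
    (uronic acid defaults to the GalA mol% when not given separately);
    ``acetic_mass`` and ``poly_mass`` are masses on a shared scale.
    """

    rha: float = 0.0
    ara: float = 0.0
    xyl: float = 0.0
    man: float = 0.0
    gal: float = 0.0
    gala: float = 0.0
    glc: float = 0.0
    methanol_mol: float = 0.0
    uronic_mol: float | None = None
    acetic_mass: float = 0.0
    poly_mass: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rha", "ara", "xyl", "man", "gal", "gala", "glc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def uronic(self) -> float:
        return self.gala if self.uronic_mol is None else self.uronic_mol


def cell_wall_ratios(profile: SugarProfile) -> dict[str, float | None]:
    """Pectin/hemicellulose structure diagnostics from molar composition.

    rgi_branching = (Ara+Gal)/Rha; pectin_linearity = GalA/(Rha+Ara+Gal);
    xyl_man = Xyl/Man.  A zero denominator (e.g. rhamnose below the
    detection limit) yields None for that ratio — flagged, not an error.
    """

    def safe(num: float, den: float) -> float | None:
        return None if den == 0 else num / den

    return {
        "rgi_branching": safe(profile.ara + profile.gal, profile.rha),
        "pectin_linearity": safe(
            profile.gala, profile.rha + profile.ara + profile.gal
        ),
        "xyl_man": safe(profile.xyl, profile.man),
    }


def esterification_degrees(profile: SugarProfile) -> tuple[float, float]:
    """(DM, DA): methyl-esterification and acetylation degrees.

    DM = mol methanol per 100 mol uronic acid; DA = mass acetic acid per
    mass polysaccharide (a raw mass ratio, as reported).
    """
    if profile.uronic <= 0:
        raise ValueError("DM needs uronic acid > 0")
    if profile.poly_mass <= 0:
        raise ValueError("DA needs polysaccharide mass > 0")
    dm = profile.methanol_mol / profile.uronic * 100.0
    da = profile.acetic_mass / profile.poly_mass
    return dm, da


def polysaccharide_partition(
    neutral_sugars_total: float,
    cellulosic_glucose: float,
    uronic_acid: float,
) -> dict[str, float]:
    """Partition measured sugars into cellulose, hemicellulose, pectin.

    Cellulose is the glucose specifically released by the second (strong-
    acid) hydrolysis; pectin is the uronic acid; hemicellulose is the total
    neutral sugar minus that cellulosic glucose.  Components therefore sum
    to neutral sugars + uronic acid.
    """
    if min(neutral_sugars_total, cellulosic_glucose, uronic_acid) < 0:
        raise ValueError("inputs must be non-negative")
    hemicellulose = neutral_sugars_total - cellulosic_glucose
    if hemicellulose < 0:
        raise ValueError(
            "inconsistent input: cellulosic glucose exceeds total neutral sugars"
        )
    return {
        "cellulose": cellulosic_glucose,
        "hemicellulose": hemicellulose,
        "pectin": uronic_acid,
    }
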