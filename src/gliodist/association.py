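"""Spatial-genomic association: pooled Pearson correlation and OLS fit.

For each modality (mutation, cnv, methylation), intra-patient biopsy pairs
contribute one (Euclidean mm, genomic distance) point; the pooled points
are summarized by the product-moment correlation r with its two-sided
t-transform p-value, and by the least-squares line

    genomic distance = intercept + slope * Euclidean mm.

Two spatial-equivalence constants are derived from the slope: the genomic
distance accrued per 10 mm (10 * slope) and the mm equivalent of one
genomic-distance unit (1 / slope).

Pairs sharing a patient are not statistically independent; the pooled
analysis treats them as such by design (documented caveat). A
within-patient permutation p-value is available as an optional robustness
output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MODALITIES = ("mutation", "cnv", "methylation")

# distance column per modality in the pairwise tables
MODALITY_DISTANCE_COLUMNS = {
    "mutation": "count_distance",
    "cnv": "canberra_distance",
    "methylation": "l1_distance",
}


def _validate_xy(x, y, min_n: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} points, got {x.size}")
    return x, y


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment r and its two-sided p-value.

    The p-value comes from t = r * sqrt(n-2) / sqrt(1-r^2) against a
    t distribution with n-2 degrees of freedom.
    """
    x, y = _validate_xy(x, y, 3)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate input: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a given correlation coefficient and sample size."""
    if not -1.0 < r < 1.0:
        raise ValueError("r must lie strictly inside (-1, 1)")
    if n < 3:
        raise ValueError("need n >= 3")
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


@dataclass
class OLSFit:
    slope: float
    intercept: float
    stderr_slope: float
    r_value: float
    n: int


def ols_fit(x, y) -> OLSFit:
    """Least-squares line y = intercept + slope * x."""
    x, y = _validate_xy(x, y, 2)
    if np.all(x == x[0]):
        raise ValueError("constant x: slope undefined")
    res = stats.linregress(x, y)
    return OLSFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr_slope=float(res.stderr),
        r_value=float(res.rvalue),
        n=int(x.size),
    )


def round_report(value: float, decimals: int = 1, small_cutoff: float = 0.2) -> float:
    """Presentation rounding: ``decimals`` places, one extra below the cutoff.

    Magnitudes under ``small_cutoff`` keep two significant digits (e.g.
    1/6.8 reports as 0.15, not 0.1), matching how small equivalence
    constants are conventionally printed.
    """
    if not math.isfinite(value):
        return value
    if abs(value) < small_cutoff:
        return round(value, decimals + 1)
    return round(value, decimals)


@dataclass
class Equivalences:
    per_10mm: float
    mm_per_unit: float
    per_10mm_rounded: float
    mm_per_unit_rounded: float


def derived_equivalences(slope: float, decimals: int = 1) -> Equivalences:
    """Spatial-equivalence constants from a fitted slope.

    ``per_10mm`` = 10 * slope (genomic distance per 10 mm of separation);
    ``mm_per_unit`` = 1 / slope (mm per genomic-distance unit; NaN for a
    zero slope, where the inverse is undefined).
    """
    per_10mm = 10.0 * slope
    mm_per_unit = 1.0 / slope if slope != 0 else float("nan")
    if slope == 0:
        logger.warning("zero slope: mm_per_unit undefined (reported as NaN)")
    return Equivalences(
        per_10mm=per_10mm,
        mm_per_unit=mm_per_unit,
        per_10mm_rounded=round_report(per_10mm, decimals),
        mm_per_unit_rounded=round_report(mm_per_unit, decimals),
    )


@dataclass
class AssociationResult:
    """Pooled spatial-genomic association summary for one modality."""

    modality: str
    n_pairs: int
    pearson_r: float | None
    p_value: float | None
    slope: float | None
    intercept: float | None
    per_10mm: float | None
    mm_per_unit: float | None
    stderr_slope: float | None = None
    insufficient_n: bool = False
    permutation_p: float | None = None
    subgroups: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "n_pairs": self.n_pairs,
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "slope": self.slope,
            "intercept": self.intercept,
            "per_10mm": self.per_10mm,
            "mm_per_unit": self.mm_per_unit,
            "stderr_slope": self.stderr_slope,
            "insufficient_n": self.insufficient_n,
            "permutation_p": self.permutation_p,
            "subgroups": self.subgroups,
        }


def assemble_records(
    pairs: pd.DataFrame,
    modality_tables: dict[str, pd.DataFrame],
    strat_columns: Sequence[str] = (),
) -> pd.DataFrame:
    """Inner-join the spatial pair table with per-modality distance tables.

    ``pairs`` must carry patient_id/sample_a/sample_b/euclidean_mm (and any
    ``strat_columns`` to carry through); each modality table must carry the
    pair key plus its distance column. Unmatched rows on either side are
    logged and excluded; duplicate pair keys are an error.
    """
    key = ["patient_id", "sample_a", "sample_b"]
    if pairs.duplicated(key).any():
        raise ValueError("duplicate pair keys in spatial table")
    records = []
    for modality, table in modality_tables.items():
        dist_col = MODALITY_DISTANCE_COLUMNS[modality]
        if table.duplicated(key).any():
            raise ValueError(f"duplicate pair keys in {modality} table")
        merged = pairs.merge(table[key + [dist_col]], on=key, how="inner")
        n_lost = len(pairs) - len(merged) + len(table) - len(merged)
        if n_lost:
            logger.info(
                "assemble_records(%s): %d unmatched row(s) excluded by the join",
                modality,
                n_lost,
            )
        out = merged[key + ["euclidean_mm", *strat_columns]].copy()
        out["modality"] = modality
        out["genomic_distance"] = merged[dist_col]
        records.append(out)
    if not records:
        return pd.DataFrame(
            columns=key + ["euclidean_mm", "modality", "genomic_distance"]
        )
    return pd.concat(records, ignore_index=True)


def permutation_pvalue(
    records: pd.DataFrame, n_perm: int = 1000, seed: int = 0
) -> float:
    """Patient-level permutation p for the pooled correlation.

    Genomic distances are shuffled within each patient, preserving the
    spatial structure, and the null distribution of |r| is compared with
    the observed value. This is a robustness extension beyond the pooled
    analysis, which ignores within-patient dependence.
    """
    rng = np.random.default_rng(seed)
    x = records["euclidean_mm"].to_numpy(dtype=float)
    y = records["genomic_distance"].to_numpy(dtype=float)
    r_obs, _ = pearson_correlation(x, y)
    groups = [np.flatnonzero(records["patient_id"] == p) for p in records["patient_id"].unique()]
    count = 0
    for _ in range(n_perm):
        y_perm = y.copy()
        for idx in groups:
            y_perm[idx] = y[rng.permutation(idx)]
        r_perm = np.corrcoef(x, y_perm)[0, 1]
        if abs(r_perm) >= abs(r_obs):
            count += 1
    return (count + 1) / (n_perm + 1)


def associate(
    records: pd.DataFrame,
    modality: str,
    permutation: bool = False,
    n_perm: int = 1000,
    seed: int = 0,
    strat_columns: Sequence[str] = (),
) -> AssociationResult:
    """Pooled association for one modality's records.

    With fewer than 3 pairs the result is flagged ``insufficient_n`` and
    the statistics are null. Optional subgroup results are computed for
    each level of each stratification column present in ``records``.
    """
    sub = records[records["modality"] == modality]
    n = len(sub)
    if n < 3:
        return AssociationResult(
            modality, n, None, None, None, None, None, None, insufficient_n=True
        )
    x = sub["euclidean_mm"].to_numpy(dtype=float)
    y = sub["genomic_distance"].to_numpy(dtype=float)
    r, p = pearson_correlation(x, y)
    fit = ols_fit(x, y)
    eq = derived_equivalences(fit.slope)
    result = AssociationResult(
        modality=modality,
        n_pairs=n,
        pearson_r=r,
        p_value=p,
        slope=fit.slope,
        intercept=fit.intercept,
        per_10mm=eq.per_10mm,
        mm_per_unit=eq.mm_per_unit,
        stderr_slope=fit.stderr_slope,
    )
    if permutation:
        result.permutation_p = permutation_pvalue(sub, n_perm=n_perm, seed=seed)
    for col in strat_columns:
        if col not in sub.columns:
            continue
        for level, grp in sub.groupby(col):
            if len(grp) < 3 or grp["euclidean_mm"].nunique() < 2:
                result.subgroups[f"{col}={level}"] = {"n_pairs": len(grp), "insufficient_n": True}
                continue
            gr, gp = pearson_correlation(grp["euclidean_mm"], grp["genomic_distance"])
            result.subgroups[f"{col}={level}"] = {
                "n_pairs": len(grp),
                "pearson_r": gr,
                "p_value": gp,
            }
    return result
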