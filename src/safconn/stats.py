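"""Within-subject paired inference for SCF across acquisition conditions.

For each paired comparison the subject-wise differences are first screened
with a Shapiro–Wilk normality test (threshold 0.05).  Normal-looking
differences go to a two-sided paired t-test; otherwise a two-sided Wilcoxon
signed-rank test is used (zero differences dropped by default; exact null
distribution at small n without ties, normal approximation with continuity
correction otherwise).  P-values are corrected per family with the
Benjamini–Hochberg step-up FDR procedure at level 0.05.

Families follow the study design: all cross-condition pairs within one
tractography method form one family for the global fraction; all cortical
regions form one family for the regional fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

SW_THRESHOLD = 0.05
DEFAULT_FDR_LEVEL = 0.05


@dataclass
class PairedComparison:
    """One paired test: label, branch taken, statistic, raw and FDR p."""

    label: str
    n_pairs: int
    normality_p: float
    test_used: str  # "paired_t" | "wilcoxon" | "degenerate"
    statistic: float
    p_two_sided: float
    mean_relative_difference_pct: float
    p_fdr: float = math.nan
    significant: bool = False


def paired_compare(
    x,
    y,
    label: str = "",
    zero_method: str = "wilcox",
) -> PairedComparison:
    """Compare paired condition values x (e.g. low res) vs y (high res).

    Differences d = x - y drive the test choice: Shapiro–Wilk p >= 0.05
    selects the paired t-test, otherwise the Wilcoxon signed-rank test.
    All-zero differences short-circuit to a degenerate result (p = 1);
    constant nonzero differences go to Wilcoxon, since Shapiro–Wilk is
    undefined on constant input while a constant shift is a legitimate
    paired effect.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    d = x - y
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(y != 0, 100.0 * d / y, np.nan)
    mean_rel = float(np.nanmean(rel)) if np.isfinite(rel).any() else math.nan

    if np.all(d == 0):
        return PairedComparison(label, n, math.nan, "degenerate", 0.0, 1.0, 0.0)
    if np.ptp(d) == 0:
        # constant nonzero differences: normality test undefined
        sw_p = math.nan
        use_t = False
    else:
        sw_p = float(sps.shapiro(d).pvalue)
        use_t = sw_p >= SW_THRESHOLD
    if use_t:
        res = sps.ttest_rel(x, y)
        return PairedComparison(
            label, n, sw_p, "paired_t", float(res.statistic), float(res.pvalue), mean_rel
        )
    method = "exact" if (n <= 25 and _no_ties(d, zero_method)) else "approx"
    res = sps.wilcoxon(
        d, zero_method=zero_method, correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return PairedComparison(
        label, n, sw_p, "wilcoxon", float(res.statistic), float(res.pvalue), mean_rel
    )


def _no_ties(d: np.ndarray, zero_method: str) -> bool:
    dd = d[d != 0] if zero_method == "wilcox" else d
    if len(dd) == 0:
        return True
    ad = np.abs(dd)
    return len(np.unique(ad)) == len(ad)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _apply_fdr(comparisons: list[PairedComparison], level: float) -> None:
    if not comparisons:
        return
    adj = bh_fdr([c.p_two_sided for c in comparisons])
    for c, q in zip(comparisons, adj):
        c.p_fdr = float(q)
        c.significant = bool(q < level)


def compare_gscf(
    table: pd.DataFrame,
    conditions: list[str] | None = None,
    fdr_level: float = DEFAULT_FDR_LEVEL,
) -> list[PairedComparison]:
    """All cross-condition paired comparisons of a subject-by-condition table.

    ``conditions`` orders the columns from highest to lowest resolution;
    each unordered pair (high, low) yields one comparison with x = low,
    y = high, so a negative relative difference means the lower resolution
    underestimates the fraction.  One BH family spans all pairs.
    """
    if conditions is None:
        conditions = list(table.columns)
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    out: list[PairedComparison] = []
    for a in range(len(conditions)):
        for b in range(a + 1, len(conditions)):
            high, low = conditions[a], conditions[b]
            sub = table[[high, low]].dropna()
            out.append(paired_compare(sub[low], sub[high], label=f"{low}_vs_{high}"))
    _apply_fdr(out, fdr_level)
    return out


def compare_rscf(
    high: pd.DataFrame,
    low: pd.DataFrame,
    regions: pd.DataFrame | None = None,
    fdr_level: float = DEFAULT_FDR_LEVEL,
    min_subjects: int = 3,
) -> tuple[list[PairedComparison], pd.DataFrame]:
    """Per-region paired comparison of RSCF at the two extreme resolutions.

    ``high`` and ``low`` are subject-by-region tables.  Regions with fewer
    than ``min_subjects`` complete pairs are excluded (reported).  One BH
    family spans all tested regions; each region is classified as
    "decrease", "increase" or "none" from the sign of its mean difference
    and FDR significance.
    """
    if list(high.columns) != list(low.columns):
        raise ValueError("subject tables do not share a region table")
    comparisons: list[PairedComparison] = []
    rows = []
    tested_regions = []
    for region in high.columns:
        pair = pd.concat([high[region], low[region]], axis=1, keys=["high", "low"]).dropna()
        if len(pair) < min_subjects:
            rows.append({"region": region, "tested": False, "n": len(pair), "direction": "excluded"})
            continue
        comparisons.append(paired_compare(pair["low"], pair["high"], label=str(region)))
        tested_regions.append(region)
    _apply_fdr(comparisons, fdr_level)
    for region, c in zip(tested_regions, comparisons):
        direction = "none"
        if c.significant:
            delta = c.mean_relative_difference_pct
            direction = "decrease" if delta < 0 else "increase"
        rows.append({"region": region, "tested": True, "n": c.n_pairs, "direction": direction})
    report = pd.DataFrame(rows)
    return comparisons, report


def top10_frequency(
    differences: pd.DataFrame,
    regions: pd.DataFrame,
    top_n: int = 10,
    min_frequency: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-method frequency of membership in the Top-N RSCF reductions.

    ``differences`` is a method-by-region table of signed RSCF differences
    (negative = reduction).  Per method, regions are ranked ascending (most
    negative first); membership is rank <= N, with all regions tied at the
    N-th value included.  The frequency table keeps regions appearing in at
    least ``min_frequency`` of the methods; the homologous table pairs
    filtered regions whose names match across opposite hemispheres.
    """
    if differences.shape[0] < 1:
        raise ValueError("need at least one method")
    region_info = regions.set_index("id")
    membership = pd.DataFrame(False, index=differences.index, columns=differences.columns)
    for method in differences.index:
        row = differences.loc[method].dropna()
        if len(row) <= top_n:
            members = row.index
        else:
            threshold = np.sort(row.to_numpy())[top_n - 1]
            members = row.index[row <= threshold]
        membership.loc[method, members] = True
    freq = membership.mean(axis=0)
    table = pd.DataFrame(
        {
            "region": freq.index,
            "name": [region_info.loc[r, "name"] for r in freq.index],
            "hemisphere": [region_info.loc[r, "hemisphere"] for r in freq.index],
            "frequency": freq.to_numpy(),
        }
    )
    table = table[table["frequency"] >= min_frequency].sort_values(
        ["frequency", "name"], ascending=[False, True]
    ).reset_index(drop=True)

    pairs = []
    by_name: dict[str, dict[str, int]] = {}
    for _, row in table.iterrows():
        by_name.setdefault(row["name"], {})[row["hemisphere"]] = row["region"]
    for name, sides in sorted(by_name.items()):
        if "L" in sides and "R" in sides:
            pairs.append({"name": name, "left_id": sides["L"], "right_id": sides["R"]})
    return table, pd.DataFrame(pairs, columns=["name", "left_id", "right_id"])
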