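"""Short-range Connectivity Fraction (SCF), global and regional.

The global SCF is the ratio of short-range (adjacent-pair) connectivity
strength to total association connectivity strength,

    GSCF = sum_{i,j : A(i,j)=1} w_ij / sum_{i,j} w_ij,

and the regional SCF of region k is the same ratio restricted to row k,

    RSCF_k = sum_{j : A(k,j)=1} w_kj / sum_j w_kj.

Because both are ratios of strengths, they are invariant to a global
rescaling of streamline counts, which makes them comparable across
acquisitions whose total streamline yield differs (e.g. after up-sampling-
induced smoothing inflates counts).  The double sums are evaluated exactly
as written over the full symmetric matrix; each unordered pair appears
twice in numerator and denominator alike, so the ratio is unaffected.

Zero denominators (a region with no connectivity, or an empty matrix)
yield *undefined* values that propagate as missing data — never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix


@dataclass
class SCFResult:
    """GSCF scalar plus per-region RSCF values for one connectome.

    ``gscf`` is NaN when total strength is zero; regions with zero row
    strength appear in ``undefined_regions`` and as NaN in ``rscf``.
    """

    gscf: float
    rscf: pd.Series
    undefined_regions: list[int] = field(default_factory=list)
    include_intra: bool = False
    length_threshold_mm: float | None = None


def _aligned(w: ConnectivityMatrix | pd.DataFrame, a: pd.DataFrame):
    if isinstance(w, ConnectivityMatrix):
        mat = w.w
        num = w.saf_numerator
        include_intra = w.include_intra
        thr = w.length_threshold_mm
    else:
        mat, num, include_intra, thr = w, None, False, None
    if mat.shape != a.shape or list(mat.index) != list(a.index):
        raise ValueError("connectivity and adjacency matrices are not aligned")
    return mat, num, include_intra, thr


def gscf(w: ConnectivityMatrix | pd.DataFrame, a: pd.DataFrame) -> float:
    """Global short-range connectivity fraction; NaN when total strength is 0.

    With the intra-regional variant the diagonal of W joins both numerator
    and denominator; with a length threshold the numerator is taken from
    the companion short-range matrix at adjacent positions.
    """
    mat, num, include_intra, thr = _aligned(w, a)
    wv = mat.to_numpy(dtype=float)
    av = a.to_numpy() > 0
    src = num.to_numpy(dtype=float) if (thr is not None and num is not None) else wv
    numerator = float(src[av].sum())
    denominator = float(wv.sum())
    if include_intra:
        numerator += float(np.diag(src).sum())
        # diagonal is already inside wv.sum(); nothing to add to the denominator
    else:
        denominator -= float(np.diag(wv).sum())
        numerator -= float(src[av & np.eye(len(wv), dtype=bool)].sum())
    if denominator == 0:
        return math.nan
    # rounding in the two sums can push the ratio one ulp past the bound
    return float(min(max(numerator / denominator, 0.0), 1.0))


def rscf(w: ConnectivityMatrix | pd.DataFrame, a: pd.DataFrame) -> pd.Series:
    """Per-region short-range fraction; NaN for regions with zero strength."""
    mat, num, include_intra, thr = _aligned(w, a)
    wv = mat.to_numpy(dtype=float)
    av = a.to_numpy() > 0
    src = num.to_numpy(dtype=float) if (thr is not None and num is not None) else wv
    diag = np.diag(wv).copy()
    sdiag = np.diag(src).copy()
    numerator = (src * av).sum(axis=1)
    denominator = wv.sum(axis=1)
    if include_intra:
        numerator = numerator + sdiag
    else:
        denominator = denominator - diag
        numerator = numerator - np.where(np.diag(av), sdiag, 0.0)
    out = np.where(denominator > 0, numerator / np.where(denominator > 0, denominator, 1.0), np.nan)
    return pd.Series(np.clip(out, 0.0, 1.0), index=mat.index)


def scf_result(w: ConnectivityMatrix | pd.DataFrame, a: pd.DataFrame) -> SCFResult:
    r = rscf(w, a)
    include_intra = w.include_intra if isinstance(w, ConnectivityMatrix) else False
    thr = w.length_threshold_mm if isinstance(w, ConnectivityMatrix) else None
    return SCFResult(
        gscf=gscf(w, a),
        rscf=r,
        undefined_regions=[int(i) for i in r.index[r.isna()]],
        include_intra=include_intra,
        length_threshold_mm=thr,
    )


def relative_difference(scf_low: float, scf_high: float) -> float:
    """Percent change of the low-resolution value relative to the high one.

    ``100 * (low - high) / high``; negative means the lower resolution
    underestimates the fraction.  NaN when the reference is 0 or either
    value is undefined.
    """
    if not np.isfinite(scf_low) or not np.isfinite(scf_high) or scf_high == 0:
        return math.nan
    return 100.0 * (scf_low - scf_high) / scf_high


@dataclass
class GroupAtlas:
    """Group-level RSCF summary across subjects sharing a region table."""

    mean: pd.Series
    sd: pd.Series
    n_defined: pd.Series
    n_undefined: pd.Series
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray


def group_rscf_atlas(results: list[SCFResult], bin_edges=None) -> GroupAtlas:
    """Per-region mean/sd of RSCF over subjects with defined values.

    Undefined (NaN) values are excluded per region and counted.  The
    histogram pools the per-region group means.
    """
    if not results:
        raise ValueError("no subjects")
    index = results[0].rscf.index
    for r in results[1:]:
        if list(r.rscf.index) != list(index):
            raise ValueError("subjects do not share a region table")
    stacked = pd.concat([r.rscf for r in results], axis=1)
    mean = stacked.mean(axis=1, skipna=True)
    sd = stacked.std(axis=1, ddof=1, skipna=True)
    n_defined = stacked.notna().sum(axis=1)
    if bin_edges is None:
        bin_edges = np.linspace(0.0, 1.0, 21)
    counts, edges = np.histogram(mean.dropna().to_numpy(), bins=bin_edges)
    return GroupAtlas(
        mean=mean,
        sd=sd,
        n_defined=n_defined,
        n_undefined=len(results) - n_defined,
        histogram_counts=counts,
        histogram_edges=np.asarray(edges),
    )
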