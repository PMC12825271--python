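"""Streamline-to-parcellation assignment and connectivity matrix construction.

The connectivity matrix W counts streamlines (or sums per-streamline
weights) between cortical region pairs, restricted to association fibers:
only same-hemisphere pairs contribute, and intra-regional connections are
excluded by default.  Cross-hemisphere ("commissural-like") streamlines and
streamlines with unassignable endpoints are dropped and counted in a report.
A length-restricted variant accumulates a companion short-range numerator
holding only contributions from streamlines at or below a length threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .adjacency import Parcellation


@dataclass
class Tractogram:
    """Streamlines (ordered 3D points in world mm) with per-streamline weights."""

    streamlines: list[np.ndarray]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float).reshape(-1, 3) for s in self.streamlines]
        for k, s in enumerate(self.streamlines):
            if not np.isfinite(s).all():
                raise ValueError(f"streamline {k} has non-finite coordinates")
        if self.weights is None:
            self.weights = np.ones(len(self.streamlines))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.streamlines):
                raise ValueError(
                    f"{len(self.weights)} weights for {len(self.streamlines)} streamlines"
                )
            if (self.weights <= 0).any():
                raise ValueError("weights must be positive")

    def __len__(self) -> int:
        return len(self.streamlines)


def streamline_length(streamline: np.ndarray) -> float:
    """Polyline length in mm: sum of Euclidean segment lengths."""
    pts = np.asarray(streamline, dtype=float).reshape(-1, 3)
    if len(pts) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def assign_endpoints(
    tractogram: Tractogram,
    parcellation: Parcellation,
    search_radius_mm: float = 2.0,
) -> list[tuple[int, int] | None]:
    """Map each streamline's first/last point to a region id, or None.

    An endpoint takes the label of its containing voxel; endpoints in
    background (or just outside the grid) fall back to the nearest labeled
    voxel center within ``search_radius_mm`` (Euclidean; ties broken by the
    lowest region id).  A streamline with any unresolvable endpoint is
    returned as None (unassigned).
    """
    parcellation.validate_labels()
    grid = parcellation.label_grid
    voxel = np.asarray(parcellation.voxel_size_mm)
    origin = np.asarray(parcellation.origin_mm)
    shape = np.asarray(grid.shape)

    def _one(point: np.ndarray) -> int | None:
        idx_f = (point - origin) / voxel
        idx = np.round(idx_f).astype(int)
        if (idx >= 0).all() and (idx < shape).all():
            label = int(grid[tuple(idx)])
            if label > 0:
                return label
        # nearest labeled voxel center within the search radius
        reach = np.ceil(search_radius_mm / voxel).astype(int) + 1
        lo = np.maximum(idx - reach, 0)
        hi = np.minimum(idx + reach + 1, shape)
        if (lo >= hi).any():
            return None
        sub = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        labeled = np.argwhere(sub > 0)
        if len(labeled) == 0:
            return None
        centers = (labeled + lo) * voxel + origin
        d = np.linalg.norm(centers - point, axis=1)
        within = d <= search_radius_mm
        if not within.any():
            return None
        labels = sub[tuple(labeled[within].T)]
        dmin = d[within].min()
        best = labels[np.abs(d[within] - dmin) < 1e-9]
        return int(best.min())

    out: list[tuple[int, int] | None] = []
    for s in tractogram.streamlines:
        a = _one(s[0])
        b = _one(s[-1])
        out.append(None if a is None or b is None else (a, b))
    return out


@dataclass
class ConnectivityMatrix:
    """Symmetric association-fiber strength matrix aligned to a region table.

    ``w`` holds the full strength; ``saf_numerator`` (populated when a
    length threshold is set) holds only strength from streamlines at or
    below ``length_threshold_mm`` and is used as the short-range numerator.
    """

    w: pd.DataFrame
    include_intra: bool = False
    length_threshold_mm: float | None = None
    saf_numerator: pd.DataFrame | None = None
    drop_report: dict = field(default_factory=dict)


def build_connectivity(
    assignments: list[tuple[int, int] | None],
    lengths: np.ndarray,
    weights: np.ndarray,
    regions: pd.DataFrame,
    include_intra: bool = False,
    length_threshold_mm: float | None = None,
) -> ConnectivityMatrix:
    """Accumulate streamline contributions into the connectivity matrix W.

    A streamline contributes its weight to ``w[i, j]`` and ``w[j, i]`` iff
    its endpoints fall in the same hemisphere and in distinct regions
    (intra-regional strength goes once to the diagonal when
    ``include_intra``).  Cross-hemisphere and unassigned streamlines are
    dropped and tallied.  With unit weights the entries are streamline
    counts (NOS).
    """
    ids = regions["id"].to_numpy()
    hemi = dict(zip(regions["id"], regions["hemisphere"]))
    idx = {int(i): k for k, i in enumerate(ids)}
    n = len(ids)
    w = np.zeros((n, n))
    num = np.zeros((n, n)) if length_threshold_mm is not None else None
    report = {"unassigned": 0, "cross_hemisphere": 0, "intra_excluded": 0, "retained": 0}
    lengths = np.asarray(lengths, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if not (len(assignments) == len(lengths) == len(weights)):
        raise ValueError("assignments, lengths and weights must be aligned")

    for pair, length, weight in zip(assignments, lengths, weights):
        if pair is None:
            report["unassigned"] += 1
            continue
        i, j = pair
        if i not in idx or j not in idx:
            raise ValueError(f"region id {i if i not in idx else j} absent from region table")
        if hemi[i] != hemi[j]:
            report["cross_hemisphere"] += 1
            continue
        if i == j:
            if not include_intra:
                report["intra_excluded"] += 1
                continue
            w[idx[i], idx[i]] += weight
            if num is not None and length <= length_threshold_mm:
                num[idx[i], idx[i]] += weight
        else:
            w[idx[i], idx[j]] += weight
            w[idx[j], idx[i]] += weight
            if num is not None and length <= length_threshold_mm:
                num[idx[i], idx[j]] += weight
                num[idx[j], idx[i]] += weight
        report["retained"] += 1

    return ConnectivityMatrix(
        w=pd.DataFrame(w, index=ids, columns=ids),
        include_intra=include_intra,
        length_threshold_mm=length_threshold_mm,
        saf_numerator=None if num is None else pd.DataFrame(num, index=ids, columns=ids),
        drop_report=report,
    )


def connectivity_from_tractogram(
    tractogram: Tractogram,
    parcellation: Parcellation,
    search_radius_mm: float = 2.0,
    include_intra: bool = False,
    length_threshold_mm: float | None = None,
) -> ConnectivityMatrix:
    """Convenience: assign endpoints, measure lengths, build W in one call."""
    assignments = assign_endpoints(tractogram, parcellation, search_radius_mm)
    lengths = np.array([streamline_length(s) for s in tractogram.streamlines])
    return build_connectivity(
        assignments,
        lengths,
        tractogram.weights,
        parcellation.regions,
        include_intra=include_intra,
        length_threshold_mm=length_threshold_mm,
    )


def write_tractogram_tck(tractogram: Tractogram, path, weights_path=None) -> None:
    """Write streamlines as an MRtrix TCK file (points in world/RAS mm).

    Weights, when requested, go to a plain-text file with one value per
    line (tcksift2 convention).
    """
    sl = [s.astype(np.float32) for s in tractogram.streamlines]
    nib.streamlines.save(
        nib.streamlines.Tractogram(sl, affine_to_rasmm=np.eye(4)), str(path)
    )
    if weights_path is not None:
        with open(weights_path, "w") as fh:
            for w in tractogram.weights:
                fh.write(f"{w:.9g}\n")


def read_tractogram_tck(path, weights_path=None) -> Tractogram:
    """Read an MRtrix TCK file (and optional per-streamline weights file)."""
    tck = nib.streamlines.load(str(path))
    streamlines = [np.asarray(s, dtype=float) for s in tck.streamlines]
    weights = None
    if weights_path is not None:
        with open(weights_path) as fh:
            weights = np.array([float(line) for line in fh if line.strip()])
        if len(weights) != len(streamlines):
            raise ValueError(
                f"weights file has {len(weights)} values for {len(streamlines)} streamlines"
            )
    return Tractogram(streamlines, weights)
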