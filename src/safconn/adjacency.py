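"""Cortical region adjacency ("borders-on") from labeled parcellations.

Two regions border each other when their labels share voxel faces
(6-connectivity).  Adjacency feeds the short-range/long-range split of the
connectivity matrix: strength between bordering regions is attributed to
short-range association fibers (U-fibers), everything else to long-range
association fibers.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

REGION_COLUMNS = ("id", "name", "hemisphere")


@dataclass
class Parcellation:
    """Integer label grid plus a region table (id, name, hemisphere).

    Label 0 is background.  Regions live on the same physical voxel lattice
    as :class:`~safconn.resolution.Volume` (voxel-center alignment).
    """

    label_grid: np.ndarray
    regions: pd.DataFrame
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.label_grid = np.asarray(self.label_grid)
        if self.label_grid.ndim != 3:
            raise ValueError("label grid must be 3D")
        if not np.issubdtype(self.label_grid.dtype, np.integer):
            raise ValueError("label grid must be integer-typed")
        missing = [c for c in REGION_COLUMNS if c not in self.regions.columns]
        if missing:
            raise ValueError(f"region table missing columns: {missing}")
        ids = self.regions["id"].to_numpy()
        if (ids <= 0).any() or len(set(ids)) != len(ids):
            raise ValueError("region ids must be unique positive integers")
        bad_hemi = set(self.regions["hemisphere"]) - {"L", "R"}
        if bad_hemi:
            raise ValueError(f"hemisphere must be 'L' or 'R', got {bad_hemi}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def region_ids(self) -> np.ndarray:
        return self.regions["id"].to_numpy()

    def hemisphere_of(self) -> dict[int, str]:
        return dict(zip(self.regions["id"], self.regions["hemisphere"]))

    def validate_labels(self) -> None:
        present = set(np.unique(self.label_grid)) - {0}
        unknown = sorted(present - set(self.region_ids.tolist()))
        if unknown:
            raise ValueError(f"labels present in grid but absent from region table: {unknown}")

    def save(self, nifti_path, table_path) -> None:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size_mm)
        aff[:3, 3] = self.origin_mm
        nib.save(nib.Nifti1Image(self.label_grid.astype(np.int32), aff), str(nifti_path))
        self.regions.to_csv(table_path, sep="\t", index=False)

    @classmethod
    def load(cls, nifti_path, table_path) -> "Parcellation":
        img = nib.load(str(nifti_path))
        grid = np.asarray(img.dataobj).astype(np.int64)
        voxel = tuple(float(v) for v in np.abs(np.diag(img.affine)[:3]))
        origin = tuple(float(v) for v in img.affine[:3, 3])
        regions = pd.read_csv(table_path, sep="\t")
        return cls(grid, regions, voxel, origin)


def shared_face_counts(label_grid: np.ndarray) -> dict[tuple[int, int], int]:
    """Count 6-connected voxel face contacts between distinct nonzero labels.

    Returns a map from label pair ``(i, j)`` with ``i < j`` to the number of
    shared faces.
    """
    grid = np.asarray(label_grid)
    counts: dict[tuple[int, int], int] = {}
    for axis in range(3):
        a = np.moveaxis(grid, axis, 0)[:-1].ravel()
        b = np.moveaxis(grid, axis, 0)[1:].ravel()
        sel = (a != b) & (a > 0) & (b > 0)
        if not sel.any():
            continue
        lo = np.minimum(a[sel], b[sel])
        hi = np.maximum(a[sel], b[sel])
        pairs, n = np.unique(np.stack([lo, hi], axis=1), axis=0, return_counts=True)
        for (i, j), c in zip(pairs, n):
            key = (int(i), int(j))
            counts[key] = counts.get(key, 0) + int(c)
    return counts


def adjacency_from_labels(
    parcellation: Parcellation,
    min_shared_faces: int = 1,
    within_hemisphere_only: bool = True,
) -> pd.DataFrame:
    """Binary borders-on matrix A aligned to the region table order.

    ``A(i, j) = 1`` iff regions i and j share at least ``min_shared_faces``
    voxel faces (and lie in the same hemisphere unless
    ``within_hemisphere_only`` is False).  Symmetric, zero diagonal.
    """
    parcellation.validate_labels()
    ids = parcellation.region_ids
    hemi = parcellation.hemisphere_of()
    idx = {int(i): k for k, i in enumerate(ids)}
    n = len(ids)
    a = np.zeros((n, n), dtype=int)
    for (i, j), c in shared_face_counts(parcellation.label_grid).items():
        if c < min_shared_faces:
            continue
        if within_hemisphere_only and hemi[i] != hemi[j]:
            continue
        a[idx[i], idx[j]] = 1
        a[idx[j], idx[i]] = 1
    return pd.DataFrame(a, index=ids, columns=ids)


def validate_adjacency(a: pd.DataFrame, regions: pd.DataFrame) -> dict:
    """Check adjacency invariants; return per-hemisphere bordering-pair counts.

    Raises on asymmetry, non-binary entries, a nonzero diagonal, or
    misaligned region ids, naming the first offending pair.
    """
    mat = a.to_numpy()
    ids = list(a.index)
    if ids != list(regions["id"]):
        raise ValueError("adjacency index does not match region table ids")
    if not np.isin(mat, (0, 1)).all():
        bad = np.argwhere(~np.isin(mat, (0, 1)))[0]
        raise ValueError(f"non-binary adjacency entry at ({ids[bad[0]]}, {ids[bad[1]]})")
    if np.diag(mat).any():
        k = int(np.flatnonzero(np.diag(mat))[0])
        raise ValueError(f"nonzero diagonal at region {ids[k]}")
    if (mat != mat.T).any():
        bad = np.argwhere(mat != mat.T)[0]
        raise ValueError(f"asymmetric adjacency at ({ids[bad[0]]}, {ids[bad[1]]})")
    hemi = dict(zip(regions["id"], regions["hemisphere"]))
    counts = {"L": 0, "R": 0}
    cross = 0
    for p in range(len(ids)):
        for q in range(p + 1, len(ids)):
            if mat[p, q]:
                if hemi[ids[p]] == hemi[ids[q]]:
                    counts[hemi[ids[p]]] += 1
                else:
                    cross += 1
    return {
        "n_regions": len(ids),
        "pairs_per_hemisphere": counts,
        "cross_hemisphere_pairs": cross,
        "within_hemisphere_only": cross == 0,
    }


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a region-by-region matrix stored as TSV with id header row/column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(int)
    df.columns = df.columns.astype(int)
    return df


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")
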