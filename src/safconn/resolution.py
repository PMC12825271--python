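"""Retrospective resolution manipulation and image-level summaries.

Lowering the spatial resolution of an acquired MRI volume is emulated by
truncating its centered discrete Fourier spectrum to the target matrix size
and applying a mild apodization (Tukey taper) to suppress Gibbs ringing.
Re-upsampling uses polynomial spline interpolation under a voxel-center
alignment convention.  Temporal SNR of a repeated b=0 series and masked
means of scalar maps are the image-quality summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class Volume:
    """A 3D or 4D image grid on a physical, axis-aligned voxel lattice.

    World coordinates follow voxel-center alignment:
    ``world_mm = origin_mm + index * voxel_size_mm`` (0-based indices).
    The 4th axis, when present, indexes repetitions/volumes.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"volume must be 3D or 4D, got {self.data.ndim}D")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be 3 positive values, got {self.voxel_size_mm}")
        self.voxel_size_mm = vs
        self.origin_mm = tuple(float(v) for v in self.origin_mm)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float64), self.affine())
        img.header.set_zooms(self.voxel_size_mm + ((1.0,) if self.data.ndim == 4 else ()))
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "Volume":
        img = nib.load(str(path))
        aff = img.affine
        voxel = tuple(float(v) for v in np.abs(np.diag(aff)[:3]))
        origin = tuple(float(v) for v in aff[:3, 3])
        return cls(np.asarray(img.dataobj), voxel, origin)


def _taper_gains(m: int, taper_fraction: float) -> np.ndarray:
    """Per-coefficient gain for one axis of the retained (fftshifted) band.

    Unit gain for |k| <= (1 - taper_fraction) * m/2; raised-cosine roll-off
    from there to the band edge.  Index ``m // 2`` is DC, whose gain is
    exactly 1 for any taper_fraction < 1.
    """
    if not 0.0 <= taper_fraction <= 1.0:
        raise ValueError(f"taper_fraction must be in [0, 1], got {taper_fraction}")
    k = np.abs(np.arange(m) - m // 2).astype(float)
    edge = m / 2.0
    flat = (1.0 - taper_fraction) * edge
    g = np.ones(m)
    if taper_fraction > 0:
        roll = k > flat
        width = edge - flat
        g[roll] = 0.5 * (1.0 + np.cos(np.pi * (k[roll] - flat) / width))
    return g


def downsample_kspace(volume: Volume, target_shape, taper_fraction: float = 0.2) -> Volume:
    """Lower spatial resolution by centered k-space truncation with apodization.

    Fourier coefficients outside the centered ``target_shape`` window are
    discarded; retained coefficients are multiplied by a separable symmetric
    taper with unit gain over the central ``1 - taper_fraction`` band of each
    axis.  The normalization preserves the image mean (DC coefficient)
    exactly, so intensity scale is invariant under down-sampling.  Voxel size
    grows by ``source_shape / target_shape`` per axis.  4D inputs are
    processed volume-by-volume.
    """
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != 3:
        raise ValueError("target_shape must have 3 entries")
    src = volume.spatial_shape
    for ax, (t, s) in enumerate(zip(target_shape, src)):
        if t <= 0:
            raise ValueError(f"target_shape axis {ax} must be positive, got {t}")
        if t > s:
            raise ValueError(
                f"target_shape axis {ax} ({t}) exceeds source shape ({s})"
            )

    def _one(vol3d: np.ndarray) -> np.ndarray:
        spec = np.fft.fftshift(np.fft.fftn(vol3d))
        # crop the centered window so DC (index s//2) maps to index t//2
        slices = tuple(
            slice(s // 2 - t // 2, s // 2 - t // 2 + t) for s, t in zip(src, target_shape)
        )
        spec = spec[slices].copy()
        for ax, (t, s) in enumerate(zip(target_shape, src)):
            gains = _taper_gains(t, taper_fraction)
            if t < s and t % 2 == 0:
                # the retained unpaired Nyquist coefficient would break
                # conjugate symmetry; drop it
                gains = gains.copy()
                gains[0] = 0.0
            shape = [1, 1, 1]
            shape[ax] = t
            spec *= gains.reshape(shape)
        scale = np.prod([t / s for t, s in zip(target_shape, src)])
        out = np.fft.ifftn(np.fft.ifftshift(spec * scale))
        mag = np.max(np.abs(out))
        if mag > 0 and np.max(np.abs(out.imag)) > 1e-10 * mag:
            raise AssertionError("inverse transform not real within tolerance")
        return out.real

    if volume.data.ndim == 4:
        out = np.stack([_one(volume.data[..., i]) for i in range(volume.data.shape[3])], axis=-1)
    else:
        out = _one(volume.data)
    voxel = tuple(v * s / t for v, s, t in zip(volume.voxel_size_mm, src, target_shape))
    return Volume(out, voxel, volume.origin_mm)


def upsample_spline(
    volume: Volume,
    target_shape=None,
    target_voxel_size_mm=None,
    spline_order: int = 3,
    boundary: str = "mirror",
) -> Volume:
    """Resample onto a finer grid with polynomial spline interpolation.

    New voxel centers are placed under the same voxel-center alignment
    convention (shared origin); boundary handling is mirror reflection by
    default (``boundary="wrap"`` selects periodic handling, appropriate
    after Fourier-domain down-sampling, whose implied signal is periodic).
    Constant volumes are preserved exactly; a spline of order ``p``
    reproduces polynomials of degree ``p`` away from the boundary.
    """
    if not 0 <= spline_order <= 5:
        raise ValueError(f"spline_order must be in [0, 5], got {spline_order}")
    modes = {"mirror": "mirror", "wrap": "grid-wrap"}
    if boundary not in modes:
        raise ValueError(f"boundary must be one of {sorted(modes)}, got {boundary!r}")
    src = volume.spatial_shape
    if target_shape is None:
        if target_voxel_size_mm is None:
            raise ValueError("provide target_shape or target_voxel_size_mm")
        tvs = np.broadcast_to(np.asarray(target_voxel_size_mm, dtype=float), (3,))
        target_shape = tuple(
            int(round(s * v / t)) for s, v, t in zip(src, volume.voxel_size_mm, tvs)
        )
    target_shape = tuple(int(t) for t in target_shape)
    for ax, (t, s) in enumerate(zip(target_shape, src)):
        if t < s:
            raise ValueError(f"target axis {ax} ({t}) coarser than source ({s})")
    voxel = tuple(v * s / t for v, s, t in zip(volume.voxel_size_mm, src, target_shape))

    # output index j sits at input index coordinate j * v_out / v_in
    coords = np.meshgrid(
        *[np.arange(t) * (vo / vi) for t, vo, vi in zip(target_shape, voxel, volume.voxel_size_mm)],
        indexing="ij",
    )
    coords = np.stack(coords)

    def _one(vol3d: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(
            np.asarray(vol3d, dtype=float), coords, order=spline_order, mode=modes[boundary]
        )

    if volume.data.ndim == 4:
        out = np.stack([_one(volume.data[..., i]) for i in range(volume.data.shape[3])], axis=-1)
    else:
        out = _one(volume.data)
    return Volume(out, voxel, volume.origin_mm)


@dataclass
class TsnrResult:
    """Temporal SNR summary: mask-averaged scalar plus per-voxel map."""

    scalar: float
    map: np.ndarray
    n_voxels_used: int
    n_zero_sd_excluded: int


def tsnr(series: Volume, mask: np.ndarray) -> TsnrResult:
    """Temporal signal-to-noise ratio of a repeated (e.g. b=0) series.

    Per voxel: temporal mean over temporal standard deviation (sample sd,
    n-1 denominator).  The scalar is the arithmetic mean of per-voxel tSNR
    over mask voxels with nonzero sd; zero-sd voxels are excluded and
    counted.
    """
    data = series.data
    if data.ndim != 4 or data.shape[3] < 2:
        raise ValueError("series must be 4D with at least 2 volumes")
    mask = np.asarray(mask) > 0
    if mask.shape != data.shape[:3]:
        raise ValueError(f"mask shape {mask.shape} does not match grid {data.shape[:3]}")
    if not mask.any():
        raise ValueError("empty mask")
    mean = data.mean(axis=3)
    sd = data.std(axis=3, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tmap = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.nan)
    ok = mask & (sd > 0)
    n_excluded = int(mask.sum() - ok.sum())
    if not ok.any():
        raise ValueError(
            "all mask voxels have zero temporal standard deviation; tSNR undefined"
        )
    return TsnrResult(
        scalar=float(tmap[ok].mean()),
        map=tmap,
        n_voxels_used=int(ok.sum()),
        n_zero_sd_excluded=n_excluded,
    )


def masked_mean(map3d: Volume | np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of a scalar map over mask>0 voxels."""
    data = map3d.data if isinstance(map3d, Volume) else np.asarray(map3d)
    mask = np.asarray(mask) > 0
    if mask.shape != data.shape:
        raise ValueError(f"mask shape {mask.shape} does not match map {data.shape}")
    if not mask.any():
        raise ValueError("empty mask")
    return float(data[mask].mean())
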