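"""Synthetic inputs with analytically known ground truth.

Every input the pipeline consumes can be generated here without any MRI
acquisition:

* a "cortical ribbon" parcellation — an annulus in a central axial slab,
  split into angular wedges per hemisphere, whose borders-on adjacency is a
  known chain (wedge k borders wedge k±1 within its hemisphere);
* tractograms mixing short-range U-fibers between adjacent wedges and
  long-range fibers between non-adjacent wedges, with known endpoint
  labels, so the downstream short-range connectivity fraction is known by
  construction;
* multi-subject multi-resolution connectome ensembles in which adjacent-
  pair counts are attenuated per condition by a known factor around shared
  (paired) lognormal subject effects;
* band-limited cosine phantoms for the k-space down-sampler; and
* noisy b=0 series for the temporal-SNR summary.

All generators are pure functions of their seed: identical inputs produce
bit-identical outputs.  Child random streams are derived deterministically
per subject/condition so partial re-runs reproduce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adjacency import Parcellation
from .connectome import Tractogram


# ---------------------------------------------------------------------------
# ribbon parcellation

def make_ribbon_parcellation(
    n_regions_per_hemisphere: int = 5,
    grid_shape=(40, 40, 40),
    voxel_size_mm=(1.0, 1.0, 1.0),
    inner_radius_mm: float = 8.0,
    outer_radius_mm: float = 14.0,
    midline_gap_mm: float = 2.0,
    slab_thickness_vox: int = 5,
) -> tuple[Parcellation, pd.DataFrame]:
    """Annular two-hemisphere wedge parcellation with known chain adjacency.

    The ribbon occupies ``inner_radius < rho < outer_radius`` (in-plane
    distance from the grid center) within a central axial slab.  Voxels
    with x below the mid-plane minus half the gap belong to hemisphere L,
    above plus half the gap to R; the gap guarantees no L-R face contact.
    Each half-annulus is split into ``n`` angular wedges; consecutive
    wedges share a radial boundary, so the true adjacency is a chain (not
    cyclic) per hemisphere.

    Returns the parcellation and its analytic adjacency matrix (region-id
    indexed DataFrame).
    """
    n = int(n_regions_per_hemisphere)
    if n < 2:
        raise ValueError("need at least 2 regions per hemisphere")
    if not (outer_radius_mm > inner_radius_mm > 0):
        raise ValueError("need outer_radius > inner_radius > 0")
    grid_shape = tuple(int(g) for g in grid_shape)
    voxel = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    center = (np.asarray(grid_shape) - 1) / 2.0 * voxel

    ii, jj, kk = np.meshgrid(*[np.arange(g) for g in grid_shape], indexing="ij")
    x = ii * voxel[0] - center[0]
    y = jj * voxel[1] - center[1]
    z = kk - (grid_shape[2] - 1) / 2.0  # slab is counted in voxels
    rho = np.hypot(x, y)
    in_slab = np.abs(z) <= slab_thickness_vox / 2.0
    in_ring = (rho > inner_radius_mm) & (rho < outer_radius_mm)
    left = x < -midline_gap_mm / 2.0
    right = x > midline_gap_mm / 2.0

    theta = np.arctan2(y, x)  # (-pi, pi]
    labels = np.zeros(grid_shape, dtype=np.int32)

    # left half-annulus spans theta in (pi/2, 3pi/2); wrap negatives up
    theta_l = np.where(theta < 0, theta + 2 * np.pi, theta)
    frac_l = (theta_l - np.pi / 2) / np.pi
    wedge_l = np.clip(np.floor(frac_l * n), 0, n - 1).astype(int)
    sel_l = in_slab & in_ring & left
    labels[sel_l] = 1 + wedge_l[sel_l]

    # right half-annulus spans theta in (-pi/2, pi/2)
    frac_r = (theta + np.pi / 2) / np.pi
    wedge_r = np.clip(np.floor(frac_r * n), 0, n - 1).astype(int)
    sel_r = in_slab & in_ring & right
    labels[sel_r] = n + 1 + wedge_r[sel_r]

    ids, names, hemis = [], [], []
    for h, base in (("L", 0), ("R", n)):
        for k in range(n):
            ids.append(base + k + 1)
            names.append(f"wedge{k + 1:02d}")
            hemis.append(h)
    regions = pd.DataFrame({"id": ids, "name": names, "hemisphere": hemis})

    present = set(np.unique(labels)) - {0}
    for rid, name, hemi in zip(ids, names, hemis):
        if rid not in present:
            raise ValueError(f"geometry produced an empty region: {hemi} {name} (id {rid})")

    parc = Parcellation(labels, regions, tuple(voxel), (0.0, 0.0, 0.0))
    adj = np.zeros((2 * n, 2 * n), dtype=int)
    for base in (0, n):
        for k in range(n - 1):
            adj[base + k, base + k + 1] = adj[base + k + 1, base + k] = 1
    true_adjacency = pd.DataFrame(adj, index=ids, columns=ids)
    return parc, true_adjacency


# ---------------------------------------------------------------------------
# tractograms

def _interior_point(parc: Parcellation, region_id: int, rng: np.random.Generator,
                    jitter_mm: float) -> np.ndarray:
    """A world point strictly inside the region: an interior-ish voxel center
    plus jitter bounded to stay within that voxel."""
    vox = np.argwhere(parc.label_grid == region_id)
    if len(vox) == 0:
        raise ValueError(f"region {region_id} is empty")
    choice = vox[rng.integers(len(vox))]
    voxel = np.asarray(parc.voxel_size_mm)
    jitter = rng.uniform(-1, 1, 3) * min(jitter_mm, 0.4 * voxel.min())
    return choice * voxel + np.asarray(parc.origin_mm) + jitter


def _bezier_arc(p0: np.ndarray, p1: np.ndarray, control: np.ndarray,
                point_spacing_mm: float) -> np.ndarray:
    """Quadratic Bezier discretized at roughly the requested point spacing."""
    # chord-based estimate, refined once on a coarse evaluation
    t = np.linspace(0, 1, 33)[:, None]
    coarse = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * control + t**2 * p1
    arc = float(np.linalg.norm(np.diff(coarse, axis=0), axis=1).sum())
    n_pts = max(3, int(math.ceil(arc / point_spacing_mm)) + 1)
    t = np.linspace(0, 1, n_pts)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * control + t**2 * p1


def make_tractogram(
    parcellation: Parcellation,
    true_adjacency: pd.DataFrame,
    short_pair_counts: dict[tuple[int, int], int] | None = None,
    long_pair_counts: dict[tuple[int, int], int] | None = None,
    weight_mode: str = "unit",
    point_spacing_mm: float = 1.0,
    jitter_mm: float = 0.3,
    u_depth_mm: float = 3.0,
    seed: int = 0,
) -> tuple[Tractogram, list[tuple[int, int]]]:
    """Streamlines with known endpoint regions on a ribbon parcellation.

    Short streamlines (between adjacent wedges) are quadratic Bezier arcs
    whose control point is pulled radially inward below the ribbon inner
    surface, giving the classic U-shape of a short-range association
    fiber.  Long streamlines (between non-adjacent same-hemisphere wedges)
    route deep through the annulus interior.  Endpoints lie strictly inside
    their labeled regions, so endpoint assignment recovers the ground
    truth exactly.
    """
    short_pair_counts = short_pair_counts or {}
    long_pair_counts = long_pair_counts or {}
    hemi = parcellation.hemisphere_of()
    adj = true_adjacency

    for (i, j), c in {**short_pair_counts, **long_pair_counts}.items():
        if c < 0:
            raise ValueError(f"negative count for pair ({i}, {j})")
        if hemi[i] != hemi[j]:
            raise ValueError(f"pair ({i}, {j}) spans hemispheres")
    for (i, j) in short_pair_counts:
        if not adj.loc[i, j]:
            raise ValueError(f"short pair ({i}, {j}) is not adjacent")

    rng = np.random.default_rng(seed)
    center = (np.asarray(parcellation.label_grid.shape) - 1) / 2.0 * np.asarray(
        parcellation.voxel_size_mm
    )
    # infer the ribbon inner radius from the labeled voxels themselves
    labeled = np.argwhere(parcellation.label_grid > 0) * np.asarray(parcellation.voxel_size_mm)
    inner_r = float(np.hypot(*(labeled - center)[:, :2].T).min())

    def _control(p0, p1, dip_radius):
        # the curve's deepest point is (mid + control)/2, so place the
        # control twice as deep as the requested dip radius
        mid = (p0 + p1) / 2.0
        radial = mid[:2] - center[:2]
        norm = np.linalg.norm(radial)
        if norm == 0:
            return mid
        target_r = max(2.0 * dip_radius - norm, 0.5)
        ctrl = mid.copy()
        ctrl[:2] = center[:2] + radial / norm * target_r
        return ctrl

    streamlines: list[np.ndarray] = []
    labels: list[tuple[int, int]] = []
    for (i, j), count in sorted(short_pair_counts.items()):
        for _ in range(count):
            p0 = _interior_point(parcellation, i, rng, jitter_mm)
            p1 = _interior_point(parcellation, j, rng, jitter_mm)
            ctrl = _control(p0, p1, inner_r - u_depth_mm)
            streamlines.append(_bezier_arc(p0, p1, ctrl, point_spacing_mm))
            labels.append((i, j))
    for (i, j), count in sorted(long_pair_counts.items()):
        for _ in range(count):
            p0 = _interior_point(parcellation, i, rng, jitter_mm)
            p1 = _interior_point(parcellation, j, rng, jitter_mm)
            ctrl = _control(p0, p1, inner_r * 0.4)  # deep interior route
            streamlines.append(_bezier_arc(p0, p1, ctrl, point_spacing_mm))
            labels.append((i, j))

    if weight_mode == "unit":
        weights = np.ones(len(streamlines))
    elif weight_mode == "lognormal":
        weights = rng.lognormal(mean=0.0, sigma=0.3, size=len(streamlines))
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    return Tractogram(streamlines, weights), labels


# ---------------------------------------------------------------------------
# connectome ensembles

def chain_regions(n_per_hemisphere: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Region table and chain adjacency matching the ribbon construction."""
    n = int(n_per_hemisphere)
    ids, names, hemis = [], [], []
    for h, base in (("L", 0), ("R", n)):
        for k in range(n):
            ids.append(base + k + 1)
            names.append(f"wedge{k + 1:02d}")
            hemis.append(h)
    regions = pd.DataFrame({"id": ids, "name": names, "hemisphere": hemis})
    adj = np.zeros((2 * n, 2 * n), dtype=int)
    for base in (0, n):
        for k in range(n - 1):
            adj[base + k, base + k + 1] = adj[base + k + 1, base + k] = 1
    return regions, pd.DataFrame(adj, index=ids, columns=ids)


@dataclass
class CohortSpec:
    """Conditions of a paired multi-resolution connectome simulation.

    ``attenuation`` maps each condition label to the factor applied to the
    expected adjacent-pair (short-range) count; the reference condition has
    factor 1.  Subject effects are multiplicative lognormal
    (``exp(N(0, subject_effect_sd^2))``) and shared across all conditions
    of a subject, producing the paired within-subject design.
    """

    n_subjects: int = 20
    n_regions_per_hemisphere: int = 5
    resolutions: tuple[str, ...] = ("hi", "lo")
    attenuation: dict = field(default_factory=lambda: {"hi": 1.0, "lo": 0.8})
    mean_short_count: float = 200.0
    mean_long_count: float = 100.0
    subject_effect_sd: float = 0.1
    noise_model: str = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_regions_per_hemisphere < 2:
            raise ValueError("need n_subjects >= 1 and >= 2 regions per hemisphere")
        missing = [r for r in self.resolutions if r not in self.attenuation]
        if missing:
            raise ValueError(f"conditions missing from attenuation map: {missing}")
        bad = {r: a for r, a in self.attenuation.items() if not 0 < a <= 1}
        if bad:
            raise ValueError(f"attenuation factors must be in (0, 1]: {bad}")
        if self.mean_short_count <= 0 or self.mean_long_count < 0:
            raise ValueError("mean_short_count must be > 0, mean_long_count >= 0")
        if self.subject_effect_sd < 0:
            raise ValueError("subject_effect_sd must be >= 0")
        if self.noise_model not in ("poisson", "none"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


@dataclass
class GroundTruth:
    """Analytic expectations for a simulated cohort."""

    expected_gscf: dict[str, float]
    true_adjacency: pd.DataFrame
    regions: pd.DataFrame
    s0: float  # total expected short-range strength at reference
    l0: float  # total expected long-range strength

    def expected_relative_difference_pct(self, low: str, high: str,
                                         attenuation: dict) -> float:
        g = lambda a: a * self.s0 / (a * self.s0 + self.l0)
        gl, gh = g(attenuation[low]), g(attenuation[high])
        return 100.0 * (gl - gh) / gh


def make_connectome_ensemble(
    spec: CohortSpec,
) -> tuple[dict[tuple[int, str], pd.DataFrame], GroundTruth]:
    """Paired multi-subject multi-resolution connectivity matrices.

    For subject s with shared multiplier ``m_s = exp(eps_s)``, an adjacent
    pair at condition r gets a Poisson(``alpha_r * muS * m_s``) count and
    each non-adjacent same-hemisphere pair a Poisson(``muL * m_s``) count
    (means used directly when ``noise_model='none'``).  Matrices are
    symmetric with zero diagonal and zero cross-hemisphere entries.
    """
    regions, adj = chain_regions(spec.n_regions_per_hemisphere)
    ids = regions["id"].to_numpy()
    hemi = regions["hemisphere"].to_numpy()
    n = len(ids)
    adj_v = adj.to_numpy()

    pair_kind = []  # (p, q, is_short)
    for p in range(n):
        for q in range(p + 1, n):
            if hemi[p] != hemi[q]:
                continue
            pair_kind.append((p, q, bool(adj_v[p, q])))
    n_short = sum(1 for *_, s in pair_kind if s)
    n_long = len(pair_kind) - n_short
    s0 = spec.mean_short_count * n_short
    l0 = spec.mean_long_count * n_long
    expected_gscf = {
        r: (a * s0) / (a * s0 + l0) if (a * s0 + l0) > 0 else math.nan
        for r, a in ((r, spec.attenuation[r]) for r in spec.resolutions)
    }

    root = np.random.SeedSequence(spec.seed)
    subj_seq = root.spawn(spec.n_subjects)
    ensemble: dict[tuple[int, str], pd.DataFrame] = {}
    for s_idx, seq in enumerate(subj_seq):
        eff_rng = np.random.default_rng(seq)
        m_s = math.exp(eff_rng.normal(0.0, spec.subject_effect_sd)) if spec.subject_effect_sd > 0 else 1.0
        cond_seq = seq.spawn(len(spec.resolutions))
        for r, cseq in zip(spec.resolutions, cond_seq):
            rng = np.random.default_rng(cseq)
            alpha = spec.attenuation[r]
            w = np.zeros((n, n))
            for p, q, is_short in pair_kind:
                mean = (alpha * spec.mean_short_count if is_short else spec.mean_long_count) * m_s
                val = rng.poisson(mean) if spec.noise_model == "poisson" else mean
                w[p, q] = w[q, p] = val
            ensemble[(s_idx, r)] = pd.DataFrame(w, index=ids, columns=ids)
    truth = GroundTruth(expected_gscf, adj, regions, s0, l0)
    return ensemble, truth


# ---------------------------------------------------------------------------
# image phantoms

def make_phantom_volume(
    grid_shape=(32, 32, 32),
    voxel_size_mm=(1.0, 1.0, 1.0),
    components: list[tuple[tuple[int, int, int], float, float]] | None = None,
    dc_level: float = 0.0,
):
    """Band-limited phantom: a finite sum of real cosines on the grid.

    Each component is ``(freq_index_per_axis, amplitude, phase)`` giving
    ``amplitude * cos(2*pi*(k . x / shape) + phase)`` over voxel indices x.
    The spectral support is known exactly by construction.
    """
    from .resolution import Volume

    grid_shape = tuple(int(g) for g in grid_shape)
    idx = np.meshgrid(*[np.arange(g) for g in grid_shape], indexing="ij")
    data = np.full(grid_shape, float(dc_level))
    for freq, amp, phase in components or []:
        if len(freq) != 3:
            raise ValueError("frequency index must have 3 entries")
        arg = sum(2 * np.pi * int(k) * x / g for k, x, g in zip(freq, idx, grid_shape))
        data = data + amp * np.cos(arg + phase)
    return Volume(data, tuple(np.broadcast_to(np.asarray(voxel_size_mm, float), (3,))))


def make_b0_series(
    grid_shape=(24, 24, 24),
    n_volumes: int = 100,
    mean_signal: float = 100.0,
    noise_sd: float = 10.0,
    seed: int = 0,
):
    """Repeated b=0 volumes: constant signal plus i.i.d. Gaussian noise
    inside an ellipsoidal brain mask, zero outside."""
    from .resolution import Volume

    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    grid_shape = tuple(int(g) for g in grid_shape)
    ii, jj, kk = np.meshgrid(*[np.arange(g) for g in grid_shape], indexing="ij")
    c = [(g - 1) / 2.0 for g in grid_shape]
    r = [0.45 * g for g in grid_shape]
    mask = ((ii - c[0]) / r[0]) ** 2 + ((jj - c[1]) / r[1]) ** 2 + ((kk - c[2]) / r[2]) ** 2 <= 1.0
    rng = np.random.default_rng(seed)
    data = np.zeros(grid_shape + (n_volumes,))
    noise = rng.normal(0.0, noise_sd, size=(int(mask.sum()), n_volumes)) if noise_sd > 0 else 0.0
    data[mask] = mean_signal + noise
    return Volume(data), mask
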