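"""Membrane-aligned molecular-crowding profiles.

Molecular crowding next to a membrane is measured as 1D voxel-intensity
line profiles taken on SINGLE tomographic slices, each aligned to its own
membrane peak before averaging. Projecting slices first would smear a
tilted membrane into the cytoplasmic signal, so no step here ever averages
across slices before alignment; slices whose membrane sits far from the
consensus position (tilted in-plane) are excluded outright.

The per-synapse statistic compares pooled voxel intensities proximal to
the membrane (default 5-30 nm) against a distal reference (50-200 nm) with
a two-tailed Welch t-test, Bonferroni-corrected across the synapse panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .volio import Tomogram

DEFAULT_WIDTH_NM = 36.0
DEFAULT_LENGTH_NM = 450.0
PEAK_SEARCH_NM = 15.0          # membrane peak looked for within +/- this of anchor
DEFAULT_TILT_TOL_VOXELS = 5
PROXIMAL_WINDOW_NM = (5.0, 30.0)
DISTAL_WINDOW_NM = (50.0, 200.0)


class ProfileGeometryError(ValueError):
    """Profile line leaves the volume."""


class InsufficientDataError(ValueError):
    """Not enough samples/profiles for the requested statistic."""


@dataclass
class ProfileSpec:
    """Geometry of one profiled region.

    anchor: a point on the membrane (nm, (x, y, z) order); direction: unit
    vector pointing into the cytoplasm; slice_axis: tomogram axis (0=z,
    1=y, 2=x) along which single slices are taken — direction must be
    perpendicular to it. ``back`` nm of the line lie on the extracellular
    side of the anchor, the rest runs into the cytoplasm.
    """

    anchor: tuple[float, float, float]
    direction: tuple[float, float, float]
    width: float = DEFAULT_WIDTH_NM
    length: float = DEFAULT_LENGTH_NM
    back: float = 50.0
    slice_axis: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.length <= 0:
            raise ValueError("width and length must be positive")
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("direction must be non-zero")
        self.direction = tuple(d / n)
        if self.slice_axis not in (0, 1, 2):
            raise ValueError("slice_axis must be 0 (z), 1 (y) or 2 (x)")


@dataclass
class SliceProfile:
    slice_index: int
    distances: np.ndarray        # signed nm, 0 at detected membrane peak
    intensities: np.ndarray
    peak_offset: float           # nm position of the peak in the unaligned frame
    included: bool = True
    exclusion_reason: str = ""


@dataclass
class AlignedProfileSet:
    profiles: list[SliceProfile]
    grid: np.ndarray             # common distance grid, nm
    mean_profile: np.ndarray
    sd_profile: np.ndarray
    n_slices_used: int
    n_excluded: int
    voxel_size: float = 1.0


@dataclass
class CrowdingResult:
    """Proximal-vs-distal crowding classification for one synapse."""

    proximal_window: tuple[float, float]
    distal_window: tuple[float, float]
    n_prox: int
    n_dist: int
    mean_prox: float
    mean_dist: float
    t_statistic: float
    p_value: float
    alpha: float
    bonferroni_m: int
    crowding_class: str = field(init=False)

    def __post_init__(self) -> None:
        thresh = self.alpha / self.bonferroni_m
        if self.p_value < thresh and self.mean_prox > self.mean_dist:
            self.crowding_class = "higher"
        elif self.p_value < thresh and self.mean_prox < self.mean_dist:
            self.crowding_class = "lower"
        else:
            self.crowding_class = "not_different"


# ------------------------------------------------------------ extraction

def extract_profiles(
    tomogram: Tomogram,
    spec: ProfileSpec,
    slice_range: tuple[int, int],
) -> list[SliceProfile]:
    """Per-slice line profiles via trilinear interpolation.

    For each tomographic slice in ``slice_range`` (half-open), the profile
    line runs from ``anchor - back*direction`` for ``length`` nm; the
    intensity at each sample is the mean over ``round(width/voxel_size)``
    parallel lanes perpendicular to the line within the slice plane. No
    projection across slices happens anywhere.
    """
    vx = tomogram.voxel_size
    grid = tomogram.grid  # (z, y, x)
    anchor = np.asarray(spec.anchor, dtype=float)            # (x, y, z)
    d = np.asarray(spec.direction, dtype=float)
    axis = spec.slice_axis                                   # 0=z,1=y,2=x
    axis_xyz = 2 - axis                                      # index into (x,y,z)
    if abs(d[axis_xyz]) > 1e-9:
        raise ProfileGeometryError(
            "profile direction must lie within the slice plane")
    # lane direction: perpendicular to d within the slice plane
    perp = np.zeros(3)
    other = [i for i in range(3) if i != axis_xyz]
    perp[other[0]], perp[other[1]] = -d[other[1]], d[other[0]]
    perp /= np.linalg.norm(perp)

    n_samples = int(round(spec.length / vx)) + 1
    t = -spec.back + vx * np.arange(n_samples)               # nm along line
    n_lanes = max(int(round(spec.width / vx)), 1)
    lane_off = (np.arange(n_lanes) - (n_lanes - 1) / 2.0) * vx

    origin = np.asarray(tomogram.origin)[::-1]               # (x, y, z) nm
    lo, hi = slice_range
    out: list[SliceProfile] = []
    for si in range(lo, hi):
        a = anchor.copy()
        a[axis_xyz] = origin[axis_xyz] + si * vx             # pin to slice
        # sample points: (n_samples, n_lanes, 3) in nm, xyz
        pts = (a[None, None, :]
               + t[:, None, None] * d[None, None, :]
               + lane_off[None, :, None] * perp[None, None, :])
        idx = (pts - origin[None, None, :]) / vx             # voxel coords xyz
        zyx = idx[..., ::-1]
        eps = 1e-9
        bad = (zyx < -eps).any() or (
            zyx > (np.array(grid.shape) - 1) + eps).any()
        if bad:
            raise ProfileGeometryError(
                f"profile line exits the volume at slice {si}")
        vals = ndimage.map_coordinates(
            grid, zyx.reshape(-1, 3).T, order=1, mode="nearest")
        prof = vals.reshape(n_samples, n_lanes).mean(axis=1)
        # membrane peak within +/- PEAK_SEARCH_NM of the anchor (t = 0)
        win = np.abs(t) <= PEAK_SEARCH_NM
        i_peak = np.nonzero(win)[0][np.argmax(prof[win])]
        peak_nm = t[i_peak]
        out.append(SliceProfile(
            slice_index=si,
            distances=t - peak_nm,
            intensities=prof,
            peak_offset=float(peak_nm),
        ))
    return out


def align_profiles(
    profiles: list[SliceProfile],
    tilt_tolerance: float | None = None,
    voxel_size: float | None = None,
) -> AlignedProfileSet:
    """Put peak-aligned profiles on a common grid; exclude tilted slices.

    A slice is "tilted" when its unaligned membrane-peak position deviates
    from the median across slices by more than ``tilt_tolerance`` nm
    (default 5 voxels) — the in-plane-tilt exclusion rule. Mean and sd are
    computed over included profiles only.
    """
    if len(profiles) < 3:
        raise InsufficientDataError("need >= 3 slice profiles to align")
    if voxel_size is None:
        voxel_size = float(np.median([np.diff(p.distances).mean()
                                      for p in profiles]))
    if tilt_tolerance is None:
        tilt_tolerance = DEFAULT_TILT_TOL_VOXELS * voxel_size

    peaks = np.array([p.peak_offset for p in profiles])
    med = np.median(peaks)
    for p in profiles:
        if abs(p.peak_offset - med) > tilt_tolerance:
            p.included = False
            p.exclusion_reason = "tilted"
    used = [p for p in profiles if p.included]
    if not used:
        raise InsufficientDataError("all profiles excluded as tilted")

    lo = max(p.distances[0] for p in used)
    hi = min(p.distances[-1] for p in used)
    grid = np.arange(0.0, hi + 1e-9, voxel_size)
    neg = np.arange(-voxel_size, lo - 1e-9, -voxel_size)[::-1]
    grid = np.concatenate([neg, grid])
    mat = np.vstack([
        np.interp(grid, p.distances, p.intensities) for p in used])
    return AlignedProfileSet(
        profiles=profiles,
        grid=grid,
        mean_profile=mat.mean(axis=0),
        sd_profile=mat.std(axis=0, ddof=1) if len(used) > 1 else np.zeros_like(grid),
        n_slices_used=len(used),
        n_excluded=len(profiles) - len(used),
        voxel_size=voxel_size,
    )


def classify_crowding(
    aligned: AlignedProfileSet,
    proximal_window: tuple[float, float] = PROXIMAL_WINDOW_NM,
    distal_window: tuple[float, float] = DISTAL_WINDOW_NM,
    alpha: float = 0.05,
    bonferroni_m: int = 1,
) -> CrowdingResult:
    """Welch two-tailed t-test of proximal vs distal pooled voxel values.

    Samples are the individual per-slice intensities of every included
    slice whose aligned distance falls inside each window (pooled across
    slices, not the averaged profile), so n counts voxels, not slices.
    """
    if bonferroni_m < 1:
        raise ValueError("bonferroni_m must be >= 1")
    prox = _pool_window(aligned, proximal_window)
    dist = _pool_window(aligned, distal_window)
    if len(prox) < 2 or len(dist) < 2:
        raise InsufficientDataError(
            f"windows too small: n_prox={len(prox)}, n_dist={len(dist)}")
    if np.ptp(prox) == 0 and np.ptp(dist) == 0 and prox.mean() == dist.mean():
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = stats.ttest_ind(prox, dist, equal_var=False)
    return CrowdingResult(
        proximal_window=proximal_window,
        distal_window=distal_window,
        n_prox=len(prox),
        n_dist=len(dist),
        mean_prox=float(prox.mean()),
        mean_dist=float(dist.mean()),
        t_statistic=float(t_stat),
        p_value=float(p_val),
        alpha=alpha,
        bonferroni_m=bonferroni_m,
    )


def _pool_window(aligned: AlignedProfileSet, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if hi <= lo:
        raise ValueError(f"empty window {window}")
    vals = []
    for p in aligned.profiles:
        if not p.included:
            continue
        m = (p.distances >= lo) & (p.distances <= hi)
        vals.append(p.intensities[m])
    return np.concatenate(vals) if vals else np.zeros(0)


def profiles_from_arrays(
    grid: np.ndarray, intensities: np.ndarray, peak_at: float = 0.0
) -> list[SliceProfile]:
    """Wrap fabricated (grid, per-slice intensity rows) as SliceProfiles."""
    out = []
    for i, row in enumerate(np.atleast_2d(intensities)):
        win = np.abs(grid - peak_at) <= PEAK_SEARCH_NM
        i_peak = np.nonzero(win)[0][np.argmax(row[win])]
        out.append(SliceProfile(
            slice_index=i,
            distances=grid - grid[i_peak],
            intensities=np.asarray(row, dtype=float),
            peak_offset=float(grid[i_peak]),
        ))
    return out
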