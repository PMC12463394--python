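"""Synthetic synapse scenes with known ground truth.

Generates paired pre/postsynaptic membrane surfaces at controllable
separation, clustered receptor point patterns on the postsynaptic membrane
(Thomas process), rendered noisy density volumes, and fiducial
correspondence pairs — everything the analysis stages consume, with the
truth tables needed to score them.

Geometry convention: the separation axis is z. The presynaptic membrane
(PreSM) sits at low z, the postsynaptic membrane (PoSM) above it at
``z_pre + separation``; the postsynaptic cytoplasm extends towards +z.
Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volio import PointTable, Tomogram

DEFAULT_VOXEL_NM = 1.194      # 11.94 Å maps, 4x-binned reconstruction scale
DEFAULT_EXTENT_NM = 1300.0    # ~1.3 um field of view
DEFAULT_CLEFT_CUTOFF_NM = 60.0
RECEPTOR_HEIGHT_NM = 14.0     # ectodomain reach into the cleft


class GenerationError(RuntimeError):
    """Scene constraints cannot be satisfied (e.g. guard distance)."""


class GeometryError(ValueError):
    """Scene does not fit the requested render grid."""


# ------------------------------------------------------------- surfaces

@dataclass
class Surface:
    """Parametric membrane sheet z = z0 + h(x, y) over a lateral extent.

    kind 'plane' has h = 0; 'undulating' is a sinusoidal sheet; 'sphere'
    is handled separately (radial parametrisation). ``extent`` is the
    lateral (x, y) size in nm, centred on the origin of the patch.
    """

    kind: str = "plane"
    z0: float = 0.0
    extent: tuple[float, float] = (DEFAULT_EXTENT_NM, DEFAULT_EXTENT_NM)
    amplitude: float = 0.0       # undulation amplitude, nm
    wavelength: float = 400.0    # undulation period, nm
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)  # sphere only
    radius: float = 0.0                                    # sphere only

    def height(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        if self.kind == "undulating":
            k = 2.0 * np.pi / self.wavelength
            return self.amplitude * np.sin(k * x) * np.sin(k * y)
        return np.zeros_like(np.asarray(x, dtype=float))

    def points_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        z = self.z0 + self.height(x, y)
        return np.column_stack([x, y, z])

    def sample_grid(self, spacing: float, rng: np.random.Generator,
                    jitter: float = 0.0) -> np.ndarray:
        """Regular lateral grid of surface samples, optional in-plane jitter."""
        if self.kind == "sphere":
            return _fibonacci_sphere(self.center, self.radius,
                                     int(4.0 * np.pi * self.radius**2 / spacing**2))
        ex, ey = self.extent
        xs = np.arange(-ex / 2.0 + spacing / 2.0, ex / 2.0, spacing)
        ys = np.arange(-ey / 2.0 + spacing / 2.0, ey / 2.0, spacing)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        gx, gy = gx.ravel(), gy.ravel()
        if jitter > 0:
            gx = gx + rng.normal(0.0, jitter, gx.shape)
            gy = gy + rng.normal(0.0, jitter, gy.shape)
        return self.points_at(gx, gy)


def _fibonacci_sphere(center: Sequence[float], radius: float, n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    pts = radius * np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )
    return pts + np.asarray(center, dtype=float)


SeparationSpec = float | tuple[float, float] | Callable[[np.ndarray, np.ndarray], np.ndarray]


def _separation_fn(separation: SeparationSpec, extent: float) -> Callable:
    """Scalar -> constant; (low, high) pair -> lateral step at x = 0."""
    if callable(separation):
        return separation
    if isinstance(separation, (tuple, list)):
        lo, hi = float(separation[0]), float(separation[1])
        return lambda x, y: np.where(np.asarray(x) < 0.0, lo, hi)
    s = float(separation)
    return lambda x, y: np.full_like(np.asarray(x, dtype=float), s)


# ---------------------------------------------------------------- scene

@dataclass
class SyntheticScene:
    presm_surface: Surface
    posm_surface: Surface
    presm_points: PointTable
    posm_points: PointTable
    true_separation: SeparationSpec
    receptor_truth: PointTable
    receptor_labels: np.ndarray          # cluster id per receptor
    cluster_centers: np.ndarray          # (k, 3) nm
    cleft_zone_truth: np.ndarray         # bool per PoSM point
    seed: int
    spacing: float = 12.0
    separation_fn: Callable = field(default=None, repr=False)  # type: ignore[assignment]


def make_synapse_scene(
    geometry: str = "plane",
    separation: SeparationSpec = 33.0,
    extent: float = DEFAULT_EXTENT_NM,
    spacing: float = 12.0,
    n_clusters: int = 2,
    receptors_per_cluster: int = 10,
    cluster_sigma: float = 20.0,
    guard_distance: float = 150.0,
    surface_noise: float = 0.0,
    posm_overhang: float = 0.0,
    cleft_cutoff: float = DEFAULT_CLEFT_CUTOFF_NM,
    sphere_radius: float = 0.0,
    undulation_amplitude: float = 0.0,
    undulation_wavelength: float = 400.0,
    seed: int = 0,
) -> SyntheticScene:
    """Build a ground-truth synapse scene.

    The receptor pattern is a Thomas process: ``n_clusters`` parent centres
    drawn uniformly on the PoSM cleft region with minimum pairwise (surface)
    distance ``guard_distance``, each with ``receptors_per_cluster``
    offspring displaced by an isotropic in-plane Gaussian of ``cluster_sigma``
    nm. Defaults mirror the study conditions: ~33 nm separation, ~2 clusters
    of ~10 receptors per synapse, 1.3 um lateral field.

    ``posm_overhang`` extends the PoSM laterally beyond the PreSM patch,
    creating a genuine perisynaptic zone (nearest-PreSM distance beyond
    ``cleft_cutoff``).
    """
    rng = np.random.default_rng(seed)
    sep_fn = _separation_fn(separation, extent)

    if geometry == "sphere":
        if sphere_radius <= 0:
            sphere_radius = 150.0
        s0 = float(np.atleast_1d(sep_fn(np.array(0.0), np.array(0.0)))[0])
        pre = Surface(kind="sphere", center=(0, 0, 0), radius=sphere_radius)
        post = Surface(kind="sphere", center=(0, 0, 0), radius=sphere_radius + s0)
        pre_pts = pre.sample_grid(spacing, rng)
        post_pts = post.sample_grid(spacing, rng)
    elif geometry in ("plane", "undulating"):
        amp = undulation_amplitude if geometry == "undulating" else 0.0
        pre = Surface(kind=geometry, z0=0.0, extent=(extent, extent),
                      amplitude=amp, wavelength=undulation_wavelength)
        post = Surface(kind=geometry, z0=0.0,
                       extent=(extent + 2 * posm_overhang,) * 2,
                       amplitude=amp, wavelength=undulation_wavelength)
        pre_pts = pre.sample_grid(spacing, rng)
        post_xy = post.sample_grid(spacing, rng)[:, :2]
        post_pts = post.points_at(post_xy[:, 0], post_xy[:, 1])
        post_pts[:, 2] += sep_fn(post_xy[:, 0], post_xy[:, 1])
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    # receptor Thomas process on the PoSM (cleft region only)
    if n_clusters > 0:
        centers_xy = _draw_guarded_centers(
            rng, n_clusters, extent * 0.4, guard_distance
        )
        offsets = rng.normal(0.0, cluster_sigma, (n_clusters, receptors_per_cluster, 2))
        rec_xy = (centers_xy[:, None, :] + offsets).reshape(-1, 2)
        labels = np.repeat(np.arange(n_clusters), receptors_per_cluster)
        if geometry == "sphere":
            # park receptors on the outer shell near its north pole region
            rec = _lift_to_sphere(rec_xy, post.center, post.radius)
            centers = _lift_to_sphere(centers_xy, post.center, post.radius)
        else:
            rec = post.points_at(rec_xy[:, 0], rec_xy[:, 1])
            rec[:, 2] += sep_fn(rec_xy[:, 0], rec_xy[:, 1])
            centers = post.points_at(centers_xy[:, 0], centers_xy[:, 1])
            centers[:, 2] += sep_fn(centers_xy[:, 0], centers_xy[:, 1])
    else:
        rec = np.zeros((0, 3))
        labels = np.zeros(0, dtype=int)
        centers = np.zeros((0, 3))

    # truth for the cleft zone, from noiseless samples
    if len(pre_pts) and len(post_pts):
        d_true, _ = cKDTree(pre_pts).query(post_pts)
        zone_truth = d_true <= cleft_cutoff
    else:
        zone_truth = np.zeros(len(post_pts), dtype=bool)

    if surface_noise > 0:
        pre_pts = pre_pts + rng.normal(0.0, surface_noise, pre_pts.shape)
        post_pts = post_pts + rng.normal(0.0, surface_noise, post_pts.shape)

    return SyntheticScene(
        presm_surface=pre,
        posm_surface=post,
        presm_points=PointTable(pre_pts, label="PreSM"),
        posm_points=PointTable(post_pts, label="PoSM"),
        true_separation=separation,
        receptor_truth=PointTable(rec, label="receptor"),
        receptor_labels=labels,
        cluster_centers=centers,
        cleft_zone_truth=zone_truth,
        seed=seed,
        spacing=spacing,
        separation_fn=sep_fn,
    )


def _draw_guarded_centers(rng: np.random.Generator, k: int, half_extent: float,
                          guard: float, max_tries: int = 2000) -> np.ndarray:
    pts: list[np.ndarray] = []
    for _ in range(max_tries):
        cand = rng.uniform(-half_extent, half_extent, 2)
        if all(np.linalg.norm(cand - p) >= guard for p in pts):
            pts.append(cand)
            if len(pts) == k:
                return np.array(pts)
    raise GenerationError(
        f"could not place {k} cluster centres with guard {guard} nm "
        f"inside half-extent {half_extent} nm"
    )


def _lift_to_sphere(xy: np.ndarray, center: Sequence[float], r: float) -> np.ndarray:
    # treat (x, y) as gnomonic-ish offsets near the +z pole
    xy = np.asarray(xy, dtype=float)
    z = np.sqrt(np.maximum(r**2 - np.sum(xy**2, axis=1), 0.0))
    return np.column_stack([xy[:, 0], xy[:, 1], z]) + np.asarray(center, float)


# --------------------------------------------------------------- render

@dataclass
class RenderParams:
    """Rendering controls for synthetic volumes.

    bilayer_gap/bilayer_width: the membrane is drawn as two Gaussian ridges
    (leaflets) ``bilayer_gap`` nm apart, each of width ``bilayer_width`` nm.
    crowding_profile maps signed distance from the PoSM (positive into the
    postsynaptic cytoplasm, nm) to mean added density.
    """

    voxel_size: float = DEFAULT_VOXEL_NM
    bilayer_gap: float = 5.0
    bilayer_width: float = 2.0
    membrane_amplitude: float = 1.0
    receptor_height: float = RECEPTOR_HEIGHT_NM
    receptor_amplitude: float = 0.0
    receptor_sigma: float = 4.0
    crowding_profile: Callable[[np.ndarray], np.ndarray] | None = None
    noise_sigma: float = 0.0
    blur_anisotropy: float | None = None  # z-sigma / xy-sigma, e.g. 2.0

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if self.receptor_height < 0 or self.noise_sigma < 0:
            raise ValueError("receptor_height and noise_sigma must be >= 0")


def proximal_bump_profile(amplitude: float, lo: float = 5.0, hi: float = 30.0,
                          baseline: float = 1.0) -> Callable:
    """Crowding profile: ``baseline`` everywhere in the cytoplasm plus a
    flat ``amplitude`` bump between ``lo`` and ``hi`` nm from the membrane —
    the synthetic analogue of a postsynaptic-density-like layer."""
    def f(s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        out = np.where(s > 0, baseline, 0.0)
        return out + np.where((s >= lo) & (s <= hi), amplitude, 0.0)
    return f


def render_tomogram(
    scene: SyntheticScene,
    params: RenderParams | None = None,
    shape: tuple[int, int, int] | None = None,
    origin: tuple[float, float, float] | None = None,
    seed: int = 0,
) -> Tomogram:
    """Render the scene into a density-positive volume.

    Only sheet geometries (plane/undulating, optionally with a lateral
    separation step) and concentric spheres are rendered; signed distances
    to each membrane are evaluated analytically per voxel. Grid geometry
    defaults to a box spanning the lateral extent and [-60, +240] nm around
    the membrane pair along z, enough margin for a 200 nm cytoplasm window.
    """
    if params is None:
        params = RenderParams()
    rng = np.random.default_rng(seed)
    vx = params.voxel_size

    sep_max = _max_separation(scene)
    if shape is None:
        ext = min(scene.presm_surface.extent[0], 400.0)
        nz = int(round((sep_max + 300.0) / vx))
        ny = nx = int(round(ext / vx))
        shape = (nz, ny, nx)
    if origin is None:
        ext_y = shape[1] * vx
        ext_x = shape[2] * vx
        origin = (-60.0, -ext_y / 2.0, -ext_x / 2.0)  # (z, y, x) nm

    nz, ny, nx = shape
    zs = origin[0] + vx * np.arange(nz)
    ys = origin[1] + vx * np.arange(ny)
    xs = origin[2] + vx * np.arange(nx)
    if scene.presm_surface.kind != "sphere":
        ex = scene.presm_surface.extent[0]
        if zs[0] > 0.0 or zs[-1] < sep_max + 200.0:
            raise GeometryError(
                "render grid does not cover the membrane pair plus a 200 nm "
                "cytoplasm margin along z"
            )
        if xs[-1] - xs[0] > ex + 2 * vx:
            raise GeometryError("render grid wider than the membrane patch")

    Z = zs[:, None, None]
    Y = ys[None, :, None]
    X = xs[None, None, :]

    if scene.presm_surface.kind == "sphere":
        r = np.sqrt(X**2 + Y**2 + Z**2)
        d_pre = r - scene.presm_surface.radius
        d_post = r - scene.posm_surface.radius
        s_cyto = d_post  # outward = postsynaptic side
    else:
        h_pre = scene.presm_surface.height(X, Y)
        sep = scene.separation_fn(X, Y)
        d_pre = Z - h_pre                    # signed distance to PreSM sheet
        d_post = Z - (h_pre + sep)           # to PoSM sheet
        s_cyto = d_post                      # positive into PoSM cytoplasm

    g, w, amp = params.bilayer_gap, params.bilayer_width, params.membrane_amplitude
    vol = amp * (
        np.exp(-0.5 * ((d_pre - g / 2) / w) ** 2)
        + np.exp(-0.5 * ((d_pre + g / 2) / w) ** 2)
        + np.exp(-0.5 * ((d_post - g / 2) / w) ** 2)
        + np.exp(-0.5 * ((d_post + g / 2) / w) ** 2)
    )
    if params.crowding_profile is not None:
        vol = vol + params.crowding_profile(s_cyto)

    if params.receptor_amplitude > 0 and len(scene.receptor_truth):
        vol += _stamp_receptors(scene, params, zs, ys, xs)

    if params.blur_anisotropy:
        vol = ndimage.gaussian_filter(
            vol, sigma=(params.blur_anisotropy, 1.0, 1.0))
    if params.noise_sigma > 0:
        vol = vol + rng.normal(0.0, params.noise_sigma, vol.shape)

    return Tomogram(grid=vol.astype(np.float32), voxel_size=vx, origin=origin)


def _max_separation(scene: SyntheticScene) -> float:
    sep = scene.true_separation
    if callable(sep):
        return float(np.max(sep(np.linspace(-650, 650, 64), np.zeros(64))))
    if isinstance(sep, (tuple, list)):
        return float(max(sep))
    return float(sep)


def _stamp_receptors(scene, params, zs, ys, xs) -> np.ndarray:
    """Gaussian blobs reaching receptor_height into the cleft (towards -z)."""
    vx = params.voxel_size
    out = np.zeros((len(zs), len(ys), len(xs)))
    sig = params.receptor_sigma
    half = int(np.ceil(3 * sig / vx))
    for p in scene.receptor_truth.coordinates:
        c = p + np.array([0.0, 0.0, -params.receptor_height / 2.0])  # (x,y,z)
        iz = int(round((c[2] - zs[0]) / vx))
        iy = int(round((c[1] - ys[0]) / vx))
        ix = int(round((c[0] - xs[0]) / vx))
        sl = tuple(slice(max(i - half, 0), min(i + half + 1, n))
                   for i, n in zip((iz, iy, ix), out.shape))
        if any(s.start >= s.stop for s in sl):
            continue
        ZZ = zs[sl[0]][:, None, None] - c[2]
        YY = ys[sl[1]][None, :, None] - c[1]
        XX = xs[sl[2]][None, None, :] - c[0]
        out[sl] += params.receptor_amplitude * np.exp(
            -0.5 * (XX**2 + YY**2 + ZZ**2) / sig**2)
    return out


# ------------------------------------------------------------- fiducials

def make_fiducial_scene(
    rotation_deg: float = 0.0,
    scale: float = 1.0,
    translation: tuple[float, float] = (0.0, 0.0),
    shear: float = 0.0,
    n_points: int = 10,
    noise_sigma: float = 0.0,
    extent: float = 100.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paired 2D fiducial lists: dst = A @ src + t + noise.

    Default ``n_points=10`` matches the minimum hole-count convention for
    a reliable fluorescence-to-EM registration. Returns (src, dst, A) where
    A is the 2x2 linear part actually applied.
    """
    if n_points < 3:
        raise ValueError("need at least 3 fiducial points")
    rng = np.random.default_rng(seed)
    src = rng.uniform(-extent, extent, (n_points, 2))
    th = np.deg2rad(rotation_deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    A = scale * R
    if shear:
        A = A @ np.array([[1.0, shear], [0.0, 1.0]])
    dst = src @ A.T + np.asarray(translation, dtype=float)
    if noise_sigma > 0:
        dst = dst + rng.normal(0.0, noise_sigma, dst.shape)
    return src, dst, A


# ---------------------------------------------------- profile fabrication

def make_flat_profiles(
    n_slices: int = 31,
    grid: np.ndarray | None = None,
    baseline: float = 1.0,
    noise_sigma: float = 0.05,
    bump_amplitude: float = 0.0,
    bump_window: tuple[float, float] = (5.0, 30.0),
    membrane_amplitude: float = 4.0,
    membrane_sigma: float = 1.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fabricate per-slice 1D intensity profiles on a common distance grid.

    A fast stand-in for full volume rendering when only the profile
    statistics are under test: membrane ridge at distance 0, flat cytoplasm
    at ``baseline`` with iid Gaussian noise, optional crowding bump of
    ``bump_amplitude`` on ``bump_window`` nm. Returns (distances_nm,
    intensities[n_slices, n_samples]).
    """
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = np.arange(-50.0, 400.0 + 1e-9, DEFAULT_VOXEL_NM)
    base = np.where(grid > 0, baseline, 0.2 * baseline)
    base = base + membrane_amplitude * np.exp(-0.5 * (grid / membrane_sigma) ** 2)
    lo, hi = bump_window
    base = base + np.where((grid >= lo) & (grid <= hi), bump_amplitude, 0.0)
    prof = base[None, :] + rng.normal(0.0, noise_sigma, (n_slices, grid.size))
    return grid, prof
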