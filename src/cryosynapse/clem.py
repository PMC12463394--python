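"""Fluorescence-to-EM fiducial registration and puncta quantification.

Registration maps cryo-fluorescence image coordinates onto an EM montage
using the centres of holes in the holey-carbon foil as fiducials (a
similarity transform by default — scaled rotation plus translation — since
that is what relates the two views of a flat grid square). Puncta
segmentation follows the watershed convention: smooth, threshold (Otsu),
seed at local maxima, then integrate the ORIGINAL pixel values per label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed
from skimage.transform import AffineTransform, SimilarityTransform

MIN_FIDUCIALS_NO_WARNING = 10  # holes per registration before we warn


class DegenerateConfigurationError(ValueError):
    """Too few or collinear fiducials for the requested model."""


@dataclass
class Transform2D:
    """y = linear @ x + translation, with the fit residual attached."""

    linear: np.ndarray
    translation: np.ndarray
    model: str
    rms_residual: float

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        if self.model == "similarity":
            s = np.sqrt(np.abs(np.linalg.det(self.linear)))
            if s <= 0:
                raise DegenerateConfigurationError("zero-scale similarity")
            R = self.linear / s
            if np.linalg.norm(R.T @ R - np.eye(2)) > 1e-8:
                raise ValueError("similarity linear part is not s*R")

    @property
    def scale(self) -> float:
        return float(np.sqrt(np.abs(np.linalg.det(self.linear))))

    @property
    def rotation_deg(self) -> float:
        return float(np.rad2deg(np.arctan2(self.linear[1, 0], self.linear[0, 0])))

    def inverse(self) -> "Transform2D":
        inv = np.linalg.inv(self.linear)
        return Transform2D(inv, -inv @ self.translation, self.model, 0.0)


def fit_point_transform(
    src: np.ndarray, dst: np.ndarray, model: str = "similarity"
) -> Transform2D:
    """Least-squares 2D registration from matched fiducial pairs.

    Similarity needs >= 2 distinct points, affine >= 3 non-collinear.
    Registrations with fewer than 10 fiducials succeed but warn, since
    hole-centre registrations are conventionally done with at least 10.
    """
    src = np.asarray(src, dtype=float).reshape(-1, 2)
    dst = np.asarray(dst, dtype=float).reshape(-1, 2)
    if src.shape != dst.shape:
        raise ValueError("src and dst must have equal shapes")
    n = len(src)
    min_n = 2 if model == "similarity" else 3
    if n < min_n:
        raise DegenerateConfigurationError(
            f"{model} needs >= {min_n} points, got {n}")
    if _collinear(src) and model == "affine":
        raise DegenerateConfigurationError("affine fit from collinear points")
    if np.allclose(src, src[0]):
        raise DegenerateConfigurationError("all source points coincide")
    if n < MIN_FIDUCIALS_NO_WARNING:
        warnings.warn(
            f"only {n} fiducials; registrations normally use >= "
            f"{MIN_FIDUCIALS_NO_WARNING} hole centres", stacklevel=2)

    if model == "similarity":
        cls = SimilarityTransform
    elif model == "affine":
        cls = AffineTransform
    else:
        raise ValueError(f"unknown model {model!r}")
    if hasattr(cls, "from_estimate"):
        tf = cls.from_estimate(src, dst)
        if not tf:
            raise DegenerateConfigurationError("transform estimation failed")
    else:  # older scikit-image
        tf = cls()
        if not tf.estimate(src, dst):
            raise DegenerateConfigurationError("transform estimation failed")
    M = np.asarray(tf.params)
    linear, t = M[:2, :2], M[:2, 2]
    resid = dst - (src @ linear.T + t)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return Transform2D(linear=linear, translation=t, model=model, rms_residual=rms)


def _collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    if len(pts) < 3:
        return True
    d = pts - pts.mean(axis=0)
    s = np.linalg.svd(d, compute_uv=False)
    return bool(s[-1] <= tol * max(s[0], 1.0))


def apply_transform(t: Transform2D, points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    return points @ t.linear.T + t.translation


def read_correspondences(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a `x_src,y_src,x_dst,y_dst` table."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    need = ["x_src", "y_src", "x_dst", "y_dst"]
    if not all(c in df.columns for c in need):
        raise ValueError(f"{path} must have columns {need}")
    return df[need[:2]].to_numpy(float), df[need[2:]].to_numpy(float)


# ------------------------------------------------------------------ puncta

@dataclass
class PunctaSet:
    """Watershed-segmented fluorescent puncta.

    integrated_intensity sums the raw (unsmoothed) pixels of each label,
    the quantity used as the per-synapse fluorescence readout.
    """

    labels: np.ndarray               # 2D int label image (above-threshold core)
    table: pd.DataFrame              # label, centroid_y, centroid_x, area, integrated_intensity
    basins: np.ndarray | None = None  # full catchment basin per punctum

    def __len__(self) -> int:
        return len(self.table)

    @property
    def background_sum(self) -> float:
        return float(self._image_sum - self.table["integrated_intensity"].sum())

    _image_sum: float = 0.0


def segment_puncta(
    image: np.ndarray,
    smoothing_sigma: float = 2.0,
    min_area: int = 4,
    min_distance: int = 3,
    mask: np.ndarray | None = None,
) -> PunctaSet:
    """Watershed puncta segmentation with integrated raw intensities.

    Pipeline: Gaussian smooth -> Otsu threshold on the smoothed image ->
    local maxima above threshold as seeds -> watershed. Area and centroid
    come from the above-threshold core of each punctum (and ``min_area``
    filters on that core), while integrated intensity sums the raw pixels
    of the punctum's full catchment basin, so the dim tails of a spot are
    counted. ``mask`` (optional) excludes e.g. autofluorescent regions
    before thresholding.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or not np.all(np.isfinite(image)):
        raise ValueError("image must be a finite 2D array")
    work = image if mask is None else np.where(mask, image, 0.0)
    empty = pd.DataFrame(
        columns=["label", "centroid_y", "centroid_x", "area", "integrated_intensity"])
    if np.allclose(work, work.flat[0]):
        ps = PunctaSet(labels=np.zeros(image.shape, dtype=int), table=empty)
        ps._image_sum = float(image.sum())
        return ps
    sm = gaussian(work, sigma=smoothing_sigma, preserve_range=True)
    thr = threshold_otsu(sm)
    fg = sm > thr
    seeds_xy = peak_local_max(sm, min_distance=min_distance, labels=fg)
    markers = np.zeros(image.shape, dtype=int)
    for i, (r, c) in enumerate(seeds_xy, start=1):
        markers[r, c] = i
    labels = watershed(-sm, markers=markers, mask=fg)
    basins = watershed(-sm, markers=markers)  # full catchment, no mask

    rows = []
    for rp in regionprops(labels, intensity_image=image):
        if rp.area < min_area:
            labels[labels == rp.label] = 0
            basins[basins == rp.label] = 0
            continue
        rows.append({
            "label": rp.label,
            "centroid_y": rp.centroid[0],
            "centroid_x": rp.centroid[1],
            "area": int(rp.area),
            "integrated_intensity": float(image[basins == rp.label].sum()),
        })
    table = pd.DataFrame(rows) if rows else empty
    ps = PunctaSet(labels=labels, table=table, basins=basins)
    ps._image_sum = float(image.sum())
    return ps
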