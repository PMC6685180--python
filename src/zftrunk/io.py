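"""Image/annotation I/O, polygon rasterization, and blinded-filename workflow.

Images are handled as plain ``numpy`` arrays of dtype ``uint8`` ("image
planes"): single-channel 2D rasters on a 0-255 scale.  Everything downstream
(fixed intensity threshold of 30, CLAHE) assumes this scale, so 16-bit input
is linearly min-max rescaled per stack at ingestion.

Region-of-interest polygons are recorded as ordered vertex lists in pixel
coordinates, ``(row, col)`` with row increasing downward, and rasterized with
a boundary-inclusive pixel-center test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon


class FormatError(ValueError):
    """Raised when an input file cannot be interpreted."""


def _as_plane(a, name: str = "plane") -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 2 or a.shape[0] < 1 or a.shape[1] < 1:
        raise ValueError(f"{name} must be a non-empty 2D array, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class PolygonROI:
    """A simple polygon in pixel coordinates.

    Parameters
    ----------
    polygon_id : str or int
        Label used to join measurements back to the ROI.
    vertices : sequence of (row, col)
        Ordered vertex list; at least 3 vertices; must be simple
        (non-self-intersecting).
    """

    polygon_id: object
    vertices: tuple = ()

    def __post_init__(self):
        verts = tuple((float(r), float(c)) for r, c in self.vertices)
        if len(verts) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        object.__setattr__(self, "vertices", verts)
        if not self.to_shapely().is_valid:
            raise ValueError(f"polygon {self.polygon_id!r} is not simple")

    def to_shapely(self) -> _ShapelyPolygon:
        # shapely is (x, y) = (col, row)
        return _ShapelyPolygon([(c, r) for r, c in self.vertices])

    @property
    def area(self) -> float:
        return self.to_shapely().area


@dataclass
class RegionMasks:
    """Named binary masks partitioning a trunk image.

    ``fish`` is the whole-animal outline, ``horizontal_myoseptum`` the band
    joining the chevron apices (dorsal/ventral divider),
    ``myoseptal_innervation`` the stripes of slow-twitch innervation along
    the vertical myosepta, and ``half_myotome_labels`` an integer raster
    (0 = outside) enumerating the sampling units.
    """

    fish: np.ndarray
    horizontal_myoseptum: np.ndarray
    myoseptal_innervation: np.ndarray
    half_myotome_labels: np.ndarray

    def __post_init__(self):
        self.fish = _as_plane(self.fish, "fish").astype(bool)
        self.horizontal_myoseptum = _as_plane(
            self.horizontal_myoseptum, "horizontal_myoseptum"
        ).astype(bool)
        self.myoseptal_innervation = _as_plane(
            self.myoseptal_innervation, "myoseptal_innervation"
        ).astype(bool)
        self.half_myotome_labels = _as_plane(
            self.half_myotome_labels, "half_myotome_labels"
        ).astype(np.int32)
        shapes = {
            a.shape
            for a in (
                self.fish,
                self.horizontal_myoseptum,
                self.myoseptal_innervation,
                self.half_myotome_labels,
            )
        }
        if len(shapes) != 1:
            raise ValueError(f"mask shapes differ: {sorted(shapes)}")
        if np.any(self.horizontal_myoseptum & ~self.fish):
            raise ValueError("horizontal myoseptum extends outside the fish mask")
        if np.any((self.half_myotome_labels > 0) & ~self.fish):
            raise ValueError("half-myotome labels extend outside the fish mask")

    @property
    def shape(self):
        return self.fish.shape

    @property
    def labels(self) -> np.ndarray:
        """Sorted positive label ids present in the raster."""
        u = np.unique(self.half_myotome_labels)
        return u[u > 0]


# ---------------------------------------------------------------------------
# TIFF ingestion


def read_stack(path) -> list[np.ndarray]:
    """Read a single- or multi-page grayscale TIFF into a list of 8-bit planes.

    16-bit input is linearly min-max rescaled to 0-255 using the global
    minimum and maximum of the *whole stack*, so relative intensities between
    planes are preserved.  A constant 16-bit stack (degenerate range) maps
    to all zeros.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - message path
        raise FormatError(f"cannot read TIFF {path.name!r}: {exc}") from exc
    data = np.asarray(data)
    if data.size == 0:
        raise FormatError(f"TIFF {path.name!r} is empty")
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(
            f"TIFF {path.name!r} has unsupported dimensionality {data.ndim}"
        )
    if data.dtype == np.uint8:
        return [p.copy() for p in data]
    if data.dtype == np.uint16:
        lo, hi = int(data.min()), int(data.max())
        if hi == lo:
            return [np.zeros(p.shape, np.uint8) for p in data]
        scaled = (data.astype(np.float64) - lo) * (255.0 / (hi - lo))
        return [np.round(p).astype(np.uint8) for p in scaled]
    raise FormatError(
        f"TIFF {path.name!r} has unsupported dtype {data.dtype}; "
        "expected uint8 or uint16 grayscale"
    )


def write_stack(path, planes: Sequence[np.ndarray]) -> None:
    """Write planes as a multi-page 8-bit TIFF."""
    arr = np.stack([_as_plane(p).astype(np.uint8) for p in planes])
    tifffile.imwrite(path, arr)


def max_projection(planes: Sequence[np.ndarray]) -> np.ndarray:
    """Pixelwise maximum-intensity projection of same-shaped planes."""
    planes = [np.asarray(p) for p in planes]
    if len(planes) == 0:
        raise ValueError("max_projection needs at least one plane")
    shape = planes[0].shape
    bad = [i for i, p in enumerate(planes) if p.shape != shape]
    if bad:
        raise ValueError(f"planes {bad} do not match shape {shape}")
    out = planes[0].copy()
    for p in planes[1:]:
        np.maximum(out, p, out=out)
    return out


# ---------------------------------------------------------------------------
# Polygon rasterization


def rasterize_polygon(roi: PolygonROI, shape) -> np.ndarray:
    """Rasterize a simple polygon to a boolean mask on an image grid.

    A pixel is inside iff its center (integer ``(row, col)``) lies inside
    the polygon under the even-odd rule; pixel centers exactly on the
    boundary count as inside.
    """
    nrows, ncols = int(shape[0]), int(shape[1])
    poly = roi.to_shapely()
    rows = np.array([r for r, _ in roi.vertices])
    cols = np.array([c for _, c in roi.vertices])
    if rows.min() < -0.5 or cols.min() < -0.5 or rows.max() > nrows - 0.5 or cols.max() > ncols - 0.5:
        raise ValueError(
            f"polygon {roi.polygon_id!r} does not fit inside shape {(nrows, ncols)}"
        )
    mask = np.zeros((nrows, ncols), bool)
    r0 = max(0, int(np.floor(rows.min())))
    r1 = min(nrows - 1, int(np.ceil(rows.max())))
    c0 = max(0, int(np.floor(cols.min())))
    c1 = min(ncols - 1, int(np.ceil(cols.max())))
    if r1 < r0 or c1 < c0:
        return mask
    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    pts = shapely.points(cc.ravel(), rr.ravel())  # (x=col, y=row)
    shapely.prepare(poly)
    inside = shapely.covers(poly, pts).reshape(rr.shape)
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside
    return mask


def polygons_to_labels(rois: Sequence[PolygonROI], shape) -> np.ndarray:
    """Rasterize a list of polygons into an integer label raster (1-based,
    in list order; later polygons overwrite earlier on overlap)."""
    labels = np.zeros((int(shape[0]), int(shape[1])), np.int32)
    for i, roi in enumerate(rois, start=1):
        labels[rasterize_polygon(roi, shape)] = i
    return labels


# ---------------------------------------------------------------------------
# Polygon / annotation CSV round-trip

POLYGON_CSV_COLUMNS = ["polygon_id", "vertex_index", "row", "col"]


def write_polygons_csv(path, rois: Sequence[PolygonROI]) -> None:
    rows = []
    for roi in rois:
        for i, (r, c) in enumerate(roi.vertices):
            rows.append({"polygon_id": roi.polygon_id, "vertex_index": i, "row": r, "col": c})
    pd.DataFrame(rows, columns=POLYGON_CSV_COLUMNS).to_csv(path, index=False)


def read_polygons_csv(path) -> list[PolygonROI]:
    df = pd.read_csv(path)
    missing = set(POLYGON_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"polygon CSV missing columns: {sorted(missing)}")
    rois = []
    for pid, g in df.groupby("polygon_id", sort=False):
        g = g.sort_values("vertex_index")
        rois.append(PolygonROI(pid, list(zip(g["row"], g["col"]))))
    return rois


# ---------------------------------------------------------------------------
# Blinding


@dataclass(frozen=True)
class BlindingKey:
    """Bijective mapping from original file names to opaque blinded names.

    The opaque names are zero-padded indices drawn from a seeded random
    permutation, so they carry no information about experimental group or
    acquisition order.  The key must be stored away from the blinded data;
    analysis code only ever sees the opaque names.
    """

    mapping: Mapping[str, str]
    seed: int

    def apply(self, name: str) -> str:
        return self.mapping[name]

    def invert(self, opaque: str) -> str:
        return self._inverse()[opaque]

    def _inverse(self) -> dict:
        return {v: k for k, v in self.mapping.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"original": list(self.mapping), "blinded": list(self.mapping.values())}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, seed: int = -1) -> "BlindingKey":
        df = pd.read_csv(path)
        return cls(dict(zip(df["original"], df["blinded"])), seed)


def blind_files(names: Sequence[str], seed: int) -> BlindingKey:
    """Build a deterministic blinding key for a list of unique file names.

    Each original name maps to ``blinded_<k><ext>`` where ``k`` runs over a
    seeded random permutation of ``0..n-1`` (zero padded) and ``<ext>`` is
    the original suffix, so blinded files stay openable by image viewers.
    """
    names = list(names)
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate names cannot be blinded: {dupes}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(names))
    width = max(3, len(str(max(len(names) - 1, 0))))
    mapping = {}
    for name, k in zip(names, perm):
        suffix = Path(name).suffix
        mapping[name] = f"blinded_{int(k):0{width}d}{suffix}"
    return BlindingKey(mapping, int(seed))
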