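"""Geometric and intensity morphometry outside the NMJ pipeline.

Myotendinous-junction (MTJ) apex angles from three-point annotations,
intersegmental-vessel (ISV) lengths from polyline annotations,
percent mean-gray reporter intensity normalized to within-batch controls,
percent of myotomes with fiber degeneration per embryo, and contingency
tallies of blinded ordinal staining scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PolygonROI, rasterize_polygon

LAMININ_CATEGORIES = ("none", "weak", "strong")
BETA_DG_CATEGORIES = ("weak", "strong")


@dataclass(frozen=True)
class AngleAnnotation:
    """Three-point MTJ angle annotation: (arm point, apex, arm point).

    The measured quantity is the full chevron angle at the apex (the middle
    point); it widens with dystrophic MTJ defects.
    """

    image_id: str
    triple: tuple

    def __post_init__(self):
        t = tuple((float(r), float(c)) for r, c in self.triple)
        if len(t) != 3:
            raise ValueError("angle annotation needs exactly three points")
        object.__setattr__(self, "triple", t)
        a, v, b = (np.asarray(p) for p in t)
        if np.array_equal(a, v) or np.array_equal(b, v):
            raise ValueError("arm point coincides with the vertex")


@dataclass(frozen=True)
class PolylineAnnotation:
    """Ordered point list traced along a vessel (segmented-line annotation)."""

    image_id: str
    vessel_id: object
    points: tuple

    def __post_init__(self):
        pts = tuple((float(r), float(c)) for r, c in self.points)
        if len(pts) < 2:
            raise ValueError("polyline needs at least two points")
        for p, q in zip(pts, pts[1:]):
            if p == q:
                raise ValueError("consecutive polyline points must be distinct")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class IntensityROI:
    """Polygonal region for mean-gray quantification, with group and batch.

    Intensities are comparable only within an acquisition batch (consistent
    exposure), so normalization is always within-batch.
    """

    image_id: str
    polygon: PolygonROI
    group: str
    batch: str = "batch0"


@dataclass(frozen=True)
class CategoricalScore:
    """One blinded ordinal staining score."""

    image_id: str
    category: str
    blinded: bool = True

    def __post_init__(self):
        if not self.category:
            raise ValueError("category must be non-empty")


# ---------------------------------------------------------------------------


def mtj_angle(a: AngleAnnotation) -> float:
    """Interior angle at the annotation vertex, degrees in (0, 180]."""
    p1, v, p2 = (np.asarray(p, float) for p in a.triple)
    u = p1 - v
    w = p2 - v
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu == 0 or nw == 0:
        raise ValueError("zero-length arm")
    cosang = np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def polyline_length(p: PolylineAnnotation, normalize_by: float | None = None) -> float:
    """Summed Euclidean length of the polyline, pixels.

    ``normalize_by`` divides by a per-embryo width scalar (for ISV length
    normalized to embryo width); it must be positive.
    """
    pts = np.asarray(p.points, float)
    length = float(np.sum(np.hypot(*(np.diff(pts, axis=0).T))))
    if normalize_by is not None:
        if normalize_by <= 0:
            raise ValueError("normalization width must be positive")
        length /= normalize_by
    return length


def percent_mean_intensity(
    rois: Sequence[IntensityROI],
    images: Mapping[str, np.ndarray],
    control_group: str,
) -> pd.DataFrame:
    """Percent mean-gray intensity per ROI, normalized to batch controls.

    For each ROI the mean gray value inside its polygon is computed; within
    each batch the mean of the control-group ROI means defines 100%, and
    every ROI is reported as ``100 * roi_mean / control_mean``.
    """
    if not rois:
        raise ValueError("no ROIs supplied")
    rows = []
    for roi in rois:
        img = images[roi.image_id]
        mask = rasterize_polygon(roi.polygon, img.shape)
        if not mask.any():
            raise ValueError(f"ROI on {roi.image_id!r} rasterizes to nothing")
        rows.append(
            {
                "image_id": roi.image_id,
                "group": roi.group,
                "batch": roi.batch,
                "mean_gray": float(np.asarray(img, float)[mask].mean()),
            }
        )
    df = pd.DataFrame(rows)
    out = []
    for batch, g in df.groupby("batch", sort=False):
        ctrl = g.loc[g["group"] == control_group, "mean_gray"]
        if ctrl.empty:
            raise ValueError(f"batch {batch!r} has no {control_group!r} ROIs")
        denom = ctrl.mean()
        if denom == 0:
            raise ValueError(f"batch {batch!r} control mean intensity is zero")
        g = g.copy()
        g["percent_intensity"] = 100.0 * g["mean_gray"] / denom
        out.append(g)
    return pd.concat(out, ignore_index=True)


def percent_myotomes_degenerated(per_embryo_flags: Sequence[Sequence[bool]]) -> list[float]:
    """Percent of myotomes flagged as degenerated, per embryo."""
    if len(per_embryo_flags) == 0:
        raise ValueError("no embryos supplied")
    out = []
    for i, flags in enumerate(per_embryo_flags):
        flags = list(flags)
        if not flags:
            raise ValueError(f"embryo {i} has no myotome flags")
        out.append(100.0 * sum(bool(f) for f in flags) / len(flags))
    return out


def tally_categories(
    scores: Sequence[CategoricalScore],
    groups: Mapping[str, str],
    categories: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tally blinded ordinal scores into a groups x categories count table.

    ``groups`` maps image_id (the blinded name) to experimental group — the
    unblinding step, applied only after all scores are in.  Any score taken
    on an unblinded image is refused: the scoring contract requires the
    scorer not to know the group.
    """
    if not scores:
        raise ValueError("no scores supplied")
    unblinded = [s.image_id for s in scores if not s.blinded]
    if unblinded:
        raise ValueError(
            f"scores on unblinded images refused: {sorted(set(unblinded))}"
        )
    cats = list(categories) if categories is not None else sorted({s.category for s in scores})
    bad = sorted({s.category for s in scores} - set(cats))
    if bad:
        raise ValueError(f"categories outside the declared set: {bad}")
    df = pd.DataFrame(
        {"group": [groups[s.image_id] for s in scores], "category": [s.category for s in scores]}
    )
    table = (
        df.groupby(["group", "category"]).size().unstack(fill_value=0)
    )
    return table.reindex(columns=cats, fill_value=0)
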