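"""Synthetic trunk phantoms with known innervation ground truth.

A phantom is a two-channel (AChR / SV2) 8-bit image of a stretch of
zebrafish trunk: chevron-shaped myotomes separated by vertical myosepta,
split dorsally/ventrally by the horizontal myoseptum.  Within each
half-myotome the generator lays chains of Gaussian puncta emulating
distributed fast-twitch innervation, recording the exact summed polyline
length and branch count per half-myotome *before* rendering — the ground
truth against which the measurement pipeline is validated.

Group presets scale the laid-down chain length per half-myotome relative to
the control baseline, reproducing the published relative skeleton-length
ratios of dystroglycanopathy-model morphants (fkrp, dag1) with and without
NAD+ supplementation.

Coordinates are 0-based ``(row, col)`` with row increasing downward;
rendering is 8-bit so the downstream fixed threshold of 30 is meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import PolygonROI, RegionMasks, polygons_to_labels, write_polygons_csv, write_stack

#: Relative target chain length per half-myotome, as a fraction of the
#: control baseline.  The morphant presets reproduce the published relative
#: skeleton lengths: fkrp 51.4%, dag1 83.9%, fkrp+NAD+ 61.9%, dag1+NAD+ 85.0%.
PRESETS = {
    "control": 1.0,
    "fkrp_like": 0.514,
    "dag1_like": 0.839,
    "nad_fkrp_like": 0.619,
    "nad_dag1_like": 0.850,
}


class PhantomParameterError(ValueError):
    """Raised when phantom parameters cannot produce a valid phantom."""


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, innervation, and noise parameters of a trunk phantom.

    Defaults describe a confocal-style maximum projection: an essentially
    black background (offset ~2/255 with sigma ~1 additive read noise, as
    in a confocal acquisition with the detector offset tuned to the dark
    level) and bright puncta (amplitude 160, spot sigma 1.8 px) spaced 5 px
    along chains.  The clean background matters: the downstream pipeline
    applies adaptive equalization before its fixed threshold, and group
    trends are threshold-robust only when the equalized background stays
    below the lowest usable threshold in sparse images too.

    Parameters
    ----------
    image_height, image_width : int
        Raster size in pixels.
    n_myotome_pairs : int
        Number of chevron myotomes; each contributes a dorsal and a ventral
        half-myotome (so 10 pairs -> 20 sampling units).
    mtj_angle : float
        Full chevron angle at the apex, degrees, in (0, 180).
    chain_length_factor : float
        Target summed chain length per half-myotome as a fraction of the
        per-geometry baseline (the chevron arm span); presets set this.
    puncta_spacing : float
        Distance between punctum centers along a chain, pixels (>= 1).
    puncta_sigma : float
        Gaussian spot sigma, pixels.
    branch_probability : float
        Per-punctum probability of spawning a 45-degree side chain.
    puncta_amplitude : float or (float, float)
        Peak added intensity per punctum, per channel (AChR, SV2).
    background_level : float
        Constant background offset, intensity units.
    noise_sigma : float
        Additive Gaussian noise sigma, per channel, independent.
    poisson_noise : bool
        If True, replace the rendered signal by a Poisson sample (shot
        noise) before additive noise.  Off by default.
    seed : int
        Seeds all randomness; identical params + seed give bit-identical
        phantoms.
    """

    image_height: int = 168
    image_width: int = 560
    n_myotome_pairs: int = 10
    mtj_angle: float = 90.0
    chain_length_factor: float = 1.0
    puncta_spacing: float = 5.0
    puncta_sigma: float = 1.8
    branch_probability: float = 0.15
    puncta_amplitude: object = 160.0
    background_level: float = 2.0
    noise_sigma: float = 1.0
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.image_height <= 0 or self.image_width <= 0:
            raise PhantomParameterError("image dimensions must be positive")
        if self.n_myotome_pairs <= 0:
            raise PhantomParameterError("n_myotome_pairs must be positive")
        if not (0 < self.mtj_angle < 180):
            raise PhantomParameterError("mtj_angle must be in (0, 180) degrees")
        if not (0 < self.chain_length_factor <= 1):
            raise PhantomParameterError("chain_length_factor must be in (0, 1]")
        if self.puncta_spacing < 1:
            raise PhantomParameterError("puncta_spacing must be >= 1 pixel")
        if not (0 <= self.branch_probability <= 1):
            raise PhantomParameterError("branch_probability must be in [0, 1]")
        if self.noise_sigma < 0 or self.background_level < 0:
            raise PhantomParameterError("background/noise must be non-negative")

    @property
    def amplitudes(self) -> tuple[float, float]:
        a = self.puncta_amplitude
        if np.isscalar(a):
            return float(a), float(a)
        a = tuple(float(x) for x in a)
        if len(a) != 2:
            raise PhantomParameterError("puncta_amplitude must be scalar or a pair")
        return a


@dataclass(frozen=True)
class GroundTruth:
    """Known innervation per half-myotome, recorded before rendering.

    ``table`` has columns half_myotome_id, true_path_length_px,
    true_branch_count; ``polygons`` maps each id to its half-myotome
    quadrilateral.
    """

    table: pd.DataFrame
    polygons: dict

    def __post_init__(self):
        t = self.table
        if (t["true_path_length_px"] < 0).any() or (t["true_branch_count"] < 0).any():
            raise ValueError("ground truth must be non-negative")


@dataclass(frozen=True)
class TrunkPhantom:
    """Two-channel trunk image plus masks, ground truth, and parameters."""

    channel_achr: np.ndarray
    channel_sv2: np.ndarray
    masks: RegionMasks
    truth: GroundTruth
    params: PhantomParams

    def __post_init__(self):
        if self.channel_achr.shape != self.channel_sv2.shape:
            raise ValueError("channels must share shape")

    def stack(self) -> dict:
        """The channel mapping :func:`zftrunk.nmj.run_nmj_pipeline` consumes."""
        return {"achr": self.channel_achr, "sv2": self.channel_sv2}


# ---------------------------------------------------------------------------
# Geometry

_MARGIN = 12          # fish border inside the raster, px
_HM_HALFWIDTH = 2     # horizontal-myoseptum half-band, px (rows)
_STRIPE_HALFWIDTH = 2  # myoseptal-innervation stripe half-width, px (cols)
_LABEL_INSET = _STRIPE_HALFWIDTH + 1  # keep labels off the stripes


@dataclass(frozen=True)
class _Geometry:
    top: int
    bottom: int
    mid: float
    col_left: float
    col_right: float
    slope: float          # horizontal offset per row away from the midline
    apices: np.ndarray    # apex column of each chevron boundary, len n+1
    arm_span: float       # chevron arm length apex -> dorsal edge, px

    def boundary_col(self, i: int, row) -> np.ndarray:
        """Column of chevron boundary i at the given row(s)."""
        return self.apices[i] + np.abs(np.asarray(row, float) - self.mid) * self.slope


def _make_geometry(p: PhantomParams) -> _Geometry:
    top = _MARGIN
    bottom = p.image_height - 1 - _MARGIN
    if bottom - top < 20:
        raise PhantomParameterError("image_height too small for trunk geometry")
    mid = (top + bottom) / 2.0
    half_angle = math.radians(p.mtj_angle) / 2.0
    h = mid - top
    # each arm deviates from the horizontal-myoseptum axis by half the chevron
    # angle: horizontal run per vertical px is 1/tan(half_angle)
    slope = 1.0 / math.tan(half_angle)
    dx = h * slope
    col_left = _MARGIN
    col_right = p.image_width - 1 - _MARGIN
    usable = col_right - col_left - dx
    width = usable / p.n_myotome_pairs
    if width < 4 * (_LABEL_INSET + 2):
        raise PhantomParameterError(
            "image_width too small for the requested myotome count / angle"
        )
    apices = col_left + width * np.arange(p.n_myotome_pairs + 1)
    arm_span = math.hypot(h, dx)
    return _Geometry(top, bottom, mid, col_left, col_right, slope, apices, arm_span)


def _half_myotome_polygon(g: _Geometry, i: int, dorsal: bool) -> list[tuple[float, float]]:
    """Quadrilateral for myotome i, dorsal or ventral half, inset off the
    myoseptal stripes and the horizontal myoseptum."""
    if dorsal:
        r_near = g.mid - _HM_HALFWIDTH - 1
        r_far = float(g.top)
    else:
        r_near = g.mid + _HM_HALFWIDTH + 1
        r_far = float(g.bottom)
    cl_near = g.boundary_col(i, r_near) + _LABEL_INSET
    cl_far = g.boundary_col(i, r_far) + _LABEL_INSET
    cr_near = g.boundary_col(i + 1, r_near) - _LABEL_INSET
    cr_far = g.boundary_col(i + 1, r_far) - _LABEL_INSET
    return [
        (r_near, float(cl_near)),
        (r_far, float(cl_far)),
        (r_far, float(cr_far)),
        (r_near, float(cr_near)),
    ]


def _build_masks(p: PhantomParams, g: _Geometry, polygons: dict) -> RegionMasks:
    shape = (p.image_height, p.image_width)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]

    fish = (
        (rr >= g.top)
        & (rr <= g.bottom)
        & (cc >= g.col_left - 1)
        & (cc <= g.col_right + 1)
    )

    hm = fish & (np.abs(rr - g.mid) <= _HM_HALFWIDTH)

    stripe = np.zeros(shape, bool)
    for i in range(len(g.apices)):
        bc = g.boundary_col(i, rr[:, 0])[:, None]
        stripe |= fish & (np.abs(cc - bc) <= _STRIPE_HALFWIDTH)

    ordered = [polygons[k] for k in sorted(polygons)]
    labels = polygons_to_labels(ordered, shape)
    labels[~fish] = 0
    return RegionMasks(fish, hm, stripe, labels)


# ---------------------------------------------------------------------------
# Chain laying

_SQ2 = math.sqrt(2.0)


def _lay_chains(
    p: PhantomParams,
    poly: Sequence[tuple[float, float]],
    g: _Geometry,
    i_myotome: int,
    rng: np.random.Generator,
) -> tuple[list[np.ndarray], np.ndarray, float, int]:
    """Lay innervation chains inside one half-myotome polygon.

    Chains are polylines of puncta spaced ``puncta_spacing`` apart, laid
    parallel to the fiber direction (anterior-posterior, i.e. along
    columns); each punctum may spawn a 45-degree side chain of a geometric
    number of puncta (one ground-truth branchpoint each).  The summed
    polyline length is an exact multiple of the spacing, landing within half
    a spacing of ``chain_length_factor x arm_span``.

    Distinct chains innervate distinct fibers, so chain rows keep a minimum
    separation of ~6 puncta sigmas (a fiber-diameter-scale gap); this also
    keeps the rendered bands of different chains from fusing.
    """
    spacing = p.puncta_spacing
    target = p.chain_length_factor * g.arm_span
    if target < spacing:
        raise PhantomParameterError(
            f"target chain length {target:.1f}px is below puncta_spacing "
            f"{spacing}px; no chain fits"
        )
    n_steps = int(round(target / spacing))

    pad = math.ceil(3 * p.puncta_sigma) + 1
    rows = sorted({poly[0][0], poly[1][0]})
    r_lo, r_hi = rows[0] + pad, rows[1] - pad
    if r_hi <= r_lo:
        raise PhantomParameterError("half-myotome too short for puncta padding")

    def col_range(row):
        lo = g.boundary_col(i_myotome, row) + _LABEL_INSET + pad
        hi = g.boundary_col(i_myotome + 1, row) - _LABEL_INSET - pad
        return lo, hi

    chains: list[np.ndarray] = []
    centers: list[tuple[float, float]] = []  # each punctum rendered once
    steps_left = n_steps
    branch_count = 0
    attempts = 0
    min_sep = 6.0 * p.puncta_sigma
    used_rows: list[float] = []
    while steps_left > 0 and attempts < 200:
        attempts += 1
        r = rng.uniform(r_lo, r_hi)
        if used_rows and min(abs(r - ur) for ur in used_rows) < min_sep and attempts < 150:
            continue
        lo, hi = col_range(r)
        if hi - lo < spacing:
            continue
        # chains traverse the myotome anterior -> posterior, as distributed
        # innervation runs along the fibers; only the start jitters
        c = rng.uniform(lo, min(lo + spacing, hi - spacing))
        pts = [(r, c)]
        while steps_left > 0 and pts[-1][1] + spacing <= hi:
            c = pts[-1][1] + spacing
            pts.append((r, c))
            steps_left -= 1
            if steps_left > 0 and rng.random() < p.branch_probability:
                side = _lay_branch(p, (r, c), r_lo, r_hi, col_range, steps_left, rng)
                if side is not None:
                    chains.append(side)
                    centers.extend(map(tuple, side[1:]))  # origin already placed
                    steps_left -= len(side) - 1
                    branch_count += 1
        if len(pts) > 1:
            chains.append(np.asarray(pts))
            centers.extend(pts)
            used_rows.append(r)
    used = n_steps - steps_left
    return chains, np.asarray(centers, float).reshape(-1, 2), used * spacing, branch_count


def _lay_branch(p, origin, r_lo, r_hi, col_range, steps_left, rng):
    """A 45-degree side chain from a punctum; length geometric, clipped to
    stay inside the (chevron-slanted) half-myotome interior."""
    k = min(int(rng.geometric(0.5)), steps_left)
    dr = p.puncta_spacing / _SQ2
    sign = -1.0 if rng.random() < 0.5 else 1.0
    r0, c0 = origin
    pts = [(r0, c0)]
    for j in range(1, k + 1):
        r, c = r0 + sign * dr * j, c0 + dr * j
        lo, hi = col_range(r)
        if not (r_lo <= r <= r_hi and lo <= c <= hi):
            break
        pts.append((r, c))
    if len(pts) < 2:
        return None
    return np.asarray(pts)


# ---------------------------------------------------------------------------
# Rendering


def _render_puncta(shape, centers: np.ndarray, amplitude: float, sigma: float) -> np.ndarray:
    """Accumulate truncated Gaussian spots (support radius ceil(3 sigma))."""
    canvas = np.zeros(shape, np.float64)
    rad = math.ceil(3 * sigma)
    win = np.arange(-rad, rad + 1)
    for r, c in centers:
        ir, ic = int(round(r)), int(round(c))
        rr = win + ir
        cc = win + ic
        gr = np.exp(-((rr - r) ** 2) / (2 * sigma**2))
        gc = np.exp(-((cc - c) ** 2) / (2 * sigma**2))
        rs = slice(max(rr[0], 0), min(rr[-1] + 1, shape[0]))
        cs = slice(max(cc[0], 0), min(cc[-1] + 1, shape[1]))
        gr = gr[rs.start - rr[0] : rs.stop - rr[0]]
        gc = gc[cs.start - cc[0] : cs.stop - cc[0]]
        canvas[rs, cs] += amplitude * np.outer(gr, gc)
    return canvas


def generate_trunk_phantom(params: PhantomParams) -> TrunkPhantom:
    """Generate a two-channel trunk phantom with known ground truth.

    The two channels share punctum positions (emulating pre/post-synaptic
    colocalization) and differ only by per-channel amplitude and
    independent noise.  Ground truth (summed chain polyline length and
    branch count per half-myotome) is recorded before rendering.
    """
    p = params
    g = _make_geometry(p)
    rng = np.random.default_rng(p.seed)

    polygons: dict[int, PolygonROI] = {}
    truth_rows = []
    all_centers = []
    # labels: anterior -> posterior, dorsal before ventral
    for i in range(p.n_myotome_pairs):
        for j, dorsal in enumerate((True, False)):
            lid = 2 * i + 1 + j
            verts = _half_myotome_polygon(g, i, dorsal)
            polygons[lid] = PolygonROI(lid, verts)
            chains, centers, length, branches = _lay_chains(p, verts, g, i, rng)
            truth_rows.append(
                {
                    "half_myotome_id": lid,
                    "true_path_length_px": length,
                    "true_branch_count": branches,
                }
            )
            if centers.size:
                all_centers.append(centers)

    truth = GroundTruth(pd.DataFrame(truth_rows), polygons)
    masks = _build_masks(p, g, polygons)

    shape = (p.image_height, p.image_width)
    centers = (
        np.concatenate(all_centers) if all_centers else np.empty((0, 2))
    )
    amp_achr, amp_sv2 = p.amplitudes
    channels = []
    for amp in (amp_achr, amp_sv2):
        signal = p.background_level + _render_puncta(shape, centers, amp, p.puncta_sigma)
        if p.poisson_noise:
            signal = rng.poisson(np.clip(signal, 0, None)).astype(np.float64)
        if p.noise_sigma > 0:
            signal = signal + rng.normal(0.0, p.noise_sigma, shape)
        channels.append(np.clip(np.round(signal), 0, 255).astype(np.uint8))

    return TrunkPhantom(channels[0], channels[1], masks, truth, p)


def preset_params(preset: str, seed: int = 0, **overrides) -> PhantomParams:
    """Parameters for a named experimental-group preset.

    Presets fix ``chain_length_factor`` at the published relative skeleton
    lengths: control 1.0, fkrp_like 0.514, dag1_like 0.839, nad_fkrp_like
    0.619, nad_dag1_like 0.850.
    """
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    return PhantomParams(
        chain_length_factor=PRESETS[preset], seed=seed, **overrides
    )


def write_phantom(phantom: TrunkPhantom, outdir) -> None:
    """Write a phantom to disk: channels as a 2-page TIFF, masks as binary
    TIFFs, ground truth and polygons as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_stack(outdir / "channels.tif", [phantom.channel_achr, phantom.channel_sv2])
    m = phantom.masks
    for name, mask in (
        ("fish", m.fish),
        ("horizontal_myoseptum", m.horizontal_myoseptum),
        ("myoseptal_innervation", m.myoseptal_innervation),
    ):
        write_stack(outdir / f"mask_{name}.tif", [mask.astype(np.uint8) * 255])
    write_stack(outdir / "half_myotome_labels.tif", [m.half_myotome_labels.astype(np.uint8)])
    phantom.truth.table.to_csv(outdir / "ground_truth.csv", index=False)
    write_polygons_csv(
        outdir / "half_myotome_polygons.csv",
        [phantom.truth.polygons[k] for k in sorted(phantom.truth.polygons)],
    )


# ---------------------------------------------------------------------------
# MTJ-angle and orientation-texture phantoms


def generate_mtj_phantom(
    mtj_angle: float,
    n_chevrons: int,
    seed: int = 0,
    shape: tuple[int, int] = (128, 320),
) -> tuple[np.ndarray, list[tuple[tuple, tuple, tuple]]]:
    """Render chevron boundary lines plus exact angle-annotation triples.

    Each triple is ``(dorsal arm point, apex, ventral arm point)`` in
    continuous (row, col) coordinates; the angle they subtend is exactly
    ``mtj_angle`` by construction.
    """
    if not (0 < mtj_angle < 180):
        raise ValueError("mtj_angle must be in (0, 180) degrees")
    if n_chevrons < 0:
        raise ValueError("n_chevrons must be >= 0")
    img = np.zeros(shape, np.uint8)
    triples: list[tuple[tuple, tuple, tuple]] = []
    if n_chevrons == 0:
        return img, triples
    H, W = shape
    top, bottom = 8.0, H - 9.0
    mid = (top + bottom) / 2.0
    h = mid - top
    slope = 1.0 / math.tan(math.radians(mtj_angle) / 2.0)
    dx = h * slope
    spacing = (W - 16 - dx) / max(n_chevrons, 1)
    if spacing <= 0:
        raise ValueError("shape too narrow for the requested chevrons/angle")
    rng = np.random.default_rng(seed)
    rows = np.arange(int(math.ceil(top)), int(math.floor(bottom)) + 1)
    for i in range(n_chevrons):
        apex_c = 8.0 + spacing * i + rng.uniform(0, 0.25 * spacing)
        cols = apex_c + np.abs(rows - mid) * slope
        ic = np.round(cols).astype(int)
        ok = (ic >= 0) & (ic < W)
        img[rows[ok], ic[ok]] = 255
        triples.append(((top, apex_c + dx), (mid, apex_c), (bottom, apex_c + dx)))
    return img, triples


def generate_orientation_texture(
    kind: str,
    orientation: float = 0.0,
    period: float = 16.0,
    contrast: float = 120.0,
    shape: tuple[int, int] = (128, 128),
    seed: int = 0,
    background: float = 128.0,
) -> np.ndarray:
    """Test textures for the anisotropy module.

    ``stripes``: sinusoidal grating whose intensity varies along direction
    ``orientation`` (degrees from the row axis toward the column axis), i.e.
    ``orientation`` is the grating normal; 0 gives horizontal stripes.
    ``noise``: i.i.d. Gaussian field, mean ``background``, sigma
    ``contrast``.  ``constant``: uniform plane at ``background``.
    """
    H, W = int(shape[0]), int(shape[1])
    if H <= 0 or W <= 0:
        raise ValueError("shape must be positive")
    if kind == "constant":
        return np.full((H, W), np.clip(round(background), 0, 255), np.uint8)
    if kind == "stripes":
        if period < 2:
            raise ValueError("stripe period must be >= 2 px")
        rad = math.radians(orientation)
        ct, st = math.cos(rad), math.sin(rad)
        # snap near-zero direction cosines so axis-aligned gratings are
        # exact transposes of each other
        if abs(ct) < 1e-12:
            ct = 0.0
        if abs(st) < 1e-12:
            st = 0.0
        rr, cc = np.mgrid[0:H, 0:W]
        u = ct * rr + st * cc
        img = background + 0.5 * contrast * np.sin(2 * np.pi * u / period)
        return np.clip(np.round(img), 0, 255).astype(np.uint8)
    if kind == "noise":
        rng = np.random.default_rng(seed)
        img = background + rng.normal(0.0, contrast, (H, W))
        return np.clip(np.round(img), 0, 255).astype(np.uint8)
    raise ValueError(f"unknown texture kind {kind!r}")
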