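"""Cortical linescan extraction and myosin enrichment indices.

The quantification mirrors a standard live-imaging workflow for cytokinesis:
the camera background is subtracted from the raw movie, the cell boundary is
traced on a single plane, a 2-pixel-wide pole-to-pole line is sampled along
one lateral side of the cortex, the cytoplasmic mean is subtracted, the
profile is max-normalised and lightly smoothed, and ratio indices
(cortical enrichment, cortex-to-furrow ratio) are computed from mean grey
values.  All intensity arithmetic is done on floating point copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage import draw, filters, measure

from furrowquant import _geom

Side = Literal["left", "right"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class TimeLapseMovie:
    """Single-channel, single-plane time-lapse stack with imaging metadata.

    Parameters
    ----------
    frames:
        ``(T, H, W)`` float array of intensities (a.u.).
    pixel_size:
        Lateral pixel size in micrometres per pixel.
    frame_interval:
        Time between frames in seconds.
    anaphase_onset_index:
        Frame index of anaphase onset (sister-chromatid separation); the
        time origin of all kinetic read-outs.
    background_subtracted:
        Whether the camera offset has already been removed.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float = 20.0
    anaphase_onset_index: int = 0
    background_subtracted: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("movie must be a (T, H, W) stack with at least 2 frames")
        if not (0 <= self.anaphase_onset_index < self.frames.shape[0]):
            raise ValueError("anaphase_onset_index outside the movie")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def times_s(self) -> np.ndarray:
        """Time of each frame relative to anaphase onset, in seconds."""
        return (np.arange(self.n_frames) - self.anaphase_onset_index) * self.frame_interval


@dataclass
class CellContour:
    """Closed subpixel cell boundary with apical/basal pole annotations.

    ``points`` is an ``(N, 2)`` array in ``(row, col)`` order, positively
    oriented and uniformly resampled in arclength.  ``long_axis`` is the unit
    vector pointing from the apical to the basal pole.
    """

    points: np.ndarray
    apical_pole_index: int
    basal_pole_index: int
    long_axis: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.long_axis = np.asarray(self.long_axis, dtype=float)
        if len(self.points) < 8:
            raise ValueError("contour needs at least 8 points")
        if self.apical_pole_index == self.basal_pole_index:
            raise ValueError("pole indices must be distinct")
        n = np.linalg.norm(self.long_axis)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("long_axis must be a unit vector")

    @property
    def n_points(self) -> int:
        return int(len(self.points))

    @property
    def apical_pole(self) -> np.ndarray:
        return self.points[self.apical_pole_index]

    @property
    def basal_pole(self) -> np.ndarray:
        return self.points[self.basal_pole_index]

    def perimeter_px(self) -> float:
        return _geom.perimeter(self.points)

    def axial_coordinate(self) -> np.ndarray:
        """Projection of each vertex on the long axis, relative to the apical pole (px)."""
        return (self.points - self.apical_pole) @ self.long_axis

    def lateral_coordinate(self) -> np.ndarray:
        """Signed perpendicular offset of each vertex from the long axis (px).

        Positive values are on the "right" side when travelling apical to
        basal.
        """
        rel = self.points - self.apical_pole
        # z-component of long_axis x rel with x = col, y = row
        return self.long_axis[1] * rel[:, 0] - self.long_axis[0] * rel[:, 1]

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        return draw.polygon2mask(shape, self.points)


@dataclass
class CorticalProfile:
    """Pole-to-pole cortical intensity trace along one lateral side.

    ``arclength`` runs from 0 at the apical pole to 1 at the basal pole along
    the sampled side; ``state`` tracks the normalisation applied so far.
    """

    arclength: np.ndarray
    intensity: np.ndarray
    side: Side
    sampling_width: int = 2
    state: str = "raw"
    contour_fractions: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.arclength = np.asarray(self.arclength, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.arclength.shape != self.intensity.shape:
            raise ValueError("arclength and intensity must align")
        if len(self.arclength) < 16:
            raise ValueError("profile needs at least 16 samples")
        if np.any(np.diff(self.arclength) <= 0):
            raise ValueError("arclength must be strictly increasing")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def subtract_camera_background(movie: TimeLapseMovie, offset: float) -> TimeLapseMovie:
    """Remove the constant camera offset from every pixel, clipping at zero.

    Rejects a second subtraction: the clip at zero makes the operation
    non-idempotent on noisy data.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    if movie.background_subtracted:
        raise ValueError("movie is already background-subtracted")
    frames = np.clip(movie.frames - offset, 0.0, None)
    return replace(movie, frames=frames, background_subtracted=True)


def _refine_edges(
    frame: np.ndarray,
    points: np.ndarray,
    search_px: float = 4.0,
    step_px: float = 0.25,
) -> np.ndarray:
    """Snap each contour vertex to the intensity-gradient maximum along its
    outward normal (subpixel, parabolic peak interpolation).

    For a boundary blurred by a symmetric PSF the gradient maximum marks the
    true edge, which corrects the level-set bias of a global threshold
    (largest where the local edge plateau is much brighter than the
    threshold, e.g. at the cortical band around a nearly closed furrow).
    """
    tang = _geom.tangents(points)
    orient = 1.0 if _geom.signed_area(points) > 0 else -1.0
    inward = np.column_stack([tang[:, 1], -tang[:, 0]]) * orient
    offsets = np.arange(-search_px, search_px + step_px / 2, step_px)
    # lines[i, j] = point i displaced by offsets[j] along the inward normal
    lines = points[:, None, :] + inward[:, None, :] * offsets[None, :, None]
    vals = ndimage.map_coordinates(
        frame, [lines[..., 0].ravel(), lines[..., 1].ravel()], order=1, mode="nearest"
    ).reshape(lines.shape[:2])
    grad = np.gradient(vals, axis=1)  # intensity rises inward: maximum marks the edge
    j = np.argmax(grad, axis=1)
    j = np.clip(j, 1, len(offsets) - 2)
    rows = np.arange(len(points))
    g0, g1, g2 = grad[rows, j - 1], grad[rows, j], grad[rows, j + 1]
    denom = g0 - 2 * g1 + g2
    frac = np.where(np.abs(denom) > 1e-12, 0.5 * (g0 - g2) / denom, 0.0)
    frac = np.clip(frac, -1.0, 1.0)
    best = offsets[j] + frac * step_px
    return points + inward * best[:, None]


def trace_contour(
    frame: np.ndarray,
    threshold: float | None = None,
    smoothing_sigma: float = 1.0,
    n_points: int = 200,
    min_area_px: int = 64,
    contour_smooth_sigma: float = 1.5,
    refine: bool = True,
) -> CellContour:
    """Trace the cell boundary on one frame as a subpixel closed contour.

    The frame is Gaussian-smoothed, thresholded (Otsu by default), and the
    largest connected component is contoured with marching squares at the
    threshold level.  Each vertex is then refined to the intensity-gradient
    maximum along its normal (the unbiased edge position under symmetric
    blur), the contour is resampled to uniform arclength and lightly
    smoothed, and the poles are assigned as the two vertices extremal along
    the principal axis of the enclosed region; the pole with the smaller
    row coordinate is labelled apical (cells are imaged apical side up).
    """
    frame = np.asarray(frame, dtype=float)
    smoothed = ndimage.gaussian_filter(frame, smoothing_sigma) if smoothing_sigma > 0 else frame
    if threshold is None:
        if smoothed.max() <= smoothed.min():
            raise ValueError("no cell found: flat frame")
        threshold = float(filters.threshold_otsu(smoothed))
    binary = smoothed > threshold
    labels, n_lab = ndimage.label(binary)
    if n_lab == 0:
        raise ValueError("no cell found: 0 components above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_lab + 1))
    big = np.flatnonzero(sizes >= min_area_px)
    if len(big) == 0:
        raise ValueError("no cell found: 0 large components above threshold")
    if len(big) > 1:
        raise ValueError(f"expected one cell, found {len(big)} large components")
    keep = big[0] + 1
    mask = labels == keep
    region = np.where(mask, smoothed, threshold - 1.0)
    contours = measure.find_contours(region, level=threshold)
    if not contours:
        raise ValueError("no cell found: no closed iso-contour")
    contour = max(contours, key=lambda c: abs(_geom.signed_area(c)))
    contour = _geom.ensure_positive_orientation(contour)
    points = _geom.resample_closed(contour, n_points)
    if refine:
        points = _refine_edges(smoothed, points)
    if contour_smooth_sigma > 0:
        # circular smoothing of the polyline damps marching-squares jitter
        points = ndimage.gaussian_filter1d(points, contour_smooth_sigma, axis=0, mode="wrap")
    return annotate_poles(points, mask=mask)


def annotate_poles(points: np.ndarray, mask: np.ndarray | None = None) -> CellContour:
    """Build a :class:`CellContour`, assigning poles along the principal axis.

    The principal axis is the leading PCA direction of the region pixels
    (or of the contour vertices when no mask is supplied); the poles are the
    contour vertices extremal along it, apical = smaller row.
    """
    points = _geom.ensure_positive_orientation(np.asarray(points, dtype=float))
    if mask is not None and mask.sum() >= 4:
        coords = np.column_stack(np.nonzero(mask)).astype(float)
    else:
        coords = points
    centred = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    proj = (points - coords.mean(axis=0)) @ axis
    i_lo, i_hi = int(np.argmin(proj)), int(np.argmax(proj))
    # apical pole toward row 0
    if points[i_lo, 0] <= points[i_hi, 0]:
        apical, basal = i_lo, i_hi
    else:
        apical, basal = i_hi, i_lo
    long_axis = points[basal] - points[apical]
    long_axis = long_axis / np.linalg.norm(long_axis)
    return CellContour(points=points, apical_pole_index=apical, basal_pole_index=basal, long_axis=long_axis)


def _side_path(contour: CellContour, side: Side) -> tuple[np.ndarray, np.ndarray]:
    """Indices and points of the apical-to-basal path along one lateral side."""
    n = contour.n_points
    a, b = contour.apical_pole_index, contour.basal_pole_index
    fwd = np.arange(a, a + (b - a) % n + 1) % n
    bwd = np.arange(b, b + (a - b) % n + 1) % n
    bwd = bwd[::-1]  # reorder to run apical -> basal
    lat = contour.lateral_coordinate()
    paths = {}
    for idx in (fwd, bwd):
        mean_lat = float(np.mean(lat[idx[1:-1]])) if len(idx) > 2 else 0.0
        key: Side = "right" if mean_lat >= 0 else "left"
        paths[key] = idx
    if side not in paths:
        raise ValueError(f"contour has no distinct {side} path")
    idx = paths[side]
    return idx, contour.points[idx]


def _bilinear(frame: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(frame, [pts[:, 0], pts[:, 1]], order=1, mode="nearest")


def pole_to_pole_profile(
    frame: np.ndarray,
    contour: CellContour,
    side: Side | None = None,
    width_px: int = 2,
    band_centre_px: float = 2.5,
) -> CorticalProfile:
    """Sample a pole-to-pole cortical linescan along one lateral side.

    At each contour sample of the chosen side the intensity is the mean of
    ``width_px`` bilinear samples taken along the inward normal at 1 px
    spacing, centred ``band_centre_px`` inside the boundary (the sampling
    line rides the middle of the cortical band, emulating a 2-pixel-wide
    linescan drawn on the cortex).  ``side=None`` picks the side with the
    higher mean signal.
    """
    frame = np.asarray(frame, dtype=float)
    if width_px < 1:
        raise ValueError("width_px must be >= 1")

    def build(side_: Side) -> CorticalProfile:
        idx, pts = _side_path(contour, side_)
        if len(pts) < 16:
            raise ValueError(f"{side_} path has only {len(pts)} samples (< 16)")
        tang = _geom.tangents(contour.points)[idx]
        # inward normal: for a positively oriented contour the interior lies
        # to the left of the increasing-index tangent, independent of the
        # direction the side path is walked in
        orient = 1.0 if _geom.signed_area(contour.points) > 0 else -1.0
        normal = np.column_stack([tang[:, 1], -tang[:, 0]]) * orient
        vals = np.zeros(len(pts))
        for k in range(width_px):
            offset = (band_centre_px + k - (width_px - 1) / 2.0) * normal
            vals += _bilinear(frame, pts + offset)
        vals /= width_px
        s = _geom.cumulative_arclength(pts, closed=False)
        arc = s / s[-1]
        # keep strictly increasing arclength (duplicate vertices collapse)
        keep = np.concatenate([[True], np.diff(arc) > 0])
        frac = idx / contour.n_points
        return CorticalProfile(
            arclength=arc[keep],
            intensity=vals[keep],
            side=side_,
            sampling_width=width_px,
            contour_fractions=frac[keep],
        )

    if side is not None:
        return build(side)
    left, right = build("left"), build("right")
    return right if right.intensity.mean() >= left.intensity.mean() else left


def cytoplasm_mean(
    frame: np.ndarray,
    contour: CellContour,
    cortical_band_width_px: float = 5.0,
) -> float:
    """Mean intensity of the cytoplasm, i.e. the cell interior eroded clear
    of the cortical band (band width + 2 px margin)."""
    frame = np.asarray(frame, dtype=float)
    mask = contour.mask(frame.shape)
    radius = int(np.ceil(cortical_band_width_px + 2))
    inner = ndimage.binary_erosion(mask, iterations=radius)
    if not inner.any():
        raise ValueError("eroded cytoplasm region is empty")
    return float(frame[inner].mean())


def normalize_profile(profile: CorticalProfile, cyto: float, smooth_k: int = 3) -> CorticalProfile:
    """Cytoplasm-subtract, max-normalise and smooth a raw linescan.

    The cytoplasmic mean is subtracted (negative values retained), the trace
    is divided by its post-subtraction maximum, and a centred moving average
    over ``smooth_k`` neighbours per side is applied (``smooth_k=3`` is the
    symmetric reading of a "6 neighbours average").
    """
    if profile.state != "raw":
        raise ValueError(f"profile already processed (state={profile.state!r})")
    if smooth_k < 0:
        raise ValueError("smooth_k must be >= 0")
    vals = profile.intensity - cyto
    peak = vals.max()
    if peak <= 0:
        raise ValueError("profile maximum is not positive after cytoplasm subtraction")
    vals = vals / peak
    if smooth_k > 0:
        window = 2 * smooth_k + 1
        kernel = np.ones(window) / window
        padded = np.pad(vals, smooth_k, mode="edge")
        vals = np.convolve(padded, kernel, mode="valid")
        state = f"smoothed({smooth_k})"
    else:
        state = "max-normalized"
    return replace(profile, intensity=vals, state=state)


def cortical_enrichment(cortex_mean: float, cyto_mean: float) -> float:
    """Cortical enrichment index (cortex - cytoplasm) / cytoplasm."""
    if cyto_mean <= 0:
        raise ValueError("cytoplasmic mean must be positive")
    return (cortex_mean - cyto_mean) / cyto_mean


def polar_cortex_mean(
    profile: CorticalProfile,
    furrow_segment: tuple[float, float] | None,
) -> float:
    """Mean raw linescan intensity over the polar cortex (everything outside
    the furrow arclength interval)."""
    if furrow_segment is None:
        return float(profile.intensity.mean())
    lo, hi = furrow_segment
    outside = (profile.arclength < lo) | (profile.arclength > hi)
    if not outside.any():
        raise ValueError("furrow segment covers the whole profile")
    return float(profile.intensity[outside].mean())


def cortex_to_furrow_ratio(
    profile: CorticalProfile,
    furrow_segment: tuple[float, float],
    cyto: float = 0.0,
) -> float:
    """Ratio of mean polar-cortex to mean furrow intensity along a linescan.

    ``furrow_segment`` is an arclength-fraction interval on the profile;
    both means are cytoplasm-subtracted.  Values below 1 indicate myosin
    focused at the furrow, above 1 myosin spread on the polar cortex.
    """
    lo, hi = furrow_segment
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("furrow segment must be a nonempty interval within [0, 1]")
    inside = (profile.arclength >= lo) & (profile.arclength <= hi)
    if not inside.any() or inside.all():
        raise ValueError("furrow segment leaves no samples on one side")
    furrow = float(profile.intensity[inside].mean()) - cyto
    cortex = float(profile.intensity[~inside].mean()) - cyto
    if furrow <= 0:
        raise ValueError("mean furrow intensity is not positive")
    return cortex / furrow
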