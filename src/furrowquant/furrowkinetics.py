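"""Cleavage-furrow detection, ingression timing and constriction kinetics.

The furrow is located as the point of maximal concave (inward) membrane
curvature on each lateral side of the long axis; ingression onset is the
first frame at which both sides show such a point.  Ring constriction is
expressed as a percentage between the ring diameter at anaphase onset (0 %)
and midbody size (100 %), and the furrow's basal offset is the projection
of the furrow midpoint onto the apico-basal axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from furrowquant import _geom
from furrowquant.cortexprofile import CellContour, TimeLapseMovie, trace_contour

__all__ = [
    "FurrowPoints",
    "FurrowState",
    "detect_furrow",
    "detect_ingression_onset",
    "width_at_axis_position",
    "ring_waist",
    "percent_constriction",
    "constriction_curve",
    "cohort_average_curve",
    "furrow_basal_distance",
    "furrow_segment",
    "segment_on_profile",
    "furrow_width_um",
]

#: default concavity threshold for calling a furrow, 1/px
CONCAVITY_THRESHOLD = 0.05
#: default window (samples) of the local circle fit used for curvature
CURVATURE_WINDOW = 11


@dataclass
class FurrowPoints:
    """Detected furrow point on each lateral side, px (row, col)."""

    left: np.ndarray
    right: np.ndarray
    left_index: int
    right_index: int

    @property
    def midpoint(self) -> np.ndarray:
        return (self.left + self.right) / 2.0

    def ring_diameter_px(self) -> float:
        return float(np.linalg.norm(self.right - self.left))


@dataclass
class FurrowState:
    """Per-frame furrow summary used for CSV export."""

    frame_index: int
    furrow_point_left: tuple[float, float] | None
    furrow_point_right: tuple[float, float] | None
    ring_diameter_um: float | None
    furrow_width_um: float | None
    percent_constriction: float | None
    basal_distance_um: float | None


def detect_furrow(
    contour: CellContour,
    threshold: float = CONCAVITY_THRESHOLD,
    window: int = CURVATURE_WINDOW,
    pole_exclusion_frac: float = 0.05,
) -> FurrowPoints | None:
    """Locate the furrow as the most concave contour sample on each side.

    Signed curvature (circle fit over ``window`` samples, concave negative)
    is evaluated along the contour; samples within ``pole_exclusion_frac``
    of either pole (in index distance) are ignored.  Returns ``None`` unless
    both lateral sides contain a sample more concave than ``-threshold``.
    """
    if contour.n_points <= 8:
        raise ValueError("degenerate contour (<= 8 points)")
    kappa = _geom.signed_curvature(contour.points, window=window)
    lat = contour.lateral_coordinate()
    n = contour.n_points
    idx = np.arange(n)
    excl = max(1, int(round(pole_exclusion_frac * n)))
    near_pole = np.zeros(n, dtype=bool)
    for pole in (contour.apical_pole_index, contour.basal_pole_index):
        d = np.abs((idx - pole + n // 2) % n - n // 2)
        near_pole |= d < excl
    found: dict[str, int] = {}
    for name, mask in (("left", lat < 0), (("right"), lat > 0)):
        cand = idx[mask & ~near_pole]
        if len(cand) == 0:
            return None
        best = cand[np.argmin(kappa[cand])]
        if kappa[best] >= -threshold:
            return None
        found[name] = int(best)
    return FurrowPoints(
        left=contour.points[found["left"]],
        right=contour.points[found["right"]],
        left_index=found["left"],
        right_index=found["right"],
    )


def detect_ingression_onset(
    contours: list[CellContour | None],
    threshold: float = CONCAVITY_THRESHOLD,
    window: int = CURVATURE_WINDOW,
) -> int | None:
    """First frame index with a furrow on both sides; ``None`` when
    ingression is never detected."""
    valid = [c for c in contours if c is not None]
    if len(valid) < 2:
        raise ValueError("need at least 2 frames with valid contours")
    for t, contour in enumerate(contours):
        if contour is None:
            continue
        try:
            if detect_furrow(contour, threshold=threshold, window=window) is not None:
                return t
        except ValueError:
            continue
    return None


def width_at_axis_position(
    frame: np.ndarray,
    contour: CellContour,
    axial_px: float,
    lateral_halfspan_px: float = 48.0,
    step_px: float = 0.25,
) -> float | None:
    """Cell width (px) at one axial position, from half-maximum edge crossings
    of the intensity profile sampled perpendicular to the long axis.

    The cortical band makes the cell edge a bright blurred step; its outer
    half-maximum crossing marks the true boundary independently of how wide
    or bright the structure is, which keeps the measurement unbiased even
    when the two furrow walls merge into a single bright band near ring
    closure.  Requires a background-subtracted frame.  Returns ``None``
    when no sufficiently contrasted structure is found.
    """
    res = _scan_width(frame, contour, axial_px, lateral_halfspan_px, step_px)
    return None if res is None else res[0]


def _scan_width(
    frame: np.ndarray,
    contour: CellContour,
    axial_px: float,
    lateral_halfspan_px: float = 48.0,
    step_px: float = 0.25,
) -> tuple[float, np.ndarray, np.ndarray] | None:
    """(width px, left edge point, right edge point) at one axial position."""
    axis = contour.long_axis
    perp = np.array([-axis[1], axis[0]])
    centre = contour.apical_pole + axial_px * axis
    offs = np.arange(-lateral_halfspan_px, lateral_halfspan_px + step_px / 2, step_px)
    pts = centre[None, :] + offs[:, None] * perp[None, :]
    vals = ndimage.map_coordinates(
        np.asarray(frame, dtype=float), [pts[:, 0], pts[:, 1]], order=1, mode="nearest"
    )
    vals = ndimage.uniform_filter1d(vals, 3)
    edge_n = max(4, int(2.0 / step_px))
    bg = float(np.median(np.concatenate([vals[:edge_n], vals[-edge_n:]])))
    peak = float(vals.max())
    if peak - bg < 10.0:
        return None
    half = bg + 0.5 * (peak - bg)
    above = vals >= half
    if not above.any():
        return None
    i_first = int(np.argmax(above))
    i_last = int(len(vals) - 1 - np.argmax(above[::-1]))
    if i_first == 0 or i_last == len(vals) - 1:
        return None  # structure runs off the sampled span

    def cross(i_hi: int, i_lo: int) -> float:
        v_hi, v_lo = vals[i_hi], vals[i_lo]
        if v_hi == v_lo:
            return float(offs[i_hi])
        t = (half - v_lo) / (v_hi - v_lo)
        return float(offs[i_lo] + t * (offs[i_hi] - offs[i_lo]))

    left = cross(i_first, i_first - 1)
    right = cross(i_last, i_last + 1)
    return (
        right - left,
        centre + left * perp,
        centre + right * perp,
    )


def _waist_scan(
    frame: np.ndarray,
    contour: CellContour,
    furrow_axial_px: float,
    axial_window_px: float,
    step: float = 0.5,
    plateau_tol: float = 0.15,
):
    """Locate the interior local width minimum nearest the furrow estimate.

    Returns ``(axial_px, (width, left, right))`` for the centre of the
    (possibly flat) local minimum, or ``None`` when the width profile has no
    interior local minimum in the window — e.g. a shallow furrow where the
    cell simply narrows toward the pole, so the minimum sits at the window
    edge and does not mark a waist.
    """
    dys = np.arange(-axial_window_px, axial_window_px + step / 2, step)
    scans = [_scan_width(frame, contour, furrow_axial_px + dy) for dy in dys]
    widths = np.array([np.nan if s is None else s[0] for s in scans])
    if np.isnan(widths).all():
        return None
    candidates = []  # (|centre dy|, centre dy, index of run minimum)
    n = len(dys)
    for i in range(1, n - 1):
        w = widths[i]
        if np.isnan(w):
            continue
        # expand the near-flat run around i; only near-equal values join the
        # plateau, so a monotone descent toward a pole is never absorbed
        lo = hi = i
        while lo - 1 >= 0 and not np.isnan(widths[lo - 1]) and abs(widths[lo - 1] - w) <= plateau_tol:
            lo -= 1
        while hi + 1 < n and not np.isnan(widths[hi + 1]) and abs(widths[hi + 1] - w) <= plateau_tol:
            hi += 1
        # a genuine waist: the plateau is interior and rises on both sides
        if lo > 0 and hi < n - 1 and widths[lo - 1] > w + plateau_tol and widths[hi + 1] > w + plateau_tol:
            centre = float(dys[lo : hi + 1].mean())
            j = lo + int(np.nanargmin(widths[lo : hi + 1]))
            candidates.append((abs(centre), centre, j))
    if not candidates:
        return None
    _, centre, j = min(candidates)
    return float(furrow_axial_px + centre), scans[j]


def ring_waist(
    frame: np.ndarray,
    contour: CellContour,
    furrow_axial_px: float,
    axial_window_px: float = 3.0,
) -> tuple[float, np.ndarray, np.ndarray] | None:
    """Ring waist near the furrow plane: (diameter px, left edge point,
    right edge point) at the local width minimum nearest the estimate, or —
    if no interior minimum exists — at the narrowest sampled row."""
    found = _waist_scan(frame, contour, furrow_axial_px, axial_window_px)
    if found is not None:
        return found[1]
    best = None
    for dy in np.arange(-axial_window_px, axial_window_px + 0.5, 0.5):
        res = _scan_width(frame, contour, furrow_axial_px + dy)
        if res is not None and (best is None or res[0] < best[0]):
            best = res
    return best


def refine_furrow_axial(
    frame: np.ndarray,
    contour: CellContour,
    furrow_axial_px: float,
    axial_window_px: float = 4.0,
) -> float | None:
    """Axial position of the measured waist near an initial furrow estimate;
    curvature-based detection can sit a couple of pixels off the true waist
    on asymmetric necks.  ``None`` when no interior local minimum exists."""
    found = _waist_scan(frame, contour, furrow_axial_px, axial_window_px)
    return None if found is None else found[0]


def percent_constriction(d: float, d0: float, d_mb: float, clip_tol: float = 0.05) -> float:
    """Linear constriction percentage: 0 % at ``d0``, 100 % at ``d_mb``.

    ``clip_tol`` is the tolerated relative overshoot beyond either anchor
    before the value is clipped into [0, 100].
    """
    if d0 <= d_mb:
        raise ValueError("d0 must exceed the midbody diameter")
    span = d0 - d_mb
    if d > d0 * (1 + clip_tol) + span * clip_tol or d < d_mb - span * clip_tol:
        raise ValueError(f"diameter {d} outside [{d_mb}, {d0}] beyond tolerance")
    pct = 100.0 * (d0 - d) / span
    return float(np.clip(pct, 0.0, 100.0))


def _chord_width_at(contour: CellContour, axial_px: float) -> float:
    """Cell width (px) at a given axial position, from the lateral extent of
    contour vertices near that axial coordinate."""
    ax = contour.axial_coordinate()
    lat = contour.lateral_coordinate()
    for tol in (1.0, 2.0, 4.0):
        near = np.abs(ax - axial_px) <= tol
        if (lat[near] > 0).any() and (lat[near] < 0).any():
            return float(lat[near].max() - lat[near].min())
    raise ValueError("could not measure the cell width at the furrow plane")


def constriction_curve(
    movie: TimeLapseMovie,
    contours: list[CellContour | None] | None = None,
    midbody_diameter_px: float = 4.0,
    smooth_k: int = 2,
    threshold: float = CONCAVITY_THRESHOLD,
) -> pd.DataFrame:
    """Percentage of ring constriction over time from anaphase onset.

    The ring diameter at each frame is the half-maximum waist width of the
    cortical signal at the furrow plane (see :func:`ring_waist`); the
    furrow plane itself is located by concave-curvature detection on that
    frame's contour.  The 0 % anchor ``d0`` is measured on the
    anaphase-onset frame as the cell width at the axial position where the
    furrow first appears (the ring does not exist yet at 0 %, so a
    geometric proxy is needed); the 100 % anchor is ``midbody_diameter_px``
    pixels.  The raw percentage series is made monotone (isotonic cleanup
    by running maximum after onset) and smoothed with a centred moving
    average of ``smooth_k`` neighbours per side.  The result carries a
    ``complete`` flag that is False when the ring never reaches midbody
    size.
    """
    if movie.n_frames < 2:
        raise ValueError("movie must have at least 2 frames")
    if not movie.background_subtracted:
        raise ValueError("subtract the camera background before measuring kinetics")
    if contours is None:
        contours = []
        for frame in movie.frames:
            try:
                contours.append(trace_contour(frame))
            except ValueError:
                contours.append(None)
    onset = detect_ingression_onset(contours, threshold=threshold)
    if onset is None:
        raise ValueError("no ingression detected in the movie")
    px = movie.pixel_size
    d_mb = midbody_diameter_px * px

    onset_contour = contours[onset]
    onset_furrow = detect_furrow(onset_contour, threshold=threshold)
    furrow_axial = float(
        (onset_furrow.midpoint - onset_contour.apical_pole) @ onset_contour.long_axis
    )
    # the onset-frame waist is shallow, so refine the furrow plane on the
    # first nearby frame that shows a genuine interior waist
    for tt in range(onset, min(onset + 4, movie.n_frames)):
        if contours[tt] is None:
            continue
        fp_tt = detect_furrow(contours[tt], threshold=threshold)
        axial_tt = (
            float((fp_tt.midpoint - contours[tt].apical_pole) @ contours[tt].long_axis)
            if fp_tt is not None
            else furrow_axial
        )
        refined = refine_furrow_axial(movie.frames[tt], contours[tt], axial_tt)
        if refined is not None:
            furrow_axial = refined
            break
    ana = movie.anaphase_onset_index
    if contours[ana] is None:
        raise ValueError("no contour at the anaphase-onset frame")
    # the cell is stationary, so the furrow plane of the onset frame can be
    # read directly on the anaphase frame; the onset contour also supplies
    # the axis (a pre-furrow cell is nearly round, so its own principal
    # axis is unreliable)
    d0_px = width_at_axis_position(movie.frames[ana], onset_contour, furrow_axial)
    if d0_px is None:
        d0_px = _chord_width_at(onset_contour, furrow_axial)
    d0 = d0_px * px
    if d0 <= d_mb:
        raise ValueError("measured d0 does not exceed the midbody diameter")

    t_s = movie.times_s()
    diam = np.full(movie.n_frames, np.nan)
    axial = furrow_axial
    for t in range(movie.n_frames):
        c = contours[t]
        if c is None:
            continue
        if t < onset:
            diam[t] = d0
            continue
        fp = detect_furrow(c, threshold=threshold)
        if fp is not None:
            axial = float((fp.midpoint - c.apical_pole) @ c.long_axis)
        waist = ring_waist(movie.frames[t], c, axial)
        if waist is not None:
            diam[t] = waist[0] * px
    pct = np.full(movie.n_frames, np.nan)
    ok = ~np.isnan(diam)
    pct[ok] = np.clip(100.0 * (d0 - diam[ok]) / (d0 - d_mb), 0.0, 100.0)
    pct[: ana + 1] = 0.0
    # isotonic cleanup: constriction cannot reverse
    run = np.fmax.accumulate(np.where(np.isnan(pct), -np.inf, pct))
    pct = np.where(np.isfinite(run), run, np.nan)
    complete = bool(np.nanmax(pct) >= 100.0 - 1e-9)
    if smooth_k > 0:
        # smooth only the ingression phase: the flat pre-onset baseline is
        # exact by definition and must not bleed into the rising segment
        window = 2 * smooth_k + 1
        kernel = np.ones(window) / window
        seg = pd.Series(pct[onset:]).ffill().bfill().to_numpy()
        # odd reflection continues the local slope, so a linear ramp is
        # smoothed without end bias
        padded = np.pad(seg, smooth_k, mode="reflect", reflect_type="odd")
        smoothed = np.convolve(padded, kernel, mode="valid")
        pct[onset:] = np.where(np.isnan(pct[onset:]), np.nan, smoothed)
    return pd.DataFrame(
        {
            "frame": np.arange(movie.n_frames),
            "t_s": t_s,
            "ring_diameter_um": diam,
            "percent": pct,
            "complete": complete,
        }
    )


def cohort_average_curve(curves: list[pd.DataFrame], smooth_k: int = 2) -> pd.DataFrame:
    """Average per-cell constriction curves on their common time grid."""
    if not curves:
        raise ValueError("no curves to average")
    merged = pd.concat([c[["t_s", "percent"]] for c in curves])
    mean = merged.groupby("t_s", sort=True)["percent"].mean().reset_index()
    if smooth_k > 0:
        window = 2 * smooth_k + 1
        mean["percent"] = (
            mean["percent"].rolling(window, center=True, min_periods=1).mean()
        )
    return mean


def furrow_basal_distance(
    contour: CellContour, furrow_midpoint: np.ndarray, pixel_size: float
) -> float:
    """Projection of (basal pole - furrow midpoint) onto the long axis, µm."""
    rel = contour.basal_pole - np.asarray(furrow_midpoint, dtype=float)
    return float(rel @ contour.long_axis) * pixel_size


def measured_basal_distance(
    frame: np.ndarray,
    contour: CellContour,
    furrow: FurrowPoints,
    pixel_size: float,
) -> float:
    """Furrow-to-basal-pole distance with the furrow plane refined to the
    measured waist when the width profile shows one (the curvature point
    alone can sit a pixel or two off the waist on asymmetric necks)."""
    axial = float((furrow.midpoint - contour.apical_pole) @ contour.long_axis)
    refined = refine_furrow_axial(frame, contour, axial)
    if refined is not None:
        axial = refined
    basal_axial = float((contour.basal_pole - contour.apical_pole) @ contour.long_axis)
    return (basal_axial - axial) * pixel_size


def furrow_segment(
    contour: CellContour,
    furrow_index: int,
    angle_threshold_deg: float = 30.0,
) -> tuple[float, float]:
    """Arclength-fraction interval of the furrow around a detected furrow point.

    The furrow extends over the maximal contiguous run of contour samples
    around ``furrow_index`` whose tangent diverges from the long axis by
    less than ``angle_threshold_deg`` (ingressed furrow walls run parallel
    to the axis).  The interval is returned as contour arclength fractions
    and may be degenerate when even the furrow-point tangent diverges more
    than the threshold (shallow furrow).  ``hi`` may exceed 1 when the
    segment wraps past the contour start (membership test:
    ``(frac - lo) % 1 <= hi - lo``).
    """
    if not 0.0 < angle_threshold_deg < 90.0:
        raise ValueError("angle threshold must lie in (0, 90) degrees")
    tang = _geom.tangents(contour.points)
    cosang = np.abs(tang @ contour.long_axis)
    ok = cosang > np.cos(np.deg2rad(angle_threshold_deg))
    n = contour.n_points
    # the maximal-curvature sample can sit on the shoulder corner of a
    # tube-like neck, where the tangent itself diverges; seed the walk from
    # the best-aligned sample in its immediate neighbourhood
    nb = np.arange(furrow_index - max(2, n // 40), furrow_index + max(2, n // 40) + 1) % n
    start = int(nb[np.argmax(cosang[nb])])
    lo = hi = start if ok[start] else furrow_index
    if ok[lo]:
        while ok[(lo - 1) % n] and (start - lo) < n // 2 - 1:
            lo -= 1
        while ok[(hi + 1) % n] and (hi - start) < n // 2 - 1:
            hi += 1
    s = _geom.cumulative_arclength(contour.points, closed=True)
    total = s[-1]
    lo_s = s[lo % n] - (total if lo < 0 else 0.0)
    hi_s = s[hi % n] + (total if hi >= n else 0.0)
    return (float(lo_s / total), float(hi_s / total))


def segment_on_profile(profile, lo_frac: float, hi_frac: float) -> tuple[float, float] | None:
    """Map a contour arclength-fraction interval onto a side profile's own
    arclength, using the profile's recorded contour fractions.  Returns
    ``None`` when the interval does not intersect the profile."""
    if profile.contour_fractions is None:
        raise ValueError("profile does not carry contour fractions")
    span = hi_frac - lo_frac
    inside = (profile.contour_fractions - lo_frac) % 1.0 <= span
    if not inside.any():
        return None
    arc = profile.arclength[inside]
    return (float(arc.min()), float(arc.max()))


def furrow_width_um(
    contour: CellContour,
    furrow_index: int,
    pixel_size: float,
    angle_threshold_deg: float = 30.0,
) -> float:
    """Arclength extent (µm) of the furrow segment on one side."""
    lo, hi = furrow_segment(contour, furrow_index, angle_threshold_deg)
    return (hi - lo) * _geom.perimeter(contour.points) * pixel_size
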