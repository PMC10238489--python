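"""Synthetic time-lapse generator for asymmetric cytokinesis with ground truth.

The phantom emulates a large (~11 µm) asymmetrically dividing cell imaged on
a single sagittal plane with a myosin-type cortical marker: a cortical band,
a contractile ring that constricts from its initial diameter ``d0`` down to
midbody size ``d_mb`` on a piecewise-linear schedule, an optional transient
polar-cortex enrichment pulse peaking near 80 % ingression, and EMCCD-style
noise (Poisson shot noise on the signal, a constant camera offset, Gaussian
read noise).

Geometry model
--------------
The cell starts as a disk of radius ``R`` whose long axis runs apical (top
row) to basal (bottom row).  Once ingression starts, the outline is built
from an axial half-width profile ``w(y)``: two lobes (neuroblast, apical;
ganglion mother cell, basal) joined at the furrow plane, each lobe a smooth
pole-rounded profile whose cross-section area is prescribed in closed form.
The furrow half-width is pinned exactly to ``d(t)/2`` and the basal lobe
area follows the circular-segment area of the initial disk cut at the
current furrow-to-basal-pole distance, so total area is conserved and the
final daughter-cell size is an analytic function of where the furrow ends
up.  The furrow either stays where it formed (``correction_on=False``;
daughter size then grows strictly with the initial basal offset) or drifts
during constriction toward the position that yields a set target area
(``correction_on=True``; daughter size then becomes independent of the
initial offset) — the two regimes whose contrast the downstream correlation
analysis is designed to detect.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import tifffile
from scipy import ndimage, optimize
from scipy.spatial import cKDTree
from furrowquant import _geom
from furrowquant.cortexprofile import TimeLapseMovie

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "IntensityModel",
    "simulate_division",
    "furrow_trajectory",
    "render_frame",
    "circular_segment_area",
]


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class SimulationParams:
    """Physical and imaging parameters of one synthetic division.

    Lengths in µm, times in s, intensities in camera a.u.  Defaults describe
    a large neuroblast-like cell (radius 5.5 µm) imaged every 20 s at
    0.16 µm/px with the polar myosin pulse peaking at 80 % constriction.
    """

    neuroblast_radius: float = 5.5
    gmc_radius: float = 2.0
    initial_furrow_basal_distance: float = 2.5
    initial_ring_diameter: float | None = None  # None: chord of the disk at delta0
    midbody_diameter: float | None = None  # None: midbody_diameter_px * pixel_size
    midbody_diameter_px: float = 4.0
    n_frames: int = 16
    frame_interval: float = 20.0
    pixel_size: float = 0.16
    image_shape: tuple[int, int] = (96, 96)
    anaphase_onset_frame: int = 1
    ingression_onset_frame: int = 3
    midbody_frame: int = 13
    cortical_band_width: float = 0.8
    ring_focus_sigma: float = 0.04  # arclength fraction
    ring_amplitude: float = 400.0
    polar_enrichment_amplitude: float = 0.0  # E
    polar_peak_constriction: float = 0.80
    polar_pulse_sigma: float = 0.15  # sigma_E, in constriction fraction
    cytoplasm_intensity: float = 120.0
    cortex_base_intensity: float = 300.0
    psf_sigma: float = 0.1  # optical blur of the signal, µm (diffraction limit at NA 1.4)
    camera_offset: float = 100.0
    read_noise_sd: float = 3.0
    shot_noise: bool = True
    correction_on: bool = False
    target_gmc_area: float | None = None  # None: pi * gmc_radius**2
    neck_elongation: float = 0.8  # intercellular-bridge (tube) length at the furrow, µm
    gmc_elongation: float = 0.0  # fractional axial stretch of the basal lobe
    neck_smooth_sigma: float = 0.15  # axial smoothing of the width profile, µm
    n_contour_points: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "neuroblast_radius",
            "gmc_radius",
            "initial_furrow_basal_distance",
            "frame_interval",
            "pixel_size",
            "cortical_band_width",
            "ring_focus_sigma",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v!r}")
        for name in (
            "ring_amplitude",
            "polar_enrichment_amplitude",
            "polar_pulse_sigma",
            "cytoplasm_intensity",
            "cortex_base_intensity",
            "camera_offset",
            "psf_sigma",
            "read_noise_sd",
            "neck_elongation",
            "gmc_elongation",
            "neck_smooth_sigma",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v!r}")
        if not 0.0 <= self.polar_peak_constriction <= 1.0:
            raise ValueError("polar_peak_constriction must lie in [0, 1]")
        if self.midbody_diameter is not None and (
            not np.isfinite(self.midbody_diameter) or self.midbody_diameter <= 0
        ):
            raise ValueError("midbody_diameter must be finite and positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if not 0 <= self.anaphase_onset_frame <= self.ingression_onset_frame:
            raise ValueError("need 0 <= anaphase_onset_frame <= ingression_onset_frame")
        if not self.ingression_onset_frame < self.midbody_frame <= self.n_frames - 1:
            raise ValueError("need ingression_onset_frame < midbody_frame <= n_frames - 1")
        if self.initial_furrow_basal_distance >= 2 * self.neuroblast_radius:
            raise ValueError("initial_furrow_basal_distance exceeds the cell length")
        if self.ring_diameter_at_onset() <= self.midbody_diameter_um():
            raise ValueError("midbody diameter must be smaller than the initial ring diameter")

    def midbody_diameter_um(self) -> float:
        if self.midbody_diameter is not None:
            return self.midbody_diameter
        return self.midbody_diameter_px * self.pixel_size

    def ring_diameter_at_onset(self) -> float:
        """d0: explicit value, or the disk chord at the initial furrow plane."""
        if self.initial_ring_diameter is not None:
            return self.initial_ring_diameter
        r, h = self.neuroblast_radius, self.initial_furrow_basal_distance
        return 2.0 * float(np.sqrt(h * (2 * r - h)))

    def target_gmc_area_um2(self) -> float:
        if self.target_gmc_area is not None:
            return self.target_gmc_area
        return float(np.pi * self.gmc_radius**2)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_shape"] = list(self.image_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        d = dict(d)
        if "image_shape" in d:
            d["image_shape"] = tuple(d["image_shape"])
        return cls(**d)


# ---------------------------------------------------------------------------
# analytic geometry
# ---------------------------------------------------------------------------


def circular_segment_area(radius: float, height: float) -> float:
    """Area of the circular segment (cap cross-section) of a disk of given
    ``radius`` cut at ``height`` from the rim, both in µm."""
    if not 0 <= height <= 2 * radius:
        raise ValueError("segment height must lie in [0, 2R]")
    r, h = radius, height
    return float(r * r * np.arccos((r - h) / r) - (r - h) * np.sqrt(2 * r * h - h * h))


def _segment_height_for_area(radius: float, area: float) -> float:
    """Invert the circular-segment area for the cut height (brentq)."""
    total = np.pi * radius**2
    if not 0 < area < total:
        raise ValueError("target area must lie strictly between 0 and the disk area")
    return float(
        optimize.brentq(lambda h: circular_segment_area(radius, h) - area, 1e-9, 2 * radius - 1e-9)
    )


def ring_diameter_schedule(params: SimulationParams) -> np.ndarray:
    """True ring diameter per frame (µm): flat at ``d0`` before ingression,
    linear decline reaching ``d_mb`` at the midbody frame, flat after."""
    d0 = params.ring_diameter_at_onset()
    dmb = params.midbody_diameter_um()
    t = np.arange(params.n_frames, dtype=float)
    start = params.ingression_onset_frame - 1  # last frame at d0
    frac = np.clip((t - start) / (params.midbody_frame - start), 0.0, 1.0)
    d = d0 + frac * (dmb - d0)
    d[t >= params.midbody_frame] = dmb  # exact anchor, no float residue
    return d


def constriction_fraction(params: SimulationParams) -> np.ndarray:
    d0 = params.ring_diameter_at_onset()
    dmb = params.midbody_diameter_um()
    return (d0 - ring_diameter_schedule(params)) / (d0 - dmb)


def polar_pulse_schedule(params: SimulationParams) -> np.ndarray:
    """E(t) = E * exp(-(c(t) - peak)^2 / (2 sigma_E^2))."""
    e = params.polar_enrichment_amplitude
    if e == 0:
        return np.zeros(params.n_frames)
    c = constriction_fraction(params)
    return e * np.exp(-((c - params.polar_peak_constriction) ** 2) / (2 * params.polar_pulse_sigma**2))


def furrow_trajectory(params: SimulationParams) -> np.ndarray:
    """Per-frame furrow-to-basal-pole distance along the long axis (µm).

    Without correction the furrow stays at its initial offset ``delta0``;
    with correction it drifts smoothly during constriction toward the offset
    whose circular-segment area equals the target daughter-cell area, making
    the final size independent of ``delta0``.
    """
    delta0 = params.initial_furrow_basal_distance
    if delta0 >= 2 * params.neuroblast_radius:
        raise ValueError("initial_furrow_basal_distance exceeds the cell length")
    if not params.correction_on:
        return np.full(params.n_frames, delta0)
    delta_star = _segment_height_for_area(params.neuroblast_radius, params.target_gmc_area_um2())
    c = constriction_fraction(params)
    blend = c * c * (3.0 - 2.0 * c)  # smoothstep in constriction fraction
    return delta0 + (delta_star - delta0) * blend


def _lobe_halfwidth(u: np.ndarray, length: float, area: float, neck_halfwidth: float) -> np.ndarray:
    """Half-width of one lobe at normalised axial position u (0 pole, 1 furrow).

    Family w(u) = (d/2) u + B sqrt(u)(1 - u); B is set so the lobe area
    2 L \\int w du equals ``area`` exactly:  area = 2 L (d/4 + 4 B / 15).
    """
    b = (area / (2.0 * length) - neck_halfwidth / 2.0) * 15.0 / 4.0
    if b < 0:
        raise ValueError("geometry infeasible: lobe area too small for the neck diameter")
    return neck_halfwidth * u + b * np.sqrt(u) * (1.0 - u)


def _twolobe_profile(
    params: SimulationParams, delta: float, d: float, gmc_elongation: float = 0.0
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Axial grid y (µm from the apical pole), half-width w(y), furrow plane
    y_f, and the quadrature area basal of the furrow plane."""
    r = params.neuroblast_radius
    tube = params.neck_elongation
    l_gmc = delta * (1.0 + gmc_elongation)
    l_nb = 2.0 * r - delta
    total = l_nb + tube + l_gmc
    y_f = l_nb + tube / 2.0

    a_gmc = circular_segment_area(r, delta)
    a_nb = np.pi * r * r - a_gmc

    dy = params.pixel_size / 2.0
    y = np.linspace(0.0, total, max(int(np.ceil(total / dy)) + 1, 64))
    in_nb = y <= l_nb
    in_tube = (y > l_nb) & (y < l_nb + tube)
    in_gmc = y >= l_nb + tube

    def build(a_nb_: float, a_gmc_: float) -> np.ndarray:
        w = np.empty_like(y)
        w[in_nb] = _lobe_halfwidth(y[in_nb] / l_nb, l_nb, a_nb_, d / 2.0)
        w[in_tube] = d / 2.0
        w[in_gmc] = _lobe_halfwidth(
            np.clip((total - y[in_gmc]) / l_gmc, 0.0, 1.0), l_gmc, a_gmc_, d / 2.0
        )
        if params.neck_smooth_sigma > 0:
            sigma = params.neck_smooth_sigma / (y[1] - y[0])
            w = ndimage.gaussian_filter1d(w, sigma, mode="nearest")
            w[0] = w[-1] = 0.0
            # restore the exact neck half-width, smoothly
            wf = float(np.interp(y_f, y, w))
            corr = (wf - d / 2.0) * np.exp(
                -((y - y_f) ** 2) / (2 * params.neck_smooth_sigma**2 * 4)
            )
            w = np.clip(w - corr, 0.0, None)
        return w

    def lobe_areas(w: np.ndarray) -> tuple[float, float]:
        basal = y >= y_f
        a_b = float(np.trapezoid(2.0 * w[basal], y[basal]))
        a_a = float(np.trapezoid(2.0 * w[~basal], y[~basal]))
        return a_a, a_b

    # the neck smoothing and restore shave a few percent off each lobe;
    # one proportional re-targeting brings the realised areas back on spec
    w = build(a_nb, a_gmc)
    got_nb, got_gmc = lobe_areas(w)
    adj_nb = a_nb + (a_nb - got_nb)
    adj_gmc = a_gmc + (a_gmc - got_gmc)
    try:
        w = build(max(adj_nb, 1e-6), max(adj_gmc, 1e-6))
    except ValueError:
        pass  # keep the uncompensated profile if the adjustment is infeasible
    basal = y >= y_f
    gmc_area = float(np.trapezoid(2.0 * w[basal], y[basal]))
    return y, w, y_f, gmc_area


def _profile_to_contour(
    y: np.ndarray, w: np.ndarray, params: SimulationParams
) -> tuple[np.ndarray, float, float]:
    """Closed (row, col) pixel contour from an axial half-width profile,
    centred in the image; returns (contour, row of y=0, centre col)."""
    h, wid = params.image_shape
    px = params.pixel_size
    row0 = (h - y[-1] / px) / 2.0
    col_c = wid / 2.0
    rows = row0 + y / px
    right = np.column_stack([rows, col_c + w / px])
    left = np.column_stack([rows[::-1], col_c - w[::-1] / px])
    contour = np.vstack([right, left[1:-1]])
    # drop consecutive duplicates (the poles appear on both sides)
    keep = np.concatenate([[True], np.linalg.norm(np.diff(contour, axis=0), axis=1) > 1e-9])
    contour = contour[keep]
    contour = _geom.ensure_positive_orientation(contour)
    return _geom.resample_closed(contour, params.n_contour_points), row0, col_c


def _circle_contour(params: SimulationParams) -> tuple[np.ndarray, float, float]:
    h, wid = params.image_shape
    r_px = params.neuroblast_radius / params.pixel_size
    theta = np.linspace(0, 2 * np.pi, params.n_contour_points, endpoint=False)
    rows = h / 2.0 + r_px * np.cos(theta + np.pi)  # start at the apical pole
    cols = wid / 2.0 + r_px * np.sin(theta + np.pi)
    contour = _geom.ensure_positive_orientation(np.column_stack([rows, cols]))
    return contour, h / 2.0 - r_px, wid / 2.0


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


@dataclass
class IntensityModel:
    """Noise-free intensity model for one frame, in camera a.u. and px."""

    cytoplasm: float
    cortex_base: float
    band_width_px: float
    ring_amplitude: float = 0.0
    ring_sigma_frac: float = 0.04
    ring_fracs: tuple[float, float] | None = None  # arclength fractions of the ring
    polar_level: float = 0.0  # uniform cortical addition, = base * E(t)


def _coverage(shape: tuple[int, int], contour: np.ndarray, supersample: int = 8) -> np.ndarray:
    """Anti-aliased interior coverage fraction per pixel.

    Rasterising the polygon on a supersampled grid and block-averaging makes
    the rendered edge profile cross half its plateau exactly at the true
    boundary, so edge positions survive into the image without the half-pixel
    dilation of a binary mask.
    """
    from PIL import Image, ImageDraw

    ss = supersample
    img = Image.new("1", (shape[1] * ss, shape[0] * ss), 0)
    xy = [(c * ss + (ss - 1) / 2.0, r * ss + (ss - 1) / 2.0) for r, c in contour]
    ImageDraw.Draw(img).polygon(xy, fill=1)
    big = np.asarray(img, dtype=float)
    return big.reshape(shape[0], ss, shape[1], ss).mean(axis=(1, 3))


def _model_frame(shape: tuple[int, int], contour: np.ndarray, model: IntensityModel) -> np.ndarray:
    cov = _coverage(shape, contour)
    img = np.zeros(shape, dtype=float)
    if not cov.any():
        return img
    inside = cov >= 0.5
    touched = cov > 0
    value = np.zeros(shape, dtype=float)
    value[touched] = model.cytoplasm
    dist_in = ndimage.distance_transform_edt(inside)
    band = touched & (dist_in <= model.band_width_px)
    if band.any():
        px = np.column_stack(np.nonzero(band)).astype(float)
        tree = cKDTree(contour)
        _, nearest = tree.query(px)
        fracs = nearest / len(contour)
        cortex = np.full(len(px), model.cortex_base + model.polar_level)
        if model.ring_fracs is not None and model.ring_amplitude > 0:
            bump = np.zeros(len(px))
            for f in model.ring_fracs:
                dfr = _geom.circ_frac_distance(fracs, f)
                bump += np.exp(-(dfr**2) / (2 * model.ring_sigma_frac**2))
            cortex = cortex + model.ring_amplitude * np.minimum(bump, 1.0)
        value[band.nonzero()] = value[band.nonzero()] + cortex
    return value * cov


def render_frame(
    shape: tuple[int, int],
    contour: np.ndarray | None,
    model: IntensityModel,
    camera_offset: float = 0.0,
    read_noise_sd: float = 0.0,
    shot_noise: bool = False,
    psf_sigma_px: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Render one frame: model signal inside the contour, blurred by the
    optical PSF, camera offset everywhere, optional Poisson shot noise on
    the signal and Gaussian read noise on top.  Deterministic for a fixed
    ``rng`` seed.

    An empty contour yields an offset-only frame; a self-intersecting
    contour is rejected.
    """
    if contour is not None and len(contour) > 0:
        if not _geom.is_simple_closed(np.asarray(contour, dtype=float)):
            raise ValueError("contour must be a simple (non self-intersecting) closed polyline")
        signal = _model_frame(shape, np.asarray(contour, dtype=float), model)
        if psf_sigma_px > 0:
            signal = ndimage.gaussian_filter(signal, psf_sigma_px)
    else:
        signal = np.zeros(shape, dtype=float)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if shot_noise:
        signal = rng.poisson(signal).astype(float)
    img = signal + camera_offset
    if read_noise_sd > 0:
        img = img + rng.normal(0.0, read_noise_sd, size=shape)
    return np.clip(img, 0.0, None)


# ---------------------------------------------------------------------------
# ground truth and the full simulation
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Per-frame truth of a synthetic division, all lengths in µm, contours
    and furrow points in px ``(row, col)``."""

    contours: list[np.ndarray]
    furrow_left: np.ndarray  # (T, 2), NaN before the ring forms
    furrow_right: np.ndarray
    ring_diameter_um: np.ndarray
    constriction: np.ndarray  # fraction in [0, 1]
    polar_pulse: np.ndarray  # E(t)
    basal_distance_um: np.ndarray
    gmc_area_um2: np.ndarray  # quadrature area basal of the furrow plane
    apical_pole_px: np.ndarray  # (T, 2)
    basal_pole_px: np.ndarray
    delta0: float
    anaphase_onset_frame: int
    ingression_onset_frame: int
    midbody_frame: int
    pixel_size: float

    @property
    def final_gmc_area_um2(self) -> float:
        return float(self.gmc_area_um2[-1])

    def to_json(self, path) -> None:
        payload = {
            "contours": [c.tolist() for c in self.contours],
            "furrow_left": self.furrow_left.tolist(),
            "furrow_right": self.furrow_right.tolist(),
            "ring_diameter_um": self.ring_diameter_um.tolist(),
            "constriction": self.constriction.tolist(),
            "polar_pulse": self.polar_pulse.tolist(),
            "basal_distance_um": self.basal_distance_um.tolist(),
            "gmc_area_um2": self.gmc_area_um2.tolist(),
            "apical_pole_px": self.apical_pole_px.tolist(),
            "basal_pole_px": self.basal_pole_px.tolist(),
            "delta0": self.delta0,
            "anaphase_onset_frame": self.anaphase_onset_frame,
            "ingression_onset_frame": self.ingression_onset_frame,
            "midbody_frame": self.midbody_frame,
            "pixel_size": self.pixel_size,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["contours"] = [np.asarray(c, dtype=float) for c in payload["contours"]]
        for key in (
            "furrow_left",
            "furrow_right",
            "ring_diameter_um",
            "constriction",
            "polar_pulse",
            "basal_distance_um",
            "gmc_area_um2",
            "apical_pole_px",
            "basal_pole_px",
        ):
            payload[key] = np.asarray(payload[key], dtype=float)
        return cls(**payload)


def simulate_division(params: SimulationParams) -> tuple[TimeLapseMovie, GroundTruth]:
    """Generate one synthetic division movie and its ground truth.

    Frames before ingression onset show the undeformed disk; from anaphase
    onset the contractile ring is rendered at the furrow plane, and from
    ingression onset the outline follows the two-lobe neck geometry with the
    scheduled ring diameter.  Identical parameters (including ``seed``) give
    byte-identical movies.
    """
    t_frames = params.n_frames
    px = params.pixel_size
    d_sched = ring_diameter_schedule(params)
    c_sched = constriction_fraction(params)
    e_sched = polar_pulse_schedule(params)
    deltas = furrow_trajectory(params)

    rng = np.random.default_rng(params.seed)
    band_px = params.cortical_band_width / px

    contours: list[np.ndarray] = []
    furrow_l = np.full((t_frames, 2), np.nan)
    furrow_r = np.full((t_frames, 2), np.nan)
    apical = np.zeros((t_frames, 2))
    basal = np.zeros((t_frames, 2))
    gmc_area = np.zeros(t_frames)
    basal_dist = np.zeros(t_frames)
    frames = np.zeros((t_frames, *params.image_shape))

    r = params.neuroblast_radius
    for t in range(t_frames):
        delta = float(deltas[t])
        if c_sched[t] <= 0:
            contour, row0, col_c = _circle_contour(params)
            y_f = 2 * r - delta
            half_w = float(np.sqrt(max(delta * (2 * r - delta), 0.0)))
            row_f = row0 + y_f / px
            total_len = 2 * r
            gmc_area[t] = circular_segment_area(r, delta)
        else:
            # lobe elongation (a late-division shape phenotype) develops in
            # proportion to constriction so early geometry stays feasible
            y, w, y_f, a_gmc = _twolobe_profile(
                params, delta, float(d_sched[t]), params.gmc_elongation * float(c_sched[t])
            )
            contour, row0, col_c = _profile_to_contour(y, w, params)
            half_w = float(d_sched[t]) / 2.0
            row_f = row0 + y_f / px
            total_len = float(y[-1])
            gmc_area[t] = a_gmc
        contours.append(contour)
        apical[t] = (row0, col_c)
        basal[t] = (row0 + total_len / px, col_c)
        basal_dist[t] = total_len - y_f if c_sched[t] > 0 else delta
        if t >= params.anaphase_onset_frame:
            furrow_l[t] = (row_f, col_c - half_w / px)
            furrow_r[t] = (row_f, col_c + half_w / px)
            ring_fracs = _ring_fracs(contour, furrow_l[t], furrow_r[t])
        else:
            ring_fracs = None
        model = IntensityModel(
            cytoplasm=params.cytoplasm_intensity,
            cortex_base=params.cortex_base_intensity,
            band_width_px=band_px,
            ring_amplitude=params.ring_amplitude,
            ring_sigma_frac=params.ring_focus_sigma,
            ring_fracs=ring_fracs,
            polar_level=params.cortex_base_intensity * float(e_sched[t]),
        )
        frames[t] = render_frame(
            params.image_shape,
            contour,
            model,
            camera_offset=params.camera_offset,
            read_noise_sd=params.read_noise_sd,
            shot_noise=params.shot_noise,
            psf_sigma_px=params.psf_sigma / px,
            rng=rng,
        )

    movie = TimeLapseMovie(
        frames=frames,
        pixel_size=px,
        frame_interval=params.frame_interval,
        anaphase_onset_index=params.anaphase_onset_frame,
        background_subtracted=False,
    )
    truth = GroundTruth(
        contours=contours,
        furrow_left=furrow_l,
        furrow_right=furrow_r,
        ring_diameter_um=d_sched,
        constriction=c_sched,
        polar_pulse=e_sched,
        basal_distance_um=basal_dist,
        gmc_area_um2=gmc_area,
        apical_pole_px=apical,
        basal_pole_px=basal,
        delta0=params.initial_furrow_basal_distance,
        anaphase_onset_frame=params.anaphase_onset_frame,
        ingression_onset_frame=params.ingression_onset_frame,
        midbody_frame=params.midbody_frame,
        pixel_size=px,
    )
    return movie, truth


def _ring_fracs(contour: np.ndarray, left: np.ndarray, right: np.ndarray) -> tuple[float, float]:
    tree = cKDTree(contour)
    _, i_l = tree.query(left)
    _, i_r = tree.query(right)
    n = len(contour)
    return (float(i_l) / n, float(i_r) / n)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def write_movie(path, movie: TimeLapseMovie) -> None:
    """Write the movie as a multi-page 16-bit TIFF."""
    data = np.clip(np.round(movie.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")


def read_movie(
    path,
    pixel_size: float,
    frame_interval: float = 20.0,
    anaphase_onset_index: int = 0,
    background_subtracted: bool = False,
) -> TimeLapseMovie:
    frames = tifffile.imread(path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    return TimeLapseMovie(
        frames=frames,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        anaphase_onset_index=anaphase_onset_index,
        background_subtracted=background_subtracted,
    )
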