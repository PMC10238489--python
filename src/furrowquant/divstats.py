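"""Cohort statistics and the in-silico furrow-position-correction experiment.

The statistical toolbox mirrors what the cytokinesis figures report:
two-tailed Mann-Whitney tests between genotypes (exact by enumeration for
small tie-free samples, tie-corrected normal approximation otherwise),
Pearson r / R² with a two-tailed t-transform p value, and median with
interquartile range for scatter-dot-plot bars.

:func:`correlation_experiment` reproduces the furrow-position-correction
contrast end to end on synthetic cohorts: without correction the initial
furrow basal offset predicts the final daughter-cell area (strong positive
correlation); with correction the two decouple (R² near zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

import scipy.ndimage as ndi
from skimage import draw

from furrowquant import furrowkinetics, morphometrics
from furrowquant.cortexprofile import (
    TimeLapseMovie,
    cortical_enrichment,
    cytoplasm_mean,
    subtract_camera_background,
    trace_contour,
)
from furrowquant.synthmovie import SimulationParams, simulate_division

__all__ = [
    "StatResult",
    "DivisionMeasurement",
    "CorrelationReport",
    "mann_whitney_two_tailed",
    "pearson_r2",
    "median_iqr",
    "measure_division_geometry",
    "simulate_cohort",
    "correlation_experiment",
]

#: combined sample size up to which the exact Mann-Whitney null is used
EXACT_SWITCH_N = 20


@dataclass
class StatResult:
    method: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    exact: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p value outside [0, 1]")


def mann_whitney_two_tailed(x, y) -> StatResult:
    """Two-tailed Mann-Whitney U test with 0.5 credit for ties.

    The exact null distribution (full enumeration over label arrangements)
    is used when the combined sample size is at most 20 and there are no
    ties; otherwise the normal approximation with tie-corrected variance and
    continuity correction, with two-sided p = min(1, 2 * one-sided).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (x.size + y.size <= EXACT_SWITCH_N) and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return StatResult(
        method="mann-whitney",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n=(int(x.size), int(y.size)),
        exact=exact,
    )


def pearson_r2(x, y) -> tuple[float, float, float]:
    """Pearson product-moment r, R² = r², and the two-tailed p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the samples")
    r, p = stats.pearsonr(x, y)
    return float(r), float(r * r), float(p)


def median_iqr(sample) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear-interpolation (type-7) quantiles."""
    a = np.asarray(sample, dtype=float)
    if a.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(a, [25.0, 50.0, 75.0])
    return float(med), float(q1), float(q3)


# ---------------------------------------------------------------------------
# full-pipeline measurement of synthetic cohorts
# ---------------------------------------------------------------------------


def _cortex_band_fractions(
    frame_shape: tuple[int, int], contour, band_width_px: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel indices of the cortical band and the contour arclength fraction
    of each band pixel (by nearest contour vertex)."""
    from scipy.spatial import cKDTree

    mask = draw.polygon2mask(frame_shape, contour.points)
    dist = ndi.distance_transform_edt(mask)
    band = mask & (dist <= band_width_px)
    px = np.column_stack(np.nonzero(band))
    _, nearest = cKDTree(contour.points).query(px.astype(float))
    return px, nearest / contour.n_points


def polar_enrichment_index(
    movie: TimeLapseMovie,
    camera_offset: float = 0.0,
    band_width_px: float = 2.0,
    furrow_exclusion_frac: float = 0.08,
) -> tuple[float, int]:
    """Myosin cortical enrichment (cortex - cyto) / cyto at the frame of
    maximal polar signal.

    For every frame from anaphase onset the mean grey value of the cortical
    band is taken over the polar cortex — band pixels more than
    ``furrow_exclusion_frac`` of the contour arclength away from either
    detected furrow point — and referenced to the cytoplasmic mean.  The
    polar myosin pulse peaks near 80 % ingression, so the index is the
    maximum over frames; returns ``(index, frame)``.
    """
    if not movie.background_subtracted:
        movie = subtract_camera_background(movie, camera_offset)
    best = (-np.inf, -1)
    for t in range(movie.anaphase_onset_index, movie.n_frames):
        try:
            contour = trace_contour(movie.frames[t])
        except ValueError:
            continue
        fp = furrowkinetics.detect_furrow(contour)
        if fp is None:
            # the polar pulse peaks during ingression; pre-furrow frames are
            # not candidates for the maximum
            continue
        px, fracs = _cortex_band_fractions(movie.frames.shape[1:], contour, band_width_px)
        if len(px) == 0:
            continue
        keep = np.ones(len(px), dtype=bool)
        for idx in (fp.left_index, fp.right_index):
            d = np.abs(fracs - idx / contour.n_points)
            keep &= np.minimum(d, 1.0 - d) > furrow_exclusion_frac
        if not keep.any():
            continue
        vals = movie.frames[t][px[keep, 0], px[keep, 1]]
        try:
            cyto = cytoplasm_mean(movie.frames[t], contour)
        except ValueError:
            continue
        if cyto <= 0:
            continue
        index = cortical_enrichment(float(vals.mean()), cyto)
        if index > best[0]:
            best = (index, t)
    if best[1] < 0:
        raise ValueError("no frame yielded a polar cortex measurement")
    return best


def cortex_furrow_ratio_index(
    movie: TimeLapseMovie,
    camera_offset: float = 0.0,
    frame: int | None = None,
    min_window_frac: float = 0.02,
) -> float:
    """Polar-cortex to furrow mean-intensity ratio along a pole-to-pole
    linescan, cytoplasm-subtracted.

    Measured at ``frame`` (default: the frame of maximal polar signal).
    The furrow window is the contour stretch whose tangent diverges < 30°
    from the long axis, padded to at least ``min_window_frac`` of the
    profile around the furrow point.  Ratios above those of a ring-focused
    cell indicate myosin spread away from the furrow.
    """
    from furrowquant.cortexprofile import cortex_to_furrow_ratio, pole_to_pole_profile

    if not movie.background_subtracted:
        movie = subtract_camera_background(movie, camera_offset)
    if frame is None:
        _, frame = polar_enrichment_index(movie)
    contour = trace_contour(movie.frames[frame])
    fp = furrowkinetics.detect_furrow(contour)
    if fp is None:
        raise ValueError(f"no furrow detected at frame {frame}")
    profile = pole_to_pole_profile(movie.frames[frame], contour)
    f_idx = fp.left_index if profile.side == "left" else fp.right_index
    lo, hi = furrowkinetics.furrow_segment(contour, f_idx)
    seg = furrowkinetics.segment_on_profile(profile, lo, hi)
    centre = (
        float(np.mean(seg))
        if seg is not None
        else float(
            profile.arclength[
                np.argmin(np.abs(profile.contour_fractions - f_idx / contour.n_points))
            ]
        )
    )
    half = max(min_window_frac, 0.0 if seg is None else (seg[1] - seg[0]) / 2.0)
    window = (max(0.0, centre - half), min(1.0, centre + half))
    cyto = cytoplasm_mean(movie.frames[frame], contour)
    return cortex_to_furrow_ratio(profile, window, cyto)


@dataclass
class DivisionMeasurement:
    """Geometry read-outs of one division, measured from the rendered movie."""

    cell_id: str
    group: str
    delta0_true: float
    onset_frame: int
    initial_basal_distance_um: float
    gmc_area_um2: float
    gmc_roundness: float


def measure_division_geometry(
    movie: TimeLapseMovie,
    camera_offset: float,
    cell_id: str = "cell",
    group: str = "",
    delta0_true: float = float("nan"),
) -> DivisionMeasurement:
    """Trace the cell, time ingression onset, and measure the furrow's
    initial basal offset and the final daughter-cell area and roundness,
    all from the rendered frames (the ground truth is never consulted)."""
    if not movie.background_subtracted:
        movie = subtract_camera_background(movie, camera_offset)

    # contours are traced lazily: onset is found scanning forward, the final
    # furrow scanning backward, so mid-movie frames need no tracing
    cache: dict[int, object] = {}

    def contour_at(t: int):
        if t not in cache:
            try:
                cache[t] = trace_contour(movie.frames[t])
            except ValueError:
                cache[t] = None
        return cache[t]

    onset = None
    for t in range(movie.n_frames):
        c = contour_at(t)
        if c is None:
            continue
        try:
            if furrowkinetics.detect_furrow(c) is not None:
                onset = t
                break
        except ValueError:
            continue
    if onset is None:
        raise ValueError("no ingression detected")
    contours = [cache.get(t) for t in range(movie.n_frames)]
    onset_contour = contours[onset]
    fp0 = furrowkinetics.detect_furrow(onset_contour)
    basal0 = furrowkinetics.measured_basal_distance(
        movie.frames[onset], onset_contour, fp0, movie.pixel_size
    )

    # measure the end-of-ingression daughter on the last frames that show a
    # furrow and take the median, which damps occasional waist-localisation
    # jumps on noisy frames
    shape = movie.frames.shape[1:]
    areas: list[float] = []
    roundnesses: list[float] = []
    t_fin = None
    for t in range(movie.n_frames - 1, onset - 1, -1):
        c = contour_at(t)
        if c is None:
            continue
        fp = furrowkinetics.detect_furrow(c)
        if fp is None:
            continue
        axial = float((fp.midpoint - c.apical_pole) @ c.long_axis)
        waist = furrowkinetics.ring_waist(movie.frames[t], c, axial)
        if waist is None:
            continue
        _, left, right = waist
        a, r = morphometrics.gmc_metrics(c, left, right, movie.pixel_size, shape)
        areas.append(a)
        roundnesses.append(r)
        if t_fin is None:
            t_fin = t
        if len(areas) == 3:
            break
    if not areas:
        raise ValueError("no furrow on any late frame")
    area = float(np.median(areas))
    roundness = float(np.median(roundnesses))
    return DivisionMeasurement(
        cell_id=cell_id,
        group=group,
        delta0_true=delta0_true,
        onset_frame=onset,
        initial_basal_distance_um=basal0,
        gmc_area_um2=area,
        gmc_roundness=roundness,
    )


def simulate_cohort(
    n_cells: int,
    base_params: SimulationParams,
    delta0_range: tuple[float, float] = (1.2, 3.6),
    seed: int = 0,
    group: str = "cohort",
) -> pd.DataFrame:
    """Simulate and fully quantify a cohort of divisions.

    Each cell draws its initial furrow basal offset uniformly from
    ``delta0_range`` and its own noise seed; the returned table holds the
    measured (not ground-truth) per-cell metrics.
    """
    if n_cells < 5:
        raise ValueError("a cohort needs at least 5 cells")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_cells):
        delta0 = float(rng.uniform(*delta0_range))
        params = replace(
            base_params,
            initial_furrow_basal_distance=delta0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        movie, _ = simulate_division(params)
        meas = measure_division_geometry(
            movie,
            camera_offset=params.camera_offset,
            cell_id=f"{group}_{i:03d}",
            group=group,
            delta0_true=delta0,
        )
        rows.append(meas.__dict__)
    return pd.DataFrame(rows)


@dataclass
class CorrelationReport:
    """Correlation of initial furrow basal offset vs final GMC area, per
    cohort, plus the between-cohort Mann-Whitney comparison of areas."""

    r_off: float
    r2_off: float
    p_off: float
    r_on: float
    r2_on: float
    p_on: float
    mann_whitney: StatResult
    table: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "correction_off": {"r": self.r_off, "r2": self.r2_off, "p": self.p_off},
            "correction_on": {"r": self.r_on, "r2": self.r2_on, "p": self.p_on},
            "mann_whitney_gmc_area": {
                "U": self.mann_whitney.statistic,
                "p": self.mann_whitney.p_value,
                "exact": self.mann_whitney.exact,
                "n": list(self.mann_whitney.n),
            },
        }


def correlation_experiment(
    n_cells: int = 30,
    base_params: SimulationParams | None = None,
    delta0_range: tuple[float, float] = (1.2, 3.6),
    seed: int = 0,
) -> CorrelationReport:
    """Run the furrow-position-correction contrast on synthetic cohorts.

    One cohort is simulated with the correction mechanism off (furrow stays
    at its initial offset) and one with it on (furrow drifts to a fixed
    target size); both are quantified by the full measurement pipeline and
    the initial basal offset is correlated with the final GMC area.
    """
    if n_cells < 5:
        raise ValueError("n_cells must be at least 5")
    if base_params is None:
        base_params = SimulationParams()
    off = simulate_cohort(
        n_cells,
        replace(base_params, correction_on=False),
        delta0_range,
        seed=seed,
        group="correction_off",
    )
    on = simulate_cohort(
        n_cells,
        replace(base_params, correction_on=True),
        delta0_range,
        seed=seed + 1,
        group="correction_on",
    )
    r_off, r2_off, p_off = pearson_r2(off.initial_basal_distance_um, off.gmc_area_um2)
    r_on, r2_on, p_on = pearson_r2(on.initial_basal_distance_um, on.gmc_area_um2)
    mw = mann_whitney_two_tailed(off.gmc_area_um2, on.gmc_area_um2)
    return CorrelationReport(
        r_off=r_off,
        r2_off=r2_off,
        p_off=p_off,
        r_on=r_on,
        r2_on=r2_on,
        p_on=p_on,
        mann_whitney=mw,
        table=pd.concat([off, on], ignore_index=True),
    )


def scatter_plot(table: pd.DataFrame, path, x="initial_basal_distance_um", y="gmc_area_um2") -> None:
    """Scatter of basal offset vs GMC area per group, with median ± IQR bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.2))
    for group, sub in table.groupby("group"):
        ax.scatter(sub[x], sub[y], s=14, alpha=0.75, label=str(group))
    ax.set_xlabel("initial furrow basal distance (µm)")
    ax.set_ylabel("GMC area (µm²)")
    ax.legend(frameon=False, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
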