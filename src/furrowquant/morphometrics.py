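"""Daughter-cell (GMC) area and roundness at the end of ingression.

Area follows the ROI pixel-count convention (number of pixels inside the
region times the squared pixel size); roundness is the standard
area/major-axis form 4A / (pi L^2), which is 1 for a disk and b/a for an
ellipse with semi-axes a >= b.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from shapely.geometry import LineString, Polygon
from shapely.ops import split as shapely_split
from skimage import draw

from furrowquant.cortexprofile import CellContour

__all__ = [
    "gmc_area",
    "gmc_roundness",
    "region_length_um",
    "region_roundness",
    "gmc_region_polygon",
    "gmc_metrics",
]


def gmc_area(region: np.ndarray, pixel_size: float, shape: tuple[int, int] | None = None) -> float:
    """Area (µm²) of a region given as a boolean mask or a closed contour.

    A contour is rasterised first; the area is the pixel count times
    ``pixel_size**2``, matching a hand-drawn ROI measurement.
    """
    region = np.asarray(region)
    if region.ndim == 2 and region.dtype != bool and region.shape[1] == 2:
        if shape is None:
            hi = np.ceil(region.max(axis=0)).astype(int) + 2
            shape = (int(hi[0]), int(hi[1]))
        mask = draw.polygon2mask(shape, region.astype(float))
    elif region.dtype == bool:
        mask = region
    else:
        raise ValueError("region must be a boolean mask or an (N, 2) contour")
    count = int(mask.sum())
    if count == 0:
        raise ValueError("region is empty")
    return count * pixel_size**2


def gmc_roundness(area: float, length: float) -> float:
    """Roundness 4A / (pi L^2) from an area and the major-axis length."""
    if area <= 0 or length <= 0:
        raise ValueError("area and length must be positive")
    return 4.0 * area / (np.pi * length**2)


def region_length_um(boundary_points: np.ndarray, pixel_size: float) -> float:
    """Major-axis length: the maximal pairwise distance between boundary
    points (exact scan over the convex hull vertices)."""
    pts = np.asarray(boundary_points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 boundary points")
    if len(pts) > 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max())) * pixel_size


def region_roundness(boundary_points: np.ndarray, pixel_size: float, shape: tuple[int, int]) -> float:
    """Roundness of a region given by its closed boundary polyline (px)."""
    area = gmc_area(np.asarray(boundary_points, dtype=float), pixel_size, shape=shape)
    length = region_length_um(boundary_points, pixel_size)
    return gmc_roundness(area, length)


def gmc_region_polygon(contour: CellContour, furrow_left: np.ndarray, furrow_right: np.ndarray) -> np.ndarray:
    """Boundary of the basal (GMC) lobe: the cell outline cut by the chord
    through the two furrow points; the piece containing the basal pole is
    returned as an (N, 2) px polyline."""
    poly = Polygon(contour.points)
    if not poly.is_valid:
        poly = poly.buffer(0)
    a = np.asarray(furrow_left, dtype=float)
    b = np.asarray(furrow_right, dtype=float)
    direction = b - a
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("furrow points coincide")
    direction = direction / norm
    ext = 3.0 * np.sqrt(poly.area)
    cut = LineString([a - ext * direction, b + ext * direction])
    pieces = shapely_split(poly, cut)
    from shapely.geometry import Point

    basal = Point(contour.basal_pole)
    best = None
    for piece in pieces.geoms:
        if piece.contains(basal) or piece.distance(basal) < 1.5:
            if best is None or piece.area > best.area:
                best = piece
    if best is None:
        best = min(pieces.geoms, key=lambda g: g.distance(basal))
    coords = np.asarray(best.exterior.coords)[:-1]
    return coords


def gmc_metrics(
    contour: CellContour,
    furrow_left: np.ndarray,
    furrow_right: np.ndarray,
    pixel_size: float,
    shape: tuple[int, int],
) -> tuple[float, float]:
    """(area µm², roundness) of the basal lobe cut at the furrow chord."""
    boundary = gmc_region_polygon(contour, furrow_left, furrow_right)
    area = gmc_area(boundary, pixel_size, shape=shape)
    length = region_length_um(boundary, pixel_size)
    return area, gmc_roundness(area, length)
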