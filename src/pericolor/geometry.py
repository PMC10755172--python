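"""Per-kernel contour, landmarks and the axial color-sampling region.

Each labeled kernel is reduced to a small set of geometric landmarks: the
boundary contour, the center of mass (mean of the contour coordinates),
the tip/base pair (the two contour points at maximal distance, i.e. the
major axis), the width (the chord through the center perpendicular to the
tip direction, within an angular tolerance), and the axial sampling band
used for color — the part of the kernel between 30% above the tip and 15%
below the base, which avoids the darker tip zone and the yellow endosperm
cap.  Kernels whose contour is too short or whose width cannot be
constructed are flagged for removal rather than silently measured.

Coordinates are (row, col) pixel positions throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

__all__ = [
    "KernelGeometryError",
    "KernelLandmarks",
    "trace_contour",
    "locate_tip_base",
    "orient_tip_base",
    "measure_width",
    "axial_region_mask",
    "measure_kernel",
    "MIN_CONTOUR_POINTS",
]

MIN_CONTOUR_POINTS = 100


class KernelGeometryError(ValueError):
    """A kernel failed a geometric QC step; carries the removal reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def trace_contour(component_mask: np.ndarray) -> np.ndarray:
    """Closed boundary polygon of a single component at pixel resolution.

    Returns an (N, 2) array of (row, col) vertices with the closing vertex
    dropped.  Raises on an empty mask.  Callers should treat contours with
    fewer than :data:`MIN_CONTOUR_POINTS` points as removal candidates.
    """
    mask = np.asarray(component_mask, dtype=bool)
    if mask.sum() == 0:
        raise KernelGeometryError("zero_area_component")
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise KernelGeometryError("no_contour_found")
    contour = max(contours, key=len) - 1.0  # undo padding offset
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    return contour


def locate_tip_base(contour: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """The contour point pair at maximal Euclidean distance (major axis).

    The maximum is attained on the convex hull, so the search enumerates
    hull vertex pairs; ties are broken by the lowest (i, j) contour index
    pair so results are deterministic.  Returns (end1, end2, length) with
    end1 the lower-index endpoint; tip/base identity is resolved separately
    by :func:`orient_tip_base`.
    """
    pts = np.asarray(contour, dtype=float)
    if len(pts) < 3:
        raise KernelGeometryError("contour_too_short")
    try:
        from scipy.spatial import ConvexHull

        hull_idx = np.sort(np.unique(ConvexHull(pts).vertices))
    except Exception:  # collinear/degenerate contours
        hull_idx = np.arange(len(pts))
    hp = pts[hull_idx]
    d2 = ((hp[:, None, :] - hp[None, :, :]) ** 2).sum(axis=2)
    flat = np.argmax(d2)
    best = d2.flat[flat]
    # deterministic tie-break: smallest (i, j) original-index pair
    ii, jj = np.where(np.isclose(d2, best))
    pairs = sorted(
        (min(hull_idx[a], hull_idx[b]), max(hull_idx[a], hull_idx[b]))
        for a, b in zip(ii, jj)
        if a != b
    )
    i, j = pairs[0]
    return pts[i], pts[j], float(np.sqrt(best))


def _axial_positions(
    mask: np.ndarray, tip: np.ndarray, base: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized position along the tip->base axis for every mask pixel."""
    rows, cols = np.nonzero(mask)
    axis = base - tip
    norm2 = float(axis @ axis)
    if norm2 == 0:
        raise KernelGeometryError("tip_equals_base")
    t = ((rows - tip[0]) * axis[0] + (cols - tip[1]) * axis[1]) / norm2
    return t, np.ravel_multi_index((rows, cols), mask.shape)


def orient_tip_base(
    end1: np.ndarray,
    end2: np.ndarray,
    mask: np.ndarray,
    image: np.ndarray | None = None,
    band: float = 0.15,
    yellowness_tol: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Decide which major-axis endpoint is the tip and which the base.

    The base end carries the yellow endosperm cap, so when an image is
    available the endpoint whose ``band`` axial slice has the higher mean
    yellowness ((R+G)/2 - B) is the base.  If color is uninformative (the
    difference falls below ``yellowness_tol``) or no image is given, a
    geometric fallback declares the blunter end — the endpoint slice with
    the larger pixel area — the base.  Returns (tip, base).
    """
    t, flat_idx = _axial_positions(mask, np.asarray(end1, float),
                                   np.asarray(end2, float))
    near1 = t <= band
    near2 = t >= 1.0 - band

    if image is not None and near1.any() and near2.any():
        img = np.asarray(image, dtype=float).reshape(-1, 3)

        def yellowness(sel: np.ndarray) -> float:
            px = img[flat_idx[sel]]
            return float((px[:, 0] + px[:, 1]).mean() / 2.0 - px[:, 2].mean())

        y1, y2 = yellowness(near1), yellowness(near2)
        if abs(y1 - y2) >= yellowness_tol:
            if y1 > y2:
                return np.asarray(end2, float), np.asarray(end1, float)
            return np.asarray(end1, float), np.asarray(end2, float)

    # geometric fallback: blunter (larger) end slice = base
    if near1.sum() >= near2.sum():
        return np.asarray(end2, float), np.asarray(end1, float)
    return np.asarray(end1, float), np.asarray(end2, float)


def measure_width(
    contour: np.ndarray,
    center: np.ndarray,
    tip: np.ndarray,
    angle_tol: float = 5.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Width chord: contour point at 90 deg (+/- tol) to the tip, through center.

    Scans every contour point P and keeps those where the angle
    tip-center-P lies within ``angle_tol`` of 90 degrees, taking the one
    closest to exactly 90.  The chord is extended from P through the center
    to the opposite contour intersection Q, and width = |P - Q|.  Raises
    :class:`KernelGeometryError` ("width_unobtainable") when no contour
    point meets the tolerance.
    """
    pts = np.asarray(contour, dtype=float)
    c = np.asarray(center, dtype=float)
    v_tip = np.asarray(tip, dtype=float) - c
    n_tip = np.linalg.norm(v_tip)
    if n_tip == 0:
        raise KernelGeometryError("center_equals_tip")
    rel = pts - c
    norms = np.linalg.norm(rel, axis=1)
    ok = norms > 1e-9
    cosang = np.clip((rel[ok] @ v_tip) / (norms[ok] * n_tip), -1.0, 1.0)
    angles = np.degrees(np.arccos(cosang))
    dev = np.abs(angles - 90.0)
    if dev.min() > angle_tol:
        raise KernelGeometryError("width_unobtainable")
    p_idx = np.flatnonzero(ok)[np.argmin(dev)]
    P = pts[p_idx]

    u = c - P
    nu = np.linalg.norm(u)
    if nu == 0:
        raise KernelGeometryError("width_unobtainable")
    u = u / nu
    # opposite intersection: contour point beyond the center along P->center
    proj = rel @ u
    beyond = proj > 0
    if not beyond.any():
        raise KernelGeometryError("width_unobtainable")
    lateral = np.abs(rel[beyond] @ np.array([-u[1], u[0]]))
    q_idx = np.flatnonzero(beyond)[np.argmin(lateral)]
    Q = pts[q_idx]
    return P, Q, float(np.linalg.norm(P - Q))


def axial_region_mask(
    component_mask: np.ndarray,
    tip: np.ndarray,
    base: np.ndarray,
    cut_tip: float = 0.30,
    cut_base: float = 0.15,
) -> np.ndarray:
    """Band of kernel pixels between ``cut_tip`` and ``1 - cut_base`` along
    the tip->base axis (defaults keep [0.30, 0.85])."""
    mask = np.asarray(component_mask, dtype=bool)
    t, flat_idx = _axial_positions(mask, np.asarray(tip, float),
                                   np.asarray(base, float))
    keep = (t >= cut_tip) & (t <= 1.0 - cut_base)
    region = np.zeros(mask.shape, dtype=bool)
    region.ravel()[flat_idx[keep]] = True
    if not region.any():
        raise KernelGeometryError("empty_axial_region")
    return region


@dataclass
class KernelLandmarks:
    """Full geometric description of one retained kernel."""

    contour: np.ndarray
    n_contour_points: int
    center: np.ndarray
    tip: np.ndarray
    base: np.ndarray
    length_px: float
    width_points: tuple[np.ndarray, np.ndarray]
    width_px: float
    axial_region: np.ndarray

    @property
    def lw_ratio(self) -> float:
        return self.length_px / self.width_px


def measure_kernel(
    component_mask: np.ndarray,
    image: np.ndarray | None = None,
    cut_tip: float = 0.30,
    cut_base: float = 0.15,
    angle_tol: float = 5.0,
    min_contour_points: int = MIN_CONTOUR_POINTS,
    use_mask_centroid: bool = False,
) -> KernelLandmarks:
    """Run the full landmark chain on one component.

    Raises :class:`KernelGeometryError` with the removal reason whenever
    any step disqualifies the kernel (short contour, unobtainable width,
    degenerate axis, empty region).  The center of mass averages the
    contour coordinates by default; ``use_mask_centroid`` switches to the
    mean of all mask pixels.
    """
    contour = trace_contour(component_mask)
    if len(contour) < min_contour_points:
        raise KernelGeometryError("contour_under_100_points")
    if use_mask_centroid:
        rows, cols = np.nonzero(component_mask)
        center = np.array([rows.mean(), cols.mean()])
    else:
        center = contour.mean(axis=0)
    end1, end2, length = locate_tip_base(contour)
    tip, base = orient_tip_base(end1, end2, component_mask, image=image)
    P, Q, width = measure_width(contour, center, tip, angle_tol=angle_tol)
    if width <= 0 or length < width:
        raise KernelGeometryError("width_exceeds_length")
    region = axial_region_mask(component_mask, tip, base,
                               cut_tip=cut_tip, cut_base=cut_base)
    return KernelLandmarks(
        contour=contour,
        n_contour_points=len(contour),
        center=center,
        tip=tip,
        base=base,
        length_px=length,
        width_points=(P, Q),
        width_px=width,
        axial_region=region,
    )
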