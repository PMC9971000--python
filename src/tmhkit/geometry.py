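"""Geometric tear-meniscus-height (TMH) measurement from binary masks.

The measurement pipeline mirrors how a clinician reads a Keratograph-style
ocular-surface photograph: the bright central ring of the corneal projection
ring (CCPR) anchors the horizontal position of the eye, and the tear meniscus
is the bright fluid band along the lower lid margin directly below it.  Given
binary masks for the two structures the steps are:

1. :func:`locate_ccpr_center` — largest connected component of the ring mask,
   cavity filling, algebraic (Kåsa) circle fit, and the bounding square of the
   fitted disk, whose centre agrees with the fit centre.
2. :func:`extract_edges` — per-column topmost/bottommost meniscus rows inside
   a 200-column window centred on the ring (±100 px, half-open, i.e. 400 edge
   coordinates in total).
3. :func:`select_measurement_columns` — seven columns spaced 30 px apart,
   symmetric about the ring centre, spanning ≈2 mm at 86 px/mm.
4. :func:`measure_tmh` — mean of the seven per-column heights (PTMH, in px)
   converted to millimetres with the instrument scale (86 px/mm).

Coordinates are 0-based; ``x`` indexes columns (width axis) and ``y`` indexes
rows (height axis, increasing downwards), so the meniscus lies at larger ``y``
than the ring centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateFitError,
    InputError,
    MissingEdgeError,
    NoTargetError,
)

#: Instrument scale of the Keratograph 5M ocular-surface photographs.
PX_PER_MM = 86.0

#: Half-width of the edge-extraction window around the ring centre column.
HALF_WINDOW_PX = 100

#: Spacing of the TMH measurement columns.
POINT_SPACING_PX = 30

#: Number of measurement points averaged into the final TMH.
N_MEASUREMENT_POINTS = 7

__all__ = [
    "PX_PER_MM",
    "HALF_WINDOW_PX",
    "POINT_SPACING_PX",
    "N_MEASUREMENT_POINTS",
    "CircleFit",
    "EdgeProfile",
    "TMHMeasurement",
    "MeasurementResult",
    "fit_circle_kasa",
    "locate_ccpr_center",
    "extract_edges",
    "select_measurement_columns",
    "measure_tmh",
    "measure_image",
]


@dataclass(frozen=True)
class CircleFit:
    """Circle fitted to the CCPR component, plus its bounding square.

    ``center`` is the subpixel fit centre; ``bbox_upper_left`` and
    ``bbox_side`` describe the axis-aligned square circumscribing the fitted
    disk, whose centre coincides with the fit centre to within a pixel.
    """

    center: tuple[float, float]
    radius: float
    rms_residual: float
    bbox_upper_left: tuple[int, int]
    bbox_side: int

    @property
    def bbox_center(self) -> tuple[float, float]:
        x0, y0 = self.bbox_upper_left
        return (x0 + self.bbox_side / 2.0, y0 + self.bbox_side / 2.0)


@dataclass(frozen=True)
class EdgeProfile:
    """Per-column upper/lower meniscus edge rows inside the window.

    ``columns`` is sorted ascending; ``upper_y[i]``/``lower_y[i]`` are the
    topmost and bottommost meniscus rows in column ``columns[i]``.
    """

    columns: np.ndarray
    upper_y: np.ndarray
    lower_y: np.ndarray

    def __post_init__(self) -> None:
        cols = np.asarray(self.columns, dtype=np.int64)
        up = np.asarray(self.upper_y, dtype=np.int64)
        lo = np.asarray(self.lower_y, dtype=np.int64)
        if not (cols.shape == up.shape == lo.shape):
            raise InputError("columns, upper_y and lower_y must align")
        if cols.size and np.any(np.diff(cols) <= 0):
            raise InputError("columns must be strictly ascending")
        if np.any(lo < up):
            raise InputError("lower_y must be >= upper_y at every column")
        object.__setattr__(self, "columns", cols)
        object.__setattr__(self, "upper_y", up)
        object.__setattr__(self, "lower_y", lo)

    def __len__(self) -> int:
        return int(self.columns.size)

    @property
    def n_coordinates(self) -> int:
        """Total number of (x, y) edge coordinates (upper + lower)."""
        return 2 * len(self)


@dataclass(frozen=True)
class TMHMeasurement:
    """Seven-point tear meniscus height measurement."""

    measurement_columns: np.ndarray
    point_heights_px: np.ndarray
    ptmh_px: float
    tmh_mm: float
    px_per_mm: float = PX_PER_MM

    def __str__(self) -> str:  # Fig-8 style, two decimals
        return f"TMH = {self.tmh_mm:.2f} mm (PTMH = {self.ptmh_px:.2f} px)"


@dataclass(frozen=True)
class MeasurementResult:
    """Full provenance of one image measurement."""

    circle: CircleFit
    edges: EdgeProfile
    tmh: TMHMeasurement
    warnings: tuple[str, ...] = field(default_factory=tuple)


def fit_circle_kasa(xs: np.ndarray, ys: np.ndarray) -> tuple[float, float, float, float]:
    """Algebraic least-squares (Kåsa) circle fit.

    Minimises ``sum((x-a)^2 + (y-b)^2 - r^2)^2`` over the linearised system
    ``x^2 + y^2 = 2ax + 2by + c``.  Returns ``(cx, cy, radius, rms_residual)``
    where the residual is the RMS radial distance error.
    """
    xs = np.asarray(xs, dtype=np.float64)
    ys = np.asarray(ys, dtype=np.float64)
    if xs.size < 3:
        raise DegenerateFitError("circle fit needs at least 3 points")
    A = np.column_stack([2.0 * xs, 2.0 * ys, np.ones_like(xs)])
    b = xs**2 + ys**2
    (cx, cy, c), *_ = np.linalg.lstsq(A, b, rcond=None)
    r2 = c + cx**2 + cy**2
    if not np.isfinite(r2) or r2 <= 0:
        raise DegenerateFitError("circle fit collapsed (non-positive radius)")
    radius = float(np.sqrt(r2))
    dists = np.hypot(xs - cx, ys - cy)
    rms = float(np.sqrt(np.mean((dists - radius) ** 2)))
    return float(cx), float(cy), radius, rms


def _largest_component(mask: np.ndarray) -> np.ndarray:
    """Boolean mask of the largest 8-connected foreground component."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise NoTargetError("mask contains no foreground pixels")
    if n == 1:
        return labels == 1
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise InputError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.dtype == bool:
        return arr
    uniq = np.unique(arr)
    if not np.isin(uniq, (0, 1)).all():
        raise InputError(f"{name} must be binary with values in {{0, 1}}")
    return arr.astype(bool)


def locate_ccpr_center(ring_mask: np.ndarray) -> CircleFit:
    """Locate the CCPR centre from its (possibly imperfect) binary mask.

    Keeps the largest connected component, fills interior cavities, fits a
    circle to the filled component's pixels by algebraic least squares, and
    derives the axis-aligned bounding square of the fitted disk.  The returned
    centre is the fit centre, which the bounding-square centre reproduces to
    within a pixel.

    Raises
    ------
    NoTargetError
        If the mask is empty.
    DegenerateFitError
        If the component is thinner than 3 px in either dimension.
    """
    mask = _as_binary(ring_mask, "ring_mask")
    comp = _largest_component(mask)
    filled = ndimage.binary_fill_holes(comp)
    ys, xs = np.nonzero(filled)
    if ys.max() - ys.min() + 1 < 3 or xs.max() - xs.min() + 1 < 3:
        raise DegenerateFitError(
            "CCPR component thinner than 3 px; cannot fit a circle"
        )
    cx, cy, radius, rms = fit_circle_kasa(xs, ys)
    side = int(round(2.0 * radius))
    upper_left = (int(round(cx - radius)), int(round(cy - radius)))
    return CircleFit(
        center=(cx, cy),
        radius=radius,
        rms_residual=rms,
        bbox_upper_left=upper_left,
        bbox_side=side,
    )


def extract_edges(
    meniscus_mask: np.ndarray,
    center_x: float,
    half_window_px: int = HALF_WINDOW_PX,
) -> EdgeProfile:
    """Per-column meniscus edges in the half-open window around ``center_x``.

    The window covers the ``2 * half_window_px`` columns in
    ``[round(center_x) - half_window_px, round(center_x) + half_window_px)``
    (with the default ±100 px this yields 200 columns, hence 400 upper+lower
    edge coordinates).  Edges are taken on the largest connected component of
    the meniscus mask: the upper edge is the minimum row, the lower edge the
    maximum row of that component in each column.  Columns with no meniscus
    pixel are dropped with a warning; whether any of them was a measurement
    column is checked downstream by :func:`measure_tmh`.

    Raises
    ------
    MissingEdgeError
        If the mask has no meniscus pixels anywhere in the window.
    """
    mask = _as_binary(meniscus_mask, "meniscus_mask")
    if half_window_px < 1:
        raise InputError("half_window_px must be >= 1")
    if not mask.any():
        raise NoTargetError("meniscus_mask contains no foreground pixels")
    comp = _largest_component(mask)
    cx = int(round(center_x))
    cols = np.arange(cx - half_window_px, cx + half_window_px)
    in_bounds = (cols >= 0) & (cols < mask.shape[1])
    kept_cols, uppers, lowers, dropped = [], [], [], []
    for col, ok in zip(cols, in_bounds):
        rows = np.nonzero(comp[:, col])[0] if ok else np.empty(0, dtype=int)
        if rows.size == 0:
            dropped.append(int(col))
            continue
        kept_cols.append(int(col))
        uppers.append(int(rows[0]))
        lowers.append(int(rows[-1]))
    if not kept_cols:
        raise MissingEdgeError(
            f"no meniscus pixels in the ±{half_window_px} px window "
            f"around column {cx}"
        )
    if dropped:
        warnings.warn(
            f"{len(dropped)} window column(s) without meniscus pixels "
            f"dropped: {dropped[:8]}{'…' if len(dropped) > 8 else ''}",
            stacklevel=2,
        )
    return EdgeProfile(
        columns=np.asarray(kept_cols),
        upper_y=np.asarray(uppers),
        lower_y=np.asarray(lowers),
    )


def select_measurement_columns(
    center_x: float,
    spacing_px: int = POINT_SPACING_PX,
    n_points: int = N_MEASUREMENT_POINTS,
) -> np.ndarray:
    """The measurement columns: ``n_points`` columns ``spacing_px`` apart,
    symmetric about the ring-centre column.

    With the defaults (7 points, 30 px) the offsets are −90 … 90, a 180 px
    span ≈ 2.1 mm at 86 px/mm.
    """
    if spacing_px < 1 or n_points < 1:
        raise InputError("spacing_px and n_points must be positive")
    cx = int(round(center_x))
    offsets = (np.arange(n_points) - (n_points - 1) // 2) * spacing_px
    if n_points % 2 == 0:  # even counts cannot be centred on a column
        offsets = offsets - spacing_px // 2
    return cx + offsets


def measure_tmh(
    edges: EdgeProfile,
    columns: np.ndarray | None = None,
    px_per_mm: float = PX_PER_MM,
    strict_difference: bool = False,
) -> TMHMeasurement:
    """Average the per-column meniscus heights at the measurement columns.

    The height at a column is the filled-row count ``lower - upper + 1``, so
    a band occupying ``t`` raster rows measures ``t`` px and an 86-row band
    converts to exactly 1.00 mm at 86 px/mm.  ``strict_difference=True``
    instead uses the bare coordinate difference ``lower - upper`` (one pixel
    less per column).

    Parameters
    ----------
    edges
        Edge profile from :func:`extract_edges`.
    columns
        The measurement columns; defaults to the 7-point grid centred on the
        middle of ``edges``' window.
    px_per_mm
        Pixel-to-millimetre conversion factor (instrument scale).

    Raises
    ------
    MissingEdgeError
        If any measurement column is absent from ``edges`` (named in the
        error message).
    """
    if px_per_mm <= 0:
        raise InputError("px_per_mm must be positive")
    if columns is None:
        mid = float(edges.columns[0] + edges.columns[-1] + 1) / 2.0
        columns = select_measurement_columns(mid)
    columns = np.asarray(columns, dtype=np.int64)
    pos = {int(c): i for i, c in enumerate(edges.columns)}
    missing = [int(c) for c in columns if int(c) not in pos]
    if missing:
        raise MissingEdgeError(
            f"measurement column(s) without meniscus pixels: {missing}"
        )
    idx = np.array([pos[int(c)] for c in columns])
    diff = edges.lower_y[idx] - edges.upper_y[idx]
    heights = diff if strict_difference else diff + 1
    heights = heights.astype(np.float64)
    ptmh = float(np.mean(heights))
    return TMHMeasurement(
        measurement_columns=columns,
        point_heights_px=heights,
        ptmh_px=ptmh,
        tmh_mm=ptmh / px_per_mm,
        px_per_mm=float(px_per_mm),
    )


def measure_image(
    meniscus_mask: np.ndarray,
    ring_mask: np.ndarray,
    px_per_mm: float = PX_PER_MM,
    half_window_px: int = HALF_WINDOW_PX,
    point_spacing_px: int = POINT_SPACING_PX,
    strict_difference: bool = False,
) -> MeasurementResult:
    """Full TMH measurement from a meniscus mask and a CCPR mask.

    Composes :func:`locate_ccpr_center`, :func:`extract_edges`,
    :func:`select_measurement_columns` and :func:`measure_tmh`, returning all
    intermediate products for provenance.  Errors from the individual stages
    propagate with a stage label prepended to the message.
    """
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            circle = locate_ccpr_center(ring_mask)
        except Exception as exc:
            raise type(exc)(f"[ccpr-location] {exc}") from exc
        try:
            edges = extract_edges(
                meniscus_mask, circle.center[0], half_window_px=half_window_px
            )
        except Exception as exc:
            raise type(exc)(f"[edge-extraction] {exc}") from exc
        columns = select_measurement_columns(
            circle.center[0], spacing_px=point_spacing_px
        )
        try:
            tmh = measure_tmh(
                edges,
                columns,
                px_per_mm=px_per_mm,
                strict_difference=strict_difference,
            )
        except Exception as exc:
            raise type(exc)(f"[tmh-measurement] {exc}") from exc
    return MeasurementResult(
        circle=circle,
        edges=edges,
        tmh=tmh,
        warnings=tuple(str(w.message) for w in caught),
    )
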