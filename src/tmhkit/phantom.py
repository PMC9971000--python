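"""Synthetic ocular-surface phantoms with exact ground truth.

Real Keratograph 5M photographs show a bright placido-ring projection on the
cornea (only the central ring, the CCPR, is ever segmented) and a bright tear
fluid band along the lower lid margin.  The phantoms generated here reduce
that scene to the parts the measurement method actually consumes:

* a dominant bright annulus near the image centre (the CCPR), optionally
  surrounded by fainter distractor rings and a concentric iris-like texture;
* a bright horizontal meniscus band whose per-column thickness follows a
  parameterised profile (constant, linear ramp, or sinusoidal), so the true
  tear meniscus height is known exactly by construction;
* a smooth illumination gradient plus additive Gaussian noise.

Masks are exact: every meniscus-mask pixel carries the meniscus brightness
before noise, the ring mask is the rasterised annulus, and the two are
disjoint by validated construction.  Thickness profiles are rasterised to an
integer row count per column, and ``true_tmh_mm`` is defined from those
rasterised counts, so running the geometry stage on the true masks recovers
the true TMH exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import geometry
from .errors import InputError, InvalidSpecError
from .geometry import EdgeProfile

__all__ = [
    "ThicknessProfile",
    "IntensityParams",
    "PhantomSpec",
    "PhantomSample",
    "generate_phantom",
    "generate_dataset",
    "scaled_spec",
]


@dataclass(frozen=True)
class ThicknessProfile:
    """Per-column meniscus thickness model, in pixels.

    ``kind`` selects the shape: ``constant`` (``base_px`` everywhere),
    ``linear`` (``base_px + slope_px_per_px * (x - center_x)``) or
    ``sinusoidal`` (``base_px + amplitude_px * sin(2π (x - center_x) /
    period_px + phase_rad)``).  Thickness is rasterised to the nearest whole
    row count when a band is drawn.
    """

    kind: str = "constant"
    base_px: float = 30.0
    slope_px_per_px: float = 0.0
    amplitude_px: float = 0.0
    period_px: float = 400.0
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "linear", "sinusoidal"):
            raise InvalidSpecError(f"unknown thickness profile kind {self.kind!r}")
        if self.kind == "sinusoidal" and self.period_px <= 0:
            raise InvalidSpecError("sinusoidal profile needs period_px > 0")

    def thickness_px(self, columns: np.ndarray, center_x: float) -> np.ndarray:
        """Rasterised (integer) thickness at each column."""
        dx = np.asarray(columns, dtype=np.float64) - center_x
        if self.kind == "constant":
            t = np.full_like(dx, self.base_px)
        elif self.kind == "linear":
            t = self.base_px + self.slope_px_per_px * dx
        else:
            t = self.base_px + self.amplitude_px * np.sin(
                2.0 * np.pi * dx / self.period_px + self.phase_rad
            )
        return np.rint(t).astype(np.int64)


@dataclass(frozen=True)
class IntensityParams:
    """Grey-level layout of the phantom, all in [0, 1]."""

    background: float = 0.15
    ring: float = 0.90
    meniscus: float = 0.75
    noise_sigma: float = 0.02
    iris_amplitude: float = 0.05
    gradient_amplitude: float = 0.05


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of one synthetic ocular-surface image.

    Defaults follow the instrument geometry of the real photographs:
    1360 × 1024 px at 86 px/mm, CCPR near the image centre, meniscus band in
    the lower quarter.  ``half_window_px`` and ``point_spacing_px`` are the
    geometry-stage window parameters the ground truth is defined against;
    they shrink together with the image for small phantoms.
    """

    width_px: int = 1360
    height_px: int = 1024
    ring_center: tuple[float, float] = (680.0, 430.0)
    ring_radius_px: float = 100.0
    ring_thickness_px: float = 18.0
    meniscus_top_y: int = 820
    thickness_profile: ThicknessProfile = field(default_factory=ThicknessProfile)
    intensity_params: IntensityParams = field(default_factory=IntensityParams)
    px_per_mm: float = geometry.PX_PER_MM
    half_window_px: int = geometry.HALF_WINDOW_PX
    point_spacing_px: int = geometry.POINT_SPACING_PX
    distractor_rings: bool = False
    seed: int = 0

    def measurement_columns(self) -> np.ndarray:
        return geometry.select_measurement_columns(
            self.ring_center[0], spacing_px=self.point_spacing_px
        )

    def window_columns(self) -> np.ndarray:
        cx = int(round(self.ring_center[0]))
        return np.arange(cx - self.half_window_px, cx + self.half_window_px)

    def validate(self) -> None:
        """Raise :class:`InvalidSpecError` on any violated invariant."""
        ip = self.intensity_params
        if self.width_px < 8 or self.height_px < 8:
            raise InvalidSpecError("image dimensions too small")
        if self.ring_radius_px <= 0 or self.ring_thickness_px <= 0:
            raise InvalidSpecError("ring radius and thickness must be positive")
        cx, cy = self.ring_center
        reach = self.ring_radius_px + self.ring_thickness_px / 2.0
        if not (
            cx - reach >= 0
            and cx + reach < self.width_px
            and cy - reach >= 0
            and cy + reach < self.height_px
        ):
            raise InvalidSpecError("ring extends outside the image bounds")
        for name in ("background", "ring", "meniscus"):
            v = getattr(ip, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidSpecError(f"intensity {name}={v} outside [0, 1]")
        if ip.noise_sigma < 0:
            raise InvalidSpecError("noise sigma must be nonnegative")
        cols = self.window_columns()
        if cols[0] < 0 or cols[-1] >= self.width_px:
            raise InvalidSpecError(
                "measurement window extends outside the image; shrink "
                "half_window_px or widen the image"
            )
        t = self.thickness_profile.thickness_px(cols, cx)
        if np.any(t <= 0):
            raise InvalidSpecError(
                "thickness profile must be positive on every window column"
            )
        if self.meniscus_top_y + int(t.max()) > self.height_px:
            raise InvalidSpecError("meniscus band extends below the image")
        if self.meniscus_top_y <= cy + reach:
            raise InvalidSpecError(
                "meniscus band overlaps or touches the ring; masks must be "
                "disjoint"
            )
        n_span = (geometry.N_MEASUREMENT_POINTS - 1) // 2 * self.point_spacing_px
        if n_span > self.half_window_px - 1:
            raise InvalidSpecError(
                "measurement columns fall outside the edge window; reduce "
                "point_spacing_px or enlarge half_window_px"
            )


@dataclass(frozen=True)
class PhantomSample:
    """A rendered phantom with its exact ground truth."""

    image: np.ndarray  # H×W×3 float in [0, 1]
    meniscus_mask: np.ndarray  # H×W uint8 {0, 1}
    ring_mask: np.ndarray  # H×W uint8 {0, 1}
    true_center: tuple[float, float]
    true_tmh_mm: float
    true_edge: EdgeProfile
    spec: PhantomSpec


def _render_meniscus_mask(spec: PhantomSpec) -> np.ndarray:
    """Rasterise the meniscus band over the full image width."""
    h, w = spec.height_px, spec.width_px
    cols = np.arange(w)
    t = spec.thickness_profile.thickness_px(cols, spec.ring_center[0])
    t = np.clip(t, 0, h - spec.meniscus_top_y)
    rows = np.arange(h)[:, None]
    band = (rows >= spec.meniscus_top_y) & (rows < spec.meniscus_top_y + t[None, :])
    return band.astype(np.uint8)


def _render_ring_mask(
    spec: PhantomSpec, radius: float | None = None, thickness: float | None = None
) -> np.ndarray:
    radius = spec.ring_radius_px if radius is None else radius
    thickness = spec.ring_thickness_px if thickness is None else thickness
    yy, xx = np.mgrid[0 : spec.height_px, 0 : spec.width_px]
    r = np.hypot(xx - spec.ring_center[0], yy - spec.ring_center[1])
    return (np.abs(r - radius) <= thickness / 2.0).astype(np.uint8)


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom. Deterministic for a fixed ``spec`` (incl. seed)."""
    spec.validate()
    ip = spec.intensity_params
    h, w = spec.height_px, spec.width_px
    rng = np.random.default_rng(spec.seed)

    meniscus = _render_meniscus_mask(spec)
    ring = _render_ring_mask(spec)
    if np.any(meniscus & ring):  # guarded already by validate(); belt-and-braces
        raise InvalidSpecError("meniscus and ring masks overlap")

    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(xx - spec.ring_center[0], yy - spec.ring_center[1])
    img = np.full((h, w), ip.background, dtype=np.float64)
    # vertical illumination gradient (brighter towards the lid margin)
    img += ip.gradient_amplitude * (yy / max(h - 1, 1))
    # concentric iris-like ripple around the ring centre, fading with radius
    iris_extent = 3.2 * spec.ring_radius_px
    ripple = ip.iris_amplitude * np.cos(2.0 * np.pi * r / (0.6 * spec.ring_radius_px))
    img += ripple * np.clip(1.0 - r / iris_extent, 0.0, 1.0)
    if spec.distractor_rings:
        # fainter outer placido rings: plausible confusers, absent from truth
        mid = 0.5 * (ip.background + ip.ring)
        for k, scale in ((1.7, 0.9), (2.4, 0.8)):
            outer = _render_ring_mask(
                spec, radius=k * spec.ring_radius_px,
                thickness=0.7 * spec.ring_thickness_px,
            )
            img[outer.astype(bool)] = mid * scale
    # target structures overlay everything else exactly
    img[ring.astype(bool)] = ip.ring
    img[meniscus.astype(bool)] = ip.meniscus
    if ip.noise_sigma > 0:
        img = img + rng.normal(0.0, ip.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    image = np.repeat(img[:, :, None], 3, axis=2)

    win = spec.window_columns()
    t_win = spec.thickness_profile.thickness_px(win, spec.ring_center[0])
    true_edge = EdgeProfile(
        columns=win,
        upper_y=np.full(win.size, spec.meniscus_top_y, dtype=np.int64),
        lower_y=spec.meniscus_top_y + t_win - 1,
    )
    mcols = spec.measurement_columns()
    t_meas = spec.thickness_profile.thickness_px(mcols, spec.ring_center[0])
    true_tmh_mm = float(np.mean(t_meas)) / spec.px_per_mm

    return PhantomSample(
        image=image,
        meniscus_mask=meniscus,
        ring_mask=ring,
        true_center=spec.ring_center,
        true_tmh_mm=true_tmh_mm,
        true_edge=true_edge,
        spec=spec,
    )


def scaled_spec(size_px: int = 128, seed: int = 0) -> PhantomSpec:
    """A square phantom at reduced resolution, geometry scaled proportionally.

    Keeps the relative layout of the full-size phantom (ring in the upper
    half, meniscus band near the bottom) while shrinking every length with
    the image, including ``px_per_mm`` (86 px/mm at the native 1024-px
    height).  Useful for fast experiments and desk-scale network training.
    """
    f = size_px / 1024.0
    hw = max(8, int(round(0.30 * size_px)))
    return PhantomSpec(
        width_px=size_px,
        height_px=size_px,
        ring_center=(size_px / 2.0, 0.375 * size_px),
        ring_radius_px=0.14 * size_px,
        ring_thickness_px=max(3.0, 0.04 * size_px),
        meniscus_top_y=int(round(0.72 * size_px)),
        thickness_profile=ThicknessProfile(base_px=max(4.0, 0.11 * size_px)),
        px_per_mm=geometry.PX_PER_MM * f,
        half_window_px=hw,
        point_spacing_px=max(2, hw // 4),
        seed=seed,
    )


#: Spec fields that ``generate_dataset`` knows how to jitter.
_JITTERABLE = (
    "ring_center_x",
    "ring_center_y",
    "ring_radius_px",
    "ring_thickness_px",
    "meniscus_top_y",
    "base_px",
    "slope_px_per_px",
    "amplitude_px",
)


def _jittered_spec(
    base: PhantomSpec, variation: dict[str, tuple[float, float]], rng: np.random.Generator
) -> PhantomSpec:
    draws = {k: rng.uniform(lo, hi) for k, (lo, hi) in variation.items()}
    cx, cy = base.ring_center
    cx += draws.pop("ring_center_x", 0.0)
    cy += draws.pop("ring_center_y", 0.0)
    profile = base.thickness_profile
    prof_updates = {
        k: getattr(profile, k) + draws.pop(k)
        for k in ("base_px", "slope_px_per_px", "amplitude_px")
        if k in draws
    }
    if prof_updates:
        profile = replace(profile, **prof_updates)
    updates: dict = {"ring_center": (cx, cy), "thickness_profile": profile}
    for k in ("ring_radius_px", "ring_thickness_px"):
        if k in draws:
            updates[k] = getattr(base, k) + draws.pop(k)
    if "meniscus_top_y" in draws:
        updates["meniscus_top_y"] = int(round(base.meniscus_top_y + draws.pop("meniscus_top_y")))
    if draws:
        raise InputError(f"unknown jitter field(s): {sorted(draws)}")
    return replace(base, **updates)


def generate_dataset(
    n: int,
    base_spec: PhantomSpec,
    variation: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    n_train: int | None = None,
) -> tuple[list[PhantomSample], pd.DataFrame]:
    """Generate ``n`` phantoms with jittered geometry and a manifest.

    ``variation`` maps a jitterable field name (see ``_JITTERABLE``) to an
    additive uniform range ``(lo, hi)``.  The train/test split assigns a
    random ``n_train``-sized subset to ``train`` (default: an ≈270/305
    fraction, the split ratio of the clinical dataset the phantoms stand in
    for); both the jitter and the split are reproducible from ``seed``.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    variation = dict(variation or {})
    unknown = set(variation) - set(_JITTERABLE)
    if unknown:
        raise InputError(f"unknown jitter field(s): {sorted(unknown)}")
    if n_train is None:
        n_train = int(round(n * 270.0 / 305.0))
    if not 0 <= n_train <= n:
        raise InputError("n_train must be between 0 and n")
    rng = np.random.default_rng(seed)
    sample_seeds = rng.integers(0, 2**31 - 1, size=n)
    split = np.array(["test"] * n, dtype=object)
    split[rng.permutation(n)[:n_train]] = "train"
    samples, rows = [], []
    for i in range(n):
        spec = _jittered_spec(base_spec, variation, rng) if variation else base_spec
        spec = replace(spec, seed=int(sample_seeds[i]))
        sample = generate_phantom(spec)
        samples.append(sample)
        rows.append(
            {
                "sample_id": f"phantom_{i:04d}",
                "split": split[i],
                "true_tmh_mm": sample.true_tmh_mm,
                "center_x": spec.ring_center[0],
                "center_y": spec.ring_center[1],
                "seed": int(sample_seeds[i]),
            }
        )
    return samples, pd.DataFrame(rows)
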