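import numpy as np
import pytest

from tmhkit import phantom


@pytest.fixture(scope="session")
def default_sample():
    """One full-size noiseless-geometry phantom (noise on, default spec)."""
    return phantom.generate_phantom(phantom.PhantomSpec())


@pytest.fixture(scope="session")
def small_sample():
    """One 128-px phantom for fast tests."""
    return phantom.generate_phantom(phantom.scaled_spec(size_px=128, seed=3))


def random_valid_spec(rng: np.random.Generator) -> phantom.PhantomSpec:
    """A random phantom spec drawn from a broad valid family.

    Mixes image sizes, ring geometry, thickness-profile shapes and the
    pixel scale; shared by property tests and the acceptance closure sweep.
    """
    size = int(rng.integers(160, 320))
    hw = int(rng.integers(24, 0.3 * size))
    spacing = max(2, hw // 4)
    kind = rng.choice(["constant", "linear", "sinusoidal"])
    base = float(rng.uniform(0.04, 0.14)) * size
    profile = phantom.ThicknessProfile(
        kind=kind,
        base_px=base,
        slope_px_per_px=float(rng.uniform(-0.03, 0.03)) if kind == "linear" else 0.0,
        amplitude_px=float(rng.uniform(0, 0.4 * base)) if kind == "sinusoidal" else 0.0,
        period_px=float(rng.uniform(2 * hw, 8 * hw)),
        phase_rad=float(rng.uniform(0, 2 * np.pi)),
    )
    radius = float(rng.uniform(0.08, 0.16)) * size
    thickness = float(rng.uniform(3, 0.05 * size))
    cx = float(rng.uniform(0.38, 0.62)) * size
    cy = float(rng.uniform(0.25, 0.42)) * size
    top = int(rng.integers(int(0.68 * size), int(0.78 * size)))
    return phantom.PhantomSpec(
        width_px=size,
        height_px=size,
        ring_center=(cx, cy),
        ring_radius_px=radius,
        ring_thickness_px=thickness,
        meniscus_top_y=top,
        thickness_profile=profile,
        px_per_mm=86.0 * size / 1024.0,
        half_window_px=hw,
        point_spacing_px=spacing,
        seed=int(rng.integers(2**31 - 1)),
    )
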