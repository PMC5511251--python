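"""Synthetic-data generators with machine-readable ground truth.

Everything the pipeline consumes can be generated here with known truth:
equatorial profiles (hierarchical-model intensity plus polynomial
background and multiplicative noise), 2D oriented fiber patterns with one
or two azimuthal populations, powder profiles with rings at chosen
d-spacings, and exponential exchange-decay curves. Four named, versioned
scenarios bundle parameter sets that mimic the study samples (WT, A2V,
their 1:1 mixture, and the weakly scattering WT + 1-6A2V mixture).

Every generator is deterministic for a given seed and returns a truth
record sufficient to score any downstream recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as P

from .dataio import DecayCurve, DetectorGeometry, Pattern2D, Profile1D
from .errors import InputError
from .model import (
    CircularLattice,
    CylinderUnit,
    HierarchicalModel,
    d_to_q,
    model_intensity_at,
)

__all__ = [
    "SampleScenario",
    "SCENARIO_VERSION",
    "gen_profile",
    "gen_pattern",
    "gen_powder",
    "gen_decay",
    "paper_scenarios",
    "default_geometry",
]

SCENARIO_VERSION = "1"


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleScenario:
    """A named, versioned bundle of generator settings with known truth.

    ``components`` lists (model, weight) pairs — a single pair for simple
    samples, two for superposed mixtures; ``model`` is the primary component
    (None for the near-featureless mixture scenario). Orientation
    populations are (center azimuth deg, Gaussian sigma deg, weight).
    """

    name: str
    components: tuple[tuple[HierarchicalModel, float], ...]
    orientations: tuple[tuple[float, float, float], ...]
    background_coeffs: tuple[float, ...]
    crystallinity_regime: str
    decay_tau: float | None
    residual_fraction: float | None
    version: str = SCENARIO_VERSION

    def __post_init__(self):
        weights = [w for _, _, w in self.orientations]
        if any(w <= 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise InputError("orientation weights must be positive and sum to 1")
        if self.crystallinity_regime not in ("high", "low"):
            raise InputError("crystallinity_regime must be 'high' or 'low'")

    @property
    def model(self) -> HierarchicalModel | None:
        return self.components[0][0] if self.components else None


def _wt_model() -> HierarchicalModel:
    # four 106 Å-diameter units on a 160 Å circle
    return HierarchicalModel(
        unit=CylinderUnit(r=53.0),
        inner=CircularLattice(4, 80.0),
        outer=CircularLattice(1, 0.0),
    )


def _a2v_model() -> HierarchicalModel:
    # three 36 Å units in a 132 Å bundle; three bundles on a 196 Å circle
    return HierarchicalModel(
        unit=CylinderUnit(r=18.0),
        inner=CircularLattice(3, 48.0),
        outer=CircularLattice(3, 98.0),
    )


def paper_scenarios() -> list[SampleScenario]:
    """The four versioned sample scenarios with full truth records."""
    wt = _wt_model()
    a2v = _a2v_model()
    return [
        SampleScenario(
            name="WT",
            components=((wt, 1.0),),
            orientations=((74.5, 6.0, 0.5), (105.5, 6.0, 0.5)),  # 31 deg apart
            background_coeffs=(0.05, 0.0),
            crystallinity_regime="high",
            decay_tau=2.58,
            residual_fraction=0.20,
        ),
        SampleScenario(
            name="A2V",
            components=((a2v, 1.0),),
            orientations=((90.0, 4.0, 1.0),),
            background_coeffs=(0.3, 0.0),
            crystallinity_regime="low",
            decay_tau=1.90,
            residual_fraction=0.40,
        ),
        SampleScenario(
            name="WT_A2V",
            components=((wt, 0.5), (a2v, 0.5)),
            orientations=((76.5, 6.0, 0.5), (103.5, 6.0, 0.5)),  # 27 deg apart
            background_coeffs=(0.05, 0.0),
            crystallinity_regime="high",
            decay_tau=2.45,
            residual_fraction=0.15,
        ),
        SampleScenario(
            name="WT_1to6A2V",
            components=(),
            orientations=((90.0, 60.0, 1.0),),
            background_coeffs=(0.5, 0.0),
            crystallinity_regime="low",
            decay_tau=None,
            residual_fraction=None,
        ),
    ]


def default_geometry(size: int = 257) -> DetectorGeometry:
    """A small-angle geometry (beam centered on a ``size``×``size`` detector)
    that covers the scenarios' features."""
    center = (size - 1) / 2.0
    return DetectorGeometry(
        wavelength=4.5, distance=5600.0, pixel_size=4.0, beam_center=(center, center)
    )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _components_intensity(
    components: tuple[tuple[HierarchicalModel, float], ...], q: np.ndarray
) -> np.ndarray:
    out = np.zeros_like(q, dtype=float)
    for model, weight in components:
        curve = model_intensity_at(model, q)
        if len(components) > 1:
            # superpositions mix normalized curves so one component cannot
            # numerically swamp the other
            top = curve.max()
            if top > 0:
                curve = curve / top
        out += weight * curve
    return out


def gen_profile(
    model: HierarchicalModel | None,
    background_coeffs=(),
    noise_fraction: float = 0.0,
    q_grid=None,
    seed: int = 0,
    components: tuple[tuple[HierarchicalModel, float], ...] | None = None,
    label: str = "synthetic",
) -> tuple[Profile1D, dict]:
    """Model intensity + polynomial background + multiplicative noise.

    Either a single ``model`` or a list of weighted ``components`` (each
    max-normalized before weighting) drives the coherent part. Returns the
    profile and a truth record.
    """
    if noise_fraction < 0:
        raise InputError("noise_fraction must be >= 0")
    if q_grid is None:
        q_grid = np.linspace(0.005, 0.25, 500)
    q = np.asarray(q_grid, dtype=float)

    if components is None:
        components = ((model, 1.0),) if model is not None else ()
    signal = _components_intensity(components, q)
    background = (
        P.polyval(q, np.asarray(background_coeffs, dtype=float))
        if len(tuple(background_coeffs))
        else np.zeros_like(q)
    )
    clean = signal + background

    rng = np.random.default_rng(seed)
    noisy = clean * (1.0 + noise_fraction * rng.standard_normal(q.size))
    noisy = np.maximum(noisy, 0.0)
    sigma = noise_fraction * clean if noise_fraction > 0 else None

    truth = {
        "kind": "profile",
        "components": [
            {**m.to_params(), "weight": w} for m, w in components
        ],
        "background_coeffs": list(np.asarray(background_coeffs, dtype=float)),
        "noise_fraction": noise_fraction,
        "seed": seed,
        "q_min": float(q[0]),
        "q_max": float(q[-1]),
        "n_points": int(q.size),
    }
    return Profile1D(q=q, intensity=noisy, sigma=sigma, label=label), truth


def gen_pattern(
    model: HierarchicalModel | None,
    populations,
    geometry: DetectorGeometry,
    noise_fraction: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (257, 257),
    components: tuple[tuple[HierarchicalModel, float], ...] | None = None,
    background_coeffs=(0.0,),
    beamstop_px: float = 4.0,
    axis_direction: float = 0.0,
) -> tuple[Pattern2D, dict]:
    """2D fiber pattern: radial model intensity times azimuthal Gaussians.

    Each pixel gets Σ_pop weight · I_model(Q) · exp(−Δφ²/2σ²) with the
    angular offset folded to the 180°-periodic fiber symmetry, plus an
    isotropic polynomial background, multiplicative noise, and a zeroed
    beam-stop disc.
    """
    if noise_fraction < 0:
        raise InputError("noise_fraction must be >= 0")
    populations = tuple((float(c), float(s), float(w)) for c, s, w in populations)
    if not populations:
        raise InputError("need at least one azimuthal population")

    if components is None:
        components = ((model, 1.0),) if model is not None else ()

    probe = Pattern2D(
        values=np.zeros(shape), geometry=geometry, axis_direction=axis_direction
    )
    qmap = probe.q_map()
    phimap = probe.azimuth_map()

    if components:
        q_feature = d_to_q(2.0 * max(m.inner_diameter for m, _ in components))
        if qmap.max() < q_feature:
            warnings.warn(
                "detector Q range does not reach the model's main feature",
                stacklevel=2,
            )

    radial = _components_intensity(components, qmap.ravel()).reshape(shape)
    angular = np.zeros(shape)
    for center, sig, weight in populations:
        delta = np.abs(np.mod(phimap - center + 90.0, 180.0) - 90.0)
        angular += weight * np.exp(-0.5 * (delta / sig) ** 2)
    clean = radial * angular + P.polyval(
        qmap, np.asarray(background_coeffs, dtype=float)
    )

    rng = np.random.default_rng(seed)
    noisy = clean * (1.0 + noise_fraction * rng.standard_normal(shape))
    noisy = np.maximum(noisy, 0.0)

    rows, cols = np.indices(shape)
    r0, c0 = geometry.beam_center
    stopped = np.hypot(rows - r0, cols - c0) <= beamstop_px
    noisy[stopped] = 0.0

    truth = {
        "kind": "pattern",
        "components": [{**m.to_params(), "weight": w} for m, w in components],
        "populations": [list(p) for p in populations],
        "background_coeffs": list(np.asarray(background_coeffs, dtype=float)),
        "noise_fraction": noise_fraction,
        "seed": seed,
        "shape": list(shape),
        "beamstop_px": beamstop_px,
        "axis_direction": axis_direction,
    }
    return (
        Pattern2D(values=noisy, geometry=geometry, axis_direction=axis_direction),
        truth,
    )


def gen_powder(
    d_spacings,
    widths,
    heights,
    q_grid=None,
    seed: int = 0,
    background_coeffs=(0.1, 0.0),
    noise_fraction: float = 0.0,
) -> tuple[Profile1D, dict]:
    """Powder-style profile: Gaussian rings at Q = 2π/d on a smooth background.

    ``widths`` are Gaussian sigmas in Q [1/Å]; an empty ``d_spacings`` list
    yields pure background.
    """
    d_spacings = [float(d) for d in d_spacings]
    if any(d <= 0 for d in d_spacings):
        raise InputError("d-spacings must be > 0")
    widths = [float(w) for w in widths]
    heights = [float(h) for h in heights]
    if not len(d_spacings) == len(widths) == len(heights):
        raise InputError("d_spacings, widths and heights must have equal length")

    if q_grid is None:
        q_grid = np.linspace(0.3, 1.8, 800)
    q = np.asarray(q_grid, dtype=float)
    clean = P.polyval(q, np.asarray(background_coeffs, dtype=float))
    centers = [d_to_q(d) for d in d_spacings]
    for c, w, h in zip(centers, widths, heights):
        clean = clean + h * np.exp(-0.5 * ((q - c) / w) ** 2)

    rng = np.random.default_rng(seed)
    noisy = np.maximum(clean * (1.0 + noise_fraction * rng.standard_normal(q.size)), 0)

    truth = {
        "kind": "powder",
        "d_spacings": d_spacings,
        "q_centers": centers,
        "widths_sigma": widths,
        "heights": heights,
        "background_coeffs": list(np.asarray(background_coeffs, dtype=float)),
        "noise_fraction": noise_fraction,
        "seed": seed,
    }
    return Profile1D(q=q, intensity=noisy, label="powder"), truth


def gen_decay(
    tau: float,
    i0: float,
    i_inf: float,
    t_grid=None,
    noise_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[DecayCurve, dict]:
    """Exponential decay i_inf + (i0 − i_inf)·exp(−t/tau) with noise."""
    if tau <= 0:
        raise InputError("tau must be > 0")
    if t_grid is None:
        t_grid = np.linspace(0.0, 8.0, 32)
    t = np.asarray(t_grid, dtype=float)
    clean = i_inf + (i0 - i_inf) * np.exp(-t / tau)
    rng = np.random.default_rng(seed)
    noisy = np.maximum(clean * (1.0 + noise_fraction * rng.standard_normal(t.size)), 0)
    truth = {
        "kind": "decay",
        "tau": tau,
        "i0": i0,
        "i_inf": i_inf,
        "noise_fraction": noise_fraction,
        "seed": seed,
        "n_points": int(t.size),
        "t_max": float(t[-1]),
    }
    return DecayCurve(t=t, intensity=noisy), truth
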