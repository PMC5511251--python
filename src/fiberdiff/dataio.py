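"""Observational data types and text-format I/O.

Shared currency of the pipeline:

* :class:`Profile1D` — a 1D scattering curve I(Q),
* :class:`Pattern2D` + :class:`DetectorGeometry` — a 2D detector image with
  the geometry needed to map pixels to (Q, azimuth),
* :class:`DecayCurve` — peak intensity versus time for exchange kinetics,
* :class:`AnalysisConfig` — the knobs of the reduction/fitting pipeline.

All file formats are plain text so fixtures stay diffable: profiles are TSV
with a ``#`` comment header, patterns are a whitespace matrix plus a small
``key: value`` geometry header.

Conventions: the public reciprocal coordinate is the momentum transfer
Q [1/Å] everywhere (d = 2π/Q); pixel coordinates are 0-based at pixel
centers; azimuth is measured in degrees from the fiber/field axis
("up", azimuth 0), so the equator lies at ±90°.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import ConfigError, FormatError, InputError, ParseError

__all__ = [
    "Profile1D",
    "DetectorGeometry",
    "Pattern2D",
    "DecayCurve",
    "AnalysisConfig",
    "read_profile",
    "write_profile",
    "read_pattern",
    "write_pattern",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Profile1D:
    """A 1D scattering curve on a strictly increasing positive Q grid."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.intensity.ndim != 1:
            raise InputError("q and intensity must be 1-D sequences")
        if self.q.size != self.intensity.size:
            raise InputError("q and intensity must have equal length")
        if self.q.size < 2:
            raise InputError("a profile needs at least 2 points")
        if not np.all(np.isfinite(self.q)) or not np.all(np.isfinite(self.intensity)):
            raise InputError("q and intensity must be finite")
        if np.any(self.q <= 0):
            raise InputError("q values must be > 0")
        if np.any(np.diff(self.q) <= 0):
            raise InputError("q must be strictly increasing")
        if np.any(self.intensity < 0):
            raise InputError("intensities must be >= 0")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise InputError("sigma must match q in length")
            if np.any(~np.isfinite(self.sigma)) or np.any(self.sigma < 0):
                raise InputError("sigma values must be finite and >= 0")

    @property
    def n(self) -> int:
        return int(self.q.size)

    def interp_at(self, q: np.ndarray) -> np.ndarray:
        """Linear interpolation of the intensity onto an arbitrary grid."""
        return np.interp(np.asarray(q, dtype=float), self.q, self.intensity)

    def window_mask(self, q_lo: float, q_hi: float) -> np.ndarray:
        return (self.q >= q_lo) & (self.q <= q_hi)


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat-detector geometry: wavelength [Å], distance [mm], pixel size [mm],
    beam center (row, col) in 0-based pixel-center coordinates."""

    wavelength: float
    distance: float
    pixel_size: float
    beam_center: tuple[float, float]

    def __post_init__(self):
        if self.wavelength <= 0:
            raise InputError("wavelength must be > 0")
        if self.distance <= 0:
            raise InputError("distance must be > 0")
        if self.pixel_size <= 0:
            raise InputError("pixel_size must be > 0")

    def q_of_radius_mm(self, rho_mm: np.ndarray) -> np.ndarray:
        """Momentum transfer Q = (4π/λ)·sin(½·atan(ρ/L)) for ρ in mm."""
        theta2 = np.arctan2(np.asarray(rho_mm, dtype=float), self.distance)
        return 4.0 * np.pi / self.wavelength * np.sin(0.5 * theta2)

    def dq_drho(self, rho_mm: np.ndarray) -> np.ndarray:
        """Derivative dQ/dρ [1/(Å·mm)] used to pick radial bin widths."""
        rho = np.asarray(rho_mm, dtype=float)
        theta2 = np.arctan2(rho, self.distance)
        dtheta = self.distance / (self.distance**2 + rho**2)
        return 4.0 * np.pi / self.wavelength * 0.5 * np.cos(0.5 * theta2) * dtheta


@dataclass
class Pattern2D:
    """A rectangular detector image plus its geometry.

    ``axis_direction`` is the azimuth (degrees) of the fiber/magnetic-field
    axis on the image; the default 0 means "up" (decreasing row index).
    """

    values: np.ndarray
    geometry: DetectorGeometry
    axis_direction: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise InputError("pattern must be a non-empty 2-D grid")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise InputError("pattern values must be finite and >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def radius_mm(self) -> np.ndarray:
        rows, cols = np.indices(self.shape)
        r0, c0 = self.geometry.beam_center
        dy = (rows - r0) * self.geometry.pixel_size
        dx = (cols - c0) * self.geometry.pixel_size
        return np.hypot(dx, dy)

    def q_map(self) -> np.ndarray:
        """Q [1/Å] of every pixel."""
        return self.geometry.q_of_radius_mm(self.radius_mm())

    def azimuth_map(self) -> np.ndarray:
        """Azimuth [deg, 0..360) of every pixel relative to the fiber axis.

        0° along the axis ("up"), so the equator sits at 90° and 270°.
        The pixel at the beam center gets azimuth 0 by convention.
        """
        rows, cols = np.indices(self.shape)
        r0, c0 = self.geometry.beam_center
        dy = rows - r0  # increases downward
        dx = cols - c0
        phi = np.degrees(np.arctan2(dx, -dy)) - self.axis_direction
        return np.mod(phi, 360.0)


@dataclass
class DecayCurve:
    """Peak intensity versus time (hours) after the D₂O→H₂O swap."""

    t: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.intensity.shape:
            raise InputError("t and intensity must be 1-D and of equal length")
        if np.any(self.t < 0) or np.any(np.diff(self.t) < 0):
            raise InputError("times must be >= 0 and non-decreasing")
        if np.any(self.intensity < 0) or not np.all(np.isfinite(self.intensity)):
            raise InputError("intensities must be finite and >= 0")

    @property
    def n(self) -> int:
        return int(self.t.size)


@dataclass
class AnalysisConfig:
    """Pipeline configuration; file representation is YAML/JSON key:value."""

    q_range: tuple[float, float] = (0.01, 0.25)
    background_degree: int = 4
    smooth_window: int = 5
    sector_opening: float = 10.0
    r_bounds: tuple[float, float] = (5.0, 120.0)
    sigma_r_bounds: tuple[float, float] = (0.0, 5.0)
    r0_bounds: tuple[float, float] = (0.0, 250.0)
    r1_bounds: tuple[float, float] = (0.0, 250.0)
    n0_candidates: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    n1_candidates: tuple[int, ...] = (1, 2, 3)
    seed: int = 0

    def __post_init__(self):
        if not self.q_range[0] < self.q_range[1]:
            raise ConfigError("q_range must satisfy Q1 < Q2")
        if self.background_degree < 0:
            raise ConfigError("background_degree must be >= 0")
        if not 0 < self.sector_opening <= 90:
            raise ConfigError("sector_opening must lie in (0, 90]")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for key, value in raw.items():
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in out.items()}

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# profile I/O
# ---------------------------------------------------------------------------

_PROFILE_HEADER = "# Q[1/A]\tI\tsigma"


def read_profile(path: str | Path, label: str | None = None) -> Profile1D:
    """Read a whitespace/TSV profile: 2 or 3 numeric columns, ``#`` comments.

    Rows are sorted by Q; rows with exactly duplicate Q are collapsed by
    averaging intensities (sigmas are RMS-combined).
    """
    path = Path(path)
    rows: list[tuple[float, ...]] = []
    ncols: int | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) not in (2, 3):
                raise ParseError(
                    f"expected 2 or 3 columns, got {len(parts)}", lineno
                )
            try:
                values = tuple(float(p) for p in parts)
            except ValueError as exc:
                raise ParseError(f"malformed numeric field ({exc})", lineno) from None
            if ncols is None:
                ncols = len(values)
            elif len(values) != ncols:
                raise ParseError(
                    f"inconsistent column count ({len(values)} != {ncols})", lineno
                )
            rows.append(values)
    if len(rows) < 2:
        raise InputError(f"{path}: fewer than 2 usable data rows")

    arr = np.asarray(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]

    q, idx = np.unique(arr[:, 0], return_inverse=True)
    counts = np.bincount(idx)
    intensity = np.bincount(idx, weights=arr[:, 1]) / counts
    sigma = None
    if ncols == 3:
        sigma = np.sqrt(np.bincount(idx, weights=arr[:, 2] ** 2) / counts)
    return Profile1D(q=q, intensity=intensity, sigma=sigma, label=label or path.stem)


def write_profile(profile: Profile1D, path: str | Path) -> None:
    """Write a profile as TSV at full double precision."""
    path = Path(path)
    cols = [profile.q, profile.intensity]
    header = "# Q[1/A]\tI"
    if profile.sigma is not None:
        cols.append(profile.sigma)
        header += "\tsigma"
    lines = [header]
    if profile.label:
        lines.insert(0, f"# {profile.label}")
    for row in zip(*cols):
        lines.append("\t".join(format(v, ".17g") for v in row))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# pattern I/O
# ---------------------------------------------------------------------------

_GEOM_KEYS = ("wavelength_A", "distance_mm", "pixel_mm", "beam_row", "beam_col")


def read_pattern(matrix_path: str | Path, header_path: str | Path) -> Pattern2D:
    """Read a text intensity matrix plus its ``key: value`` geometry header."""
    matrix_path = Path(matrix_path)
    header_path = Path(header_path)

    rows: list[list[float]] = []
    width: int | None = None
    with matrix_path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            try:
                row = [float(p) for p in parts]
            except ValueError as exc:
                raise ParseError(f"malformed numeric field ({exc})", lineno) from None
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise FormatError(
                    f"{matrix_path}: ragged row at line {lineno} "
                    f"({len(row)} values, expected {width})"
                )
            rows.append(row)
    if not rows:
        raise InputError(f"{matrix_path}: empty matrix")

    header: dict[str, float] = {}
    with header_path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if ":" not in stripped:
                raise ParseError("expected 'key: value'", lineno)
            key, _, value = stripped.partition(":")
            try:
                header[key.strip()] = float(value)
            except ValueError:
                raise ParseError(f"non-numeric value for key {key.strip()!r}", lineno)

    for key in _GEOM_KEYS:
        if key not in header:
            raise ConfigError(f"geometry header missing required key {key!r}")

    geometry = DetectorGeometry(
        wavelength=header["wavelength_A"],
        distance=header["distance_mm"],
        pixel_size=header["pixel_mm"],
        beam_center=(header["beam_row"], header["beam_col"]),
    )
    return Pattern2D(
        values=np.asarray(rows, dtype=float),
        geometry=geometry,
        axis_direction=header.get("axis_deg", 0.0),
    )


def write_pattern(
    pattern: Pattern2D, matrix_path: str | Path, header_path: str | Path
) -> None:
    """Write the matrix and geometry header of a pattern as plain text."""
    lines = []
    for row in pattern.values:
        lines.append(" ".join(format(v, ".17g") for v in row))
    Path(matrix_path).write_text("\n".join(lines) + "\n")

    g = pattern.geometry
    header = (
        f"wavelength_A: {g.wavelength:.17g}\n"
        f"distance_mm: {g.distance:.17g}\n"
        f"pixel_mm: {g.pixel_size:.17g}\n"
        f"beam_row: {g.beam_center[0]:.17g}\n"
        f"beam_col: {g.beam_center[1]:.17g}\n"
        f"axis_deg: {pattern.axis_direction:.17g}\n"
    )
    Path(header_path).write_text(header)
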