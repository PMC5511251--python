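"""1D/2D reduction: background, Gaussian peaks, sectors, orientation, merging.

The reduction steps mirror common fiber-pattern practice: a polynomial
background is pinned to the intensity minima between peaks and subtracted;
the residual is fit by a sum of Gaussians to extract spacings, integral
intensities and integral widths; 2D patterns are reduced by sector
integration (a sector plus its mirror, so "10° opening" means ±5° around
the equator or meridian) and by azimuthal profiles in a radial Q band, from
which the mutual orientation of coexisting fiber populations is read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as P
from scipy.optimize import curve_fit
from scipy.stats import f as f_dist

from .dataio import Pattern2D, Profile1D
from .errors import AnalysisError, DegenerateDataError, InputError
from .model import q_to_d

__all__ = [
    "BackgroundModel",
    "PeakFit",
    "AzimuthalProfile",
    "OrientationResult",
    "estimate_background",
    "fit_gaussian_peaks",
    "coherence_length",
    "sector_integrate",
    "azimuthal_profile",
    "mutual_orientation",
    "merge_profiles",
]

SQRT_2PI = np.sqrt(2.0 * np.pi)


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------


@dataclass
class BackgroundModel:
    """Polynomial background pinned to intensity minima.

    ``coefficients`` are in ascending order over Q. ``degree_used`` may be
    lower than requested when too few anchor minima were found.
    """

    coefficients: np.ndarray
    anchor_q: np.ndarray
    anchor_intensity: np.ndarray
    degree_used: int
    degree_requested: int

    def evaluate(self, q) -> np.ndarray:
        return P.polyval(np.asarray(q, dtype=float), self.coefficients)

    def evaluate_clipped(self, profile: Profile1D) -> np.ndarray:
        """Evaluation on the profile grid, clipped so B(Q) <= I(Q) pointwise."""
        return np.minimum(self.evaluate(profile.q), profile.intensity)


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.copy()
    if window % 2 == 0:
        raise InputError("smooth_window must be odd")
    pad = window // 2
    padded = np.pad(y, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def estimate_background(
    profile: Profile1D, degree: int = 4, smooth_window: int = 5
) -> BackgroundModel:
    """Fit a polynomial through the intensity minima of a smoothed profile.

    The profile is smoothed by a centered moving average, strict local
    minima of the smoothed curve are collected, the two endpoints are always
    added as anchors, and a least-squares polynomial of the requested degree
    is fit to the anchors' raw intensities. When there are fewer anchors
    than degree+1 the degree is reduced (recorded in ``degree_used``), which
    makes the fit an exact interpolation through the anchors.
    """
    if degree < 0:
        raise InputError("degree must be >= 0")
    if profile.n < degree + 1:
        raise InputError("profile has fewer points than degree + 1")
    y = _smooth(profile.intensity, smooth_window)
    interior = np.arange(1, profile.n - 1)
    is_min = (y[interior] < y[interior - 1]) & (y[interior] < y[interior + 1])
    idx = np.unique(np.concatenate([[0], interior[is_min], [profile.n - 1]]))
    anchor_q = profile.q[idx]
    anchor_i = profile.intensity[idx]

    degree_used = min(degree, len(idx) - 1)
    if degree_used < 0:
        raise AnalysisError("no anchors available for background fit")
    coeffs = P.polyfit(anchor_q, anchor_i, degree_used)
    return BackgroundModel(
        coefficients=coeffs,
        anchor_q=anchor_q,
        anchor_intensity=anchor_i,
        degree_used=degree_used,
        degree_requested=degree,
    )


# ---------------------------------------------------------------------------
# Gaussian peaks
# ---------------------------------------------------------------------------


@dataclass
class PeakFit:
    """One Gaussian peak with its standard derived quantities."""

    center: float
    height: float
    width_sigma: float
    low_signal: bool = False

    @property
    def integral_intensity(self) -> float:
        return self.height * self.width_sigma * SQRT_2PI

    @property
    def integral_width(self) -> float:
        """Integral breadth: integral intensity / height = σ·√(2π) [1/Å]."""
        return self.width_sigma * SQRT_2PI

    @property
    def d_spacing(self) -> float:
        return q_to_d(self.center)


def _gaussian_sum(q, *params):
    n = len(params) // 3
    out = np.zeros_like(q)
    for i in range(n):
        h, c, s = params[3 * i : 3 * i + 3]
        out = out + h * np.exp(-0.5 * ((q - c) / s) ** 2)
    return out


def _peak_seed_centers(q: np.ndarray, resid: np.ndarray, n_peaks: int) -> np.ndarray:
    interior = np.arange(1, len(q) - 1)
    is_max = (resid[interior] >= resid[interior - 1]) & (
        resid[interior] > resid[interior + 1]
    )
    cand = interior[is_max]
    cand = cand[np.argsort(resid[cand])[::-1]]
    if len(cand) < n_peaks:
        extra = np.argsort(resid)[::-1]
        cand = np.unique(np.concatenate([cand, extra[: n_peaks * 3]]))[:n_peaks]
        cand = cand[np.argsort(resid[cand])[::-1]]
    return q[cand[:n_peaks]]


def fit_gaussian_peaks(
    profile: Profile1D,
    n_peaks: int,
    background: BackgroundModel | None = None,
    max_restarts: int = 3,
    seed: int = 0,
) -> list[PeakFit]:
    """Nonlinear least squares of a sum of Gaussians to (I − B).

    Initial centers sit at the largest residual maxima; fits that fail to
    converge are restarted with jittered starts. Returned peaks are sorted
    by center; a peak whose height is below 3× the robust residual noise is
    flagged ``low_signal``.
    """
    if not 1 <= n_peaks <= 6:
        raise InputError("n_peaks must lie in 1..6")
    q = profile.q
    resid = profile.intensity.astype(float)
    if background is not None:
        resid = resid - background.evaluate_clipped(profile)

    span = q[-1] - q[0]
    dq = np.median(np.diff(q))
    centers0 = _peak_seed_centers(q, resid, n_peaks)
    amp0 = np.interp(centers0, q, resid)
    amp_hi = max(resid.max(), 1e-30) * 2.0

    rng = np.random.default_rng(seed)
    lower, upper, p0 = [], [], []
    for c, a in zip(centers0, amp0):
        p0 += [max(a, 1e-12), c, span / (8.0 * n_peaks)]
        lower += [0.0, q[0], dq / 2.0]
        upper += [amp_hi, q[-1], span]

    best_exc: Exception | None = None
    start = np.asarray(p0, dtype=float)
    for attempt in range(max_restarts + 1):
        try:
            popt, _ = curve_fit(
                _gaussian_sum,
                q,
                resid,
                p0=start,
                bounds=(lower, upper),
                maxfev=20000,
            )
            break
        except (RuntimeError, ValueError) as exc:
            best_exc = exc
            jitter = 1.0 + 0.2 * rng.standard_normal(len(p0))
            start = np.clip(np.asarray(p0) * jitter, lower, upper)
    else:
        raise AnalysisError(
            f"Gaussian peak fit failed after {max_restarts + 1} attempts: {best_exc}",
            diagnostics={"residual_max": float(resid.max())},
        )

    model = _gaussian_sum(q, *popt)
    noise = 1.4826 * np.median(np.abs(resid - model - np.median(resid - model)))
    peaks = []
    for i in range(n_peaks):
        h, c, s = popt[3 * i : 3 * i + 3]
        peaks.append(
            PeakFit(
                center=float(c),
                height=float(h),
                width_sigma=float(s),
                low_signal=bool(h < 3.0 * noise),
            )
        )
    peaks.sort(key=lambda p: p.center)
    return peaks


def coherence_length(peak: PeakFit) -> float:
    """Scherrer-type coherence length L = 2π / integral width [Å]."""
    width = peak.integral_width
    if width < 1e-12:
        warnings.warn("zero integral width: resolution-limited peak", stacklevel=2)
        return float("inf")
    return 2.0 * np.pi / width


# ---------------------------------------------------------------------------
# 2D reduction
# ---------------------------------------------------------------------------


def _fold_angle_diff(phi: np.ndarray, center: float) -> np.ndarray:
    """Angular distance between azimuths under the 180° (Friedel) fold."""
    return np.abs(np.mod(phi - center + 90.0, 180.0) - 90.0)


def sector_integrate(
    pattern: Pattern2D, center_azimuth: float, opening: float = 10.0
) -> Profile1D:
    """Average pixel intensities in a sector (and its mirror) into I(Q).

    ``opening`` is the full sector opening: pixels whose azimuth lies within
    ±opening/2 of ``center_azimuth`` or of its antipode are kept, then
    radially binned on a regular Q grid whose bin width is the median
    per-pixel radial ΔQ.
    """
    if not 0 < opening <= 90:
        raise InputError("opening must lie in (0, 90]")
    qmap = pattern.q_map().ravel()
    phimap = pattern.azimuth_map().ravel()
    rho = pattern.radius_mm().ravel()
    values = pattern.values.ravel()

    sel = (rho > 0) & (_fold_angle_diff(phimap, center_azimuth) <= opening / 2.0)
    if not np.any(sel):
        raise AnalysisError("no pixels fall inside the requested sector")
    qs, vs = qmap[sel], values[sel]

    dq = np.median(pattern.geometry.dq_drho(rho[sel]) * pattern.geometry.pixel_size)
    n_bins = max(2, int(np.ceil((qs.max() - qs.min()) / dq)))
    edges = np.linspace(qs.min(), qs.max() + 1e-12, n_bins + 1)
    which = np.digitize(qs, edges) - 1
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=vs, minlength=n_bins)
    keep = counts > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Profile1D(
        q=centers[keep],
        intensity=sums[keep] / counts[keep],
        label=f"sector@{center_azimuth:g}deg",
    )


@dataclass
class AzimuthalProfile:
    """Mean intensity versus azimuth in a radial Q band."""

    phi: np.ndarray
    intensity: np.ndarray
    q_band: tuple[float, float]

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.phi.shape != self.intensity.shape:
            raise InputError("phi and intensity must have equal length")
        if np.any(np.diff(self.phi) <= 0):
            raise InputError("phi must be strictly increasing")
        if np.any(self.phi < 0) or np.any(self.phi >= 360):
            raise InputError("phi must lie in [0, 360)")


def azimuthal_profile(
    pattern: Pattern2D, q_band: tuple[float, float], bin_width: float = 2.0
) -> AzimuthalProfile:
    """Mean intensity in azimuth bins over pixels with Q inside the band."""
    q_lo, q_hi = q_band
    if not q_lo < q_hi:
        raise InputError("q_band must satisfy Qlo < Qhi")
    qmap = pattern.q_map().ravel()
    phimap = pattern.azimuth_map().ravel()
    rho = pattern.radius_mm().ravel()
    values = pattern.values.ravel()

    sel = (rho > 0) & (qmap >= q_lo) & (qmap <= q_hi)
    if not np.any(sel):
        raise AnalysisError("no pixels fall inside the requested Q band")

    n_bins = int(round(360.0 / bin_width))
    which = np.minimum((phimap[sel] / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=values[sel], minlength=n_bins)
    keep = counts > 0
    centers = (np.arange(n_bins) + 0.5) * bin_width
    return AzimuthalProfile(
        phi=centers[keep], intensity=sums[keep] / counts[keep], q_band=(q_lo, q_hi)
    )


# ---------------------------------------------------------------------------
# mutual orientation
# ---------------------------------------------------------------------------


@dataclass
class OrientationResult:
    """One- or two-population azimuthal decomposition (after 180° folding)."""

    peak_centers: list[float]
    widths: list[float]
    separation: float | None = None
    f_pvalue: float | None = None

    def __post_init__(self):
        if self.separation is not None and not 0 < self.separation <= 90:
            raise InputError("separation must lie in (0, 90]")


def _one_gauss(phi, h, c, s, b):
    return b + h * np.exp(-0.5 * ((phi - c) / s) ** 2)


def _two_gauss(phi, h1, c1, s1, h2, c2, s2, b):
    return (
        b
        + h1 * np.exp(-0.5 * ((phi - c1) / s1) ** 2)
        + h2 * np.exp(-0.5 * ((phi - c2) / s2) ** 2)
    )


def _fold_half_turn(az: AzimuthalProfile) -> tuple[np.ndarray, np.ndarray]:
    phi = np.mod(az.phi, 180.0)
    order = np.argsort(phi, kind="stable")
    phi, inten = phi[order], az.intensity[order]
    uq, idx = np.unique(phi, return_inverse=True)
    counts = np.bincount(idx)
    folded = np.bincount(idx, weights=inten) / counts
    return uq, folded


def mutual_orientation(az: AzimuthalProfile, alpha: float = 0.05) -> OrientationResult:
    """Decide one vs two fiber populations and report their separation.

    The azimuthal profile is folded to a half turn, fit by one and by two
    Gaussians on a constant base, and the extra pair of parameters is kept
    only if an F-test at level ``alpha`` favors the richer model. Ties and
    numerically perfect single-Gaussian fits go to the simpler model.
    """
    phi, inten = _fold_half_turn(az)
    n = len(phi)
    if n < 8:
        raise AnalysisError("too few azimuth bins for orientation analysis")

    base = float(np.percentile(inten, 10))
    span = float(inten.max() - base)
    if span <= 0:
        raise DegenerateDataError("flat azimuthal profile: no orientation signal")

    # single-Gaussian fit
    c0 = float(phi[np.argmax(inten)])
    try:
        p1, _ = curve_fit(
            _one_gauss,
            phi,
            inten,
            p0=[span, c0, 15.0, base],
            bounds=([0, 0, 0.5, 0], [10 * span + 1e-30, 180, 180, np.inf]),
            maxfev=20000,
        )
        rss1 = float(np.sum((inten - _one_gauss(phi, *p1)) ** 2))
    except (RuntimeError, ValueError) as exc:
        raise AnalysisError(f"single-Gaussian orientation fit failed: {exc}")

    # two-Gaussian fit seeded at the two largest separated maxima
    interior = np.arange(1, n - 1)
    is_max = (inten[interior] >= inten[interior - 1]) & (
        inten[interior] > inten[interior + 1]
    )
    maxima = interior[is_max]
    maxima = maxima[np.argsort(inten[maxima])[::-1]]
    if len(maxima) >= 2:
        cA, cB = float(phi[maxima[0]]), float(phi[maxima[1]])
    else:
        cA, cB = c0 - 10.0, c0 + 10.0
    try:
        p2, _ = curve_fit(
            _two_gauss,
            phi,
            inten,
            p0=[span, cA, 8.0, span, cB, 8.0, base],
            bounds=(
                [0, 0, 0.5, 0, 0, 0.5, 0],
                [10 * span + 1e-30, 180, 90, 10 * span + 1e-30, 180, 90, np.inf],
            ),
            maxfev=40000,
        )
        rss2 = float(np.sum((inten - _two_gauss(phi, *p2)) ** 2))
    except (RuntimeError, ValueError):
        p2, rss2 = None, np.inf

    tss = float(np.sum((inten - inten.mean()) ** 2))
    two_better = False
    pvalue = None
    if p2 is not None and rss1 > 1e-12 * tss and n > 7:
        df2 = n - 7
        if rss2 <= 0:
            two_better, pvalue = True, 0.0
        else:
            fstat = ((rss1 - rss2) / 3.0) / (rss2 / df2)
            pvalue = float(f_dist.sf(max(fstat, 0.0), 3, df2))
            two_better = pvalue < alpha

    if two_better:
        h1, c1, s1, h2, c2, s2, _ = p2
        sep = abs(float(c1) - float(c2))
        if sep > 90.0:
            sep = 180.0 - sep
        centers = sorted([float(c1), float(c2)])
        return OrientationResult(
            peak_centers=centers,
            widths=[float(s1), float(s2)],
            separation=sep if sep > 0 else None,
            f_pvalue=pvalue,
        )
    return OrientationResult(
        peak_centers=[float(p1[1])],
        widths=[float(p1[2])],
        separation=None,
        f_pvalue=pvalue,
    )


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------


def merge_profiles(profiles: list[Profile1D]) -> Profile1D:
    """Merge overlapping profiles (e.g. multiple detector distances).

    Profiles are ordered by their lowest Q; each subsequent profile is
    scaled to the running merge by the median intensity ratio over the
    overlap, then concatenated; exactly duplicated Q points are averaged.
    """
    if len(profiles) < 2:
        raise InputError("need at least 2 profiles to merge")
    ordered = sorted(profiles, key=lambda p: (p.q[0], p.q[-1]))

    q = ordered[0].q.copy()
    inten = ordered[0].intensity.copy()
    for prof in ordered[1:]:
        lo = max(q[0], prof.q[0])
        hi = min(q[-1], prof.q[-1])
        if lo >= hi:
            raise InputError(
                f"no Q overlap between consecutive profiles ({q[-1]:g} < {prof.q[0]:g})"
            )
        in_overlap = (prof.q >= lo) & (prof.q <= hi)
        ref = np.interp(prof.q[in_overlap], q, inten)
        new = prof.intensity[in_overlap]
        ok = new > 0
        if not np.any(ok):
            raise InputError("overlap contains no positive intensities to scale by")
        factor = float(np.median(ref[ok] / new[ok]))
        q = np.concatenate([q, prof.q])
        inten = np.concatenate([inten, prof.intensity * factor])

    order = np.argsort(q, kind="stable")
    q, inten = q[order], inten[order]
    uq, idx = np.unique(q, return_inverse=True)
    counts = np.bincount(idx)
    merged = np.bincount(idx, weights=inten) / counts
    return Profile1D(q=uq, intensity=merged, label="merged")
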