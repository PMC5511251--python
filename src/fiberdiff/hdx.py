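"""D→H exchange kinetics: band integration and exponential decay fitting.

The decay of the predominant diffraction peak after the D₂O→H₂O swap is fit
by a three-parameter exponential

    I(t) = i_inf + (i0 − i_inf) · exp(−t / tau)

so that both the exchange time ``tau`` and the residual (asymptotic)
intensity are available; a fixed-asymptote two-parameter variant is exposed
for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .dataio import DecayCurve, Profile1D
from .errors import AnalysisError, DegenerateDataError, InputError

__all__ = ["ExchangeFit", "peak_band_timeseries", "fit_decay"]


@dataclass
class ExchangeFit:
    """Exponential-fit parameters of an exchange decay curve."""

    tau: float
    i0: float
    i_inf: float
    rms_residual: float
    residual_fraction: float = 0.0

    def __post_init__(self):
        if self.tau <= 0:
            raise InputError("tau must be > 0")
        frac = self.i_inf / self.i0 if self.i0 != 0 else 0.0
        if not 0.0 <= frac <= 1.0:
            # round-off next to the bounds is clipped quietly
            if not -1e-9 <= frac <= 1.0 + 1e-9:
                warnings.warn(
                    f"residual fraction {frac:.3f} outside [0, 1]; clipping",
                    stacklevel=2,
                )
            frac = min(max(frac, 0.0), 1.0)
        self.residual_fraction = float(frac)

    def evaluate(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.i_inf + (self.i0 - self.i_inf) * np.exp(-t / self.tau)


def peak_band_timeseries(
    profiles: list[Profile1D], times, q_band: tuple[float, float]
) -> DecayCurve:
    """Integrate each profile over a Q band to one intensity per time point."""
    q_lo, q_hi = q_band
    if not q_lo < q_hi:
        raise InputError("q_band must satisfy Qlo < Qhi (zero-width band rejected)")
    times = np.asarray(times, dtype=float)
    if len(profiles) != times.size:
        raise InputError("profiles and times must have equal length")
    if len(profiles) < 4:
        raise InputError("need at least 4 time points")

    values = np.empty(len(profiles))
    for i, prof in enumerate(profiles):
        if q_lo < prof.q[0] or q_hi > prof.q[-1]:
            raise InputError(
                f"band ({q_lo:g}, {q_hi:g}) outside profile range at time point {i}"
            )
        # integrate on the native grid plus interpolated band edges
        inside = (prof.q > q_lo) & (prof.q < q_hi)
        q = np.concatenate([[q_lo], prof.q[inside], [q_hi]])
        y = np.concatenate(
            [[prof.interp_at(q_lo)], prof.intensity[inside], [prof.interp_at(q_hi)]]
        )
        values[i] = np.trapezoid(y, q)
    return DecayCurve(t=times, intensity=values)


def _decay(t, tau, i0, i_inf):
    return i_inf + (i0 - i_inf) * np.exp(-t / tau)


def fit_decay(curve: DecayCurve, fix_asymptote: float | None = None) -> ExchangeFit:
    """Least-squares exponential fit of a decay curve.

    ``fix_asymptote`` pins i_inf (e.g. 0.0 for the two-parameter variant).
    Initial guesses: i0 = first point, i_inf = last point, tau = span/3.
    Rising curves (negative amplitude) are fit but flagged with a warning.
    """
    if curve.n < 4:
        raise InputError("decay fitting needs at least 4 points")
    t, y = curve.t, curve.intensity
    if np.ptp(y) == 0:
        raise DegenerateDataError("flat intensity curve: nothing to fit")

    span = max(t[-1] - t[0], 1e-9)
    tau0 = span / 3.0

    try:
        if fix_asymptote is None:
            popt, _ = curve_fit(
                _decay,
                t,
                y,
                p0=[tau0, y[0], y[-1]],
                bounds=([1e-9, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
            tau, i0, i_inf = (float(v) for v in popt)
        else:
            i_inf = float(fix_asymptote)
            popt, _ = curve_fit(
                lambda tt, tau, i0: _decay(tt, tau, i0, i_inf),
                t,
                y,
                p0=[tau0, y[0]],
                bounds=([1e-9, -np.inf], [np.inf, np.inf]),
                maxfev=20000,
            )
            tau, i0 = (float(v) for v in popt)
    except (RuntimeError, ValueError) as exc:
        raise AnalysisError(f"decay fit failed to converge: {exc}")

    if i0 < i_inf:
        warnings.warn(
            "fitted amplitude is negative (rising curve); interpreting as "
            "background build-up",
            stacklevel=2,
        )
    resid = y - _decay(t, tau, i0, i_inf)
    return ExchangeFit(
        tau=tau,
        i0=i0,
        i_inf=i_inf,
        rms_residual=float(np.sqrt(np.mean(resid**2))),
    )
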