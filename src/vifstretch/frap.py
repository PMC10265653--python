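"""Fluorescence recovery after photobleaching: Soumpasis diffusion fits.

For pure lateral diffusion into a uniformly bleached circular spot of
radius w, the normalized recovery follows the Soumpasis solution

    f_S(t) = exp(-2 tau_D / t) * [I0(2 tau_D / t) + I1(2 tau_D / t)],

where tau_D is the characteristic diffusion time and I0, I1 are modified
Bessel functions of the first kind. The diffusion coefficient follows as
D = w^2 / (4 tau_D); the mobile fraction from the recovery plateau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import i0e, i1e


@dataclass
class FRAPCurve:
    """A normalized post-bleach recovery curve.

    times start after the bleach (strictly increasing, > 0); intensities
    are normalized to the mean pre-bleach level ``F_pre``; ``w`` is the
    bleach-spot radius in um (required to convert tau_D into D).
    """

    times: np.ndarray
    intensities: np.ndarray
    w: float
    F_pre: float = 1.0

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.intensities = np.asarray(self.intensities, float)
        if self.times.ndim != 1 or self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must be matching 1D arrays")
        if np.any(np.diff(self.times) <= 0) or self.times[0] <= 0:
            raise ValueError("times must be strictly increasing and positive")
        if self.w <= 0:
            raise ValueError("bleach-spot radius must be positive")


@dataclass
class FRAPFit:
    """Result of a Soumpasis fit."""

    tau_D: float
    D: float
    mobile_fraction: float
    F0: float
    F_inf: float
    residual_rms: float
    stderr: dict

    def __post_init__(self):
        if self.mobile_fraction > 1.05:
            import warnings
            warnings.warn("mobile fraction exceeds 1.05; check normalization")


def soumpasis_model(t, tau_D):
    """Soumpasis recovery fraction f_S(t; tau_D), stable for all t > 0.

    Uses exponentially scaled Bessel functions: with x = 2 tau_D / t,
    f_S = i0e(x) + i1e(x), which avoids overflow for t << tau_D.
    """
    t = np.asarray(t, float)
    if np.any(t <= 0) or tau_D <= 0:
        raise ValueError("t and tau_D must be positive")
    x = 2.0 * tau_D / t
    return i0e(x) + i1e(x)


def fit_frap(curve: FRAPCurve) -> FRAPFit:
    """Nonlinear least-squares fit of (tau_D, F0, F_inf) to a recovery curve.

    The initial tau_D is taken from the half-recovery time (f_S(tau_D) is
    close to 1/2, so the time at which the curve crosses the midpoint of
    its range is a good starting value).
    """
    t, y = curve.times, curve.intensities
    if len(t) < 10:
        raise ValueError("need at least 10 post-bleach samples")
    f0_guess = float(np.min(y[: max(len(y) // 20, 3)]))
    finf_guess = float(np.mean(y[-max(len(y) // 10, 3):]))
    half = (f0_guess + finf_guess) / 2.0
    above = np.nonzero(y >= half)[0]
    tau0 = float(t[above[0]]) if len(above) else float(t[len(t) // 2])

    def model(tt, tau, f0, finf):
        return f0 + (finf - f0) * soumpasis_model(tt, tau)

    try:
        popt, pcov = curve_fit(model, t, y, p0=[tau0, f0_guess, finf_guess],
                               bounds=([1e-6, -np.inf, -np.inf],
                                       [np.inf, np.inf, np.inf]),
                               maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"Soumpasis fit did not converge: {exc}") from exc
    tau, f0, finf = popt
    perr = np.sqrt(np.diag(pcov))
    resid = y - model(t, *popt)
    mobile = (finf - f0) / (curve.F_pre - f0)
    return FRAPFit(
        tau_D=float(tau),
        D=float(curve.w**2 / (4.0 * tau)),
        mobile_fraction=float(mobile),
        F0=float(f0),
        F_inf=float(finf),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        stderr={"tau_D": float(perr[0]), "F0": float(perr[1]),
                "F_inf": float(perr[2])},
    )


def diffusion_distance(D: float, t: float) -> float:
    """Root-mean-square 2D displacement sqrt(4 D t) of a diffusing particle."""
    if D < 0 or t <= 0:
        raise ValueError("need D >= 0 and t > 0")
    return float(np.sqrt(4.0 * D * t))
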