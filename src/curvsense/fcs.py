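"""Fluorescence correlation spectroscopy: model, fitting, conversions.

The autocorrelation model is the standard 2D anomalous-diffusion form with
a fixed triplet-state contribution:

    G(t) = 1 + (1 + A exp(-t / tau_c)) * (1 / N_p) * 1 / (1 + (t / tau_D)^alpha)

Free parameters are the particle number ``N_p``, diffusion time ``tau_D``
and the anomalous exponent ``alpha`` (bounded to [0.9, 1.0]); ``A`` and
``tau_c`` are held fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from . import constants

__all__ = ["FCSFit", "fcs_model", "fit_fcs", "hydrodynamic_radius",
           "calibrate_beam_waist", "HydroRadius"]


@dataclass(frozen=True)
class FCSFit:
    n_particles: float
    tau_d_s: float
    alpha: float
    triplet_amplitude: float = constants.TRIPLET_AMPLITUDE
    triplet_time_s: float = constants.TRIPLET_TIME_S
    residual_norm: float = float("nan")
    boundary_pinned: bool = False


def fcs_model(t, n_particles: float, tau_d_s: float, alpha: float = 1.0,
              triplet_amplitude: float = constants.TRIPLET_AMPLITUDE,
              triplet_time_s: float = constants.TRIPLET_TIME_S) -> np.ndarray:
    """Evaluate the autocorrelation model at lag times ``t`` (seconds)."""
    if n_particles <= 0 or tau_d_s <= 0:
        raise ValueError("particle number and diffusion time must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("lag times must be non-negative")
    triplet = 1.0 + triplet_amplitude * np.exp(-t / triplet_time_s)
    return 1.0 + triplet / n_particles / (1.0 + (t / tau_d_s) ** alpha)


def fit_fcs(lag_s: Sequence[float], g: Sequence[float],
            triplet_amplitude: float = constants.TRIPLET_AMPLITUDE,
            triplet_time_s: float = constants.TRIPLET_TIME_S,
            alpha_bounds: tuple[float, float] = constants.ALPHA_BOUNDS,
            ) -> FCSFit:
    """Least-squares fit of (N_p, tau_D, alpha) with triplet terms fixed."""
    t = np.asarray(lag_s, dtype=float)
    y = np.asarray(g, dtype=float)
    if len(t) < 5 or len(t) != len(y):
        raise ValueError("need matching lag/G arrays with at least 5 points")
    if np.any(np.diff(t) <= 0) or t[0] <= 0:
        raise ValueError("lag times must be positive and strictly increasing")
    if t[-1] / t[0] < 100:
        raise ValueError("trace must span at least two decades of lag time")

    def model(tt, n_p, tau_d, alpha):
        return fcs_model(tt, n_p, tau_d, alpha, triplet_amplitude, triplet_time_s)

    amp = max(y.max() - 1.0, 1e-9)
    n0 = (1.0 + triplet_amplitude) / amp
    # initial tau: lag where the decaying part first drops below half amplitude
    half = 1.0 + amp / 2.0
    below = np.flatnonzero(y < half)
    tau0 = t[below[0]] if len(below) else math.sqrt(t[0] * t[-1])
    tau_lo, tau_hi = t[0] / 10.0, t[-1] * 10.0
    popt, _ = curve_fit(
        model, t, y, p0=(n0, tau0, 0.95),
        bounds=([1e-12, tau_lo, alpha_bounds[0]],
                [np.inf, tau_hi, alpha_bounds[1]]), maxfev=20000)
    n_p, tau_d, alpha = (float(v) for v in popt)
    resid = y - model(t, n_p, tau_d, alpha)
    pinned = bool(np.isclose(tau_d, tau_lo) or np.isclose(tau_d, tau_hi))
    return FCSFit(n_p, tau_d, alpha, triplet_amplitude, triplet_time_s,
                  residual_norm=float(np.sqrt((resid ** 2).sum())),
                  boundary_pinned=pinned)


@dataclass(frozen=True)
class HydroRadius:
    """Stokes-Einstein conversion record."""

    beam_waist_nm: float
    diffusion_nm2_per_s: float
    temperature_K: float
    viscosity_Pa_s: float
    r_h_nm: float


def hydrodynamic_radius(fit: FCSFit, beam_waist_nm: float,
                        temperature_K: float = constants.TEMPERATURE_K,
                        viscosity_Pa_s: float = constants.WATER_VISCOSITY_PA_S,
                        ) -> HydroRadius:
    """Hydrodynamic radius from a fitted diffusion time.

    ``D = w^2 / (4 tau_D)`` for a calibrated beam waist ``w``, then
    ``r_H = k_B T / (6 pi eta D)``.
    """
    if beam_waist_nm <= 0:
        raise ValueError("beam waist must be positive (calibrate it first)")
    if temperature_K <= 0 or viscosity_Pa_s <= 0:
        raise ValueError("temperature and viscosity must be positive")
    d_nm2_s = beam_waist_nm ** 2 / (4.0 * fit.tau_d_s)
    d_m2_s = d_nm2_s * 1e-18
    r_m = (constants.BOLTZMANN_J_PER_K * temperature_K
           / (6.0 * math.pi * viscosity_Pa_s * d_m2_s))
    return HydroRadius(beam_waist_nm, d_nm2_s, temperature_K, viscosity_Pa_s,
                       r_h_nm=r_m * 1e9)


def calibrate_beam_waist(tau_d_ref_s: float, d_ref_nm2_per_s: float) -> float:
    """Beam waist (nm) from a reference species of known diffusivity."""
    if tau_d_ref_s <= 0 or d_ref_nm2_per_s <= 0:
        raise ValueError("reference values must be positive")
    return math.sqrt(4.0 * d_ref_nm2_per_s * tau_d_ref_s)
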