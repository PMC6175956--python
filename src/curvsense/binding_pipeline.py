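"""Tethered-vesicle binding analysis.

Input is a per-punctum table of lipid and protein fluorescence amplitudes.
The pipeline calibrates vesicle diameters against a dynamic-light-scattering
mean, converts protein intensity to bound-protein counts via a
single-molecule brightness, bins by diameter, computes bound density and
fractional membrane coverage, normalizes to the 200 nm reference window,
fits saturation isotherms per diameter class with a geometric
binding-capacity correction, and evaluates two-channel filopodium
partition coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import gaussian_kde

from . import constants

__all__ = [
    "DiameterCalibration", "ProteinCalibration", "LangmuirFit",
    "GeometryCorrection",
    "calibrate_diameters", "proteins_per_vesicle", "bin_profile",
    "density_and_coverage", "footprint_from_chain_length",
    "normalized_sensitivity", "fit_langmuir", "correct_bmax",
    "filopodia_partition", "intensity_mode",
]


@dataclass(frozen=True)
class DiameterCalibration:
    """Brightness-to-diameter scaling anchored to a DLS mean diameter.

    Lipid brightness is taken proportional to membrane area, i.e.
    ``diameter = dls_mean * (intensity / modal_intensity) ** (1 / exponent)``
    with exponent 2 by default.
    """

    dls_mean_diameter_nm: float
    brightness_exponent: float = 2.0

    def __post_init__(self) -> None:
        if self.dls_mean_diameter_nm <= 0 or self.brightness_exponent <= 0:
            raise ValueError("calibration parameters must be positive")


@dataclass(frozen=True)
class ProteinCalibration:
    """Modal brightness of a single labelled protein (arbitrary units)."""

    single_molecule_intensity: float

    def __post_init__(self) -> None:
        if self.single_molecule_intensity <= 0:
            raise ValueError("single-molecule intensity must be positive")


def intensity_mode(intensities: np.ndarray) -> float:
    """Peak of a kernel-smoothed intensity histogram (Silverman bandwidth)."""
    x = np.asarray(intensities, dtype=float)
    if x.std() == 0:
        raise ValueError("degenerate intensity distribution (all values equal)")
    kde = gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 2048)
    return float(grid[np.argmax(kde(grid))])


def calibrate_diameters(lipid_intensities: Sequence[float],
                        calibration: DiameterCalibration) -> np.ndarray:
    """Vesicle diameters (nm) from lipid-channel brightness.

    The modal brightness of the population is mapped onto the DLS mean
    diameter of the preparation; other puncta scale as a power law with the
    configured exponent (2 for area-proportional brightness).
    """
    x = np.asarray(lipid_intensities, dtype=float)
    if len(x) < 50:
        raise ValueError("need at least 50 puncta for a stable mode estimate")
    if np.any(x < 0):
        raise ValueError("intensities must be non-negative")
    mode = intensity_mode(x)
    return calibration.dls_mean_diameter_nm * (x / mode) ** (
        1.0 / calibration.brightness_exponent)


def proteins_per_vesicle(protein_intensities: Sequence[float],
                         calibration: ProteinCalibration) -> np.ndarray:
    """Real-valued bound-protein counts (intensity / single-molecule peak)."""
    x = np.asarray(protein_intensities, dtype=float)
    if np.any(x < 0):
        raise ValueError("intensities must be non-negative")
    return x / calibration.single_molecule_intensity


def bin_profile(diameters_nm: Sequence[float], counts: Sequence[float],
                bin_step: float = constants.BIN_STEP_NM,
                bin_min: float = constants.BIN_MIN_NM,
                bin_max: float = constants.BIN_MAX_NM) -> pd.DataFrame:
    """Moving-average profile: mean bound count per 5 nm diameter bin.

    Bins are half-open ``[c - 2.5, c + 2.5)`` around centres 20, 25, ...,
    250 nm; empty bins are omitted; the 95% CI is 1.96 x SEM.
    """
    d = np.asarray(diameters_nm, dtype=float)
    c = np.asarray(counts, dtype=float)
    if len(d) == 0 or len(d) != len(c):
        raise ValueError("diameters and counts must be equal-length, non-empty")
    centers = np.arange(bin_min, bin_max + bin_step / 2, bin_step)
    rows = []
    half = constants.BIN_HALF_WIDTH_NM
    for center in centers:
        sel = (d >= center - half) & (d < center + half)
        n = int(sel.sum())
        if n == 0:
            continue
        vals = c[sel]
        sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        rows.append({
            "diameter_nm": float(center),
            "mean_count": float(vals.mean()),
            "sem": sem,
            "ci95": 1.96 * sem,
            "n": n,
        })
    if not rows:
        raise ValueError("no puncta fall inside the binning range")
    return pd.DataFrame(rows)


def density_and_coverage(profile: pd.DataFrame,
                         footprint_nm2: float) -> pd.DataFrame:
    """Bound density (proteins/nm^2) and fractional coverage per bin.

    Density divides the mean count by the vesicle surface area ``pi d^2``;
    coverage multiplies density by the protein footprint.  The
    puncta-weighted population-average coverage is stored in
    ``df.attrs['mean_coverage']`` for coverage-matched comparisons.
    """
    if footprint_nm2 <= 0:
        raise ValueError("footprint must be positive")
    out = profile.copy()
    area = math.pi * out["diameter_nm"] ** 2
    out["density_per_nm2"] = out["mean_count"] / area
    out["density_ci95"] = out["ci95"] / area
    out["coverage"] = out["density_per_nm2"] * footprint_nm2
    out.attrs["mean_coverage"] = float(
        np.average(out["coverage"], weights=out["n"]))
    out.attrs["footprint_nm2"] = float(footprint_nm2)
    return out


def footprint_from_chain_length(n_residues: int) -> float:
    """Membrane footprint (nm^2), linear in chain length.

    Anchored at 115 nm^2 for a 569-residue chain.
    """
    if n_residues <= 0:
        raise ValueError("residue count must be positive")
    return (constants.REFERENCE_FOOTPRINT_NM2 * n_residues
            / constants.REFERENCE_FOOTPRINT_RESIDUES)


def normalized_sensitivity(profile: pd.DataFrame,
                           reference_window=constants.REFERENCE_WINDOW_NM,
                           ) -> pd.DataFrame:
    """Density profile divided by its 190-210 nm window average.

    The reference value is the puncta-weighted mean density over bins whose
    centres fall inside the window; the result is 1 there by construction.
    """
    lo, hi = reference_window
    sel = (profile["diameter_nm"] >= lo) & (profile["diameter_nm"] <= hi)
    if not sel.any():
        raise ValueError(f"no bins inside the reference window {reference_window}")
    ref = float(np.average(profile.loc[sel, "density_per_nm2"],
                           weights=profile.loc[sel, "n"]))
    if ref <= 0:
        raise ValueError("reference density is not positive")
    out = profile.copy()
    out["normalized_sensitivity"] = out["density_per_nm2"] / ref
    out["normalized_ci95"] = out["density_ci95"] / ref
    out.attrs.update(profile.attrs)
    out.attrs["reference_density_per_nm2"] = ref
    return out


@dataclass(frozen=True)
class LangmuirFit:
    """Saturation-isotherm parameters for one vesicle-diameter class."""

    kd_nM: float
    bmax: float
    kd_sd: float
    bmax_sd: float
    residual_norm: float

    def bound(self, conc_nM) -> np.ndarray:
        conc = np.asarray(conc_nM, dtype=float)
        return self.bmax * conc / (self.kd_nM + conc)


def _langmuir(conc, bmax, kd):
    return bmax * conc / (kd + conc)


def _fit_once(conc: np.ndarray, bound: np.ndarray) -> tuple[float, float]:
    p0 = (max(bound.max(), 1e-12), max(np.median(conc), 1e-12))
    popt, _ = curve_fit(_langmuir, conc, bound, p0=p0,
                        bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000)
    return float(popt[0]), float(popt[1])


def fit_langmuir(concentrations_nM: Sequence[float],
                 bound_series: Sequence[float],
                 ci_series: Optional[Sequence[float]] = None) -> LangmuirFit:
    """Unweighted least-squares fit of ``bound = Bmax c / (Kd + c)``.

    Parameter uncertainties are the standard deviation of three fits: to the
    mean curve and to the mean plus/minus its confidence interval.
    """
    conc = np.asarray(concentrations_nM, dtype=float)
    bound = np.asarray(bound_series, dtype=float)
    if len(conc) < 3:
        raise ValueError("need at least 3 concentrations")
    if len(conc) != len(bound):
        raise ValueError("concentration and bound series differ in length")
    bmax, kd = _fit_once(conc, bound)
    if bmax <= 0 or kd <= 0:
        raise RuntimeError("isotherm fit returned non-positive parameters")
    if ci_series is not None:
        ci = np.asarray(ci_series, dtype=float)
        fits = [(bmax, kd)]
        for shifted in (bound + ci, np.clip(bound - ci, 0.0, None)):
            fits.append(_fit_once(conc, shifted))
        arr = np.array(fits)
        bmax_sd = float(arr[:, 0].std(ddof=1))
        kd_sd = float(arr[:, 1].std(ddof=1))
    else:
        bmax_sd = kd_sd = float("nan")
    resid = bound - _langmuir(conc, bmax, kd)
    return LangmuirFit(kd_nM=kd, bmax=bmax, kd_sd=kd_sd, bmax_sd=bmax_sd,
                       residual_norm=float(np.sqrt((resid ** 2).sum())))


@dataclass(frozen=True)
class GeometryCorrection:
    """Spherical-shell area correction of the apparent binding capacity.

    Bound proteins occupy a shell one protein radius above the membrane, so
    apparent capacity per membrane area grows as ``(r_v + r_p)^2 / r_v^2``.
    """

    r_v_nm: float
    r_p_nm: float
    area_ratio: float
    bmax: float
    bmax_corrected: float


def correct_bmax(bmax: float, r_v_nm: float,
                 r_p_nm: float = constants.PROTEIN_RADIUS_NM) -> GeometryCorrection:
    """Divide the apparent Bmax by the protein-shell area ratio."""
    if r_v_nm <= 0 or r_p_nm < 0:
        raise ValueError("vesicle radius must be positive, protein radius non-negative")
    ratio = (r_v_nm + r_p_nm) ** 2 / r_v_nm ** 2
    return GeometryCorrection(r_v_nm, r_p_nm, ratio, bmax, bmax / ratio)


def filopodia_partition(filo_table: pd.DataFrame) -> tuple[pd.Series, float, float, int]:
    """Per-filopodium two-channel partition coefficients and their mean.

    The coefficient is the background-subtracted green filopodium/membrane
    intensity ratio divided by the same ratio in the red channel.
    Filopodia whose background-subtracted membrane intensity is not positive
    are excluded.  Returns (coefficients, mean, 95% CI half-width,
    n_excluded).
    """
    required = ["green_filo", "green_mem", "green_bg",
                "red_filo", "red_mem", "red_bg"]
    missing = [c for c in required if c not in filo_table.columns]
    if missing:
        raise ValueError(f"filopodia table lacks columns {missing}")
    g_mem = filo_table["green_mem"] - filo_table["green_bg"]
    r_mem = filo_table["red_mem"] - filo_table["red_bg"]
    good = (g_mem > 0) & (r_mem > 0)
    n_excluded = int((~good).sum())
    sub = filo_table[good]
    coeff = (((sub["green_filo"] - sub["green_bg"]) / g_mem[good])
             / ((sub["red_filo"] - sub["red_bg"]) / r_mem[good]))
    if len(coeff) == 0:
        raise ValueError("no usable filopodia after exclusions")
    mean = float(coeff.mean())
    ci95 = float(1.96 * coeff.std(ddof=1) / math.sqrt(len(coeff))) if len(coeff) > 1 else 0.0
    return coeff, mean, ci95, n_excluded
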