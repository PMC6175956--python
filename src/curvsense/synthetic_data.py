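"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is a pure function of (config, seed): vesicle populations
with log-normal diameters centred on the three preparation means, lipid
brightness proportional to membrane area, bound-protein counts drawn from a
saturating binding law with a curvature-dependent dissociation constant,
log-normal single-molecule brightness, noisy autocorrelation traces, and
paired-channel filopodium intensities with a known partition factor.
Ground truth is always returned alongside the generated table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import constants
from .fcs import fcs_model

__all__ = ["SynthConfig", "gen_vesicle_puncta", "gen_binding_series",
           "gen_single_molecule", "gen_fcs_trace", "gen_filopodia"]

FoldLaw = Union[None, Mapping[float, float], Callable[[np.ndarray], np.ndarray]]


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth parameters for the generators."""

    seed: int = 0
    prep_mean_diameters_nm: tuple = constants.PREP_MEAN_DIAMETERS_NM
    diameter_cv: float = 0.25
    diameter_range_nm: tuple = (15.0, 300.0)
    n_puncta: int = 1000
    kd_ref_nM: float = 160.0
    bmax_density_per_nm2: float = 2.7e-3
    concentration_nM: float = 5.0
    lipid_scale: float = 0.05       # lipid intensity per nm^2 of membrane
    lipid_cv: float = 0.05
    single_molecule_intensity: float = 100.0
    intensity_cv: float = 0.05
    protein_background: float = 0.0
    filopodia_factor: float = 2.34
    filopodia_n: int = 94
    filopodia_cv: float = 0.15

    def __post_init__(self) -> None:
        if min(self.prep_mean_diameters_nm) <= 0:
            raise ValueError("preparation mean diameters must be positive")
        if self.kd_ref_nM <= 0 or self.bmax_density_per_nm2 <= 0:
            raise ValueError("binding-law parameters must be positive")
        if (self.lipid_scale <= 0 or self.single_molecule_intensity <= 0
                or self.filopodia_factor <= 0):
            raise ValueError("scales must be positive")


def _fold_function(fold: FoldLaw) -> Callable[[np.ndarray], np.ndarray]:
    if fold is None:
        return lambda d: np.ones_like(np.asarray(d, dtype=float))
    if callable(fold):
        return fold
    items = sorted(fold.items())
    xs = np.array([k for k, _ in items], dtype=float)
    ys = np.array([v for _, v in items], dtype=float)
    if np.any(ys <= 0):
        raise ValueError("fold factors must be positive")
    return lambda d: np.interp(np.asarray(d, dtype=float), xs, ys)


def _truncated_lognormal(rng: np.random.Generator, mean: float, cv: float,
                         lo: float, hi: float, n: int) -> np.ndarray:
    if cv <= 0:
        return np.full(n, np.clip(mean, lo, hi))
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, math.sqrt(sigma2), size=2 * (n - filled))
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled:filled + len(keep)] = keep
        filled += len(keep)
    return out


def _diameters(config: SynthConfig, rng: np.random.Generator):
    """Equal-sized draws from each preparation, pooled and shuffled.

    Returns (diameters, preparation mean per punctum).
    """
    lo, hi = config.diameter_range_nm
    preps = config.prep_mean_diameters_nm
    counts = [config.n_puncta // len(preps)] * len(preps)
    counts[0] += config.n_puncta - sum(counts)
    parts = [_truncated_lognormal(rng, m, config.diameter_cv, lo, hi, c)
             for m, c in zip(preps, counts)]
    d = np.concatenate(parts)
    prep = np.concatenate([np.full(c, m) for m, c in zip(preps, counts)])
    order = rng.permutation(len(d))
    return d[order], prep[order]


def _puncta_from_diameters(config: SynthConfig, rng: np.random.Generator,
                           diameters: np.ndarray, prep: np.ndarray,
                           concentration_nM: float,
                           fold: Callable) -> pd.DataFrame:
    area = math.pi * diameters ** 2
    kd = config.kd_ref_nM / fold(diameters)
    mean_count = (config.bmax_density_per_nm2 * area * concentration_nM
                  / (kd + concentration_nM))
    count = rng.poisson(mean_count).astype(float)
    lipid = config.lipid_scale * diameters ** 2 * (
        1.0 + config.lipid_cv * rng.standard_normal(len(diameters)))
    protein = (count * config.single_molecule_intensity
               * (1.0 + config.intensity_cv * rng.standard_normal(len(diameters)))
               + config.protein_background)
    return pd.DataFrame({
        "lipid_intensity": np.clip(lipid, 0.0, None),
        "protein_intensity": np.clip(protein, 0.0, None),
        "prep_mean": prep,
        "replicate": np.zeros(len(diameters), dtype=int),
        "true_diameter_nm": diameters,
        "true_count": count,
        "true_kd_nM": kd,
    })


def gen_vesicle_puncta(config: SynthConfig, fold: FoldLaw = None,
                       rng: Optional[np.random.Generator] = None,
                       ) -> tuple[pd.DataFrame, dict]:
    """One per-punctum table plus its ground truth.

    ``fold`` maps vesicle diameter to the binding-strength enhancement
    relative to the reference diameter (dissociation constant divided by
    the fold); None means curvature-blind binding.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    f = _fold_function(fold)
    d, prep = _diameters(config, rng)
    table = _puncta_from_diameters(config, rng, d, prep,
                                   config.concentration_nM, f)
    truth = {
        "kd_ref_nM": config.kd_ref_nM,
        "bmax_density_per_nm2": config.bmax_density_per_nm2,
        "concentration_nM": config.concentration_nM,
        "single_molecule_intensity": config.single_molecule_intensity,
        "lipid_scale": config.lipid_scale,
    }
    return table, truth


def gen_binding_series(config: SynthConfig, concentrations_nM: Sequence[float],
                       fold: FoldLaw = None,
                       rng: Optional[np.random.Generator] = None,
                       ) -> tuple[dict[float, pd.DataFrame], dict]:
    """One puncta table per solution concentration, same vesicle population."""
    if len(concentrations_nM) < 3:
        raise ValueError("need at least 3 concentrations")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    f = _fold_function(fold)
    d, prep = _diameters(config, rng)
    tables = {float(c): _puncta_from_diameters(config, rng, d, prep, float(c), f)
              for c in concentrations_nM}
    truth = {
        "kd_ref_nM": config.kd_ref_nM,
        "bmax_density_per_nm2": config.bmax_density_per_nm2,
        "single_molecule_intensity": config.single_molecule_intensity,
        "lipid_scale": config.lipid_scale,
    }
    return tables, truth


def gen_single_molecule(config: SynthConfig, n: int,
                        rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Log-normal brightness sample whose mode is the configured intensity."""
    if n < 1:
        raise ValueError("sample size must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cv = config.intensity_cv
    if cv <= 0:
        return np.full(n, config.single_molecule_intensity)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(config.single_molecule_intensity) + sigma2  # mode = exp(mu - sigma^2)
    return rng.lognormal(mu, math.sqrt(sigma2), size=n)


def gen_fcs_trace(n_particles: float, tau_d_s: float, alpha: float = 1.0,
                  lag_s: Optional[np.ndarray] = None, noise_cv: float = 0.02,
                  seed: int = 0,
                  triplet_amplitude: float = constants.TRIPLET_AMPLITUDE,
                  triplet_time_s: float = constants.TRIPLET_TIME_S,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Model autocorrelation on a log lag grid with multiplicative noise.

    Noise is Gaussian and proportional to the decaying part ``G - 1``
    (shot-noise-like).  Returns (lag_s, G).
    """
    if lag_s is None:
        lag_s = np.logspace(-6, 0, 120)
    rng = np.random.default_rng(seed)
    g = fcs_model(lag_s, n_particles, tau_d_s, alpha,
                  triplet_amplitude, triplet_time_s)
    if noise_cv > 0:
        g = 1.0 + (g - 1.0) * (1.0 + noise_cv * rng.standard_normal(len(lag_s)))
    return np.asarray(lag_s, dtype=float), g


def gen_filopodia(config: SynthConfig,
                  rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Paired-channel filopodium intensities with a known partition factor.

    Red-channel filopodium/membrane ratios scatter around 1; green ratios
    around the configured factor.  Backgrounds and membrane levels are
    fixed plausible values; intensities are reconstructed from the ratios.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.filopodia_n
    cv = config.filopodia_cv
    red_ratio = np.clip(1.0 + cv * rng.standard_normal(n), 0.05, None)
    green_ratio = np.clip(
        config.filopodia_factor * (1.0 + cv * rng.standard_normal(n)), 0.05, None)
    green_bg, red_bg = 50.0, 40.0
    green_mem = green_bg + 400.0 * (1.0 + 0.1 * rng.standard_normal(n))
    red_mem = red_bg + 500.0 * (1.0 + 0.1 * rng.standard_normal(n))
    return pd.DataFrame({
        "green_filo": green_ratio * (green_mem - green_bg) + green_bg,
        "green_mem": green_mem,
        "green_bg": np.full(n, green_bg),
        "red_filo": red_ratio * (red_mem - red_bg) + red_bg,
        "red_mem": red_mem,
        "red_bg": np.full(n, red_bg),
        "true_factor": np.full(n, config.filopodia_factor),
    })
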