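"""From chain entropy to membrane-curvature sensitivity.

Sweeps tethered-chain entropy against substrate diameter, converts entropy
differences to relative binding partition coefficients via the Boltzmann
relation (enthalpy assumed curvature independent, so temperature cancels
when entropies are carried in units of k_B), and calibrates which lattice
walk model matches a measured chain size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import constants
from .hsmc_entropy import EntropyEstimate, HSMCConfig, tethered_entropy
from .saw_lattice import (ChainStats, MCConfig, SAWModel, Substrate,
                          chain_stats, kuhn_length, validate_model)

__all__ = [
    "CurvatureSweep", "PartitioningPrediction", "KuhnCalibration",
    "entropy_vs_curvature", "relative_partitioning", "calibrate_kuhn_length",
    "predict_sensitivity_profile",
]


@dataclass
class CurvatureSweep:
    """Tethered-chain entropy per substrate diameter (sphere exteriors)."""

    model: SAWModel
    n_bonds: int
    contour_nm: float
    diameters_nm: list[float]          # requested
    realized_diameters_nm: list[float]  # after lattice rounding
    entropies: list[EntropyEstimate]
    flat: Optional[EntropyEstimate] = None
    reference_diameter_nm: float = constants.REFERENCE_DIAMETER_NM

    def __post_init__(self) -> None:
        if len(self.diameters_nm) != len(self.entropies):
            raise ValueError("one entropy estimate per diameter required")


@dataclass
class PartitioningPrediction:
    """Relative partition coefficients versus the reference diameter."""

    diameters_nm: np.ndarray
    delta_delta_s: np.ndarray  # k_B units, relative to reference
    k_ratio: np.ndarray
    reference_diameter_nm: float = constants.REFERENCE_DIAMETER_NM

    def fold_at(self, d_nm) -> np.ndarray:
        """Interpolated partition ratio at arbitrary diameters."""
        order = np.argsort(self.diameters_nm)
        return np.interp(d_nm, self.diameters_nm[order], self.k_ratio[order])


@dataclass
class KuhnCalibration:
    """Ranking of candidate walk models against a measured chain size."""

    table: pd.DataFrame  # model, n_bonds, rg_sim_nm, rg_se_nm, implied_lk_nm
    target_rg_nm: float
    best: SAWModel


def entropy_vs_curvature(model: SAWModel, contour_nm: float,
                         diameters_nm: Sequence[float],
                         hsmc_config: HSMCConfig = HSMCConfig(),
                         include_flat: bool = False,
                         reference_diameter_nm: float = constants.REFERENCE_DIAMETER_NM,
                         ) -> CurvatureSweep:
    """Tethered entropy on sphere exteriors spanning the given diameters.

    The chain has ``round(contour_nm / step_length_nm)`` bonds; each sphere
    radius is rounded to the nearest lattice site distance and the realized
    diameter is reported alongside the requested one.
    """
    validate_model(model)
    if contour_nm <= 0:
        raise ValueError("contour length must be positive")
    n_bonds = max(1, round(contour_nm / model.step_length_nm))
    a = model.lattice_constant_nm
    radii = []
    for d in diameters_nm:
        r = int(round((d / 2.0) / a))
        if r < 2:
            raise ValueError(f"diameter {d} nm is below the lattice resolution "
                             f"(lattice constant {a:.3f} nm)")
        radii.append(r)
    ss = np.random.SeedSequence(hsmc_config.seed)
    seeds = [int(s) for s in ss.generate_state(len(radii) + 1, dtype=np.uint32)]
    entropies = []
    realized = []
    for r, seed in zip(radii, seeds):
        sub = Substrate("sphere_exterior", radius=r)
        cfg = HSMCConfig(hsmc_config.n_bar, hsmc_config.n_bar_prime,
                         hsmc_config.n_recon, seed, hsmc_config.draw,
                         hsmc_config.max_retries)
        entropies.append(tethered_entropy(model, n_bonds, sub, cfg))
        realized.append(2.0 * r * a)
    flat = None
    if include_flat:
        cfg = HSMCConfig(hsmc_config.n_bar, hsmc_config.n_bar_prime,
                         hsmc_config.n_recon, seeds[-1], hsmc_config.draw,
                         hsmc_config.max_retries)
        flat = tethered_entropy(model, n_bonds, Substrate("plane"), cfg)
    return CurvatureSweep(model, n_bonds, contour_nm, list(diameters_nm),
                          realized, entropies, flat=flat,
                          reference_diameter_nm=reference_diameter_nm)


def relative_partitioning(sweep: CurvatureSweep,
                          temperature_K: float = constants.TEMPERATURE_K,
                          ) -> PartitioningPrediction:
    """Boltzmann conversion of entropy differences to partition ratios.

    ``k_ratio = exp(delta_delta_s)`` with entropies in k_B, so the stored
    temperature does not enter the numbers; it is kept for interface
    clarity only.
    """
    del temperature_K  # entropy carried in k_B units; cancels
    d = np.asarray(sweep.diameters_nm, dtype=float)
    ref = sweep.reference_diameter_nm
    hits = np.flatnonzero(np.isclose(d, ref))
    if len(hits) == 0:
        raise ValueError(f"reference diameter {ref} nm not present in sweep")
    s = np.array([e.s_mean for e in sweep.entropies])
    dds = s - s[hits[0]]
    return PartitioningPrediction(d, dds, np.exp(dds), reference_diameter_nm=ref)


def calibrate_kuhn_length(model_family: Sequence[SAWModel], contour_nm: float,
                          target_rg_nm: float,
                          mc_config: MCConfig) -> KuhnCalibration:
    """Pick the walk model whose free-chain Rg best matches a target.

    Each candidate is simulated at the common physical contour length; the
    implied Kuhn length ``<Ree^2>/L_c`` is reported for every candidate.
    """
    if len(model_family) == 0:
        raise ValueError("model family must not be empty")
    if target_rg_nm <= 0 or contour_nm <= 0:
        raise ValueError("target Rg and contour must be positive")
    rows = []
    for model in model_family:
        validate_model(model)
        n_bonds = max(1, round(contour_nm / model.step_length_nm))
        stats = chain_stats(model, n_bonds, mc_config)
        rows.append({
            "model": model.name,
            "n_bonds": n_bonds,
            "rg_sim_nm": stats.rg_mean,
            "rg_se_nm": stats.rg_se,
            "implied_lk_nm": kuhn_length(stats, n_bonds * model.step_length_nm),
            "abs_err_nm": abs(stats.rg_mean - target_rg_nm),
        })
    table = pd.DataFrame(rows).sort_values("abs_err_nm").reset_index(drop=True)
    best = next(m for m in model_family if m.name == table.loc[0, "model"])
    return KuhnCalibration(table=table, target_rg_nm=target_rg_nm, best=best)


def predict_sensitivity_profile(prediction: PartitioningPrediction) -> pd.DataFrame:
    """Predicted bound-density ratio versus diameter, 1 at the reference.

    Directly comparable to the normalized sensitivity column produced by
    the vesicle-binding pipeline.
    """
    ref = prediction.reference_diameter_nm
    if not np.any(np.isclose(prediction.diameters_nm, ref)):
        raise ValueError(f"prediction lacks the {ref} nm reference diameter")
    return pd.DataFrame({
        "diameter_nm": prediction.diameters_nm,
        "delta_delta_s_kB": prediction.delta_delta_s,
        "predicted_sensitivity": prediction.k_ratio,
    })
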