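"""Absolute conformational entropy of lattice chains by scanning Monte Carlo.

A chain of n bonds is built one bond at a time.  For bond j, the already
fixed bonds (the "past") are frozen and the remaining future segment is
simulated by local-move Monte Carlo; the fraction of scan steps in which
the segment's first bond points along direction k estimates the conditional
probability ``p_j(k | past)``.  The bond direction is then drawn from that
empirical distribution, its probability stored, and the product over bonds
gives the construction probability ``P_i`` of the finished conformation.
Since all valid walks carry equal weight, ``-ln P_i`` averaged over
reconstructions brackets ``ln(number of walks)``:

* upper estimate: plain mean of ``-ln P_i``;
* lower estimate: mean of ``-ln P_i`` weighted by ``P_i`` itself.

Both coincide with the exact ``ln Z`` in the limit of long scans.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from . import constants
from ._kernels import extend_segment, hsmc_scan
from .saw_lattice import (NO_SUBSTRATE, Conformation, SAWModel, Substrate,
                          validate_model)

__all__ = [
    "HSMCConfig", "ReconstructionRecord", "EntropyEstimate", "DeadEndError",
    "scan_bond_distribution", "reconstruct_chain", "entropy_from_samples",
    "tethered_entropy",
]

log = logging.getLogger(__name__)


class DeadEndError(RuntimeError):
    """The future segment admits no valid completion from this prefix."""


@dataclass(frozen=True)
class HSMCConfig:
    """Scan sizing for entropy runs.

    For bond j of an n-bond chain the scan runs
    ``n_bar * n_nbr * (n - j + 1)`` recorded steps after
    ``n_bar_prime * n_nbr * (n - j + 1)`` equilibration steps, one step
    being a full sweep of the future segment (one local-move attempt per
    movable bead).
    """

    n_bar: int = constants.N_BAR
    n_bar_prime: int = constants.N_BAR_PRIME
    n_recon: int = constants.N_RECONSTRUCTIONS
    seed: int = 0
    draw: str = "weighted"  # "weighted" | "uniform" (over observed directions)
    max_retries: int = 20

    def __post_init__(self) -> None:
        if min(self.n_bar, self.n_bar_prime, self.n_recon) <= 0:
            raise ValueError("n_bar, n_bar_prime and n_recon must be positive")
        if self.draw not in ("weighted", "uniform"):
            raise ValueError("draw must be 'weighted' or 'uniform'")

    def n_mc(self, model: SAWModel, n_bonds: int, j: int) -> int:
        return self.n_bar * model.n_nbr * (n_bonds - j + 1)

    def n_equil(self, model: SAWModel, n_bonds: int, j: int) -> int:
        return self.n_bar_prime * model.n_nbr * (n_bonds - j + 1)


@dataclass
class ReconstructionRecord:
    """One reconstructed conformation and its construction probability."""

    conformation: Conformation
    log_p: float
    per_bond_p: np.ndarray

    def __post_init__(self) -> None:
        if self.log_p > 1e-12:
            raise ValueError("log construction probability must be <= 0")


@dataclass(frozen=True)
class EntropyEstimate:
    """Upper/lower entropy estimates and their mean, in units of k_B."""

    s_upper: float
    s_lower: float
    s_mean: float
    se: float
    n_obs: int
    n_discarded: int = 0


def _kernel_args(model: SAWModel, substrate: Substrate):
    return (model.step.direction_set, model.max_excl_sq,
            substrate.kind_code, substrate.radius_sq)


def _fresh_chain(model: SAWModel, n_bonds: int, substrate: Substrate,
                 seed: int) -> np.ndarray:
    coords = np.zeros((n_bonds + 1, 3), dtype=np.int64)
    coords[:] = substrate.tether_site
    dirs, sx, kind, rsq = _kernel_args(model, substrate)
    if not extend_segment(coords, 1, dirs, sx, kind, rsq, seed, 200):
        raise DeadEndError("no valid extended starting conformation")
    return coords


def scan_bond_distribution(past_bonds: Sequence[Sequence[int]],
                           model: SAWModel, substrate: Substrate,
                           j: int, n_total_bonds: int,
                           config: HSMCConfig,
                           seed: Optional[int] = None):
    """Direction-frequency table for bond j given a frozen bond prefix.

    ``past_bonds`` holds bonds 1..j-1 as integer 3-vectors.  Returns
    ``(counts, n_mc)`` where ``counts[k]`` is the number of scan steps with
    bond j along ``model.step.direction_set[k]`` and ``counts.sum() == n_mc``.
    """
    validate_model(model)
    past = np.asarray(past_bonds, dtype=np.int64).reshape(-1, 3)
    if len(past) != j - 1:
        raise ValueError(f"expected {j - 1} past bonds for bond index {j}, got {len(past)}")
    if not (1 <= j <= n_total_bonds):
        raise ValueError("bond index out of range")
    coords = np.zeros((n_total_bonds + 1, 3), dtype=np.int64)
    coords[0] = substrate.tether_site
    for i, b in enumerate(past):
        coords[i + 1] = coords[i] + b
    dirs, sx, kind, rsq = _kernel_args(model, substrate)
    base_seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed)
    s_ext, s_scan = (int(v) & 0x7FFFFFFF for v in ss.generate_state(2, dtype=np.uint32))
    if not extend_segment(coords, j, dirs, sx, kind, rsq, s_ext, 200):
        raise DeadEndError(f"no valid completion of the future segment at bond {j}")
    counts = hsmc_scan(coords, dirs, sx, kind, rsq, j,
                       config.n_equil(model, n_total_bonds, j),
                       config.n_mc(model, n_total_bonds, j), s_scan)
    return counts, int(counts.sum())


def reconstruct_chain(model: SAWModel, n_bonds: int,
                      substrate: Substrate = NO_SUBSTRATE,
                      config: HSMCConfig = HSMCConfig(),
                      rng: Optional[np.random.Generator] = None) -> ReconstructionRecord:
    """Build one chain bond-by-bond, recording per-bond probabilities.

    Raises ``DeadEndError`` if the chain cannot be extended at some bond
    (possible for stiff models near substrates); callers resample.
    """
    validate_model(model)
    if n_bonds < 1:
        raise ValueError("n_bonds must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dirs, sx, kind, rsq = _kernel_args(model, substrate)
    coords = _fresh_chain(model, n_bonds, substrate,
                          int(rng.integers(0, 2 ** 31 - 1)))
    per_bond_p = np.empty(n_bonds)
    log_p = 0.0
    for j in range(1, n_bonds + 1):
        counts = hsmc_scan(coords, dirs, sx, kind, rsq, j,
                           config.n_equil(model, n_bonds, j),
                           config.n_mc(model, n_bonds, j),
                           int(rng.integers(0, 2 ** 31 - 1)))
        n_mc = int(counts.sum())
        if n_mc == 0:  # cannot happen: the scanned segment is itself valid
            raise AssertionError("scan recorded no bond directions")
        if config.draw == "weighted":
            k = int(rng.choice(len(counts), p=counts / n_mc))
        else:
            observed = np.flatnonzero(counts)
            k = int(rng.choice(observed))
        p = counts[k] / n_mc
        per_bond_p[j - 1] = p
        log_p += math.log(p)
        coords[j] = coords[j - 1] + dirs[k]
        if j < n_bonds:
            ok = extend_segment(coords, j + 1, dirs, sx, kind, rsq,
                                int(rng.integers(0, 2 ** 31 - 1)), 200)
            if not ok:
                raise DeadEndError(f"dead end while re-extending after bond {j}")
    conf = Conformation(coords, anchored=substrate.kind != "none")
    return ReconstructionRecord(conf, log_p, per_bond_p)


def entropy_from_samples(records: Sequence[ReconstructionRecord]) -> EntropyEstimate:
    """Combine reconstruction records into entropy estimates (k_B units).

    The standard error of the mean estimate is obtained by jackknife over
    records.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 reconstruction records")
    logp = np.array([r.log_p for r in records])

    def s_mean_of(lp: np.ndarray) -> tuple[float, float, float]:
        s_up = -float(lp.mean())
        w = np.exp(lp - logsumexp(lp))
        s_lo = -float(w @ lp)
        return s_up, s_lo, 0.5 * (s_up + s_lo)

    s_upper, s_lower, s_mean = s_mean_of(logp)
    n = len(logp)
    loo = np.empty(n)
    for i in range(n):
        loo[i] = s_mean_of(np.delete(logp, i))[2]
    se = math.sqrt((n - 1) / n * float(((loo - loo.mean()) ** 2).sum()))
    return EntropyEstimate(s_upper, s_lower, s_mean, se, n_obs=n)


def tethered_entropy(model: SAWModel, n_bonds: int,
                     substrate: Substrate = NO_SUBSTRATE,
                     config: HSMCConfig = HSMCConfig()) -> EntropyEstimate:
    """Full entropy estimate: n_recon reconstructions, then the estimators."""
    rng = np.random.default_rng(config.seed)
    records: list[ReconstructionRecord] = []
    discarded = 0
    while len(records) < config.n_recon:
        try:
            records.append(reconstruct_chain(model, n_bonds, substrate,
                                             config, rng=rng))
        except DeadEndError:
            discarded += 1
            log.warning("discarded a dead-end reconstruction (%d so far)", discarded)
            if discarded > config.max_retries * config.n_recon:
                raise
    est = entropy_from_samples(records)
    return EntropyEstimate(est.s_upper, est.s_lower, est.s_mean, est.se,
                           est.n_obs, n_discarded=discarded)
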