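"""Self-avoiding-walk models on the simple cubic lattice.

A walk model is written ``nbrPQRexclX``: bond vectors are all signed
coordinate permutations of the non-negative integer triple ``(P, Q, R)``,
and every occupied site excludes its neighbours up to the X-th
nearest-neighbour shell from occupancy.  Physically one bond is 0.38 nm
long regardless of the lattice step class, so the lattice constant is
``0.38 / sqrt(P^2 + Q^2 + R^2)`` nm.

The module also provides local-move Monte Carlo sampling of chains (free or
tethered to a substrate), structural observables, and an exact
depth-first enumeration oracle used to validate entropy estimates.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from . import constants
from ._kernels import extend_segment, run_sample, run_stats

__all__ = [
    "StepClass", "ExclusionShell", "SAWModel", "Substrate", "Conformation",
    "MCConfig", "MCRun", "ChainStats",
    "build_step_directions", "build_exclusion_offsets", "validate_model",
    "is_valid_conformation", "initial_conformation", "mc_run",
    "radius_of_gyration", "chain_stats", "kuhn_length", "enumerate_saws",
    "contour_length_nm", "n_bonds_for_residues",
]

_NAME_RE = re.compile(r"^nbr(\d)(\d)(\d)excl(\d+)$")


def build_step_directions(p: int, q: int, r: int) -> np.ndarray:
    """All distinct signed coordinate permutations of (p, q, r).

    Returns an ``(n, 3)`` int64 array in lexicographic order.  Raises
    ``ValueError`` for negative components or the all-zero triple.
    """
    for v in (p, q, r):
        if int(v) != v or v < 0:
            raise ValueError(f"step components must be non-negative integers, got {(p, q, r)}")
    if p == q == r == 0:
        raise ValueError("step class (0,0,0) has no walk directions")
    dirs = set()
    for perm in itertools.permutations((p, q, r)):
        for signs in itertools.product((1, -1), repeat=3):
            dirs.add(tuple(int(s * v) for s, v in zip(signs, perm)))
    return np.array(sorted(dirs), dtype=np.int64)


@dataclass(frozen=True)
class StepClass:
    """The (P, Q, R) bond family of a lattice walk."""

    P: int
    Q: int
    R: int

    def __post_init__(self) -> None:
        build_step_directions(self.P, self.Q, self.R)  # validates

    @property
    def direction_set(self) -> np.ndarray:
        return build_step_directions(self.P, self.Q, self.R)

    @property
    def n_nbr(self) -> int:
        return len(self.direction_set)

    @property
    def step_len_sq(self) -> int:
        return self.P ** 2 + self.Q ** 2 + self.R ** 2


def lattice_shell_distances(n_shells: int) -> list[int]:
    """The n smallest realizable squared distances on the cubic lattice.

    Note not every integer is a sum of three squares (7 is skipped).
    """
    if n_shells < 0:
        raise ValueError("shell count must be non-negative")
    out: list[int] = []
    c = 1
    while True:
        rng = range(-c, c + 1)
        dsq = sorted({x * x + y * y + z * z for x in rng for y in rng for z in rng} - {0})
        complete = [d for d in dsq if d <= c * c]  # shells fully inside cube
        if len(complete) >= n_shells:
            return complete[:n_shells]
        c += 1


def build_exclusion_offsets(x: int) -> np.ndarray:
    """Union of the first x nearest-neighbour shells, as an (m, 3) array."""
    if int(x) != x or x < 0:
        raise ValueError(f"exclusion order must be a non-negative integer, got {x}")
    if x == 0:
        return np.empty((0, 3), dtype=np.int64)
    dmax = lattice_shell_distances(x)[-1]
    c = int(math.isqrt(dmax))
    rng = range(-c, c + 1)
    offs = [(a, b, d) for a in rng for b in rng for d in rng
            if 0 < a * a + b * b + d * d <= dmax]
    return np.array(sorted(offs), dtype=np.int64)


@dataclass(frozen=True)
class ExclusionShell:
    """Exclusion of lattice sites up to the X-th nearest-neighbour shell."""

    X: int

    def __post_init__(self) -> None:
        if int(self.X) != self.X or self.X < 0:
            raise ValueError(f"exclusion order must be a non-negative integer, got {self.X}")

    @property
    def excluded_offsets(self) -> np.ndarray:
        return build_exclusion_offsets(self.X)

    @property
    def max_excl_sq(self) -> int:
        """Largest excluded squared distance (0 when X = 0)."""
        if self.X == 0:
            return 0
        return int(lattice_shell_distances(self.X)[-1])


@dataclass(frozen=True)
class SAWModel:
    """A validated walk model: step class + exclusion shell + physical scale.

    ``self_avoiding=False`` switches off all bead-bead exclusion (an ideal
    random walk); it exists purely as a test mode with exactly known
    entropy ``n_bonds * ln(n_nbr)``.
    """

    step: StepClass
    shell: ExclusionShell
    step_length_nm: float = constants.STEP_LENGTH_NM
    self_avoiding: bool = True

    def __post_init__(self) -> None:
        if self.step_length_nm <= 0 or not math.isfinite(self.step_length_nm):
            raise ValueError("step_length_nm must be positive and finite")
        if self.self_avoiding and self.step.step_len_sq <= self.shell.max_excl_sq:
            raise ValueError(
                f"invalid model {self.name}: bonded beads at squared distance "
                f"{self.step.step_len_sq} would sit inside the exclusion shell "
                f"(max excluded squared distance {self.shell.max_excl_sq})")

    @property
    def name(self) -> str:
        return f"nbr{self.step.P}{self.step.Q}{self.step.R}excl{self.shell.X}"

    @property
    def lattice_constant_nm(self) -> float:
        return self.step_length_nm / math.sqrt(self.step.step_len_sq)

    @property
    def n_nbr(self) -> int:
        return self.step.n_nbr

    @property
    def max_excl_sq(self) -> int:
        """Clash threshold passed to the kernels (-1 disables exclusion)."""
        return self.shell.max_excl_sq if self.self_avoiding else -1

    @classmethod
    def from_name(cls, name: str, step_length_nm: float = constants.STEP_LENGTH_NM) -> "SAWModel":
        m = _NAME_RE.match(name)
        if m is None:
            raise ValueError(f"model name {name!r} does not match 'nbrPQRexclX'")
        p, q, r, x = (int(g) for g in m.groups())
        return cls(StepClass(p, q, r), ExclusionShell(x), step_length_nm=step_length_nm)


def validate_model(model: SAWModel) -> SAWModel:
    """Re-run the model consistency checks; returns the model unchanged."""
    SAWModel(model.step, model.shell, model.step_length_nm, model.self_avoiding)
    return model


_SUBSTRATE_CODES = {
    "none": 0,
    "plane": 1,
    "sphere_exterior": 2,
    "sphere_interior": 3,
    "cylinder_exterior": 4,
}


@dataclass(frozen=True)
class Substrate:
    """An impenetrable tethering substrate, discretized on the lattice.

    The solid region is defined in lattice units around the origin:

    * ``plane``: half-space ``z < 0`` (surface = plane z = 0).
    * ``sphere_exterior``: solid ball of radius R centred at the origin;
      the chain lives outside, tethered at ``(0, 0, R)``.
    * ``sphere_interior``: the chain is confined inside the ball.
    * ``cylinder_exterior``: solid cylinder along z; chain outside,
      tethered at ``(R, 0, 0)``.

    ``radius`` is rounded to the nearest integer site distance; the realized
    value is what all predicates use.
    """

    kind: str = "none"
    radius: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _SUBSTRATE_CODES:
            raise ValueError(f"unknown substrate kind {self.kind!r}")
        if self.kind in ("sphere_exterior", "sphere_interior", "cylinder_exterior"):
            if self.radius <= 0:
                raise ValueError(f"substrate kind {self.kind!r} needs a positive radius")

    @property
    def kind_code(self) -> int:
        return _SUBSTRATE_CODES[self.kind]

    @property
    def lattice_radius(self) -> int:
        return int(round(self.radius))

    @property
    def radius_sq(self) -> int:
        return self.lattice_radius ** 2

    @property
    def tether_site(self) -> np.ndarray:
        if self.kind in ("none", "plane"):
            return np.zeros(3, dtype=np.int64)
        if self.kind == "cylinder_exterior":
            return np.array([self.lattice_radius, 0, 0], dtype=np.int64)
        return np.array([0, 0, self.lattice_radius], dtype=np.int64)

    def excludes(self, site: Sequence[int]) -> bool:
        x, y, z = (int(v) for v in site)
        code = self.kind_code
        if code == 0:
            return False
        if code == 1:
            return z < 0
        if code == 2:
            return x * x + y * y + z * z < self.radius_sq
        if code == 3:
            return x * x + y * y + z * z > self.radius_sq
        return x * x + y * y < self.radius_sq


NO_SUBSTRATE = Substrate("none")


@dataclass
class Conformation:
    """An ordered lattice chain of N+1 beads (optionally anchored)."""

    coords: np.ndarray
    anchored: bool = False
    anchor_index: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 or len(self.coords) < 1:
            raise ValueError("coords must be a non-empty (n_beads, 3) array")
        if self.anchored and self.anchor_index != 0:
            raise ValueError("only terminal-bead (index 0) anchoring is supported")

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    @property
    def n_bonds(self) -> int:
        return len(self.coords) - 1

    @property
    def bonds(self) -> np.ndarray:
        return np.diff(self.coords, axis=0)

    def to_xyz(self, path) -> None:
        """Plain-text XYZ: one line per bead, 'index x y z' in lattice units."""
        with open(path, "w") as fh:
            for i, (x, y, z) in enumerate(self.coords):
                fh.write(f"{i} {x} {y} {z}\n")

    def to_csv(self, path, model: Optional[SAWModel] = None,
               substrate: Optional[Substrate] = None) -> None:
        header = ["# curvsense conformation"]
        if model is not None:
            header.append(f"# model={model.name} step_length_nm={model.step_length_nm}")
        if substrate is not None:
            header.append(f"# substrate={substrate.kind} radius={substrate.radius}")
        with open(path, "w") as fh:
            for line in header:
                fh.write(line + "\n")
            fh.write("bead,x,y,z\n")
            for i, (x, y, z) in enumerate(self.coords):
                fh.write(f"{i},{x},{y},{z}\n")


def is_valid_conformation(conf: Conformation, model: SAWModel,
                          substrate: Substrate = NO_SUBSTRATE) -> bool:
    """True iff all bond, exclusion and substrate constraints hold."""
    coords = conf.coords
    dirs = {tuple(d) for d in model.step.direction_set.tolist()}
    for b in conf.bonds:
        if tuple(b) not in dirs:
            return False
    sx = model.max_excl_sq
    n = len(coords)
    for i in range(n):
        if substrate.excludes(coords[i]):
            return False
        for j in range(i + 1, n):
            d = coords[j] - coords[i]
            if int(d @ d) <= sx:
                return False
    return True


def _kernel_args(model: SAWModel, substrate: Substrate):
    return (model.step.direction_set, model.max_excl_sq,
            substrate.kind_code, substrate.radius_sq)


def initial_conformation(model: SAWModel, n_bonds: int,
                         substrate: Substrate = NO_SUBSTRATE,
                         seed: int = 0, extended: bool = True) -> Conformation:
    """A valid conformation grown from the tether site.

    With ``extended=True`` straight lines along every allowed direction are
    tried first and randomized greedy growth is the fallback; with
    ``extended=False`` the chain is grown as a random coil directly, which
    equilibrates much faster in long structural runs.
    """
    validate_model(model)
    if n_bonds < 1:
        raise ValueError("n_bonds must be >= 1")
    tether = substrate.tether_site
    if substrate.excludes(tether):
        raise ValueError("tether site is excluded by the substrate")
    coords = np.zeros((n_bonds + 1, 3), dtype=np.int64)
    coords[:] = tether
    dirs, sx, kind, rsq = _kernel_args(model, substrate)
    ok = extend_segment(coords, 1, dirs, sx, kind, rsq, seed & 0x7FFFFFFF,
                        200, extended)
    if not ok:
        raise RuntimeError(
            f"no valid extended conformation found for model {model.name} "
            f"with substrate {substrate.kind}")
    anchored = substrate.kind != "none"
    return Conformation(coords, anchored=anchored, anchor_index=0)


@dataclass(frozen=True)
class MCConfig:
    """Run configuration for local-move Monte Carlo.

    One MC step is a sequence of ``n_bonds`` local-move attempts on
    randomly chosen beads.
    """

    n_steps: int
    n_blocks: int = constants.MC_BLOCKS
    n_traj: int = constants.MC_TRAJECTORIES
    seed: int = 0
    n_equil: Optional[int] = None  # default: n_steps // 10
    sample_every: int = 1

    def __post_init__(self) -> None:
        if self.n_steps <= 0 or self.n_blocks <= 0 or self.n_traj <= 0:
            raise ValueError("n_steps, n_blocks and n_traj must be positive")
        if self.n_steps % self.n_blocks:
            raise ValueError("n_steps must be divisible by n_blocks")
        if self.sample_every <= 0:
            raise ValueError("sample_every must be positive")

    @property
    def equil_steps(self) -> int:
        return self.n_steps // 10 if self.n_equil is None else self.n_equil


@dataclass
class MCRun:
    """Sampled trajectory plus acceptance statistics from one MC run."""

    samples: np.ndarray  # (n_samples, n_beads, 3)
    accepted: int
    attempted: int
    anchored: bool

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / self.attempted if self.attempted else 0.0

    def conformations(self) -> list[Conformation]:
        return [Conformation(c, anchored=self.anchored) for c in self.samples]


def _trajectory_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n, dtype=np.uint32)]


def mc_run(conf: Conformation, model: SAWModel,
           substrate: Substrate = NO_SUBSTRATE,
           config: MCConfig = MCConfig(n_steps=10_000)) -> MCRun:
    """Sample conformations by accept-iff-valid local moves.

    The proposal is symmetric and every proposal that satisfies all
    constraints is accepted, so sampling is uniform over valid
    conformations.  The anchored bead (index 0) never moves when the
    conformation is anchored.
    """
    if not is_valid_conformation(conf, model, substrate):
        raise ValueError("starting conformation is invalid for this model/substrate")
    coords = conf.coords.copy()
    dirs, sx, kind, rsq = _kernel_args(model, substrate)
    lo_mov = 1 if conf.anchored else 0
    n_samples = config.n_steps // config.sample_every
    out = np.empty((n_samples, conf.n_beads, 3), dtype=np.int64)
    seed = _trajectory_seeds(config.seed, 1)[0]
    # equilibration (not sampled)
    if config.equil_steps:
        warm = np.empty((0, conf.n_beads, 3), dtype=np.int64)
        run_sample(coords, dirs, sx, kind, rsq, lo_mov, config.equil_steps,
                   config.equil_steps + 1, seed, warm)
        seed = (seed + 1) & 0x7FFFFFFF
    idx, accepted, attempted = run_sample(
        coords, dirs, sx, kind, rsq, lo_mov, config.n_steps,
        config.sample_every, seed, out)
    return MCRun(out[:idx], accepted, attempted, conf.anchored)


def radius_of_gyration(conf: Conformation, model: SAWModel) -> float:
    """Root-mean-square bead distance from the centroid, in nm."""
    c = conf.coords.astype(float)
    centred = c - c.mean(axis=0)
    rg_lat = math.sqrt(float((centred ** 2).sum()) / len(c))
    return rg_lat * model.lattice_constant_nm


@dataclass(frozen=True)
class ChainStats:
    """Structural averages with standard errors across trajectories."""

    rg_mean: float
    rg_se: float
    ree_sq_mean: float
    ree_sq_se: float
    n_samples: int
    n_traj: int
    acceptance_rate: float


def chain_stats(model: SAWModel, n_bonds: int, config: MCConfig,
                substrate: Substrate = NO_SUBSTRATE) -> ChainStats:
    """Mean Rg and Ree^2 (nm, nm^2) over independent trajectories."""
    validate_model(model)
    if config.n_traj < 2:
        raise ValueError("need at least 2 trajectories for a standard error")
    dirs, sx, kind, rsq = _kernel_args(model, substrate)
    lo_mov = 1 if substrate.kind != "none" else 0
    a = model.lattice_constant_nm
    seeds = _trajectory_seeds(config.seed, config.n_traj)
    rg_traj = np.empty(config.n_traj)
    ree_traj = np.empty(config.n_traj)
    n_total = 0
    acc_total = 0
    att_total = 0
    for t, seed in enumerate(seeds):
        # random-coil start: equilibration only has to relax locally
        conf = initial_conformation(model, n_bonds, substrate, seed=seed,
                                    extended=False)
        rg_sum, ree_sum, n_samp, acc, att = run_stats(
            conf.coords, dirs, sx, kind, rsq, lo_mov, config.equil_steps,
            config.n_steps, config.n_blocks, config.sample_every, seed)
        if n_samp.sum() == 0:
            raise RuntimeError("no samples collected; increase n_steps")
        good = n_samp > 0
        block_rg = rg_sum[good] / n_samp[good]
        block_ree = ree_sum[good] / n_samp[good]
        rg_traj[t] = block_rg.mean() * a
        ree_traj[t] = block_ree.mean() * a * a
        n_total += int(n_samp.sum())
        acc_total += acc
        att_total += att
    nt = config.n_traj
    return ChainStats(
        rg_mean=float(rg_traj.mean()),
        rg_se=float(rg_traj.std(ddof=1) / math.sqrt(nt)),
        ree_sq_mean=float(ree_traj.mean()),
        ree_sq_se=float(ree_traj.std(ddof=1) / math.sqrt(nt)),
        n_samples=n_total,
        n_traj=nt,
        acceptance_rate=acc_total / att_total if att_total else 0.0,
    )


def kuhn_length(stats: ChainStats, contour_nm: float) -> float:
    """Effective segment length of the equivalent freely jointed chain (nm).

    Defined as ``<Ree^2> / L_c`` at the chain's own contour length.
    """
    if contour_nm <= 0:
        raise ValueError("contour length must be positive")
    if stats.ree_sq_mean < 0:
        raise ValueError("mean squared end-to-end distance must be non-negative")
    return stats.ree_sq_mean / contour_nm


def n_bonds_for_residues(n_residues: int) -> int:
    """Residues map to beads; a chain of n residues has n - 1 bonds."""
    if n_residues < 2:
        raise ValueError("need at least two residues for one bond")
    return n_residues - 1


def contour_length_nm(n_residues: int,
                      step_length_nm: float = constants.STEP_LENGTH_NM) -> float:
    """Backbone contour length of an n-residue chain (bonds x bond length)."""
    if n_residues <= 0:
        raise ValueError("residue count must be positive")
    return n_bonds_for_residues(n_residues) * step_length_nm


def enumerate_saws(model: SAWModel, n_bonds: int,
                   substrate: Substrate = NO_SUBSTRATE,
                   budget: int = 20_000_000) -> int:
    """Exact count of valid n-bond walks from the tether site (origin if free).

    Depth-first enumeration; refuses when the worst case ``n_nbr ** n_bonds``
    exceeds ``budget``.
    """
    validate_model(model)
    if n_bonds < 1:
        raise ValueError("n_bonds must be >= 1")
    if model.n_nbr ** n_bonds > budget:
        raise ValueError(
            f"enumeration budget exceeded: {model.n_nbr}^{n_bonds} walks; "
            "use a smaller n_bonds or raise the budget")
    dirs = [tuple(d) for d in model.step.direction_set.tolist()]
    sx = model.max_excl_sq
    start = tuple(int(v) for v in substrate.tether_site)
    if substrate.excludes(start):
        raise ValueError("tether site is excluded by the substrate")
    coords = [start]

    def ok(site) -> bool:
        if substrate.excludes(site):
            return False
        x, y, z = site
        for (px, py, pz) in coords:
            dx, dy, dz = px - x, py - y, pz - z
            if dx * dx + dy * dy + dz * dz <= sx:
                return False
        return True

    def walk(remaining: int) -> int:
        if remaining == 0:
            return 1
        total = 0
        hx, hy, hz = coords[-1]
        for dx, dy, dz in dirs:
            site = (hx + dx, hy + dy, hz + dz)
            if ok(site):
                coords.append(site)
                total += walk(remaining - 1)
                coords.pop()
        return total

    return walk(n_bonds)
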