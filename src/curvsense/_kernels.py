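"""Numba kernels for lattice-chain Monte Carlo.

All kernels operate on an ``(n_beads, 3)`` int64 coordinate array in place.
Conventions shared by every kernel:

* ``dirs``   -- ``(n_dirs, 3)`` int64 array of allowed bond vectors.
* ``sx``     -- largest excluded squared distance between two beads.  A pair
  of beads at squared distance ``<= sx`` clashes; ``sx = 0`` forbids only
  site coincidence and ``sx = -1`` disables self-avoidance entirely
  (ideal-walk test mode).
* ``kind`` / ``rsq`` -- substrate code and squared radius (lattice units):
  0 none, 1 solid half-space ``z < 0``, 2 solid sphere of radius ``r``
  centred at the origin (chain outside), 3 chain confined inside a sphere,
  4 solid cylinder along ``z`` (chain outside).
* ``lo_mov`` -- index of the first movable bead; beads below it are frozen.

Randomness comes from numba's internal generator, seeded explicitly at the
top of every kernel so that runs are reproducible.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _excluded_site(x, y, z, kind, rsq):
    if kind == 0:
        return False
    if kind == 1:
        return z < 0
    if kind == 2:
        return x * x + y * y + z * z < rsq
    if kind == 3:
        return x * x + y * y + z * z > rsq
    # kind == 4: solid cylinder along z
    return x * x + y * y < rsq


@njit(cache=True)
def _clash(coords, upto, skip, x, y, z, sx):
    """Site (x,y,z) falls inside the exclusion shell of a bead < upto."""
    for j in range(upto):
        if j == skip:
            continue
        dx = coords[j, 0] - x
        dy = coords[j, 1] - y
        dz = coords[j, 2] - z
        if dx * dx + dy * dy + dz * dz <= sx:
            return True
    return False


@njit(cache=True)
def _clash2(coords, skip_a, skip_b, x, y, z, sx):
    """Site (x,y,z) clashes with any bead other than skip_a/skip_b."""
    for j in range(coords.shape[0]):
        if j == skip_a or j == skip_b:
            continue
        dx = coords[j, 0] - x
        dy = coords[j, 1] - y
        dz = coords[j, 2] - z
        if dx * dx + dy * dy + dz * dz <= sx:
            return True
    return False


@njit(cache=True)
def _in_dirs(dirs, dx, dy, dz):
    for m in range(dirs.shape[0]):
        if dirs[m, 0] == dx and dirs[m, 1] == dy and dirs[m, 2] == dz:
            return True
    return False


@njit(cache=True)
def _single_move(coords, dirs, sx, kind, rsq, lo_mov):
    """Displace one random movable bead to ``base + random direction``.

    The base is the preceding bead (bead 1 for bead 0); interior beads must
    keep a valid bond to the following bead.
    """
    nb = coords.shape[0]
    i = lo_mov + np.random.randint(0, nb - lo_mov)
    k = np.random.randint(0, dirs.shape[0])
    base = 1 if i == 0 else i - 1
    x = coords[base, 0] + dirs[k, 0]
    y = coords[base, 1] + dirs[k, 1]
    z = coords[base, 2] + dirs[k, 2]
    if 0 < i < nb - 1:
        if not _in_dirs(dirs, coords[i + 1, 0] - x, coords[i + 1, 1] - y,
                        coords[i + 1, 2] - z):
            return False
    if _excluded_site(x, y, z, kind, rsq):
        return False
    if _clash(coords, nb, i, x, y, z, sx):
        return False
    coords[i, 0] = x
    coords[i, 1] = y
    coords[i, 2] = z
    return True


@njit(cache=True)
def _segment_regrow(coords, dirs, sx, kind, rsq, lo_seg, seg_len, scratch):
    """Rebuild ``seg_len`` consecutive beads with fresh random bonds.

    A start bead i >= ``lo_seg`` (>= 1) is chosen at random; beads
    i..i+seg_len-1 are proposed anew from bead i-1 with independent uniform
    bond directions; if a bead follows the segment its bond must stay
    valid.  The proposal probability is the same in both directions (the
    old segment corresponds to one particular direction tuple), so
    accept-iff-valid preserves the uniform distribution.
    """
    nb = coords.shape[0]
    i = lo_seg + np.random.randint(0, nb - seg_len - lo_seg + 1)
    px = coords[i - 1, 0]
    py = coords[i - 1, 1]
    pz = coords[i - 1, 2]
    for s in range(seg_len):
        k = np.random.randint(0, dirs.shape[0])
        px += dirs[k, 0]
        py += dirs[k, 1]
        pz += dirs[k, 2]
        if _excluded_site(px, py, pz, kind, rsq):
            return False
        scratch[s, 0] = px
        scratch[s, 1] = py
        scratch[s, 2] = pz
    if i + seg_len <= nb - 1:
        if not _in_dirs(dirs, coords[i + seg_len, 0] - px,
                        coords[i + seg_len, 1] - py,
                        coords[i + seg_len, 2] - pz):
            return False
    # clash of each proposed site against all beads outside the segment
    for s in range(seg_len):
        x = scratch[s, 0]
        y = scratch[s, 1]
        z = scratch[s, 2]
        for j in range(nb):
            if i <= j < i + seg_len:
                continue
            dx = coords[j, 0] - x
            dy = coords[j, 1] - y
            dz = coords[j, 2] - z
            if dx * dx + dy * dy + dz * dz <= sx:
                return False
        # and against the other proposed sites
        for t in range(s):
            dx = scratch[t, 0] - x
            dy = scratch[t, 1] - y
            dz = scratch[t, 2] - z
            if dx * dx + dy * dy + dz * dz <= sx:
                return False
    for s in range(seg_len):
        coords[i + s, 0] = scratch[s, 0]
        coords[i + s, 1] = scratch[s, 1]
        coords[i + s, 2] = scratch[s, 2]
    return True


#: longest segment regrown in one local move
MAX_SEGMENT = 4


@njit(cache=True)
def _attempt_move_s(coords, dirs, sx, kind, rsq, lo_mov, scratch):
    """One symmetric local-move proposal; accept iff the result is valid.

    Attempts alternate at random between single-bead displacements and
    regrowth of a short random segment (2..4 beads), which decorrelates
    bonds whose bead is pinned between a frozen predecessor and the rest
    of the chain.  ``scratch`` is a reusable (MAX_SEGMENT, 3) workspace.
    """
    nb = coords.shape[0]
    lo_seg = lo_mov if lo_mov >= 1 else 1
    span = nb - lo_seg  # beads eligible for segment regrowth
    max_len = MAX_SEGMENT if span >= MAX_SEGMENT else span
    if max_len >= 2 and np.random.randint(0, 2) == 0:
        seg_len = 2 + np.random.randint(0, max_len - 1)
        return _segment_regrow(coords, dirs, sx, kind, rsq, lo_seg, seg_len,
                               scratch)
    return _single_move(coords, dirs, sx, kind, rsq, lo_mov)


@njit(cache=True)
def _attempt_move(coords, dirs, sx, kind, rsq, lo_mov):
    scratch = np.empty((MAX_SEGMENT, 3), np.int64)
    return _attempt_move_s(coords, dirs, sx, kind, rsq, lo_mov, scratch)


@njit(cache=True)
def run_stats(coords, dirs, sx, kind, rsq, lo_mov, n_equil, n_steps,
              n_blocks, sample_every, seed):
    """Local-move MC accumulating block averages of Rg and Ree^2.

    One MC step is ``n_beads - 1`` local-move attempts.  Returns per-block
    sums of Rg (lattice units) and Ree^2 (lattice units^2), per-block sample
    counts, and (accepted, attempted) move totals.
    """
    np.random.seed(seed)
    nb = coords.shape[0]
    moves_per_step = nb - 1
    scratch = np.empty((MAX_SEGMENT, 3), np.int64)
    for _ in range(n_equil * moves_per_step):
        _attempt_move_s(coords, dirs, sx, kind, rsq, lo_mov, scratch)
    block_len = max(n_steps // n_blocks, 1)
    rg_sum = np.zeros(n_blocks)
    ree_sum = np.zeros(n_blocks)
    n_samp = np.zeros(n_blocks, np.int64)
    accepted = 0
    attempted = 0
    for s in range(n_steps):
        for _ in range(moves_per_step):
            attempted += 1
            if _attempt_move_s(coords, dirs, sx, kind, rsq, lo_mov, scratch):
                accepted += 1
        if (s + 1) % sample_every == 0:
            b = min(s // block_len, n_blocks - 1)
            cx = 0.0
            cy = 0.0
            cz = 0.0
            for j in range(nb):
                cx += coords[j, 0]
                cy += coords[j, 1]
                cz += coords[j, 2]
            cx /= nb
            cy /= nb
            cz /= nb
            sq = 0.0
            for j in range(nb):
                sq += ((coords[j, 0] - cx) ** 2 + (coords[j, 1] - cy) ** 2
                       + (coords[j, 2] - cz) ** 2)
            rg_sum[b] += np.sqrt(sq / nb)
            dx = coords[nb - 1, 0] - coords[0, 0]
            dy = coords[nb - 1, 1] - coords[0, 1]
            dz = coords[nb - 1, 2] - coords[0, 2]
            ree_sum[b] += dx * dx + dy * dy + dz * dz
            n_samp[b] += 1
    return rg_sum, ree_sum, n_samp, accepted, attempted


@njit(cache=True)
def run_sample(coords, dirs, sx, kind, rsq, lo_mov, n_steps, sample_every,
               seed, out):
    """Local-move MC storing a conformation snapshot every sample_every steps.

    ``out`` is a preallocated ``(n_samples, n_beads, 3)`` array.  Returns the
    number of snapshots written plus (accepted, attempted) totals.
    """
    np.random.seed(seed)
    nb = coords.shape[0]
    moves_per_step = nb - 1
    scratch = np.empty((MAX_SEGMENT, 3), np.int64)
    accepted = 0
    attempted = 0
    idx = 0
    for s in range(n_steps):
        for _ in range(moves_per_step):
            attempted += 1
            if _attempt_move_s(coords, dirs, sx, kind, rsq, lo_mov, scratch):
                accepted += 1
        if (s + 1) % sample_every == 0 and idx < out.shape[0]:
            for j in range(nb):
                out[idx, j, 0] = coords[j, 0]
                out[idx, j, 1] = coords[j, 1]
                out[idx, j, 2] = coords[j, 2]
            idx += 1
    return idx, accepted, attempted


@njit(cache=True)
def extend_segment(coords, start, dirs, sx, kind, rsq, seed, n_restarts,
                   try_straight=True):
    """Rebuild beads start..end as an allowed extended conformation.

    Beads below ``start`` are honoured as frozen obstacles.  Straight lines
    along each allowed direction are tried first (unless ``try_straight`` is
    False); if none fits, randomized greedy growth with restarts is
    attempted.  Returns True on success.
    """
    np.random.seed(seed)
    nb = coords.shape[0]
    nd = dirs.shape[0]
    n_straight = nd if try_straight else 0
    for k in range(n_straight):
        ok = True
        for i in range(start, nb):
            x = coords[i - 1, 0] + dirs[k, 0]
            y = coords[i - 1, 1] + dirs[k, 1]
            z = coords[i - 1, 2] + dirs[k, 2]
            if _excluded_site(x, y, z, kind, rsq) or _clash(
                    coords, i, -1, x, y, z, sx):
                ok = False
                break
            coords[i, 0] = x
            coords[i, 1] = y
            coords[i, 2] = z
        if ok:
            return True
    for _ in range(n_restarts):
        ok = True
        for i in range(start, nb):
            off = np.random.randint(0, nd)
            placed = False
            for t in range(nd):
                k = (off + t) % nd
                x = coords[i - 1, 0] + dirs[k, 0]
                y = coords[i - 1, 1] + dirs[k, 1]
                z = coords[i - 1, 2] + dirs[k, 2]
                if not _excluded_site(x, y, z, kind, rsq) and not _clash(
                        coords, i, -1, x, y, z, sx):
                    coords[i, 0] = x
                    coords[i, 1] = y
                    coords[i, 2] = z
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return True
    return False


@njit(cache=True)
def hsmc_scan(coords, dirs, sx, kind, rsq, j, n_equil, n_scan, seed):
    """Scan the direction of bond j while the past (beads < j) is frozen.

    One MC step is a sweep of the future segment: one local-move attempt
    per movable bead.  Runs ``n_equil`` equilibration steps, then
    ``n_scan`` recorded steps, noting after each one the current direction
    of bond j (bead j-1 -> bead j).  Returns per-direction counts summing
    to ``n_scan``.
    """
    np.random.seed(seed)
    nd = dirs.shape[0]
    moves_per_step = coords.shape[0] - j  # movable beads j..n
    scratch = np.empty((MAX_SEGMENT, 3), np.int64)
    for _ in range(n_equil * moves_per_step):
        _attempt_move_s(coords, dirs, sx, kind, rsq, j, scratch)
    counts = np.zeros(nd, np.int64)
    for _ in range(n_scan):
        for _ in range(moves_per_step):
            _attempt_move_s(coords, dirs, sx, kind, rsq, j, scratch)
        dx = coords[j, 0] - coords[j - 1, 0]
        dy = coords[j, 1] - coords[j - 1, 1]
        dz = coords[j, 2] - coords[j - 1, 2]
        for m in range(nd):
            if dirs[m, 0] == dx and dirs[m, 1] == dy and dirs[m, 2] == dz:
                counts[m] += 1
                break
    return counts
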