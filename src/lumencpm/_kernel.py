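"""Compiled inner loop: copy attempts, Metropolis acceptance and the
copy-triggered bookkeeping rules, plus the per-vesicle swap move.

All functions operate in place on the flat state arrays of
:class:`~lumencpm.state.SimState`.  Randomness comes from an explicit
xorshift64* generator state (``uint64[1]``) so trajectories are
bit-reproducible and the de-novo fluid-insertion extension can be proven to
leave the base dynamics untouched when disabled.

Bookkeeping applied when an accepted relabel shrinks a compartment:

* a vesicle deleted by a fluid transfers one target unit from its cell to
  that fluid; deleted by a same-cell vacuole it donates its target to the
  vacuole (fusion-by-copy); deleted by anything else its cell loses one
  target unit to ECM fluid;
* a luminal-fluid body deleted by another luminal body donates its target to
  it, otherwise to ECM fluid;
* a vacuole reduced to a single site is demoted to a vesicle (target 1, or 0
  if the vacuole's target was 0); the residual target follows the invading
  compartment if that is luminal fluid or a vacuole, otherwise goes to ECM
  fluid, and the owning cell's target tracks any residual leaving the cell;
* a cell whose total area reaches zero surrenders its residual target to
  ECM fluid.

These transfers keep the system-wide cell-level target total exactly
constant.
"""

import numpy as np
from numba import njit

from .params import (ECM, ECM_FLUID, KIND_CELL, LUMINAL_FLUID, VACUOLE,
                     VESICLE)

ECMF_CELL = 1  # cell identifier of the global ECM-fluid body
ECMF_COMP = 1  # its (single) compartment

# Moore offsets with the first-order (von Neumann) sites first, so that the
# first ``n_contact`` entries span the configured contact neighbourhood.
_DR = np.array([-1, 0, 0, 1, -1, -1, 1, 1], dtype=np.int64)
_DC = np.array([0, -1, 1, 0, -1, 1, -1, 1], dtype=np.int64)


# ----------------------------------------------------------------- RNG ----
@njit(cache=True)
def seed_rng(seed):
    """Initialise a 1-element uint64 xorshift64* state via splitmix64."""
    z = (np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15))
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    out = np.empty(1, dtype=np.uint64)
    out[0] = z if z != np.uint64(0) else np.uint64(0xDEADBEEF)
    return out


@njit(cache=True, inline="always")
def _next_u64(rng):
    x = rng[0]
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    rng[0] = x
    return x * np.uint64(0x2545F4914F6CDD1D)


@njit(cache=True, inline="always")
def _rand(rng):
    return (_next_u64(rng) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


# ------------------------------------------------------------- energies ----
@njit(cache=True, inline="always")
def _pair_j(a, b, comp_type, comp_cell, JE, JI):
    if a == b:
        return 0.0
    ta = comp_type[a]
    tb = comp_type[b]
    if comp_cell[a] == comp_cell[b]:
        return JI[ta, tb]
    return JE[ta, tb]


@njit(cache=True)
def delta_copy(lattice, tr, tc, w,
               comp_type, comp_cell, comp_area, comp_target,
               cell_kind, cell_area, cell_target,
               JE, JI, lam_t, lam_k, n_contact):
    """Energy change of relabelling site (tr, tc) to compartment ``w``."""
    d = lattice[tr, tc]
    de = 0.0
    for k in range(n_contact):
        n = lattice[tr + _DR[k], tc + _DC[k]]
        de += _pair_j(w, n, comp_type, comp_cell, JE, JI)
        de -= _pair_j(d, n, comp_type, comp_cell, JE, JI)
    lw = lam_t[comp_type[w]]
    if lw > 0.0:
        a = float(comp_area[w]) - float(comp_target[w])
        de += lw * ((a + 1.0) ** 2 - a ** 2)
    ld = lam_t[comp_type[d]]
    if ld > 0.0:
        a = float(comp_area[d]) - float(comp_target[d])
        # a compartment deleted by the copy drops out of the energy
        new = 0.0 if comp_area[d] == 1 else ld * (a - 1.0) ** 2
        de += new - ld * a ** 2
    cw = comp_cell[w]
    cd = comp_cell[d]
    if cw != cd:
        lcw = lam_k[cell_kind[cw]]
        if lcw > 0.0:
            a = float(cell_area[cw]) - float(cell_target[cw])
            de += lcw * ((a + 1.0) ** 2 - a ** 2)
        lcd = lam_k[cell_kind[cd]]
        if lcd > 0.0:
            a = float(cell_area[cd]) - float(cell_target[cd])
            new = 0.0 if cell_area[cd] == 1 else lcd * (a - 1.0) ** 2
            de += new - lcd * a ** 2
    return de


# ---------------------------------------------------------- bookkeeping ----
@njit(cache=True)
def apply_relabel(lattice, tr, tc, w,
                  comp_type, comp_cell, comp_area, comp_target,
                  cell_kind, cell_area, cell_target):
    """Relabel site (tr, tc) to compartment ``w`` with all side-effect rules."""
    d = lattice[tr, tc]
    lattice[tr, tc] = w
    comp_area[w] += 1
    comp_area[d] -= 1
    cw = comp_cell[w]
    cd = comp_cell[d]
    if cw != cd:
        cell_area[cw] += 1
        cell_area[cd] -= 1
    td = comp_type[d]
    tw = comp_type[w]
    if comp_area[d] == 0:
        if td == VESICLE:
            if tw == LUMINAL_FLUID or tw == ECM_FLUID:
                cell_target[cd] -= 1
                cell_target[cw] += 1
            elif tw == VACUOLE and cw == cd:
                comp_target[w] += comp_target[d]
            else:
                cell_target[cd] -= 1
                cell_target[ECMF_CELL] += 1
            comp_target[d] = 0
        elif td == LUMINAL_FLUID:
            if tw == LUMINAL_FLUID:
                cell_target[cw] += cell_target[cd]
            else:
                cell_target[ECMF_CELL] += cell_target[cd]
            cell_target[cd] = 0
        elif td == VACUOLE:
            # vacuoles are demoted at area 1, so this is defensive only
            resid = comp_target[d]
            comp_target[d] = 0
            if resid > 0:
                cell_target[cd] -= resid
                cell_target[ECMF_CELL] += resid
        if cell_kind[cd] == KIND_CELL and cell_area[cd] == 0:
            resid = cell_target[cd]
            cell_target[cd] = 0
            cell_target[ECMF_CELL] += resid
    elif td == VACUOLE and comp_area[d] == 1:
        big = comp_target[d]
        new_t = 1 if big >= 1 else 0
        resid = big - new_t
        comp_type[d] = VESICLE
        comp_target[d] = new_t
        if resid > 0:
            if tw == VACUOLE:
                comp_target[w] += resid
                if cw != cd:
                    cell_target[cw] += resid
                    cell_target[cd] -= resid
            elif tw == LUMINAL_FLUID:
                cell_target[cw] += resid
                cell_target[cd] -= resid
            else:
                cell_target[ECMF_CELL] += resid
                cell_target[cd] -= resid
    return d


# ----------------------------------------------------------- main loop ----
@njit(cache=True)
def run_copy_attempts(lattice,
                      comp_type, comp_cell, comp_area, comp_target,
                      cell_kind, cell_area, cell_target,
                      JE, JI, lam_t, lam_k, n_contact, mu,
                      p_insert, insertion_enabled,
                      src_r, src_c, n_attempts, rng, counters):
    """Perform ``n_attempts`` modified-Metropolis copy attempts.

    ``counters`` (int64[5]) accumulates: attempts, accepted copies, same-
    compartment no-ops, insertion evaluations, accepted insertions.  Source
    sites are drawn uniformly from the fixed non-ECM pool; targets uniformly
    from the 8-site Moore neighbourhood.  With probability ``p_insert`` the
    attempt evaluates de-novo ECM-fluid insertion at the target instead of
    the membrane extension; the branch draws no randomness when
    ``p_insert`` is zero or the extension is disabled, so the base model's
    trajectory is untouched.
    """
    n_src = src_r.shape[0]
    for _ in range(n_attempts):
        counters[0] += 1
        i = int(_rand(rng) * n_src)
        sr = src_r[i]
        sc = src_c[i]
        k = int(_rand(rng) * 8)
        tr = sr + _DR[k]
        tc = sc + _DC[k]
        d = lattice[tr, tc]
        if comp_type[d] == ECM:
            continue
        if insertion_enabled and p_insert > 0.0 and _rand(rng) < p_insert:
            counters[3] += 1
            if d == ECMF_COMP:
                continue
            de = delta_copy(lattice, tr, tc, ECMF_COMP,
                            comp_type, comp_cell, comp_area, comp_target,
                            cell_kind, cell_area, cell_target,
                            JE, JI, lam_t, lam_k, n_contact)
            if de <= 0.0 or _rand(rng) < np.exp(-de / mu):
                apply_relabel(lattice, tr, tc, ECMF_COMP,
                              comp_type, comp_cell, comp_area, comp_target,
                              cell_kind, cell_area, cell_target)
                counters[4] += 1
            continue
        s = lattice[sr, sc]
        if s == d:
            counters[2] += 1
            continue
        if comp_type[s] == VESICLE:
            continue
        de = delta_copy(lattice, tr, tc, s,
                        comp_type, comp_cell, comp_area, comp_target,
                        cell_kind, cell_area, cell_target,
                        JE, JI, lam_t, lam_k, n_contact)
        if de <= 0.0 or _rand(rng) < np.exp(-de / mu):
            apply_relabel(lattice, tr, tc, s,
                          comp_type, comp_cell, comp_area, comp_target,
                          cell_kind, cell_area, cell_target)
            counters[1] += 1


# -------------------------------------------------------- vesicle moves ----
@njit(cache=True)
def delta_swap(lattice, vr, vc, nr, nc, comp_type, comp_cell, JE, JI,
               n_contact):
    """Contact-energy change of exchanging the contents of two sites
    (areas are unchanged by a swap)."""
    v = lattice[vr, vc]
    n = lattice[nr, nc]
    de = 0.0
    for k in range(n_contact):
        ar = vr + _DR[k]
        ac = vc + _DC[k]
        if ar == nr and ac == nc:
            continue
        m = lattice[ar, ac]
        de += _pair_j(n, m, comp_type, comp_cell, JE, JI)
        de -= _pair_j(v, m, comp_type, comp_cell, JE, JI)
    for k in range(n_contact):
        ar = nr + _DR[k]
        ac = nc + _DC[k]
        if ar == vr and ac == vc:
            continue
        m = lattice[ar, ac]
        de += _pair_j(v, m, comp_type, comp_cell, JE, JI)
        de -= _pair_j(n, m, comp_type, comp_cell, JE, JI)
    return de


@njit(cache=True)
def vesicle_swap_attempt(lattice, vr, vc, sigma,
                         comp_type, comp_cell, comp_area, comp_target,
                         cell_kind, cell_area, cell_target,
                         JE, JI, lam_t, lam_k, n_contact, mu, p_move, rng):
    """One biased-random-walk step of a vesicle.

    Picks a random Moore neighbour; a same-cell neighbour is exchanged with
    probability ``p_move * min(1, exp(-dE/mu))`` (preferential adhesion to
    apical membrane, vesicles and vacuoles enters through the internal
    contact energies); a fluid neighbour triggers copy-style secretion of
    the vesicle pixel into that fluid; ECM or another cell's site blocks
    the move.

    Returns 0 (no move), 1 (swap) or 2 (secreted into fluid).
    """
    if lattice[vr, vc] != sigma:
        return 0  # displaced earlier in this pass
    k = int(_rand(rng) * 8)
    nr = vr + _DR[k]
    nc = vc + _DC[k]
    n = lattice[nr, nc]
    if n == sigma:
        return 0
    tn = comp_type[n]
    if comp_cell[n] == comp_cell[sigma]:
        de = delta_swap(lattice, vr, vc, nr, nc, comp_type, comp_cell,
                        JE, JI, n_contact)
        p = p_move if de <= 0.0 else p_move * np.exp(-de / mu)
        if _rand(rng) < p:
            lattice[vr, vc] = n
            lattice[nr, nc] = sigma
            return 1
        return 0
    if tn == LUMINAL_FLUID or tn == ECM_FLUID:
        de = delta_copy(lattice, vr, vc, n,
                        comp_type, comp_cell, comp_area, comp_target,
                        cell_kind, cell_area, cell_target,
                        JE, JI, lam_t, lam_k, n_contact)
        p = p_move if de <= 0.0 else p_move * np.exp(-de / mu)
        if _rand(rng) < p:
            apply_relabel(lattice, vr, vc, n,
                          comp_type, comp_cell, comp_area, comp_target,
                          cell_kind, cell_area, cell_target)
            return 2
    return 0
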