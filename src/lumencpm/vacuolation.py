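"""Vacuolation: pinocytosis, vesicle transport, fusion, demotion, secretion
and fluid fusion, with exact target-area conservation.

Pinocytotic vesicles (one site, target area 1, kept small by a stiff
elasticity) form where polarized membrane pixels became internalized; they
random-walk through the cell (biased towards the apical membrane and other
vesicles/vacuoles by the internal contact energies), fuse into vacuoles,
and are secreted as luminal fluid when they reach the apical membrane.
Every rule transfers target area so that the cell-level total over all
cells and fluid bodies stays exactly constant; see the module docstrings of
``_kernel`` for the copy-triggered counterparts.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from . import params as P
from . import _kernel
from ._grid import MOORE_OFFSETS, VN_OFFSETS, shifted
from .state import ECM_FLUID_CELL, ECM_FLUID_COMP, SimState

#: 4-connectivity structuring element for "first-order connected".
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _kernel_args(sim):
    s = sim.state
    return (s.comp_type, s.comp_cell, s.comp_area, s.comp_target,
            s.cell_kind, s.cell_area, s.cell_target)


# ------------------------------------------------------------ pinocytosis --
def pinocytose(sim, candidates) -> list[int]:
    """Convert internalized membrane pixels into vesicles with prob P_pin.

    ``candidates`` are the (rows, cols) reported by the repolarization pass;
    they have already been retyped to cytoplasm.  Each created vesicle is a
    new one-site compartment with target area 1; the pinocytosing cell's
    target grows by one and the ECM-fluid target shrinks by one (the vesicle
    contains ECM fluid taken up at the membrane).
    """
    state = sim.state
    rows, cols = candidates
    if rows.size == 0:
        return []
    take = sim.np_rng.random(rows.size) < sim.mech.P_pin
    created = []
    warned = False
    for r, c in zip(rows[take], cols[take]):
        if state.cell_target[ECM_FLUID_CELL] <= 0:
            # the extracellular fluid reservoir is exhausted: there is
            # nothing to take up, so the pixel stays cytoplasm (creating an
            # unfunded vesicle would slowly bleed the cell's target into
            # the fluids through the deletion/secretion rules)
            if not warned:
                warnings.warn("pinocytosis: ECM-fluid target exhausted; "
                              "uptake suspended")
                warned = True
            continue
        sigma_old = int(state.lattice[r, c])
        xi = int(state.comp_cell[sigma_old])
        v = state.new_compartment(P.VESICLE, xi, target=1)
        state.paint_site(r, c, v)
        state.cell_target[xi] += 1
        state.cell_target[ECM_FLUID_CELL] -= 1
        created.append(v)
    return created


# --------------------------------------------------------- vesicle steps --
def vesicle_steps(sim) -> int:
    """One biased-random-walk step per vesicle compartment (period 1 MCS)."""
    state = sim.state
    tl = state.type_lattice()
    rows, cols = np.nonzero(tl == P.VESICLE)
    if rows.size == 0:
        return 0
    sigmas = state.lattice[rows, cols]
    _, first = np.unique(sigmas, return_index=True)
    moved = 0
    for i in np.sort(first):
        res = _kernel.vesicle_swap_attempt(
            state.lattice, rows[i], cols[i], sigmas[i],
            *_kernel_args(sim),
            sim.params.JE, sim.params.JI, sim._lam_t, sim._lam_k,
            sim.params.n_contact, sim.params.mu, sim.mech.P_A,
            sim.kernel_rng)
        moved += res != 0
    return moved


# ---------------------------------------------------------------- fusion --
def fuse_vesicles_vacuoles(sim) -> list[tuple[int, ...]]:
    """Fuse Moore-adjacent same-cell vesicle/vacuole compartments.

    Each unordered adjacent pair is considered once per MCS and fuses with
    probability P_fuse; transitively linked pairs collapse into a single
    vacuole whose target area is the sum of the fused targets.
    """
    state = sim.state
    lat = state.lattice
    tl = state.type_lattice()
    cl = state.cell_lattice()
    vv = (tl == P.VESICLE) | (tl == P.VACUOLE)
    if not vv.any():
        return []
    pairs = set()
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        a = shifted(lat, dr, dc, -1)
        ok = (vv & shifted(vv, dr, dc, False)
              & (shifted(cl, dr, dc, -1) == cl) & (a != lat) & (a >= 0))
        if ok.any():
            sa = lat[ok]
            sb = a[ok]
            lo = np.minimum(sa, sb)
            hi = np.maximum(sa, sb)
            pairs.update(zip(lo.tolist(), hi.tolist()))
    if not pairs:
        return []
    parent = {}

    def find(x):
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    for lo, hi in sorted(pairs):
        if sim.np_rng.random() < sim.mech.P_fuse:
            ra, rb = find(lo), find(hi)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    groups = {}
    for sigma in {s for pair in pairs for s in pair}:
        root = find(sigma)
        if root != sigma:
            groups.setdefault(root, []).append(sigma)
    if not groups:
        return []
    idmap = np.arange(state.n_comps, dtype=lat.dtype)
    events = []
    for root, members in sorted(groups.items()):
        for m in members:
            idmap[m] = root
            state.comp_area[root] += state.comp_area[m]
            state.comp_target[root] += state.comp_target[m]
            state.comp_area[m] = 0
            state.comp_target[m] = 0
        state.comp_type[root] = P.VACUOLE
        events.append((root, *members))
    state.lattice = idmap[lat]
    return events


# -------------------------------------------------------------- demotion --
def demote_vacuole_fragments(sim) -> list[int]:
    """Demote split-off single vacuole pixels (surrounded by same-cell
    cytoplasm) to vesicles; the donor vacuole's target drops by the new
    vesicle's target (1, or 0 if the donor's target was already 0)."""
    state = sim.state
    lat = state.lattice
    tl = state.type_lattice()
    cl = state.cell_lattice()
    vac = tl == P.VACUOLE
    if not vac.any():
        return []
    lone = vac.copy()
    all_cyt = vac.copy()
    for dr, dc in MOORE_OFFSETS:
        lone &= shifted(lat, dr, dc, -1) != lat
        all_cyt &= ((shifted(tl, dr, dc, P.ECM) == P.CYTOPLASM)
                    & (shifted(cl, dr, dc, -1) == cl))
    rows, cols = np.nonzero(lone & all_cyt)
    created = []
    for r, c in zip(rows, cols):
        sigma = int(lat[r, c])
        xi = int(state.comp_cell[sigma])
        if state.comp_area[sigma] >= 2:
            new_t = 1 if state.comp_target[sigma] >= 1 else 0
            v = state.new_compartment(P.VESICLE, xi, target=new_t)
            state.paint(np.array([r]), np.array([c]), v)
            state.comp_target[sigma] -= new_t
            created.append(v)
        else:
            # the whole vacuole is this one pixel: demote in place
            big = int(state.comp_target[sigma])
            new_t = min(big, 1)
            resid = big - new_t
            state.comp_type[sigma] = P.VESICLE
            state.comp_target[sigma] = new_t
            if resid > 0:
                state.cell_target[xi] -= resid
                state.cell_target[ECM_FLUID_CELL] += resid
            created.append(sigma)
    return created


# -------------------------------------------------------------- secretion --
def secrete(sim) -> list[dict]:
    """Secrete vesicles/vacuoles that reached the apical membrane.

    A vesicle/vacuole pixel with a first-order (von Neumann) apical
    neighbour triggers secretion of its whole first-order-connected patch of
    same-cell vesicle/vacuole pixels into one new luminal-fluid body.  The
    luminal target is the combined target of the fully secreted compartments
    plus, for a partially secreted vacuole, the secreted part's share
    (bounded by the vacuole's remaining target); the secreting cell's target
    drops by the same amount.
    """
    state = sim.state
    tl = state.type_lattice()
    cl = state.cell_lattice()
    vv = (tl == P.VESICLE) | (tl == P.VACUOLE)
    if not vv.any():
        return []
    apical_nb = np.zeros(tl.shape, dtype=bool)
    for dr, dc in VN_OFFSETS:
        apical_nb |= shifted(tl, dr, dc, P.ECM) == P.APICAL
    trig = vv & apical_nb
    if not trig.any():
        return []
    events = []
    for xi in sorted(np.unique(cl[trig]).tolist()):
        mask = vv & (cl == xi)
        labels, _ = ndimage.label(mask, structure=_CROSS)
        for lab in sorted(np.unique(labels[trig & (cl == xi)]).tolist()):
            if lab == 0:
                continue
            rows, cols = np.nonzero(labels == lab)
            sigmas = state.lattice[rows, cols]
            transferred = 0
            for sigma, cnt in zip(*np.unique(sigmas, return_counts=True)):
                if cnt == state.comp_area[sigma]:
                    transferred += int(state.comp_target[sigma])
                    state.comp_target[sigma] = 0
                else:
                    part = min(int(cnt), int(state.comp_target[sigma]))
                    transferred += part
                    state.comp_target[sigma] -= part
            new_xi = state.new_cell(P.KIND_FLUID)
            new_sigma = state.new_compartment(P.LUMINAL_FLUID, new_xi)
            state.paint(rows, cols, new_sigma)
            state.cell_target[new_xi] = transferred
            state.cell_target[xi] -= transferred
            events.append({"cell": int(xi), "luminal": int(new_sigma),
                           "sites": int(rows.size),
                           "target": int(transferred)})
    return events


# ----------------------------------------------------------- fluid fusion --
def fuse_fluids(sim) -> list[dict]:
    """Merge adjacent luminal-fluid bodies; absorb luminal fluid into ECM
    fluid when it touches the ECM or is completely surrounded by ECM fluid.
    Targets are transferred with each merge."""
    state = sim.state
    events = []
    tl = state.type_lattice()
    if not (tl == P.LUMINAL_FLUID).any():
        return events

    # 1. luminal-luminal merges (Moore adjacency, unconditional)
    lat = state.lattice
    lum = tl == P.LUMINAL_FLUID
    pairs = set()
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        a = shifted(lat, dr, dc, -1)
        ok = lum & shifted(lum, dr, dc, False) & (a != lat) & (a >= 0)
        if ok.any():
            sa, sb = lat[ok], a[ok]
            pairs.update(zip(np.minimum(sa, sb).tolist(),
                             np.maximum(sa, sb).tolist()))
    if pairs:
        parent = {}

        def find(x):
            while parent.get(x, x) != x:
                parent[x] = parent.get(parent[x], parent[x])
                x = parent[x]
            return x

        for lo, hi in sorted(pairs):
            ra, rb = find(lo), find(hi)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
        idmap = np.arange(state.n_comps, dtype=lat.dtype)
        for sigma in sorted({s for pair in pairs for s in pair}):
            root = find(sigma)
            if root != sigma:
                idmap[sigma] = root
                xo, xr = int(state.comp_cell[sigma]), int(state.comp_cell[root])
                state.comp_area[root] += state.comp_area[sigma]
                state.cell_area[xr] += state.cell_area[xo]
                state.cell_target[xr] += state.cell_target[xo]
                state.comp_area[sigma] = 0
                state.cell_area[xo] = 0
                state.cell_target[xo] = 0
                events.append({"kind": "merge", "into": root, "gone": int(sigma)})
        state.lattice = idmap[lat]
        tl = state.type_lattice()

    # 2 + 3. absorption into ECM fluid: ECM contact, or fully surrounded
    lat = state.lattice
    lum = tl == P.LUMINAL_FLUID
    if not lum.any():
        return events
    touches_ecm = np.zeros(lat.shape, dtype=bool)
    bad_surround = np.zeros(lat.shape, dtype=bool)
    for dr, dc in MOORE_OFFSETS:
        ntl = shifted(tl, dr, dc, P.ECM)
        nlat = shifted(lat, dr, dc, -1)
        touches_ecm |= ntl == P.ECM
        # a neighbour outside the compartment that is not ECM fluid
        bad_surround |= (nlat != lat) & (ntl != P.ECM_FLUID)
    absorb = set(np.unique(lat[lum & touches_ecm]).tolist())
    for sigma in np.unique(lat[lum]).tolist():
        if sigma not in absorb:
            sel = lat == sigma
            if not bad_surround[sel].any():
                absorb.add(sigma)
    for sigma in sorted(absorb):
        rows, cols = np.nonzero(lat == sigma)
        xo = int(state.comp_cell[sigma])
        state.paint(rows, cols, ECM_FLUID_COMP)
        state.cell_target[ECM_FLUID_CELL] += state.cell_target[xo]
        state.cell_target[xo] = 0
        events.append({"kind": "absorb", "gone": int(sigma)})
    return events
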