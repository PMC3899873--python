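"""Effective energy of the lattice: E = E_area + E_contact.

``E_area`` penalises deviations of actual from target area quadratically
with a role-dependent elasticity: cells at the cell level (lambda_cell),
fluid bodies per body (lambda_fluids), vesicles and vacuoles per compartment
(lambda_vesicle / lambda_vacuole).  ``E_contact`` sums a type-pair contact
energy over all Moore-neighbour site pairs that straddle a compartment
interface; the internal table J_I applies within a cell, the external table
J_E between cells.

``total_energy`` is the slow, from-scratch evaluation used as the oracle
against which the kernel's incremental deltas are verified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import params as P
from .state import SimState

#: offsets with the first-order sites first (mirrors the compiled kernel)
_OFFSETS = ((-1, 0), (0, -1), (0, 1), (1, 0),
            (-1, -1), (-1, 1), (1, -1), (1, 1))
#: forward half of each neighbourhood (each unordered pair counted once)
_FORWARD = {4: ((0, 1), (1, 0)),
            8: ((0, 1), (1, 0), (1, 1), (1, -1))}


def area_energy(actual: float, target: float, lam: float) -> float:
    """Quadratic area penalty ``lam * (actual - target)**2``."""
    if actual < 0 or target < 0:
        raise ValueError("areas must be non-negative")
    if lam < 0:
        raise ValueError("elasticity must be non-negative")
    return lam * (actual - target) ** 2


def contact_energy_pair(state: SimState, sigma_a: int, sigma_b: int,
                        params: P.EnergyParams) -> float:
    """Contact energy of one site pair: 0 within a compartment, J_I within a
    cell, J_E between cells."""
    if sigma_a == sigma_b:
        return 0.0
    ta = state.comp_type[sigma_a]
    tb = state.comp_type[sigma_b]
    if state.comp_cell[sigma_a] == state.comp_cell[sigma_b]:
        return float(params.JI[ta, tb])
    return float(params.JE[ta, tb])


@dataclass(frozen=True)
class EnergyDelta:
    delta_area: float
    delta_contact: float

    @property
    def total(self) -> float:
        return self.delta_area + self.delta_contact


def total_energy(state: SimState, params: P.EnergyParams) -> float:
    """Recompute E = E_area + E_contact from scratch (vectorised)."""
    return (total_area_energy(state, params)
            + total_contact_energy(state, params))


def total_area_energy(state: SimState, params: P.EnergyParams) -> float:
    nc = state.n_comps
    lam_t = params.lambda_by_type()[state.comp_type[:nc]]
    live = state.comp_area[:nc] > 0
    dev = (state.comp_area[:nc] - state.comp_target[:nc]).astype(np.float64)
    e = float(np.sum(lam_t[live] * dev[live] ** 2))
    ncell = state.n_cells
    lam_c = params.lambda_by_kind()[state.cell_kind[:ncell]]
    live_c = state.cell_area[:ncell] > 0
    devc = (state.cell_area[:ncell] - state.cell_target[:ncell]).astype(np.float64)
    e += float(np.sum(lam_c[live_c] * devc[live_c] ** 2))
    return e


def pair_views(arr: np.ndarray, dr: int, dc: int):
    """Views (a, b) with b displaced by (dr, dc) relative to a."""
    h, w = arr.shape
    ra = slice(max(0, -dr), h - max(0, dr))
    rb = slice(max(0, dr), h - max(0, -dr))
    ca = slice(max(0, -dc), w - max(0, dc))
    cb = slice(max(0, dc), w - max(0, -dc))
    return arr[ra, ca], arr[rb, cb]


def total_contact_energy(state: SimState, params: P.EnergyParams) -> float:
    lat = state.lattice
    types = state.comp_type[lat]
    cells = state.comp_cell[lat]
    e = 0.0
    # each unordered neighbour pair once
    for dr, dc in _FORWARD[params.n_contact]:
        a, b = pair_views(lat, dr, dc)
        ta, tb = pair_views(types, dr, dc)
        ca, cb = pair_views(cells, dr, dc)
        diff = a != b
        ji = diff & (ca == cb)
        je = diff & (ca != cb)
        e += float(params.JI[ta[ji], tb[ji]].sum())
        e += float(params.JE[ta[je], tb[je]].sum())
    return e


def delta_energy_copy(state: SimState, source_site, target_site,
                      params: P.EnergyParams,
                      winner: int | None = None) -> EnergyDelta:
    """Exact energy change of relabelling ``target_site`` to the source
    site's compartment (or to ``winner`` if given, e.g. the ECM-fluid
    compartment for a fluid-insertion proposal).

    Pure function: no side effects, no bookkeeping rules.  Contact terms run
    over the target site's Moore neighbourhood; area terms cover the growing
    and shrinking compartments and (if different) their cells.
    """
    sr, sc = source_site
    tr, tc = target_site
    w = int(state.lattice[sr, sc]) if winner is None else int(winner)
    d = int(state.lattice[tr, tc])
    if w == d:
        return EnergyDelta(0.0, 0.0)
    d_contact = 0.0
    for dr, dc in _OFFSETS[:params.n_contact]:
        nr, nc = tr + dr, tc + dc
        n = int(state.lattice[nr, nc])
        d_contact += (contact_energy_pair(state, w, n, params)
                      - contact_energy_pair(state, d, n, params))
    lam_t = params.lambda_by_type()
    lam_k = params.lambda_by_kind()
    d_area = 0.0
    for sigma, delta in ((w, 1), (d, -1)):
        lam = lam_t[state.comp_type[sigma]]
        if lam > 0:
            a = float(state.comp_area[sigma])
            A = float(state.comp_target[sigma])
            # compartments deleted (or not yet born) carry no area term
            new = 0.0 if a + delta == 0 else lam * (a + delta - A) ** 2
            old = 0.0 if a == 0 else lam * (a - A) ** 2
            d_area += new - old
    cw = int(state.comp_cell[w])
    cd = int(state.comp_cell[d])
    if cw != cd:
        for xi, delta in ((cw, 1), (cd, -1)):
            lam = lam_k[state.cell_kind[xi]]
            if lam > 0:
                a = float(state.cell_area[xi])
                A = float(state.cell_target[xi])
                new = 0.0 if a + delta == 0 else lam * (a + delta - A) ** 2
                old = 0.0 if a == 0 else lam * (a - A) ** 2
                d_area += new - old
    return EnergyDelta(d_area, d_contact)


def metropolis_probability(delta: float, mu: float) -> float:
    """min(1, exp(-delta/mu)): certain acceptance for non-positive deltas."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if delta <= 0:
        return 1.0
    return math.exp(-delta / mu)


def metropolis_accept(delta: float, mu: float, rng: np.random.Generator) -> bool:
    p = metropolis_probability(delta, mu)
    return p >= 1.0 or rng.random() < p
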