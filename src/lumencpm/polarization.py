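"""Apical/basolateral cell-surface (re)polarization.

Every other MCS each cell's surface is re-derived from its position
relative to the ECM: a membrane site (a cell site with at least one Moore
neighbour outside the cell) becomes basolateral when it touches the ECM
directly, or when at least two of its same-cell membrane neighbours touch
the ECM (the lateral-junction rule); the remaining membrane sites become
apical, and interior sites fall back to cytoplasm.  Only ECM counts as
polarizing contact — fluids do not.  The pass is deterministic given the
lattice and idempotent.

The same pass detects pinocytosis candidates: sites still typed
apical/basolateral that have become internal (no outside neighbour) since
the previous pass.  They are retyped to cytoplasm here and reported to the
vacuolation module, which may convert them to vesicles.
"""

from __future__ import annotations

import numpy as np

from . import params as P
from ._grid import MOORE_OFFSETS, VN_OFFSETS, shifted
from .state import SimState

_SURFACE_TYPES = (P.CYTOPLASM, P.BASOLATERAL, P.APICAL)

#: neighbourhood used for "in direct contact with the ECM" and for the
#: lateral-junction neighbour count ("moore" or "von_neumann")
ECM_CONTACT_NEIGHBORHOOD = "moore"


def _contact_offsets():
    return (MOORE_OFFSETS if ECM_CONTACT_NEIGHBORHOOD == "moore"
            else VN_OFFSETS)


def identify_membrane(state: SimState, xi: int):
    """Sites of cell ``xi`` with >=1 Moore neighbour outside the cell.

    Returns (rows, cols) index arrays in raster order.  All other cell
    sites belong to the cytoplasm after a repolarization pass.
    """
    cl = state.cell_lattice()
    inside = cl == xi
    if not inside.any():
        raise ValueError(f"cell {xi} has no sites")
    outside_nb = np.zeros_like(inside)
    for dr, dc in MOORE_OFFSETS:
        outside_nb |= shifted(cl, dr, dc, -1) != cl
    return np.nonzero(inside & outside_nb)


def repolarize(state: SimState):
    """One repolarization pass over every polarizable cell.

    Returns the pinocytosis candidates: (rows, cols) of membrane-typed
    sites that were found internal (and retyped to cytoplasm) in this pass.
    """
    state.ensure_membrane_compartments()
    lat = state.lattice
    cl = state.cell_lattice()
    tl = state.type_lattice()
    polar = state.cell_polarizable[cl]
    body = polar & np.isin(tl, _SURFACE_TYPES)

    outside_nb = np.zeros(lat.shape, dtype=bool)
    for dr, dc in MOORE_OFFSETS:
        outside_nb |= shifted(cl, dr, dc, -1) != cl
    membrane = body & outside_nb

    ecm_nb = np.zeros(lat.shape, dtype=bool)
    for dr, dc in _contact_offsets():
        ecm_nb |= shifted(tl, dr, dc, P.ECM) == P.ECM
    # direct ECM contact
    baso = membrane & ecm_nb
    # lateral-junction rule: >=2 same-cell membrane neighbours touching ECM
    qual = baso
    count = np.zeros(lat.shape, dtype=np.int8)
    for dr, dc in _contact_offsets():
        count += (shifted(qual, dr, dc, False)
                  & (shifted(cl, dr, dc, -1) == cl)).astype(np.int8)
    baso = baso | (membrane & (count >= 2))
    apical = membrane & ~baso
    interior = body & ~membrane

    # internalized membrane pixels are pinocytosis candidates
    cand = polar & np.isin(tl, (P.APICAL, P.BASOLATERAL)) & ~outside_nb
    cand_sites = np.nonzero(cand)

    for mask, table in ((baso, state.cell_bas),
                        (apical, state.cell_api),
                        (interior, state.cell_cyt)):
        if mask.any():
            lat[mask] = table[cl[mask]]

    # re-count areas of the surface compartments we may have touched
    affected = []
    for xi in state.cell_ids():
        if state.cell_polarizable[xi]:
            affected.extend(s for s in (state.cell_cyt[xi], state.cell_bas[xi],
                                        state.cell_api[xi]) if s >= 0)
    if affected:
        counts = np.bincount(lat.ravel(), minlength=state.n_comps)
        idx = np.asarray(affected)
        state.comp_area[idx] = counts[idx]
    return cand_sites
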