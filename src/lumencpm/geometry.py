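"""Initial lattice geometries.

``build_branched_sprout`` lays out the reference vessel: a Y-shaped cord of
12 cells embedded in immobile ECM, with single-cell-wide regions at the two
branch tips, a two-cell-wide trunk, and an ECM-fluid cap at each of the
three ends of the branch.  The cap regions double as the continuity probes:
a lumen is continuous when the fluid at all of them belongs to one
connected component.  ``build_layered_vessel`` lays out straight vessels of
one, two or three cell layers with caps (and probes) at both ends.  Tiny
hand-built fixtures for unit and oracle tests live in ``build_fixture``.

Cells start as a single (unpolarized) cytoplasm compartment whose target
area equals its initial area; the first repolarization pass happens at
MCS 2.  The lattice always keeps at least a one-site immobile ECM frame,
so every non-ECM site has a full Moore neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import params as P
from .state import ECM_COMP, ECM_FLUID_CELL, ECM_FLUID_COMP, SimState


@dataclass
class GeometrySpec:
    kind: str = "branched_sprout"   # branched_sprout | layered_vessel | fixture
    width: int = 550
    height: int = 550
    cell_size: int = 25
    #: cap region (width across the vessel axis, depth along it), sites
    cap_size: tuple[int, int] = (25, 10)
    n_layers: int = 1               # layered_vessel only
    cells_per_row: int = 6          # layered_vessel only
    fixture: str = ""               # fixture only

    def __post_init__(self) -> None:
        if self.kind not in ("branched_sprout", "layered_vessel", "fixture"):
            raise ValueError(f"unknown geometry kind {self.kind!r}")
        if self.kind == "layered_vessel" and self.n_layers not in (1, 2, 3):
            raise ValueError("n_layers must be 1, 2 or 3")


def build(spec: GeometrySpec) -> SimState:
    if spec.kind == "branched_sprout":
        return build_branched_sprout(spec)
    if spec.kind == "layered_vessel":
        return build_layered_vessel(spec.n_layers, spec)
    return build_fixture(spec.fixture)


# --------------------------------------------------------------- helpers --
def _blank(width: int, height: int) -> SimState:
    state = SimState(width=width, height=height)
    # everything starts as ECM (compartment 0)
    state.comp_area[ECM_COMP] = width * height
    state.cell_area[0] = width * height
    return state


def _add_cell(state: SimState, r0: int, r1: int, c0: int, c1: int) -> int:
    if not (0 < r0 < r1 < state.height and 0 < c0 < c1 < state.width):
        raise ValueError("cell rectangle leaves no ECM frame; enlarge dims")
    area = (r1 - r0) * (c1 - c0)
    xi = state.new_cell(P.KIND_CELL, target=area, polarizable=True)
    sigma = state.new_compartment(P.CYTOPLASM, xi)
    state.cell_cyt[xi] = sigma
    state.fill_rect(r0, r1, c0, c1, sigma)
    return xi


def _add_cap(state: SimState, r0: int, r1: int, c0: int, c1: int,
             probe_extra=None) -> None:
    """Fill a rectangle with ECM fluid and record it as a continuity probe.

    ``probe_extra`` optionally widens the probe region beyond the fluid cap
    (the adjacent tip-cell footprint): during a run the vessel stretches
    into the cap while the fluid pools just inside the vessel end, so the
    probe must cover the branch-tip region, not only the initial fluid.
    """
    if not (0 < r0 < r1 < state.height and 0 < c0 < c1 < state.width):
        raise ValueError("cap rectangle leaves no ECM frame; enlarge dims")
    state.fill_rect(r0, r1, c0, c1, ECM_FLUID_COMP)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    rows, cols = rr.ravel(), cc.ravel()
    if probe_extra is not None:
        er0, er1, ec0, ec1 = probe_extra
        err, ecc = np.mgrid[er0:er1, ec0:ec1]
        rows = np.concatenate([rows, err.ravel()])
        cols = np.concatenate([cols, ecc.ravel()])
    state.probes.append((rows, cols))


def _finish(state: SimState) -> SimState:
    # fluid target = initial fluid area (near-incompressible from the start)
    state.cell_target[ECM_FLUID_CELL] = state.cell_area[ECM_FLUID_CELL]
    state.check_areas()
    return state


# ------------------------------------------------------------ the sprout --
def build_branched_sprout(spec: GeometrySpec) -> SimState:
    """Y-shaped cord of 12 cells: a 2x3-cell trunk and two 3-cell arms that
    step diagonally outward, one cell wide, plus three ECM-fluid caps."""
    c = spec.cell_size
    s = c // 2  # lateral step of the arm cells
    capw, caph = spec.cap_size
    state = _blank(spec.width, spec.height)
    cx = spec.width // 2
    arm_h = 3 * c
    trunk_h = 3 * c
    top = (spec.height - (arm_h + trunk_h)) // 2
    t0 = top + arm_h            # first trunk row
    # trunk: 2 columns x 3 rows
    for i in range(3):
        _add_cell(state, t0 + i * c, t0 + (i + 1) * c, cx - c, cx)
        _add_cell(state, t0 + i * c, t0 + (i + 1) * c, cx, cx + c)
    # arms: 3 cells each, stepping half a cell outward per cell
    for i in range(1, 4):
        r0 = t0 - i * c
        _add_cell(state, r0, r0 + c, cx - c - i * s, cx - i * s)      # left
        _add_cell(state, r0, r0 + c, cx + i * s, cx + c + i * s)      # right
    # caps: one beyond each arm tip, one below the trunk; probes span the
    # cap plus the tip-cell footprint
    tip_r0 = t0 - 3 * c
    lc0 = cx - c - 3 * s + (c - capw) // 2
    rc0 = cx + 3 * s + (c - capw) // 2
    _add_cap(state, tip_r0 - caph, tip_r0, lc0, lc0 + capw,
             probe_extra=(tip_r0, tip_r0 + c, cx - c - 3 * s, cx - 3 * s))
    _add_cap(state, tip_r0 - caph, tip_r0, rc0, rc0 + capw,
             probe_extra=(tip_r0, tip_r0 + c, cx + 3 * s, cx + c + 3 * s))
    _add_cap(state, t0 + trunk_h, t0 + trunk_h + caph,
             cx - capw // 2, cx - capw // 2 + capw,
             probe_extra=(t0 + 2 * c, t0 + trunk_h, cx - c, cx + c))
    return _finish(state)


# ---------------------------------------------------------------- vessels --
def build_layered_vessel(n_layers: int, spec: GeometrySpec) -> SimState:
    """Straight horizontal vessel, ``n_layers`` cells thick, with aligned
    cells and an ECM-fluid cap at each end."""
    if n_layers not in (1, 2, 3):
        raise ValueError("n_layers must be 1, 2 or 3")
    c = spec.cell_size
    m = spec.cells_per_row
    capw, caph = spec.cap_size
    state = _blank(spec.width, spec.height)
    r0 = (spec.height - n_layers * c) // 2
    c0 = (spec.width - m * c) // 2
    for layer in range(n_layers):
        for j in range(m):
            _add_cell(state, r0 + layer * c, r0 + (layer + 1) * c,
                      c0 + j * c, c0 + (j + 1) * c)
    thick = n_layers * c
    capw = min(capw, thick)
    rr = r0 + (thick - capw) // 2
    _add_cap(state, rr, rr + capw, c0 - caph, c0,
             probe_extra=(r0, r0 + thick, c0, c0 + c))
    _add_cap(state, rr, rr + capw, c0 + m * c, c0 + m * c + caph,
             probe_extra=(r0, r0 + thick, c0 + (m - 1) * c, c0 + m * c))
    return _finish(state)


# --------------------------------------------------------------- fixtures --
def build_fixture(name: str) -> SimState:
    """Tiny deterministic lattices for unit and oracle tests."""
    if name == "two_cell_contact":
        state = _blank(20, 20)
        _add_cell(state, 8, 13, 4, 9)
        _add_cell(state, 8, 13, 9, 14)
        return _finish(state)

    if name == "vesicle_in_cell":
        state = _blank(20, 20)
        xi = _add_cell(state, 6, 13, 6, 13)
        v = state.new_compartment(P.VESICLE, xi, target=1)
        state.paint(np.array([9]), np.array([9]), v)
        _add_cap(state, 2, 4, 2, 6)   # some ECM fluid to trade targets with
        return _finish(state)

    if name == "two_apical_membranes":
        # two cells stacked vertically, facing rows typed apical,
        # outer rows basolateral; ECM fluid column on the left
        state = _blank(13, 13)
        for (r0, r1) in ((3, 6), (6, 9)):
            xi = _add_cell(state, r0, r1, 4, 9)
            state.ensure_membrane_compartments()
            facing = r1 - 1 if r0 == 3 else r0
            outer = r0 if r0 == 3 else r1 - 1
            cols = np.arange(4, 9)
            state.paint(np.full(5, facing), cols, state.cell_api[xi])
            state.paint(np.full(5, outer), cols, state.cell_bas[xi])
        _add_cap(state, 3, 9, 1, 3)
        return _finish(state)

    if name == "three_cap_channel":
        # three probe regions joined by an ECM-fluid channel: continuity
        # holds by construction
        state = _blank(30, 30)
        _add_cap(state, 3, 6, 3, 8)
        _add_cap(state, 3, 6, 22, 27)
        _add_cap(state, 24, 27, 12, 17)
        state.fill_rect(6, 14, 5, 7, ECM_FLUID_COMP)      # from cap 1 down
        state.fill_rect(6, 14, 24, 26, ECM_FLUID_COMP)    # from cap 2 down
        state.fill_rect(12, 14, 5, 26, ECM_FLUID_COMP)    # crossbar
        state.fill_rect(14, 24, 14, 16, ECM_FLUID_COMP)   # stem to cap 3
        return _finish(state)

    if name == "oracle_mixed":
        # every site type present: two polarized cells (one holding a
        # vesicle, one a two-site vacuole), a luminal-fluid pocket between
        # them, an ECM-fluid region, all in ECM
        state = _blank(20, 20)
        for (r0, c0) in ((3, 3), (11, 9)):
            xi = _add_cell(state, r0, r0 + 6, c0, c0 + 6)
            state.ensure_membrane_compartments()
            rr, cc = np.mgrid[r0:r0 + 6, c0:c0 + 6]
            border = ((rr == r0) | (rr == r0 + 5)
                      | (cc == c0) | (cc == c0 + 5))
            half = cc < c0 + 3
            state.paint(rr[border & half], cc[border & half],
                        state.cell_bas[xi])
            state.paint(rr[border & ~half], cc[border & ~half],
                        state.cell_api[xi])
        v = state.new_compartment(P.VESICLE, 2, target=1)
        state.paint(np.array([5]), np.array([5]), v)
        vac = state.new_compartment(P.VACUOLE, 3, target=3)
        state.paint(np.array([13, 13]), np.array([11, 12]), vac)
        lum_xi = state.new_cell(P.KIND_FLUID, target=6)
        lum = state.new_compartment(P.LUMINAL_FLUID, lum_xi)
        state.fill_rect(9, 11, 6, 9, lum)
        _add_cap(state, 2, 5, 12, 17)
        return _finish(state)

    raise ValueError(f"unknown fixture {name!r}")
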