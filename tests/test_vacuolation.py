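"""Vacuolation rules: pinocytosis bookkeeping, vesicle motion, fusion,
demotion, secretion and fluid fusion, each with its target-area transfers."""

import numpy as np
import pytest

from lumencpm import geometry, polarization, vacuolation
from lumencpm import params as P
from lumencpm.core import Simulation
from lumencpm.params import EnergyParams, MechanismConfig
from lumencpm.state import ECM_FLUID_CELL


def _sim_with_cell(size=9, pad=5, **mech_kw):
    state = geometry._blank(size + 2 * pad, size + 2 * pad)
    geometry._add_cell(state, pad, pad + size, pad, pad + size)
    geometry._add_cap(state, 1, 3, 1, 8)
    geometry._finish(state)
    mech = MechanismConfig(mcs=0, seed=1, **mech_kw)
    return Simulation(state, mech=mech)


def _mark_membrane_site_internal(sim, r, c):
    """Type one interior cytoplasm site as apical so the next
    repolarization reports it as a pinocytosis candidate."""
    state = sim.state
    state.ensure_membrane_compartments()
    xi = int(state.comp_cell[state.lattice[r, c]])
    state.paint_site(r, c, int(state.cell_api[xi]))


# ------------------------------------------------------------ pinocytosis --
def test_pinocytosis_bookkeeping_single_pixel():
    """One internalized membrane pixel at P_pin=1 becomes a one-site
    vesicle with target 1; cell target +1, ECM-fluid target -1."""
    sim = _sim_with_cell()
    state = sim.state
    xi = 2
    cell_t0 = int(state.cell_target[xi])
    fluid_t0 = int(state.cell_target[ECM_FLUID_CELL])
    _mark_membrane_site_internal(sim, 9, 9)
    cand = polarization.repolarize(state)
    assert cand[0].size == 1
    created = vacuolation.pinocytose(sim, cand)
    assert len(created) == 1
    v = created[0]
    assert state.comp_type[v] == P.VESICLE
    assert state.comp_area[v] == 1
    assert state.comp_target[v] == 1
    assert state.cell_target[xi] == cell_t0 + 1
    assert state.cell_target[ECM_FLUID_CELL] == fluid_t0 - 1
    state.check_areas()


def test_pinocytosis_zero_rate_leaves_cytoplasm():
    sim = _sim_with_cell(P_pin=0.0)
    _mark_membrane_site_internal(sim, 9, 9)
    cand = polarization.repolarize(sim.state)
    created = vacuolation.pinocytose(sim, cand)
    assert created == []
    assert sim.state.type_lattice()[9, 9] == P.CYTOPLASM


def test_pinocytosis_counts_are_binomial():
    """k candidates at P_pin = 0.5: created counts over repeated trials are
    consistent with Binomial(k, 0.5)."""
    k, trials = 9, 400
    total = 0
    for t in range(trials):
        sim = _sim_with_cell(P_pin=0.5)
        sim.np_rng = np.random.default_rng(t)
        for i in range(k):
            _mark_membrane_site_internal(sim, 8 + i % 3 * 2, 8 + i // 3 * 2)
        cand = polarization.repolarize(sim.state)
        assert cand[0].size == k
        total += len(vacuolation.pinocytose(sim, cand))
    mean = total / trials
    se = np.sqrt(k * 0.25 / trials)
    assert abs(mean - k * 0.5) < 4 * se


# --------------------------------------------------------- vesicle motion --
def test_vesicle_never_moves_at_zero_step_probability():
    state = geometry.build_fixture("vesicle_in_cell")
    sim = Simulation(state, mech=MechanismConfig(mcs=0, seed=2, P_A=0.0))
    before = state.lattice.copy()
    for _ in range(50):
        vacuolation.vesicle_steps(sim)
    assert np.array_equal(before, state.lattice)


def test_vesicle_random_walk_is_isotropic_with_uniform_energies():
    """With uniform internal contact energies the vesicle walk shows no
    directional drift and a linearly growing mean squared displacement."""
    params = EnergyParams()
    JI = params.JI.copy()
    JI[:] = 10.0
    params = EnergyParams(JE=params.JE, JI=JI)
    disp = []
    for seed in range(120):
        state = geometry.build_fixture("vesicle_in_cell")
        # enlarge: embed vesicle in a bigger cell so walls rarely matter
        sim = Simulation(state, params=params,
                         mech=MechanismConfig(mcs=0, seed=seed, P_A=1.0))
        r0 = np.array(np.nonzero(state.type_lattice() == P.VESICLE)).ravel()
        for _ in range(6):
            vacuolation.vesicle_steps(sim)
        r1 = np.array(np.nonzero(state.type_lattice() == P.VESICLE)).ravel()
        disp.append(r1 - r0)
    disp = np.array(disp, dtype=float)
    # no drift beyond ~4 standard errors of a Moore random walk
    assert np.all(np.abs(disp.mean(axis=0)) <
                  4 * disp.std(axis=0) / np.sqrt(len(disp)) + 1e-9)
    assert (disp ** 2).sum(axis=1).mean() > 0.5  # it does move


def test_vesicle_prefers_apical_contact():
    """Acceptance of steps toward the apical membrane (J_I=1) exceeds steps
    into plain cytoplasm (J_I=10): the biased walk of the transport rule."""
    state = geometry.build_fixture("oracle_mixed")
    sim = Simulation(state, mech=MechanismConfig(mcs=0, seed=3))
    # count over many seeded attempts from the fixed configuration
    toward_api = 0
    total = 0
    for seed in range(300):
        st = state.copy()
        s2 = Simulation(st, mech=MechanismConfig(mcs=0, seed=seed))
        vacuolation.vesicle_steps(s2)
        rows, cols = np.nonzero(st.type_lattice() == P.VESICLE)
        if not np.array_equal(st.lattice, state.lattice):
            total += 1
            # apical half of cell 2 is to the right (columns >= 6)
            if cols[0] > 5:
                toward_api += 1
    assert total > 50
    assert toward_api / total > 0.5


# ----------------------------------------------------------------- fusion --
def _cell_with(sim_or_none=None):
    state = geometry._blank(20, 20)
    geometry._add_cell(state, 5, 14, 5, 14)
    geometry._finish(state)
    return state


def test_adjacent_vesicles_fuse_into_vacuole():
    state = _cell_with()
    xi = 2
    v1 = state.new_compartment(P.VESICLE, xi, target=1)
    v2 = state.new_compartment(P.VESICLE, xi, target=1)
    state.paint_site(9, 9, v1)
    state.paint_site(9, 10, v2)
    sim = Simulation(state, mech=MechanismConfig(mcs=0, seed=1, P_fuse=1.0))
    events = vacuolation.fuse_vesicles_vacuoles(sim)
    assert len(events) == 1
    root = events[0][0]
    assert state.comp_type[root] == P.VACUOLE
    assert state.comp_target[root] == 2
    assert state.comp_area[root] == 2
    state.check_areas()


def test_vesicle_fuses_into_vacuole_sums_targets():
    state = _cell_with()
    xi = 2
    vac = state.new_compartment(P.VACUOLE, xi, target=5)
    state.paint(np.array([9, 9, 10]), np.array([9, 10, 9]), vac)
    v = state.new_compartment(P.VESICLE, xi, target=1)
    state.paint_site(10, 10, v)
    sim = Simulation(state, mech=MechanismConfig(mcs=0, seed=1, P_fuse=1.0))
    events = vacuolation.fuse_vesicles_vacuoles(sim)
    assert len(events) == 1
    root = events[0][0]
    assert state.comp_target[root] == 6
    assert state.comp_type[root] == P.VACUOLE


def test_no_fusion_at_zero_probability():
    state = _cell_with()
    xi = 2
    for (r, c) in ((9, 9), (9, 10)):
        state.paint_site(r, c, state.new_compartment(P.VESICLE, xi, target=1))
    sim = Simulation(state, mech=MechanismConfig(mcs=0, seed=1, P_fuse=0.0))
    assert vacuolation.fuse_vesicles_vacuoles(sim) == []
    assert not (state.comp_type[:state.n_comps] == P.VACUOLE).any()


def test_different_cells_never_fuse():
    state = geometry.build_fixture("two_cell_contact")
    v1 = state.new_compartment(P.VESICLE, 2, target=1)
    v2 = state.new_compartment(P.VESICLE, 3, target=1)
    state.paint_site(10, 8, v1)   # last column of left cell
    state.paint_site(10, 9, v2)   # first column of right cell
    sim = Simulation(state, mech=MechanismConfig(mcs=0, seed=1, P_fuse=1.0))
    assert vacuolation.fuse_vesicles_vacuoles(sim) == []


# --------------------------------------------------------------- demotion --
def test_detached_vacuole_pixel_demotes_to_vesicle():
    state = _cell_with()
    xi = 2
    vac = state.new_compartment(P.VACUOLE, xi, target=4)
    # main body plus one split-off pixel surrounded by cytoplasm
    state.paint(np.array([7, 7, 8]), np.array([7, 8, 7]), vac)
    state.paint_site(11, 11, vac)
    sim = Simulation(state, mech=MechanismConfig(mcs=0, seed=1))
    created = vacuolation.demote_vacuole_fragments(sim)
    assert len(created) == 1
    v = created[0]
    assert state.comp_type[v] == P.VESICLE
    assert state.comp_target[v] == 1
    assert state.comp_target[vac] == 3
    state.check_areas()


def test_zero_target_donor_makes_zero_target_vesicle():
    state = _cell_with()
    xi = 2
    vac = state.new_compartment(P.VACUOLE, xi, target=0)
    state.paint(np.array([7, 7]), np.array([7, 8]), vac)
    state.paint_site(11, 11, vac)
    sim = Simulation(state, mech=MechanismConfig(mcs=0, seed=1))
    created = vacuolation.demote_vacuole_fragments(sim)
    assert state.comp_target[created[0]] == 0
    assert state.comp_target[vac] == 0


def test_connected_vacuole_is_not_demoted():
    state = _cell_with()
    xi = 2
    vac = state.new_compartment(P.VACUOLE, xi, target=3)
    state.paint(np.array([9, 9, 10]), np.array([9, 10, 9]), vac)
    sim = Simulation(state, mech=MechanismConfig(mcs=0, seed=1))
    assert vacuolation.demote_vacuole_fragments(sim) == []
    assert state.comp_type[vac] == P.VACUOLE


# -------------------------------------------------------------- secretion --
def _polarized_cell_with_vacuole(target=8, shape="blob"):
    state = geometry.build_fixture("two_cell_contact")
    polarization.repolarize(state)
    # apical interface is at columns 8/9; place the vacuole against it
    xi = 2
    vac = state.new_compartment(P.VACUOLE, xi, target=target)
    if shape == "blob":
        rows = np.array([9, 10, 11, 9, 10, 11, 10, 9])
        cols = np.array([7, 7, 7, 6, 6, 6, 5, 5])
    else:
        rows = np.array([10])
        cols = np.array([7])
    state.paint(rows, cols, vac)
    return state, xi, vac


def test_full_vacuole_secretion_transfers_combined_target():
    state, xi, vac = _polarized_cell_with_vacuole(target=8)
    cell_t0 = int(state.cell_target[xi])
    total0 = state.total_target()
    sim = Simulation(state, mech=MechanismConfig(mcs=0, seed=1))
    events = vacuolation.secrete(sim)
    assert len(events) == 1
    ev = events[0]
    assert ev["target"] == 8
    assert ev["sites"] == 8
    lum = ev["luminal"]
    assert state.comp_type[lum] == P.LUMINAL_FLUID
    assert state.cell_target[state.comp_cell[lum]] == 8
    assert state.cell_target[xi] == cell_t0 - 8
    assert state.comp_area[vac] == 0
    assert state.total_target() == total0
    state.check_areas()


def test_partial_vacuole_secretion_subtracts_secreted_part():
    """Only the 4-connected part of the vacuole at the apical membrane is
    secreted; its size comes off the vacuole's target."""
    state, xi, vac = _polarized_cell_with_vacuole(target=8)
    # split the vacuole: keep its 4-connected component of 7 sites at the
    # membrane, detach one pixel diagonally (8-adjacent, 4-disconnected)
    state.paint_site(10, 5, state.cell_cyt[xi])   # remove bridging pixel
    state.paint_site(9, 5, state.cell_cyt[xi])
    state.paint_site(8, 4, vac)                   # diagonal outlier
    sim = Simulation(state, mech=MechanismConfig(mcs=0, seed=1))
    total0 = state.total_target()
    events = vacuolation.secrete(sim)
    assert len(events) == 1
    secreted_sites = events[0]["sites"]
    assert secreted_sites == 6
    assert events[0]["target"] == 6
    assert state.comp_target[vac] == 2            # 8 - secreted part
    assert state.comp_area[vac] == 1
    assert state.total_target() == total0


def test_secretion_requires_apical_contact():
    state = _cell_with()
    xi = 2
    vac = state.new_compartment(P.VACUOLE, xi, target=3)
    state.paint(np.array([9, 9, 10]), np.array([9, 10, 9]), vac)
    sim = Simulation(state, mech=MechanismConfig(mcs=0, seed=1))
    assert vacuolation.secrete(sim) == []   # unpolarized cell: no apical


# ----------------------------------------------------------- fluid fusion --
def test_adjacent_luminal_bodies_merge_with_target_sum():
    state = _cell_with()
    a_xi = state.new_cell(P.KIND_FLUID, target=3)
    a = state.new_compartment(P.LUMINAL_FLUID, a_xi)
    b_xi = state.new_cell(P.KIND_FLUID, target=4)
    b = state.new_compartment(P.LUMINAL_FLUID, b_xi)
    state.paint(np.array([8, 8]), np.array([8, 9]), a)
    state.paint(np.array([9, 9]), np.array([8, 9]), b)
    sim = Simulation(state, mech=MechanismConfig(mcs=0, seed=1))
    total0 = state.total_target()
    vacuolation.fuse_fluids(sim)
    keep = a if state.comp_area[a] > 0 else b
    assert state.comp_area[keep] == 4
    assert state.cell_target[state.comp_cell[keep]] == 7
    assert state.total_target() == total0


def test_luminal_touching_ecm_is_absorbed_into_ecm_fluid():
    state = _cell_with()
    xi = state.new_cell(P.KIND_FLUID, target=2)
    lum = state.new_compartment(P.LUMINAL_FLUID, xi)
    state.paint(np.array([4, 4]), np.array([8, 9]), lum)  # row 4: beside ECM
    fluid_t0 = int(state.cell_target[ECM_FLUID_CELL])
    sim = Simulation(state, mech=MechanismConfig(mcs=0, seed=1))
    vacuolation.fuse_fluids(sim)
    assert state.comp_area[lum] == 0
    assert state.cell_target[ECM_FLUID_CELL] == fluid_t0 + 2
    assert (state.type_lattice()[4, 8:10] == P.ECM_FLUID).all()


def test_luminal_surrounded_by_ecm_fluid_is_absorbed():
    state = geometry._blank(20, 20)
    geometry._add_cap(state, 5, 12, 5, 12)
    geometry._finish(state)
    xi = state.new_cell(P.KIND_FLUID, target=4)
    lum = state.new_compartment(P.LUMINAL_FLUID, xi)
    state.paint(np.array([8, 8]), np.array([8, 9]), lum)
    sim = Simulation(state, mech=MechanismConfig(mcs=0, seed=1))
    vacuolation.fuse_fluids(sim)
    assert state.comp_area[lum] == 0
    assert not (state.type_lattice() == P.LUMINAL_FLUID).any()


def test_enclosed_luminal_in_cell_is_not_absorbed():
    state = _cell_with()
    xi = state.new_cell(P.KIND_FLUID, target=2)
    lum = state.new_compartment(P.LUMINAL_FLUID, xi)
    state.paint(np.array([9, 9]), np.array([8, 9]), lum)  # inside the cell
    sim = Simulation(state, mech=MechanismConfig(mcs=0, seed=1))
    vacuolation.fuse_fluids(sim)
    assert state.comp_area[lum] == 2


# ---------------------------------------------------- disabled mechanism --
def test_no_vacuolation_types_when_disabled(tiny_spec):
    state = geometry.build(tiny_spec)
    mech = MechanismConfig(mcs=0, seed=6, enable_vacuolation=False)
    sim = Simulation(state, mech=mech)
    sim.run(40)
    tl = state.type_lattice()
    for t in (P.VESICLE, P.VACUOLE, P.LUMINAL_FLUID):
        assert not (tl == t).any()
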