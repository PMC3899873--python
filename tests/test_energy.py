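"""Energy terms: area penalty, contact pairs, and the incremental delta
against a from-scratch recomputation oracle."""

import numpy as np
import pytest

from conftest import random_valid_proposal
from lumencpm import _kernel, energy, geometry
from lumencpm import params as P
from lumencpm.params import EnergyParams


@pytest.mark.parametrize("actual,target,lam,expected", [
    (26, 25, 7, 7),        # one site over target at the cell elasticity
    (25, 25, 25, 0),       # at target: no cost
    (2, 1, 1000, 1000),    # stiff vesicle one site too large
    (0, 3, 6, 54),         # collapsed fluid body
])
def test_area_energy_quadratic(actual, target, lam, expected):
    assert energy.area_energy(actual, target, lam) == expected


def test_area_energy_rejects_negative_input():
    with pytest.raises(ValueError):
        energy.area_energy(-1, 5, 7)
    with pytest.raises(ValueError):
        energy.area_energy(5, 5, -2)


def test_energy_params_validation():
    with pytest.raises(ValueError):
        EnergyParams(mu=0)
    bad = EnergyParams().JE.copy()
    bad[0, 1] += 5  # break symmetry
    with pytest.raises(ValueError):
        EnergyParams(JE=bad)


def test_contact_energy_pair_reference_values(mixed_state):
    """Apical-apical across cells is the repulsive reference (200); the
    apical-basolateral adherens-junction term within a cell is 70; there is
    no interface energy within a single compartment."""
    st = mixed_state
    params = EnergyParams()
    api1, api2 = st.cell_api[2], st.cell_api[3]
    bas1 = st.cell_bas[2]
    assert energy.contact_energy_pair(st, api1, api2, params) == 200
    assert energy.contact_energy_pair(st, api1, bas1, params) == 70
    assert energy.contact_energy_pair(st, api1, api1, params) == 0


def test_repulsion_scalar_overwrites_both_entries():
    params = EnergyParams().with_repulsion(60)
    assert params.JE[P.APICAL, P.APICAL] == 60
    assert params.JE[P.CYTOPLASM, P.APICAL] == 60
    assert params.JE[P.APICAL, P.CYTOPLASM] == 60
    # everything else untouched
    assert params.JE[P.APICAL, P.BASOLATERAL] == 50


def _pure_relabel(state, tr, tc, w):
    """Apply a relabel with area bookkeeping only (the oracle's move)."""
    d = int(state.lattice[tr, tc])
    state.lattice[tr, tc] = w
    state.comp_area[d] -= 1
    state.comp_area[w] += 1
    cd, cw = state.comp_cell[d], state.comp_cell[w]
    if cd != cw:
        state.cell_area[cd] -= 1
        state.cell_area[cw] += 1


def test_shrinking_singleton_vesicle_delta(mixed_state):
    """Copying cytoplasm over an isolated one-site vesicle: the compartment
    is deleted, so its stiff area term (lambda 1000) vanishes rather than
    being charged at (0 - target)^2 — otherwise the documented deletions of
    vesicles by copies could essentially never be accepted.  Verified
    against full recomputation."""
    st = mixed_state
    params = EnergyParams()
    vr, vc = 5, 5  # the vesicle site; its left neighbour is cytoplasm
    sigma = int(st.lattice[vr, vc])
    assert st.comp_type[sigma] == P.VESICLE
    delta = energy.delta_energy_copy(st, (vr, vc - 1), (vr, vc), params)
    e0 = energy.total_energy(st, params)
    after = st.copy()
    _pure_relabel(after, vr, vc, int(st.lattice[vr, vc - 1]))
    e1 = energy.total_energy(after, params)
    assert delta.total == pytest.approx(e1 - e0, abs=1e-9)
    # the vesicle was exactly at target (area 1, target 1): deleting it
    # removes a zero-valued term, so the area part has no vesicle penalty
    assert abs(delta.delta_area) < 1000


def test_delta_matches_full_recomputation_on_random_proposals(mixed_state):
    """>=10^3 random proposals on the mixed 20x20 fixture: the incremental
    delta (python and compiled paths) equals E_after - E_before exactly."""
    params = EnergyParams()
    rng = np.random.default_rng(42)
    st = mixed_state
    lam_t = params.lambda_by_type()
    lam_k = params.lambda_by_kind()
    for trial in range(1000):
        (sr, sc), (tr, tc) = random_valid_proposal(st, rng)
        w = int(st.lattice[sr, sc])
        delta = energy.delta_energy_copy(st, (sr, sc), (tr, tc), params)
        de_kernel = _kernel.delta_copy(
            st.lattice, tr, tc, w,
            st.comp_type, st.comp_cell, st.comp_area, st.comp_target,
            st.cell_kind, st.cell_area, st.cell_target,
            params.JE, params.JI, lam_t, lam_k, params.n_contact)
        e0 = energy.total_energy(st, params)
        after = st.copy()
        _pure_relabel(after, tr, tc, w)
        e1 = energy.total_energy(after, params)
        assert delta.total == pytest.approx(e1 - e0, abs=1e-9)
        assert de_kernel == pytest.approx(e1 - e0, abs=1e-9)
        # evolve the fixture every few proposals so configurations vary
        if trial % 4 == 0:
            st = after


def test_delta_total_is_sum_of_parts(mixed_state):
    rng = np.random.default_rng(1)
    params = EnergyParams()
    src, tgt = random_valid_proposal(mixed_state, rng)
    d = energy.delta_energy_copy(mixed_state, src, tgt, params)
    assert d.total == d.delta_area + d.delta_contact


def test_fluid_insertion_delta_between_apposed_apical_membranes():
    """De-novo ECM-fluid insertion at a touching apical-apical interface:
    the incremental delta equals full-energy recomputation on the
    hand-built two-membrane fixture."""
    st = geometry.build_fixture("two_apical_membranes")
    params = EnergyParams()  # J_rep = 200 reference
    tl = st.type_lattice()
    # find an apical site whose vertical neighbour is the other cell's apical
    rows, cols = np.nonzero(tl == P.APICAL)
    cl = st.cell_lattice()
    pick = None
    for r, c in zip(rows, cols):
        if tl[r + 1, c] == P.APICAL and cl[r + 1, c] != cl[r, c]:
            pick = (r, c)
            break
    assert pick is not None
    delta = energy.delta_energy_copy(st, pick, pick, params, winner=1)
    e0 = energy.total_energy(st, params)
    after = st.copy()
    _pure_relabel(after, pick[0], pick[1], 1)
    e1 = energy.total_energy(after, params)
    assert delta.total == pytest.approx(e1 - e0, abs=1e-9)
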