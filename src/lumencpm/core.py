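"""Simulation driver: the Monte Carlo step and the mechanism scheduler.

One Monte Carlo step (MCS) performs as many copy attempts as there are
lattice sites, then runs the extra lumen-formation mechanisms whose period
divides the MCS index, in fixed order: vesicle movement, vesicle/vacuole
fusion, vacuole demotion, fluid fusion (every MCS); cell-surface
polarization, pinocytosis, secretion (every other MCS).  Pinocytosis
candidates — membrane-typed pixels that became internal — are detected by
the polarization pass of the same MCS, before retyping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel, energy
from . import params as P
from . import polarization, vacuolation
from .state import SimState

_EVENT_NAMES = ("attempts", "accepted", "noop", "insertion_evals",
                "insertions")


@dataclass
class StepStats:
    mcs: int
    counters: np.ndarray

    def as_dict(self) -> dict:
        return {k: int(v) for k, v in zip(_EVENT_NAMES, self.counters)}


class Simulation:
    """A single stochastic simulation run.

    Parameters
    ----------
    state : SimState
        Initial lattice (from the geometry builders).
    params : EnergyParams, optional
        Contact energies and elasticities.  The two J_rep entries are reset
        to the neutral contact energy when ``mech.enable_repulsion`` is
        false, and to ``j_rep`` when given.
    mech : MechanismConfig, optional
        Mechanism flags, rates and schedule.
    seed : int, optional
        Overrides ``mech.seed``.  One seed drives both the compiled kernel
        stream and the mechanism-level generator.
    """

    def __init__(self, state: SimState,
                 params: P.EnergyParams | None = None,
                 mech: P.MechanismConfig | None = None,
                 seed: int | None = None,
                 j_rep: float | None = None):
        self.state = state
        self.mech = mech if mech is not None else P.MechanismConfig()
        self.params = P.mechanism_params(self.mech, params, j_rep)
        self.seed = int(self.mech.seed if seed is None else seed)
        self.kernel_rng = _kernel.seed_rng(self.seed)
        self.np_rng = np.random.default_rng((self.seed, 0x5EED))
        self._lam_t = self.params.lambda_by_type()
        self._lam_k = self.params.lambda_by_kind()
        self.src_r, self.src_c = state.non_ecm_sites()
        self.counters = np.zeros(5, dtype=np.int64)
        #: test hook: physically remove the fluid-insertion branch
        self.insertion_enabled = True

    # ------------------------------------------------------------------
    def step(self) -> StepStats:
        """Advance one MCS (copy attempts + scheduled mechanisms)."""
        s = self.state
        s.mcs += 1
        self.counters[:] = 0
        _kernel.run_copy_attempts(
            s.lattice,
            s.comp_type, s.comp_cell, s.comp_area, s.comp_target,
            s.cell_kind, s.cell_area, s.cell_target,
            self.params.JE, self.params.JI, self._lam_t, self._lam_k,
            self.params.n_contact,
            self.params.mu, self.mech.P_I, self.insertion_enabled,
            self.src_r, self.src_c, s.width * s.height,
            self.kernel_rng, self.counters)
        m = self.mech
        mcs = s.mcs
        if m.enable_vacuolation:
            if mcs % m.n_vesicle_move == 0:
                vacuolation.vesicle_steps(self)
            if mcs % m.n_fusion == 0:
                vacuolation.fuse_vesicles_vacuoles(self)
            if mcs % m.n_demotion == 0:
                vacuolation.demote_vacuole_fragments(self)
        if mcs % m.n_fluid_fusion == 0:
            vacuolation.fuse_fluids(self)
        candidates = None
        if m.enable_polarization and mcs % m.n_polarization == 0:
            candidates = polarization.repolarize(s)
        if m.enable_vacuolation:
            if (m.enable_polarization and candidates is not None
                    and mcs % m.n_pinocytosis == 0):
                vacuolation.pinocytose(self, candidates)
            if mcs % m.n_secretion == 0:
                vacuolation.secrete(self)
        return StepStats(mcs, self.counters.copy())

    def run(self, n_mcs: int | None = None, callback=None) -> SimState:
        """Run ``n_mcs`` steps (default: the configured total)."""
        n = self.mech.mcs if n_mcs is None else n_mcs
        for _ in range(n):
            stats = self.step()
            if callback is not None:
                callback(self, stats)
        return self.state

    # ------------------------------------------------------------------
    def total_energy(self) -> float:
        return energy.total_energy(self.state, self.params)

    def delta_energy_copy(self, source_site, target_site) -> energy.EnergyDelta:
        """Exact energy change of the proposed copy (pure, no side effects)."""
        return energy.delta_energy_copy(self.state, source_site, target_site,
                                        self.params)
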