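"""Model parameters: contact-energy tables, elasticities, mechanism settings.

The model distinguishes eight site types.  Contact energies come in two
symmetric type-by-type tables: ``J_E`` (external; interfaces between
compartments of *different* cells) and ``J_I`` (internal; interfaces between
compartments of the *same* cell, defined for intracellular types only).
A contact energy of 10 is neutral; lower values are adhesive, higher values
repulsive.  Cell--cell repulsion is controlled by a single scalar ``J_rep``
that overwrites both J_E(apical, apical) and J_E(cytoplasm, apical).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# ---------------------------------------------------------------------------
# Site / compartment type codes.  Order is load-bearing: it indexes the J
# tables and the per-type elasticity vector.
ECM = 0
ECM_FLUID = 1
LUMINAL_FLUID = 2
CYTOPLASM = 3
BASOLATERAL = 4
APICAL = 5
VESICLE = 6
VACUOLE = 7

N_TYPES = 8

TYPE_NAMES = {
    ECM: "ECM",
    ECM_FLUID: "ECM_fluid",
    LUMINAL_FLUID: "luminal_fluid",
    CYTOPLASM: "cytoplasm",
    BASOLATERAL: "basolateral",
    APICAL: "apical",
    VESICLE: "vesicle",
    VACUOLE: "vacuole",
}
TYPE_CODES = {name: code for code, name in TYPE_NAMES.items()}

#: Types that can occur inside a cell (J_I is defined for these only).
INTRACELLULAR_TYPES = (CYTOPLASM, BASOLATERAL, APICAL, VESICLE, VACUOLE)
#: Fluid types (the continuity metric runs over these).
FLUID_TYPES = (ECM_FLUID, LUMINAL_FLUID)

# Cell kinds (one per cell identifier xi).
KIND_ECM = 0
KIND_FLUID = 1
KIND_CELL = 2

# ---------------------------------------------------------------------------
# Reference contact energies.  Pairs not listed are symmetric duplicates.
# J_E(apical, apical) and J_E(cytoplasm, apical) together form J_rep
# (reference 200).  Values are shipped as editable defaults in
# data/reference_config.yaml as well; this dict is the in-code source.

_JE_DEFAULT = {
    ("cytoplasm", "cytoplasm"): 10,
    ("basolateral", "cytoplasm"): 10,
    ("basolateral", "basolateral"): 30,
    ("apical", "cytoplasm"): 200,
    ("apical", "basolateral"): 50,
    ("apical", "apical"): 200,
    ("vesicle", "cytoplasm"): 10,
    ("vesicle", "basolateral"): 10,
    ("vesicle", "apical"): 10,
    ("vesicle", "vesicle"): 10,
    ("vacuole", "cytoplasm"): 10,
    ("vacuole", "basolateral"): 10,
    ("vacuole", "apical"): 10,
    ("vacuole", "vesicle"): 10,
    ("vacuole", "vacuole"): 10,
    ("ECM", "cytoplasm"): 130,
    ("ECM", "basolateral"): 10,
    ("ECM", "apical"): 10,
    ("ECM", "vesicle"): 10,
    ("ECM", "vacuole"): 10,
    ("ECM", "ECM"): 10,
    ("ECM_fluid", "cytoplasm"): 10,
    ("ECM_fluid", "basolateral"): 200,
    ("ECM_fluid", "apical"): 50,
    ("ECM_fluid", "vesicle"): 10,
    ("ECM_fluid", "vacuole"): 10,
    ("ECM_fluid", "ECM"): 130,
    ("ECM_fluid", "ECM_fluid"): 0,
    ("luminal_fluid", "cytoplasm"): 10,
    ("luminal_fluid", "basolateral"): 200,
    ("luminal_fluid", "apical"): 50,
    ("luminal_fluid", "vesicle"): 10,
    ("luminal_fluid", "vacuole"): 10,
    ("luminal_fluid", "ECM"): 130,
    ("luminal_fluid", "ECM_fluid"): 0,
    ("luminal_fluid", "luminal_fluid"): 0,
}

_JI_DEFAULT = {
    ("cytoplasm", "cytoplasm"): 10,
    ("cytoplasm", "basolateral"): 5,
    ("cytoplasm", "apical"): 5,
    ("cytoplasm", "vesicle"): 10,
    ("cytoplasm", "vacuole"): 20,
    ("basolateral", "basolateral"): 10,
    ("basolateral", "apical"): 70,
    ("basolateral", "vesicle"): 100,
    ("basolateral", "vacuole"): 100,
    ("apical", "apical"): 10,
    ("apical", "vesicle"): 1,
    ("apical", "vacuole"): 1,
    ("vesicle", "vesicle"): 10,
    ("vesicle", "vacuole"): 5,
    ("vacuole", "vacuole"): 5,
}

#: Neutral contact energy; used for J_E(apical, apical)/(cytoplasm, apical)
#: when the repulsion module is switched off.
J_NEUTRAL = 10.0

#: Reference repulsion strength (Table-1 value of the two J_rep entries).
J_REP_REFERENCE = 200.0


def _table_from_pairs(pairs: dict, undefined: float = 0.0) -> np.ndarray:
    table = np.full((N_TYPES, N_TYPES), undefined, dtype=np.float64)
    for (a, b), v in pairs.items():
        ia, ib = TYPE_CODES[a], TYPE_CODES[b]
        table[ia, ib] = v
        table[ib, ia] = v
    return table


@dataclass
class EnergyParams:
    """Contact-energy tables, motility temperature and elasticities.

    Attributes
    ----------
    JE, JI : (8, 8) float arrays
        External / internal contact energy by type pair; symmetric.
    mu : float
        Motility "temperature" of the modified Metropolis rule.
    lambda_cell, lambda_fluids, lambda_vacuole, lambda_vesicle : float
        Area elasticities: cells are constrained at the cell level, fluid
        bodies per fluid body, vesicles and vacuoles per compartment.
    """

    JE: np.ndarray = field(default_factory=lambda: _table_from_pairs(_JE_DEFAULT))
    JI: np.ndarray = field(default_factory=lambda: _table_from_pairs(_JI_DEFAULT))
    mu: float = 50.0
    lambda_cell: float = 7.0
    lambda_fluids: float = 6.0
    lambda_vacuole: float = 50.0
    lambda_vesicle: float = 1000.0
    #: neighbourhood over which contact energies are summed:
    #: "moore" (orders 1-2, 8 sites) or "von_neumann" (first order, 4 sites).
    #: Copy targets are always drawn from the Moore neighbourhood.
    contact_neighborhood: str = "moore"

    def __post_init__(self) -> None:
        self.JE = np.asarray(self.JE, dtype=np.float64)
        self.JI = np.asarray(self.JI, dtype=np.float64)
        if self.JE.shape != (N_TYPES, N_TYPES) or self.JI.shape != (N_TYPES, N_TYPES):
            raise ValueError("contact-energy tables must be 8x8")
        if not (np.allclose(self.JE, self.JE.T) and np.allclose(self.JI, self.JI.T)):
            raise ValueError("contact-energy tables must be symmetric")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        for lam in (self.lambda_cell, self.lambda_fluids,
                    self.lambda_vacuole, self.lambda_vesicle):
            if lam < 0:
                raise ValueError("elasticities must be non-negative")
        if self.contact_neighborhood not in ("von_neumann", "moore"):
            raise ValueError("contact_neighborhood must be 'von_neumann' "
                             "or 'moore'")

    @property
    def n_contact(self) -> int:
        """Number of contact-neighbourhood offsets (4 or 8)."""
        return 4 if self.contact_neighborhood == "von_neumann" else 8

    # -- derived lookup vectors used by the kernel ---------------------------
    def lambda_by_type(self) -> np.ndarray:
        """Per-compartment elasticity by type (zero except vesicle/vacuole)."""
        lam = np.zeros(N_TYPES, dtype=np.float64)
        lam[VESICLE] = self.lambda_vesicle
        lam[VACUOLE] = self.lambda_vacuole
        return lam

    def lambda_by_kind(self) -> np.ndarray:
        """Cell-level elasticity by cell kind (ECM, fluid body, cell)."""
        return np.array([0.0, self.lambda_fluids, self.lambda_cell])

    @property
    def j_rep(self) -> float:
        return float(self.JE[APICAL, APICAL])

    def with_repulsion(self, j_rep: float) -> "EnergyParams":
        """Return a copy with J_E(apical,apical) = J_E(cytoplasm,apical) = j_rep."""
        JE = self.JE.copy()
        for a, b in ((APICAL, APICAL), (CYTOPLASM, APICAL)):
            JE[a, b] = j_rep
            JE[b, a] = j_rep
        return replace(self, JE=JE, JI=self.JI.copy())


@dataclass
class MechanismConfig:
    """Which lumen-formation mechanisms run, with what rates and schedule.

    ``P_pin``, ``P_A`` and ``P_fuse`` are the pinocytosis, vesicle-step and
    fusion probabilities (reference 1.0 each); ``P_I`` is the probability of
    evaluating de-novo ECM-fluid insertion instead of a membrane extension
    (reference 0: the unextended model).  Schedule periods ``n_m`` give the
    MCS interval of each extra mechanism; mechanism *m* runs when the MCS
    index is divisible by ``n_m``.
    """

    enable_polarization: bool = True
    enable_vacuolation: bool = True
    enable_repulsion: bool = True
    P_pin: float = 1.0
    P_A: float = 1.0
    P_fuse: float = 1.0
    P_I: float = 0.0
    n_vesicle_move: int = 1
    n_fusion: int = 1
    n_demotion: int = 1
    n_fluid_fusion: int = 1
    n_polarization: int = 2
    n_pinocytosis: int = 2
    n_secretion: int = 2
    mcs: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("P_pin", "P_A", "P_fuse", "P_I"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        for name in ("n_vesicle_move", "n_fusion", "n_demotion", "n_fluid_fusion",
                     "n_polarization", "n_pinocytosis", "n_secretion"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.mcs < 0:
            raise ValueError("mcs must be >= 0")


def mechanism_params(mech: MechanismConfig,
                     params: EnergyParams | None = None,
                     j_rep: float | None = None) -> EnergyParams:
    """Resolve the energy table for a mechanism composition.

    With repulsion disabled, the two J_rep entries fall back to the neutral
    contact energy (10); otherwise they take ``j_rep`` (default: the table's
    current value, reference 200).
    """
    params = params if params is not None else EnergyParams()
    if not mech.enable_repulsion:
        return params.with_repulsion(J_NEUTRAL)
    if j_rep is not None:
        return params.with_repulsion(j_rep)
    return params
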