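"""Simulation state: the lattice and the compartment/cell bookkeeping tables.

The 2-D lattice maps every site to a compartment identifier (sigma).  Flat
arrays indexed by sigma record each compartment's type, owning cell (xi),
actual area and target area; a second set of arrays indexed by xi records
the cell-level kind, actual area and target area.  The lattice is the single
source of spatial truth; areas are redundant bookkeeping kept exactly in
sync (and recountable for verification).

Compartment 0 is the (immobile) ECM, compartment 1 the single global body of
ECM fluid; their cell identifiers are 0 and 1.  Cells keep persistent
cytoplasm/apical/basolateral compartment ids; a membrane compartment with
zero area simply has no sites at the moment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import params as P

#: Moore neighbourhood offsets, raster order.
MOORE = np.array([(-1, -1), (-1, 0), (-1, 1),
                  (0, -1), (0, 1),
                  (1, -1), (1, 0), (1, 1)], dtype=np.int64)
#: von Neumann (first-order) offsets.
VON_NEUMANN = np.array([(-1, 0), (0, -1), (0, 1), (1, 0)], dtype=np.int64)

ECM_COMP = 0
ECM_FLUID_COMP = 1
ECM_CELL = 0
ECM_FLUID_CELL = 1

_INITIAL_CAPACITY = 64


@dataclass
class SimState:
    width: int
    height: int
    #: nm per lattice site edge (metadata only; 250 nm reference).
    site_length_nm: float = 250.0

    lattice: np.ndarray = field(init=False)
    comp_type: np.ndarray = field(init=False)
    comp_cell: np.ndarray = field(init=False)
    comp_area: np.ndarray = field(init=False)
    comp_target: np.ndarray = field(init=False)
    cell_kind: np.ndarray = field(init=False)
    cell_area: np.ndarray = field(init=False)
    cell_target: np.ndarray = field(init=False)
    #: per-cell persistent compartment ids (-1 while absent)
    cell_cyt: np.ndarray = field(init=False)
    cell_bas: np.ndarray = field(init=False)
    cell_api: np.ndarray = field(init=False)
    cell_polarizable: np.ndarray = field(init=False)
    n_comps: int = field(init=False, default=0)
    n_cells: int = field(init=False, default=0)
    #: continuity probe regions: list of (rows, cols) index arrays
    probes: list = field(default_factory=list)
    mcs: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        self.lattice = np.zeros((self.height, self.width), dtype=np.int32)
        cap = _INITIAL_CAPACITY
        self.comp_type = np.zeros(cap, dtype=np.int8)
        self.comp_cell = np.zeros(cap, dtype=np.int32)
        self.comp_area = np.zeros(cap, dtype=np.int64)
        self.comp_target = np.zeros(cap, dtype=np.int64)
        self.cell_kind = np.zeros(cap, dtype=np.int8)
        self.cell_area = np.zeros(cap, dtype=np.int64)
        self.cell_target = np.zeros(cap, dtype=np.int64)
        self.cell_cyt = np.full(cap, -1, dtype=np.int32)
        self.cell_bas = np.full(cap, -1, dtype=np.int32)
        self.cell_api = np.full(cap, -1, dtype=np.int32)
        self.cell_polarizable = np.zeros(cap, dtype=bool)
        # reserved identifiers: ECM and the global ECM fluid
        assert self.new_cell(P.KIND_ECM) == ECM_CELL
        assert self.new_cell(P.KIND_FLUID) == ECM_FLUID_CELL
        assert self.new_compartment(P.ECM, ECM_CELL) == ECM_COMP
        assert self.new_compartment(P.ECM_FLUID, ECM_FLUID_CELL) == ECM_FLUID_COMP

    # ------------------------------------------------------------------ ids
    def _grow(self, which: str, needed: int) -> None:
        if which == "comp":
            cap = len(self.comp_type)
            if needed < cap:
                return
            new = max(needed + 1, cap * 2)
            for name in ("comp_type", "comp_cell", "comp_area", "comp_target"):
                arr = getattr(self, name)
                out = np.zeros(new, dtype=arr.dtype)
                out[:cap] = arr
                setattr(self, name, out)
        else:
            cap = len(self.cell_kind)
            if needed < cap:
                return
            new = max(needed + 1, cap * 2)
            for name, fillv in (("cell_kind", 0), ("cell_area", 0),
                                ("cell_target", 0), ("cell_cyt", -1),
                                ("cell_bas", -1), ("cell_api", -1),
                                ("cell_polarizable", False)):
                arr = getattr(self, name)
                out = np.full(new, fillv, dtype=arr.dtype)
                out[:cap] = arr
                setattr(self, name, out)

    def new_compartment(self, ctype: int, cell: int, target: int = 0) -> int:
        sigma = self.n_comps
        self._grow("comp", sigma)
        self.comp_type[sigma] = ctype
        self.comp_cell[sigma] = cell
        self.comp_area[sigma] = 0
        self.comp_target[sigma] = target
        self.n_comps += 1
        return sigma

    def new_cell(self, kind: int, target: int = 0, polarizable: bool = False) -> int:
        xi = self.n_cells
        self._grow("cell", xi)
        self.cell_kind[xi] = kind
        self.cell_area[xi] = 0
        self.cell_target[xi] = target
        self.cell_polarizable[xi] = polarizable
        self.n_cells += 1
        return xi

    # ----------------------------------------------------------- site paint
    def paint(self, rows, cols, sigma: int) -> None:
        """Assign sites to a compartment, keeping area bookkeeping in sync.

        Intended for construction and scheduled (non-kernel) mechanisms; the
        sites must currently belong to live compartments.
        """
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        if rows.size == 1:
            self.paint_site(int(rows[0]), int(cols[0]), sigma)
            return
        old = self.lattice[rows, cols]
        self.lattice[rows, cols] = sigma
        n = old.size
        dec = np.bincount(old, minlength=self.n_comps)
        self.comp_area[:self.n_comps] -= dec
        self.comp_area[sigma] += n
        old_cells = self.comp_cell[old]
        decc = np.bincount(old_cells, minlength=self.n_cells)
        self.cell_area[:self.n_cells] -= decc
        self.cell_area[self.comp_cell[sigma]] += n

    def paint_site(self, r: int, c: int, sigma: int) -> None:
        """O(1) single-site variant of :meth:`paint`."""
        old = int(self.lattice[r, c])
        if old == sigma:
            return
        self.lattice[r, c] = sigma
        self.comp_area[old] -= 1
        self.comp_area[sigma] += 1
        co, cn = self.comp_cell[old], self.comp_cell[sigma]
        if co != cn:
            self.cell_area[co] -= 1
            self.cell_area[cn] += 1

    def fill_rect(self, r0: int, r1: int, c0: int, c1: int, sigma: int) -> None:
        rr, cc = np.mgrid[r0:r1, c0:c1]
        self.paint(rr.ravel(), cc.ravel(), sigma)

    # ------------------------------------------------------------- derived
    def type_lattice(self) -> np.ndarray:
        """Per-site type code (int8 view derived from the compartment map)."""
        return self.comp_type[self.lattice]

    def cell_lattice(self) -> np.ndarray:
        return self.comp_cell[self.lattice]

    def compartments_of_type(self, ctype: int) -> np.ndarray:
        """Live (area > 0) compartment ids of the given type."""
        n = self.n_comps
        mask = (self.comp_type[:n] == ctype) & (self.comp_area[:n] > 0)
        return np.flatnonzero(mask)

    def cell_ids(self) -> np.ndarray:
        n = self.n_cells
        return np.flatnonzero((self.cell_kind[:n] == P.KIND_CELL)
                              & (self.cell_area[:n] > 0))

    def cell_sites(self, xi: int):
        mask = self.cell_lattice() == xi
        return np.nonzero(mask)

    def counts_by_type(self) -> dict:
        """Number of live compartments per type name (for run logs)."""
        n = self.n_comps
        live = self.comp_area[:n] > 0
        out = {}
        for code, name in P.TYPE_NAMES.items():
            out[name] = int(np.count_nonzero(live & (self.comp_type[:n] == code)))
        return out

    # ---------------------------------------------------------- invariants
    def total_target(self) -> int:
        """Conserved cell-level target-area total (cells + fluid bodies)."""
        n = self.n_cells
        return int(self.cell_target[:n].sum())

    def recount_areas(self):
        """Recount areas from the lattice (verification oracle)."""
        comp = np.bincount(self.lattice.ravel(), minlength=self.n_comps)
        cell = np.zeros(self.n_cells, dtype=np.int64)
        np.add.at(cell, self.comp_cell[:self.n_comps], comp[:self.n_comps])
        return comp.astype(np.int64), cell

    def check_areas(self) -> None:
        comp, cell = self.recount_areas()
        if not np.array_equal(comp, self.comp_area[:self.n_comps]):
            bad = np.flatnonzero(comp != self.comp_area[:self.n_comps])
            raise AssertionError(f"compartment area bookkeeping out of sync: {bad[:10]}")
        if not np.array_equal(cell, self.cell_area[:self.n_cells]):
            bad = np.flatnonzero(cell != self.cell_area[:self.n_cells])
            raise AssertionError(f"cell area bookkeeping out of sync: {bad[:10]}")

    # ------------------------------------------------------------- helpers
    def ensure_membrane_compartments(self) -> None:
        """Create cytoplasm/apical/basolateral compartment ids for every
        polarizable cell that lacks them (lazily, before a repolarization)."""
        for xi in self.cell_ids():
            if not self.cell_polarizable[xi]:
                continue
            if self.cell_bas[xi] < 0:
                self.cell_bas[xi] = self.new_compartment(P.BASOLATERAL, xi)
            if self.cell_api[xi] < 0:
                self.cell_api[xi] = self.new_compartment(P.APICAL, xi)

    def non_ecm_sites(self):
        """Fixed source-site pool for copy attempts (ECM is immobile)."""
        rows, cols = np.nonzero(self.type_lattice() != P.ECM)
        return rows.astype(np.int64), cols.astype(np.int64)

    def copy(self) -> "SimState":
        import copy as _copy
        other = SimState.__new__(SimState)
        for name, val in self.__dict__.items():
            if isinstance(val, np.ndarray):
                setattr(other, name, val.copy())
            elif name == "probes":
                setattr(other, name, [(r.copy(), c.copy()) for r, c in val])
            else:
                setattr(other, name, _copy.copy(val))
        return other
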