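"""Continuity readout, replicate runners, parameter sweeps and proportion
comparisons.

A replicate is "continuous" when, at the final MCS, the fluid sites (ECM
fluid plus luminal fluid) contain a single 4-connected component that
intersects every probe region (the cap regions recorded by the geometry
builders).  The continuity fraction of a condition is the fraction of
replicates that are continuous; replicate r runs with seed base_seed + r.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from . import geometry
from . import params as P
from .core import Simulation
from .state import SimState

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


# ------------------------------------------------------------- continuity --
def lumen_continuity(state: SimState, probes=None) -> bool:
    """True iff one single 4-connected fluid component touches all probes."""
    probes = state.probes if probes is None else probes
    if not probes:
        raise ValueError("no probe regions recorded on this state")
    fluid = np.isin(state.type_lattice(), P.FLUID_TYPES)
    labels, _ = ndimage.label(fluid, structure=_CROSS)
    common: set | None = None
    for rows, cols in probes:
        found = set(np.unique(labels[rows, cols]).tolist()) - {0}
        common = found if common is None else (common & found)
        if not common:
            return False
    return bool(common)


# --------------------------------------------------------------- running --
@dataclass
class RunResult:
    seed: int
    continuous: bool
    mcs: int
    state: SimState | None = None


@dataclass
class SweepResult:
    parameter: str | tuple[str, str]
    table: pd.DataFrame
    replicates: int
    base_seed: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_replicate(spec: geometry.GeometrySpec,
                  mech: P.MechanismConfig,
                  params: P.EnergyParams | None = None,
                  seed: int = 0,
                  j_rep: float | None = None,
                  keep_state: bool = False) -> RunResult:
    """Build the geometry, run the configured number of MCS, score continuity."""
    state = geometry.build(spec)
    sim = Simulation(state, params=params, mech=mech, seed=seed, j_rep=j_rep)
    sim.run()
    cont = lumen_continuity(state)
    return RunResult(seed=seed, continuous=cont, mcs=state.mcs,
                     state=state if keep_state else None)


def continuity_fraction(spec: geometry.GeometrySpec,
                        mech: P.MechanismConfig,
                        replicates: int = 30,
                        base_seed: int = 0,
                        params: P.EnergyParams | None = None,
                        j_rep: float | None = None) -> tuple[float, list[RunResult]]:
    """Fraction of replicate runs with a continuous lumen at the final MCS."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    results = [run_replicate(spec, mech, params=params, seed=base_seed + r,
                             j_rep=j_rep)
               for r in range(replicates)]
    frac = sum(r.continuous for r in results) / replicates
    return frac, results


# ----------------------------------------------------------------- sweeps --
_SWEEPABLE = ("P_pin", "J_rep", "P_I", "lambda_fluids", "n_layers",
              "enable_polarization", "enable_vacuolation", "enable_repulsion")


def _apply_value(spec, mech, params, name, value):
    params = params if params is not None else P.EnergyParams()
    if name not in _SWEEPABLE:
        raise ValueError(f"unknown sweep parameter {name!r}; "
                         f"choose from {_SWEEPABLE}")
    j_rep = None
    if name == "J_rep":
        j_rep = float(value)
    elif name == "lambda_fluids":
        params = replace(params, JE=params.JE.copy(), JI=params.JI.copy(),
                         lambda_fluids=float(value))
    elif name == "n_layers":
        spec = replace(spec, n_layers=int(value))
    else:
        mech = replace(mech, **{name: value})
    return spec, mech, params, j_rep


def sweep(spec: geometry.GeometrySpec,
          mech: P.MechanismConfig,
          parameter: str | tuple[str, str],
          grid,
          replicates: int = 30,
          base_seed: int = 0,
          params: P.EnergyParams | None = None) -> SweepResult:
    """Continuity fraction over a 1-D grid or a 2-D (heat-map) grid.

    ``parameter`` is a sweepable name, or a pair of names with ``grid`` a
    pair of value lists (full cartesian product).
    """
    rows = []
    if isinstance(parameter, tuple):
        pa, pb = parameter
        grid_a, grid_b = grid
        points = [((pa, va), (pb, vb)) for va in grid_a for vb in grid_b]
    else:
        points = [((parameter, v),) for v in grid]
    for i, assignment in enumerate(points):
        sp, me, pa_, j_rep = spec, mech, params, None
        row = {}
        for name, value in assignment:
            sp, me, pa_, jr = _apply_value(sp, me, pa_, name, value)
            if jr is not None:
                j_rep = jr
            row[name] = value
        frac, results = continuity_fraction(
            sp, me, replicates=replicates,
            base_seed=base_seed + 1000 * i, params=pa_, j_rep=j_rep)
        row.update(k=sum(r.continuous for r in results), n=replicates,
                   fraction=frac)
        rows.append(row)
    return SweepResult(parameter=parameter, table=pd.DataFrame(rows),
                       replicates=replicates, base_seed=base_seed)


# ------------------------------------------------------------ statistics --
def compare_fractions(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Two-sided Pearson chi-square test of equal proportions (no
    continuity correction) on the 2x2 table [[k1, n1-k1], [k2, n2-k2]].

    Returns (chi2, p).  Degenerate margins (all successes or all failures
    pooled) give chi2 = 0, p = 1.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not 0 <= k <= n:
            raise ValueError("need 0 <= k <= n with n > 0")
    a, b, c, d = k1, n1 - k1, k2, n2 - k2
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, df=1))
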