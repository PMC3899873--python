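"""Configuration parsing, snapshot/log writers.

The config is one YAML document with sections ``energy`` (full J_E/J_I
tables by type name, mu, optional J_rep override), ``lambdas``,
``mechanisms``, ``run`` and ``geometry``.  Unspecified keys take the
reference defaults; the full reference document ships with the package
(``data/reference_config.yaml``) so the contact-energy tables are
user-overridable.

Snapshots are lossless plain-text dumps: two CSV integer grids (compartment
id and type code), CSV compartment/cell tables and a JSON sidecar with the
probe regions; ``load_snapshot(write_snapshot(state))`` reproduces the
lattice exactly.  A PNG rendering (colour by type, outline by cell) can be
written alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import params as P
from .geometry import GeometrySpec
from .state import SimState

_TYPE_ORDER = [P.TYPE_NAMES[i] for i in range(P.N_TYPES)]


# ----------------------------------------------------------------- config --
@dataclass
class Config:
    energy: P.EnergyParams
    mech: P.MechanismConfig
    geometry: GeometrySpec
    replicates: int = 30

    def __iter__(self):  # allow (energy, mech, geometry) unpacking
        return iter((self.energy, self.mech, self.geometry))


class ConfigError(ValueError):
    pass


def _table_to_nested(table: np.ndarray, internal_only: bool = False) -> dict:
    names = (_TYPE_ORDER if not internal_only
             else [P.TYPE_NAMES[i] for i in P.INTRACELLULAR_TYPES])
    out = {}
    for a in names:
        ia = P.TYPE_CODES[a]
        out[a] = {b: float(table[ia, P.TYPE_CODES[b]]) for b in names}
    return out


def default_config_dict() -> dict:
    ep = P.EnergyParams()
    me = P.MechanismConfig()
    ge = GeometrySpec()
    return {
        "energy": {
            "J_E": _table_to_nested(ep.JE),
            "J_I": _table_to_nested(ep.JI, internal_only=True),
            "mu": ep.mu,
            "J_rep": float(ep.JE[P.APICAL, P.APICAL]),
            "contact_neighborhood": ep.contact_neighborhood,
        },
        "lambdas": {"cell": ep.lambda_cell, "fluids": ep.lambda_fluids,
                    "vacuole": ep.lambda_vacuole,
                    "vesicle": ep.lambda_vesicle},
        "mechanisms": {
            "enable_polarization": me.enable_polarization,
            "enable_vacuolation": me.enable_vacuolation,
            "enable_repulsion": me.enable_repulsion,
            "P_pin": me.P_pin, "P_A": me.P_A, "P_fuse": me.P_fuse,
            "P_I": me.P_I,
        },
        "run": {"mcs": me.mcs, "replicates": 30, "seed": me.seed},
        "geometry": {"kind": ge.kind, "width": ge.width, "height": ge.height,
                     "cell_size": ge.cell_size,
                     "cap_size": list(ge.cap_size),
                     "n_layers": ge.n_layers,
                     "cells_per_row": ge.cells_per_row},
    }


def _merge(base: dict, extra: dict, path: str = "") -> dict:
    out = dict(base)
    for key, val in extra.items():
        if key not in base:
            raise ConfigError(f"unknown config key {path + key!r}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val, path + key + ".")
        else:
            out[key] = val
    return out


def _nested_to_table(nested: dict, base: np.ndarray) -> np.ndarray:
    table = base.copy()
    bad = []
    for a, row in nested.items():
        if a not in P.TYPE_CODES:
            bad.append(f"energy type {a!r}")
            continue
        for b, v in row.items():
            if b not in P.TYPE_CODES:
                bad.append(f"energy type {b!r}")
                continue
            table[P.TYPE_CODES[a], P.TYPE_CODES[b]] = v
            table[P.TYPE_CODES[b], P.TYPE_CODES[a]] = v
    if bad:
        raise ConfigError("invalid keys: " + ", ".join(sorted(set(bad))))
    return table


def config_from_dict(doc: dict | None) -> Config:
    merged = _merge(default_config_dict(), doc or {})
    en, la, me, ru, ge = (merged["energy"], merged["lambdas"],
                          merged["mechanisms"], merged["run"],
                          merged["geometry"])
    try:
        energy = P.EnergyParams(
            JE=_nested_to_table(en["J_E"], P.EnergyParams().JE),
            JI=_nested_to_table(en["J_I"], P.EnergyParams().JI),
            mu=float(en["mu"]),
            contact_neighborhood=en["contact_neighborhood"],
            lambda_cell=float(la["cell"]),
            lambda_fluids=float(la["fluids"]),
            lambda_vacuole=float(la["vacuole"]),
            lambda_vesicle=float(la["vesicle"]))
        if en.get("J_rep") is not None:
            energy = energy.with_repulsion(float(en["J_rep"]))
        mech = P.MechanismConfig(mcs=int(ru["mcs"]), seed=int(ru["seed"]),
                                 **{k: me[k] for k in me})
        geometry = GeometrySpec(kind=ge["kind"], width=int(ge["width"]),
                                height=int(ge["height"]),
                                cell_size=int(ge["cell_size"]),
                                cap_size=tuple(ge["cap_size"]),
                                n_layers=int(ge["n_layers"]),
                                cells_per_row=int(ge["cells_per_row"]))
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
    return Config(energy=energy, mech=mech, geometry=geometry,
                  replicates=int(ru["replicates"]))


def load_config(path=None) -> Config:
    """Load a YAML config (or the reference defaults when ``path`` is None)."""
    if path is None:
        return config_from_dict({})
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is not None and not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    return config_from_dict(doc)


def write_default_config(path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(default_config_dict(), fh, sort_keys=False)


# -------------------------------------------------------------- snapshots --
def write_snapshot(state: SimState, base, png: bool = False) -> list[Path]:
    """Dump a state losslessly to ``{base}.*.csv`` + ``{base}.meta.json``."""
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    files = []

    def _save(suffix, arr, fmt="%d"):
        p = base.with_name(base.name + suffix)
        np.savetxt(p, arr, fmt=fmt, delimiter=",")
        files.append(p)

    _save(".sigma.csv", state.lattice)
    _save(".types.csv", state.type_lattice())
    nc, ncell = state.n_comps, state.n_cells
    _save(".comps.csv", np.column_stack([
        np.arange(nc), state.comp_type[:nc], state.comp_cell[:nc],
        state.comp_area[:nc], state.comp_target[:nc]]))
    _save(".cells.csv", np.column_stack([
        np.arange(ncell), state.cell_kind[:ncell], state.cell_area[:ncell],
        state.cell_target[:ncell], state.cell_cyt[:ncell],
        state.cell_bas[:ncell], state.cell_api[:ncell],
        state.cell_polarizable[:ncell].astype(int)]))
    meta = {"width": state.width, "height": state.height, "mcs": state.mcs,
            "site_length_nm": state.site_length_nm,
            "probes": [[r.tolist(), c.tolist()] for r, c in state.probes]}
    mp = base.with_name(base.name + ".meta.json")
    mp.write_text(json.dumps(meta))
    files.append(mp)
    if png:
        files.append(render_png(state, base.with_name(base.name + ".png")))
    return files


def load_snapshot(base) -> SimState:
    base = Path(base)
    meta = json.loads(base.with_name(base.name + ".meta.json").read_text())
    state = SimState(width=meta["width"], height=meta["height"],
                     site_length_nm=meta["site_length_nm"])
    state.mcs = meta["mcs"]
    state.probes = [(np.asarray(r), np.asarray(c)) for r, c in meta["probes"]]
    lattice = np.loadtxt(base.with_name(base.name + ".sigma.csv"),
                         dtype=np.int32, delimiter=",", ndmin=2)
    comps = np.loadtxt(base.with_name(base.name + ".comps.csv"),
                       dtype=np.int64, delimiter=",", ndmin=2)
    cells = np.loadtxt(base.with_name(base.name + ".cells.csv"),
                       dtype=np.int64, delimiter=",", ndmin=2)
    state.lattice = lattice
    state._grow("comp", len(comps))
    state._grow("cell", len(cells))
    state.n_comps = len(comps)
    state.n_cells = len(cells)
    state.comp_type[:len(comps)] = comps[:, 1]
    state.comp_cell[:len(comps)] = comps[:, 2]
    state.comp_area[:len(comps)] = comps[:, 3]
    state.comp_target[:len(comps)] = comps[:, 4]
    state.cell_kind[:len(cells)] = cells[:, 1]
    state.cell_area[:len(cells)] = cells[:, 2]
    state.cell_target[:len(cells)] = cells[:, 3]
    state.cell_cyt[:len(cells)] = cells[:, 4]
    state.cell_bas[:len(cells)] = cells[:, 5]
    state.cell_api[:len(cells)] = cells[:, 6]
    state.cell_polarizable[:len(cells)] = cells[:, 7].astype(bool)
    state.check_areas()
    return state


# -------------------------------------------------------------- rendering --
_TYPE_COLORS = np.array([
    [235, 235, 225],   # ECM: pale
    [200, 225, 245],   # ECM fluid: light blue
    [150, 205, 245],   # luminal fluid: blue
    [70, 105, 180],    # cytoplasm: dark blue
    [130, 130, 130],   # basolateral: grey
    [245, 150, 50],    # apical: orange
    [220, 40, 40],     # vesicle: red
    [240, 210, 60],    # vacuole: yellow
], dtype=np.uint8)


def render(state: SimState) -> np.ndarray:
    """RGB image: colour by type, black outline at cell boundaries."""
    img = _TYPE_COLORS[state.type_lattice()].copy()
    cl = state.cell_lattice()
    edge = np.zeros(cl.shape, dtype=bool)
    edge[:, :-1] |= cl[:, :-1] != cl[:, 1:]
    edge[:-1, :] |= cl[:-1, :] != cl[1:, :]
    ecm = state.type_lattice() == P.ECM
    img[edge & ~ecm] = 0
    return img


def render_png(state: SimState, path) -> Path:
    import matplotlib.image
    matplotlib.image.imsave(path, render(state))
    return Path(path)


# ---------------------------------------------------------------- run log --
def log_line(sim, continuity: bool | None = None) -> str:
    counts = sim.state.counts_by_type()
    parts = [f"mcs={sim.state.mcs}", f"E={sim.total_energy():.1f}"]
    parts += [f"n_{k}={v}" for k, v in counts.items()]
    parts.append(f"continuous={continuity}")
    return " ".join(parts)
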