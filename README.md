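# lumencpm

A two-dimensional, multi-scale **compartmental cellular Potts model (CPM)
of blood-vessel lumen formation**.  During angiogenesis a freshly sprouted
cord of endothelial cells must hollow so blood can perfuse.  Two candidate
mechanisms are debated: *vacuolation* — pinocytotic vesicles fuse into
vacuoles that are exocytosed at the apical membrane — and *cell–cell
repulsion* — negatively charged CD34-sialomucins on apposed apical
membranes push adjacent cells apart.  `lumencpm` implements both on a
shared CPM substrate so they can be studied separately or combined, and
scores outcomes with a *continuity fraction*: the fraction of replicate
simulations in which the fluid at all tips of a branched vessel forms one
connected component.

It is aimed at computational biologists studying tissue morphogenesis with
lattice models, and at anyone who needs a hackable, well-tested
compartmental CPM kernel in Python.

## Model in brief

Cells are sets of lattice sites partitioned into compartments σ (cytoplasm,
apical/basolateral membrane, vesicles, vacuoles) that share a cell
identifier ξ.  The lattice evolves by modified-Metropolis copy attempts on
the effective energy

    E = Σ λ·(a − A)²  +  Σ J(τ, τ′),

an area-elasticity term per cell/fluid/vesicle/vacuole and a contact
energy per boundary site pair (internal table J_I within a cell, external
table J_E between cells; J_rep ≡ J_E(apical, apical) = J_E(cytoplasm,
apical) is the repulsion strength).  A copy is accepted with probability
min(1, e^(−ΔE/μ)).  On top of the copy dynamics, scheduled mechanisms run
each MCS (vesicle walks, vesicle→vacuole fusion, vacuole demotion, fluid
fusion) or every other MCS (surface polarization by ECM contact,
pinocytosis with rate `P_pin`, apical secretion), with exact conservation
of the system-wide target-area total.  See `docs/methods.md` for the full
rule set and the numerical conventions.

## Worked example

```python
from lumencpm import (GeometrySpec, MechanismConfig, Simulation,
                      build, lumen_continuity)

spec = GeometrySpec(width=150, height=150, cell_size=15, cap_size=(15, 8))
state = build(spec)                       # Y-shaped 12-cell sprout in ECM
sim = Simulation(state, mech=MechanismConfig(mcs=2000, seed=3))
sim.run()
print(state.counts_by_type())
print("continuous lumen:", lumen_continuity(state))
```

prints (seed 3, combined mechanism at reference parameters):

```
{'ECM': 1, 'ECM_fluid': 1, 'luminal_fluid': 4, 'cytoplasm': 12,
 'basolateral': 12, 'apical': 12, 'vesicle': 57, 'vacuole': 0}
continuous lumen: False
```

i.e. after 2,000 MCS the twelve cells are polarized (one cytoplasm, one
apical and one basolateral compartment each), carry 57 transport vesicles,
and the surviving secreted sublumens (`luminal_fluid` bodies, most of
which have already fused with the ECM fluid) have not yet merged into a
single channel connecting all three branch tips, so this replicate does
not count as continuous.  Replicate
studies wrap this loop:

```python
from lumencpm import continuity_fraction
frac, runs = continuity_fraction(spec, MechanismConfig(mcs=2000),
                                 replicates=10, base_seed=1)
```

A command-line interface mirrors the library
(`lumencpm run`, `lumencpm sweep --param J_rep --grid 20:200:20`,
`lumencpm continuity <snapshot>`); snapshots are lossless CSV grids plus a
PNG rendering, and all defaults — including the full contact-energy
tables — live in an editable YAML config
(`src/lumencpm/data/reference_config.yaml`).

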