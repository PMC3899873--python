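# Model and methods

`lumencpm` simulates the hollowing (lumen formation) of a pre-formed
endothelial sprout in two dimensions with a compartmentalised cellular
Potts model (CPM).  This note records the model, the numerical choices and
the limits of what the shipped tests demonstrate.

## Lattice and state

The vessel is a branched cord of 12 cells (25×25 sites each at reference
scale; one site = 250 nm) embedded in immobile extracellular matrix (ECM)
on a 550×550 lattice, with a body of ECM fluid at each of the three ends
of the branch.  Every lattice site carries a compartment identifier σ;
every compartment has a type τ — cytoplasm, apical membrane, basolateral
membrane, vesicle, vacuole, ECM, ECM fluid or luminal fluid — and belongs
to a cell identifier ξ (cells, the ECM, and each fluid body are "cells" in
this generalised sense).  Because the ECM is immobile and nothing may
overwrite it, the non-ECM region — the carved vessel channel plus the
fluid caps — is invariant over a run; all dynamics happen inside it.

## Dynamics

Motility follows the modified Metropolis rule of the CPM.  Each Monte
Carlo step (MCS) performs as many copy attempts as there are lattice
sites: a random non-ECM source site tries to copy its compartment
identifier onto a random Moore-neighbour target; the change in effective
energy

    E = E_area + E_contact

is accepted with probability min(1, exp(−ΔE/μ)), μ = 50.  `E_area`
penalises deviations of actual from target area quadratically: per cell
(λ_cell = 7), per fluid body (λ_fluids = 6), per vacuole (λ_vacuole = 50)
and per vesicle (λ_vesicle = 1000; target 1 site keeps vesicles at the
250-nm pixel scale).  A compartment deleted by a copy drops out of
`E_area` (see "Extinction convention" below).  `E_contact` sums a
symmetric type-pair contact energy over neighbouring site pairs that
straddle a compartment boundary — the internal table J_I within a cell,
the external table J_E between cells.  J = 10 is neutral; lower is
adhesive, higher repulsive.  Cell–cell repulsion by CD34-sialomucins is
the scalar J_rep = J_E(apical, apical) = J_E(cytoplasm, apical)
(reference 200; the cytoplasm entry covers membrane pixels displaced
between polarization passes).

Extra mechanisms run after the copy attempts of each MCS, in fixed order
with fixed periods: vesicle movement, vesicle/vacuole fusion, vacuole
demotion and fluid fusion every MCS; cell-surface polarization,
pinocytosis and secretion every other MCS.

* **Polarization** retypes each cell's border sites (Moore neighbour
  outside the cell): basolateral on direct ECM contact or when at least
  two same-cell membrane neighbours touch the ECM (lateral junctions),
  apical otherwise; interior former-membrane sites revert to cytoplasm.
  Only ECM polarizes — fluid contact does not.
* **Pinocytosis**: a membrane-typed site that became internal turns into a
  fresh one-site vesicle with probability P_pin (else cytoplasm); the cell
  target grows by one and the ECM-fluid target shrinks by one (fluid
  uptake).  If the ECM-fluid target pool is exhausted, uptake is suspended
  (nothing left to take up).
* **Vesicle transport**: each vesicle swaps content with a random Moore
  neighbour with probability P_A·min(1, e^(−ΔE/μ)); adhesion to apical
  membrane, vesicles and vacuoles (J_I) biases the walk.  A fluid
  neighbour triggers copy-style secretion instead; ECM or another cell
  blocks the move.
* **Fusion**: Moore-adjacent same-cell vesicles/vacuoles fuse with
  probability P_fuse per adjacent pair into a vacuole whose target is the
  sum of the fused targets.
* **Demotion**: a single vacuole pixel split off and surrounded by
  same-cell cytoplasm becomes a vesicle (target 1, or 0 if the donor's
  target was 0), the donor losing that target; a vacuole reduced to one
  site by a copy becomes a vesicle and its residual target follows the
  invading compartment (luminal fluid or vacuole) or returns to ECM fluid.
* **Secretion**: a vesicle/vacuole pixel with a first-order apical
  neighbour is secreted, together with its 4-connected same-cell patch of
  vesicle/vacuole pixels, as one new luminal-fluid body; the transferred
  target is the combined target of fully secreted compartments plus, for a
  partially secreted vacuole, min(secreted size, vacuole target).
* **Fluid fusion**: adjacent luminal bodies merge (targets summed);
  luminal fluid merges into ECM fluid on ECM contact or when completely
  surrounded by ECM fluid.

Copy-triggered variants of fusion, demotion and secretion are applied
inside the kernel at the moment a copy shrinks or deletes a vesicle,
vacuole or luminal body.

**Target-area conservation.**  The bookkeeping treats the cell-level (ξ)
targets of cells and fluid bodies as the conserved currency; vesicle and
vacuole σ-targets are sub-allocations of their cell's target.  Every rule
above transfers matching amounts, so the system-wide total is exactly
invariant — the suite asserts this after every MCS of a mechanism-rich
run.  Where the original rule set left the owning cell's share ambiguous
(the residual target of a vacuole demoted by a copy), the cell's target
follows the residual out of the cell; any other reading breaks the
invariant.

**Extinction convention.**  A compartment (or cell) whose area reaches
zero is deleted and its area term vanishes rather than being charged at
λ(0 − A)².  The alternative — keeping the term — would suppress the
documented copy-triggered deletions of vesicles by a factor e^(−λ/μ) =
e^(−20) and make them unobservable.

**De-novo fluid insertion (P_I).**  With probability P_I a copy attempt
evaluates the insertion of a fresh ECM-fluid site at the target instead of
the membrane extension, bypassing the "vacuum attachment" of apposed
membranes.  With P_I = 0 the branch draws no randomness, and the suite
verifies bit-identical trajectories against a kernel with the branch
disabled.

## Mechanism compositions

The vacuolation mechanism is motility + polarization + vacuolation; the
cell–cell repulsion mechanism is motility + polarization + repulsion; the
combined mechanism enables all four modules.  Disabling repulsion resets
the two J_rep entries to the neutral 10 (the table's 200 *is* the
reference repulsion strength).

## Readout

A run is *continuous* when, at its final MCS, one single 4-connected
component of fluid sites (ECM plus luminal fluid) intersects all probe
regions.  Probes are the fluid caps plus the adjacent tip-cell footprint:
the ECM is immobile, so the vessel stretches into the caps while the fluid
pools just inside the vessel end, and the branch-tip *region* is the
meaningful location of "fluid at the tips".  The continuity fraction of a
condition is the fraction of continuous replicates; replicate r uses seed
base_seed + r, making every fraction bit-reproducible.  Proportions are
compared with a two-sided Pearson chi-square test without continuity
correction, which reproduces the reported p ≈ 1.1×10⁻³ for 9/30 vs 0/30.

## Numerical choices

* Copy targets are drawn uniformly from the 8-site Moore neighbourhood
  ("second neighbouring site" read as orders 1–2); contact energies are
  summed over the Moore neighbourhood by default
  (`EnergyParams.contact_neighborhood` switches to first-order sums; the
  scaled-down outcomes were indistinguishable).
* A proposal with source and target in the same compartment counts as an
  attempt and is rejected as a no-op; ECM can be neither source nor
  target.
* The inner loop is compiled (numba) and uses an explicit xorshift64*
  generator; scheduled mechanisms run vectorised at Python level with a
  separate generator derived from the same seed.  Identical seed + config
  gives byte-identical trajectories.
* Fusion and merge passes consider each unordered adjacent pair once per
  MCS, in deterministic (sorted) order; secreted patches are labelled with
  4-connectivity ("first-order connected").
* The contact-energy tables ship as an editable YAML config
  (`data/reference_config.yaml`); the fluid rows of the reference tables
  are a reconstruction (see Limitations).

## Scaled-down study conditions

The reference conditions (550×550 lattice, 10,000 MCS, 30 replicates) cost
hours of CPU per condition.  The shipped tests and the acceptance script
therefore use a scaled-down sprout — 150×150 lattice, 15×15-site cells,
15×8 caps, 2,000 MCS, 10 replicates — and, for pure invariant checks, a
100×100 / 9×9-cell build.  Scaling down is not neutral for this model:
vesicles (1 site) and membranes (1 site thick) do not scale with the
cells, lateral-junction seals span a larger fraction of each cell–cell
interface, and cell-shape fluctuations are smaller relative to the cell.
Mechanism-level behaviour (polarized rims, pinocytosis, vacuole growth,
secretion, sublumen formation) is preserved, and the negative controls
(no polarization, weak repulsion, compressible fluids) behave as at full
scale; but repositioning-dependent *continuity* emerges more slowly than
a naive (length/time) rescaling suggests, so scaled-down continuity
fractions under-estimate the full-scale ones.  The full-scale combined
mechanism at reference settings is the model's strongest regime and can
be run overnight via the CLI.

## What the synthetic geometry does and does not capture

The branched sprout is an idealised Y of square cells in a rigid channel:
no ECM remodelling or degradation, no chemotaxis, no sprout growth, no
blood pressure, and a 2-D cross-section (an intracellular lumen that would
be a torus in 3-D appears as a split cell).  Passing tests demonstrate the
internal consistency of the mechanisms and their qualitative controls,
not quantitative agreement with any particular experiment.

## Known limitations

* The fluid and ECM rows of the reference contact tables are a
  best-effort reconstruction; they are deliberately user-overridable.
* Continuity at desk scale is conservative (see above).
* No 3-D lattice; no parallel kernel; single-threaded runs only.
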