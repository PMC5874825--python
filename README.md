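# solvagg

Solvation-structure and aggregation analysis for small-molecule solutes
that coexist in water as **nonionic** and **zwitterionic** tautomers
(the bundled rigid fragments model meta-aminobenzoic acid, mABA/mABA±,
a classic polymorphism test case). The package is aimed at molecular
modellers who want the *analysis* half of such a study — everything
downstream of the electronic-structure and force-field engines — as
tested, reusable code:

* **Hydration structure** — radial distribution functions g(r) with
  running coordination numbers n(r) = 4π(N/V)∫₀ʳ g(r′)r′²dr′,
  first-peak metrics and the g_max/g_min amplitude ratio used as a
  hydrogen-bond-strength proxy, a 2.5 Å X···H existence criterion, and
  hydration-shell occupancy distributions (mean and mean absolute
  deviation).
* **Low-lying dimer search** — random rigid-body placement of a mobile
  molecule around a central unit, a 4 Å contact filter, pluggable
  energy evaluation, Boltzmann ranking
  f_i = e^−(E_i−E₀)/RT / Σ_j e^−(E_j−E₀)/RT, and selection of the
  f_i ≥ 0.01 set plus 10–15 random structures with
  3 ≤ E_i−E₀ ≤ 15 kcal·mol⁻¹.
* **Association thermodynamics** — ΔG*_ass = G*(AB) − G*(A) − G*(B)
  assembled by either a gas-phase route (with the RT·ln(R̃T) ≈ 1.89
  kcal·mol⁻¹ standard-state correction) or a solution-phase route, with
  Boltzmann ensemble averaging ⟨G⟩ = Σᵢ fᵢG(Xᵢ) over isomers.
* **Aggregation statistics** — species-resolved molecular pair counts
  (minimum interatomic distance ≤ 4.0 Å), reduction of each solute to
  three sites (amino/ring/carboxyl group COMs, labelled A/B/C and
  A*/B*/C*), and the 6×6 percent-normalised **pairwise interaction
  matrix** (PIM) of intermolecular site contacts.

A synthetic-data module generates every input with exact geometric
ground truth (planted H-bond contacts, planted pair frequencies,
closed-form isomer ensembles, a deterministic Lennard-Jones + Coulomb
site oracle), so the full pipeline runs and is validated without any
quantum-chemistry or MD engine.

## Worked example

```python
import numpy as np
from solvagg import (make_solvated_solute, compute_rdf, hbond_series,
                     first_peak_metrics, peak_ratio,
                     hydration_shell_distribution)

traj = make_solvated_solute(n_waters=210, box=18.6,
                            donor_contact_prob=0.6, n_frames=40, seed=1)
top = traj.topology
hb = hbond_series(traj, top.select(label="Nm"),
                  top.select(label="Hw", species="water"), cutoff=2.5)
shell = hydration_shell_distribution(traj, solute=0, shell_radius=4.5)
print(f"N_m H-bond fraction: {hb.mean():.2f}")
print(f"shell mean {shell.mean:.2f}, MAD {shell.mad:.2f}")
```

prints (seed 1):

```
N_m H-bond fraction: 0.65
shell mean 6.85, MAD 1.23
```

The H-bond fraction recovers the planted per-frame contact probability
of 0.6 (40 frames give a binomial standard error of ±0.08); the shell
statistics count water centres of mass within 4.5 Å of the solute COM
in this deliberately small synthetic box. The command-line interface
runs the same stages end to end and writes TSV/JSON reports:

```sh
solvagg all --seed 1 --out run1        # solvation, search, thermo, pim
solvagg pim --seed 1 --out run2        # one stage only
```

## Input formats

Trajectories are plain text in two dialects: extended XYZ (comment line
`Lattice="ax 0 0 0 by 0 0 0 cz" Time=<ps>`, Å) and fixed-column GRO
(nm, multi-frame by concatenation). Atom → molecule → functional-group
→ species assignments travel in a YAML sidecar:

```yaml
atoms:
  - {element: O, mass: 15.999, label: Om, molecule: 0, group: carboxyl}
  - {element: H, mass: 1.008,  label: Hw, molecule: 1, group: water}
species:
  0: nonionic
  1: water
```

See `docs/methods.md` for the model conventions, parameter defaults and
known limitations.
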