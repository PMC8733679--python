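# arrbind

Analysis of GPCR–arrestin complexes from molecular-dynamics trajectories:
how membrane lipids and receptor phosphorylation shape the binding mode of
β-arrestin on a membrane-embedded receptor such as the β2-adrenergic
receptor (β2AR).

The package is aimed at structural/computational biophysicists who already
have trajectories (or deposited structures) and want the observables that
characterise receptor–arrestin coupling:

- **Membrane-contact probability profiles** — per residue, the fraction of
  analysed simulation time in which the residue lies closer than 0.5 nm to
  any lipid atom (direct contact or a single bridging water), with SEM over
  analysis windows pooled across replicas. Used for the receptor's third
  intracellular loop (ICL3) and C-terminus.
- **Ionic-lock distance** — the Cα–Cα distance between the TM3/TM6 lock
  residues (R131–E268 in β2AR numbering; generic positions 3.50/6.30),
  which reports the opening of the receptor's cytosolic pocket.
- **Binding-mode coordinates** — insertion depth
  `d = |n · (COM(TM bundle) − COM(N-lobe strands))|` along the membrane
  normal `n`, and rotation `α`, the signed in-plane angle of the arrestin
  about the membrane normal relative to a reference complex; plus 2D
  (d, α) densities, core-disengagement classification (`d > 5.3 nm`), and a
  dynamics metric: the mean per-window standard deviation of d and α.
- **Windowed RMSF** — per-residue root-mean-square fluctuation after
  least-squares superposition on the receptor core, per analysis window.
- **Group–group nonbonded energetics** — truncated short-range Coulomb +
  Lennard-Jones energies and forces between named groups (e.g.
  ICL3 ↔ membrane), with the phosphate groups of phospho-Ser/Thr excluded
  so phosphorylated and non-phosphorylated receptors are comparable.
- **Lipid binding and salt bridges** — counts of distinct lipid molecules
  bound at a site (e.g. anionic PG lipids at the basic patch of arrestin's
  C-lobe), loop anchoring fractions, residue-pair contact matrices,
  salt-bridge occupancies.
- **ICL2 helicity** — dihedral-window helix assignment (φ ∈ [−100°, −30°],
  ψ ∈ [−80°, −5°], minimum run 4) and helical-residue counts per window.

Because full-scale MD is not reproducible at desk scale, the package ships
a first-class **synthetic toy-system generator** (`arrbind.synth`): a
bead-resolution membrane–receptor–arrestin complex with rigid-body
Ornstein–Uhlenbeck dynamics for (d, α), two-state Markov membrane-contact
processes for loop residues, toggling ICL2 helicity and per-residue
Gaussian jitter — all seeded and exported with exact ground truth, so every
analysis stage is verifiable by parameter recovery.

## Worked example

```python
import numpy as np
from arrbind import (BindingModeReference, MembraneFrame, binding_mode_series,
                     dynamics_metric, make_windows)
from arrbind.synth import (SELECTIONS, ToySystemSpec, build_toy_complex,
                           default_dynamics, simulate_trajectory)

toy = build_toy_complex(ToySystemSpec(), seed=1)
bundle = simulate_trajectory(toy, default_dynamics(n_frames=2000, seed=1))

s = toy.structure
tm, nlobe, clobe = (s.select(SELECTIONS[k])
                    for k in ("tm_bundle", "nlobe", "clobe"))
ref = BindingModeReference(s, tm, nlobe, clobe,
                           MembraneFrame(np.array([0.0, 0.0, 1.0]), 0.0))
w = make_windows(bundle.trajectory, length=50.0)
series = binding_mode_series(bundle.trajectory, tm, nlobe, tm, nlobe, clobe,
                             ref, w)
metric = dynamics_metric(series, w)
print(f"d = {series.d.mean():.3f} nm, SD(d) = {metric.d_sd_mean:.4f} nm, "
      f"SD(alpha) = {metric.alpha_sd_mean:.2f} deg")
```

prints

```
d = 4.468 nm, SD(d) = 0.0636 nm, SD(alpha) = 3.38 deg
```

i.e. the arrestin N-lobe sits ≈4.47 nm below the TM-bundle center (a tight,
core-engaged complex), and the windowed standard deviations — the complex's
"dynamics" — recover the generator's stationary values (0.065 nm and 3.5°).
More narrative scripts live in `examples/` (contact profiles, energetics and
bound lipids, helicity and RMSF, single-structure metrics).

## Selection grammar

`select(structure, expr)` supports `chain`, `resid` (values and inclusive
ranges `100:110`), `resname`, `name`, `element`, `all`, combined with
`and` / `or` / `not` and parentheses; multiple values after a keyword form a
union, e.g. `"chain R and name CA and resid 29:60 67:96"`.

## Command line

A thin CLI wraps the pipeline:
`arrbind simulate|contacts|geometry|energetics|helicity|structure-metrics
-c config.yaml`. The YAML config names the topology, replica trajectories,
selections, cutoffs and window schemes; outputs are tidy TSV plus a JSON
report stamped with the configuration hash. Exit codes: 0 success, 2
configuration error, 3 data error.

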