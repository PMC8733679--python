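# Methods

## Scope and units

`arrbind` computes trajectory observables for membrane-embedded
receptor–arrestin complexes. All lengths are nm, times ns, masses amu,
charges elementary charges, energies kJ/mol; loaders normalise on input
(PDB Å → nm). Residues are identified by `(chain id, residue id)` with the
source file's numbering preserved verbatim, so published residue numbers
(R131, E268, S246/S261/S262, F139, K232, E314, …) can be used directly.

## Structural model and periodic geometry

Structures are flat atom tables with one coordinate set and an optional
periodic cell stored as a 3×3 matrix of lattice vectors; trajectories are
in-memory frame stacks over a fixed topology. File parsing and writing
(PDB, GRO, XTC, DCD, multi-model PDB) is delegated to MDAnalysis behind the
loader functions. Masses are resolved from a small element table; an
unknown element is an error, not a guess (overrides are accepted per atom
name or element).

Minimum-image distances wrap displacement vectors by fractional rounding
and then search the 27 nearest images. For orthorhombic cells the rounding
alone is exact and used directly; the 27-image search is exact for every
cell whose shortest inter-face distance exceeds twice the largest distance
of interest, which holds for all boxes used here. The implementation is
contract-tested against a literal image-enumeration oracle at 1e-12.

Centers of mass are computed on wrapped coordinates without unwrapping;
a recentering utility shifts frames so the membrane midplane sits at z = 0,
and callers measuring across the membrane are expected to apply it (the toy
builder centres the membrane at z = 0 by construction). Whether source
trajectories should be recentred before analysis is a convention this
package fixes explicitly rather than inheriting silently.

Contact observables evaluate full vectorised pairwise minimum-image
distance blocks rather than a cell-list grid: at the system sizes this
package targets (≤ a few thousand atoms per frame) the dense evaluation is
faster to verify and comfortably fast, and it is by construction identical
to the brute-force double loop that the tests enforce.

## Contacts and occupancies

A residue is in membrane contact in a frame when the minimum distance
between any of its atoms and any membrane atom (all lipid species count)
is below the cutoff, 0.5 nm by default — a distance that covers direct
interactions and ones bridged by a single water. Hydrogens are included
when present; a heavy-atom-only mode is available through selections.
Contact probability is the fraction of analysed frames in contact; the SEM
is the standard deviation of per-window means over √(number of windows),
and replicas pool by contributing windows (three replicas × two intervals
= six pooled intervals). The salt-bridge criterion is 0.4 nm between
charged heavy atoms (side-chain carboxylate/phosphate oxygens vs side-chain
nitrogens); the bound-lipid criterion reuses the 0.5 nm contact cutoff and
counts distinct lipid molecules with at least one atom within the cutoff of
the site. Both cutoffs are configuration-exposed since different
conventions exist in the literature.

## Binding-mode geometry

The membrane frame is the box z-axis with the midplane at the mean
phosphate z when membrane atoms exist; for membrane-free experimental
structures the normal falls back to the long principal axis of the TM
bundle Cα cloud, oriented so the arrestin lies on its negative side. The
insertion depth d is the absolute normal projection of the vector between
the TM-bundle center of mass and the center of mass of the four
membrane-proximal N-lobe β-strands of the arrestin. Because no consensus
residue list exists for those strands, they are configuration-supplied
(defaults per arrestin isoform in `arrbind.presets`), and depth results
should be read together with their sensitivity to the selection, which the
acceptance checks print.

The rotation α superposes the frame's receptor TM Cαs onto the reference
complex, applies the transform to the arrestin, projects the
N-lobe → C-lobe anchor vector into the membrane plane and takes the signed
angle from the reference's direction, wrapped to (−180°, 180°]. The sign is
positive counterclockwise as seen from the cytosolic side (a convention
this package fixes; sources rarely state one). α of the reference against
itself is 0 by definition — no attempt is made to reproduce small nonzero
rotations sometimes quoted for the reference complex itself, whose
operational definition is ambiguous.

Frames with d > 5.3 nm are classified core-disengaged (the arrestin has
left the receptor core and at most remains tail-attached). Complex
dynamics is the mean over analysis windows of the within-window sample SD
(n−1) of d and of α, with α unwrapped within each window so that seam
crossings near ±180° do not inflate the SD; wrapped-versus-unwrapped is
another unstated convention fixed here. The 2D (d, α) density is a plain
normalised histogram (default grid d ∈ [4.0, 5.4] nm × α ∈ [−40°, 50°],
bins 0.025 nm × 1°; no kernel smoothing); samples outside the grid are
clamped into the edge bins and their count reported.

RMSF superposes every frame of a window onto the window-mean structure via
the fit group (two passes: fit to the first frame, re-fit to the resulting
mean), then takes the RMS displacement of each residue's Cα about its
window-mean position; windows and replicas contribute to the mean ± SEM.

## Nonbonded energetics

Group–group energies are plainly truncated sums over inter-group pairs
within the cutoff (default 1.2 nm, minimum image) of
`f·q_i·q_j/(ε_r·r) + 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶]` with
f = 138.935458 kJ·mol⁻¹·nm·e⁻², ε_r = 1 and Lorentz–Berthelot combination
by default. No Ewald/PME, switching or shifting is applied: these energies
are a defined desk-scale approximation for comparing scenarios (e.g. how
strongly ICL3 binds the membrane across phosphorylation states), not a
reproduction of force-field absolute values, and only monotone orderings of
scripted scenarios are asserted in tests. The exclusion set implements the
convention of omitting the phosphate groups (P and its bonded oxygens) of
phospho-Ser/Thr side chains so phosphorylated and non-phosphorylated
receptors give comparable values. Forces are the analytic negative
gradient, verified against central differences; Newton's third law holds
between groups. Parameters come from a flat per-atom TSV
(chain, resid, atom_name, charge_e, sigma_nm, epsilon_kjmol, excluded)
rather than any force-field file dialect.

## Helicity

Backbone φ/ψ torsions use the standard C(i−1)–N–Cα–C and N–Cα–C–N(i+1)
definitions; residues missing an atom get NaN. A residue is helical when
(φ, ψ) fall inside the windows φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°] and it
belongs to a run of ≥ 4 such residues. A dihedral-window rule (rather than
hydrogen-bond pattern assignment) was chosen because the toy backbones
carry no carbonyl hydrogen-bonding geometry; the windows and minimum run
are configuration-exposed, and helicity counts on experimental structures
should be expected to differ by ±1 residue from pattern-based assignments.

## The synthetic toy system

`arrbind.synth` builds, from one seeded NumPy generator, a bead-resolution
complex: a two-leaflet lipid slab in the xy-plane centred at z = 0 (PC-like,
PG-like with −1 head charge, and cholesterol-like pseudo-molecules of 3–4
beads on a 1.4 nm grid, default composition 54:36:10 like the study
membrane, with a lipid-free pore for the receptor); a seven-helix receptor
bundle of Cα beads spanning the slab with β2AR-like residue numbering;
bead-chain ICL3 (230–266) and C-terminus (343–362) loops below the
membrane; a full-backbone ICL2 (137–146) built by an internal-coordinate
backbone builder; and a two-lobe arrestin with four marked N-lobe strands,
C-edge loop beads, a 7-residue basic patch near the anionic heads, and the
salt-bridge partners E135/E314.

The simulator applies, per frame: (1) rigid-body arrestin motion so that
d(t) and α(t) follow exactly discretised Ornstein–Uhlenbeck processes
(update x′ = μ + (x−μ)e^(−dt/τ) + σ√(1−e^(−2dt/τ))·ξ, started from the
stationary law); (2) two-state Markov contact processes for scripted loop
residues with exact discrete transition probabilities for the prescribed
stationary probability and dwell times — the contact pose pins the residue
0.35 nm below its "home" lipid head, the detached pose 1.2 nm (scripted
residues are pinned in-plane to their home lipid rather than following the
rigid body, so the scripted distances are exact by construction); (3) a
whole-segment helical/coil toggle of the ICL2 backbone drawn per frame —
a per-residue draw would interact with the minimum-run rule and break the
simple count = p × (assignable residues) ground truth; (4) isotropic
per-atom Gaussian jitter with per-residue amplitudes (default 0.01 nm;
0.005 nm on the ICL2 backbone so torsion noise stays well inside the
helical windows).

Defaults encode the study conditions: OU d with mean 4.48 nm and SD
0.065 nm, α with mean 0° and SD 3.5°; relaxation times 1 ns (a realistic
rigid-body relaxation scale — short enough that 100-ns windows hold ≥100
relaxation times, so windowed SDs are nearly unbiased); TM6-proximal ICL3
contact probability 0.8 against 0.15 for the TM5-proximal half; C-terminus
contact probabilities interpolating 0.7 → 0.4 (G351) → 0.1 (G361); C-edge
dwell probability 0.95; ICL2 helical fraction 0.625 (5 of 8 assignable
residues); dt 0.1 ns, 5000 frames.

What the toy does *not* emulate: lipid geometry and diffusion, solvent,
force-field energetics driving the motion, correlated loop conformational
change, or any coupling between observables (contacts, helicity and
binding mode are driven independently). Passing parameter-recovery tests
therefore demonstrates that the *analysis* is correct and unbiased at known
ground truth — not that the generator is a physical model of real systems.

For statistical tests the generator also exports effective sample sizes:
a two-state chain with per-frame autocorrelation λ = e^(−(k_on+k_off)·dt)
has n_eff = n(1−λ)/(1+λ); an OU series sampled at dt has
n_eff ≈ n·dt/(2τ). Recovery tolerances are 3 standard errors on those
effective sizes (means), 10 % on SD-type quantities, 5 % on RMSF.

## Numerical and degenerate-case conventions

Sample SDs use the n−1 denominator. Analysis windows are half-open
[start, end) and only complete windows after the burn-in are kept
(a 2000-ns run with 500 ns burn-in and 500-ns windows yields 3); a window
with no frames is an error, a trajectory too short for any window yields an
empty set with a warning. Angles wrap to (−180°, 180°]. A degenerate
(near-normal) anchor vector is an error for α. Empty selections are errors
unless explicitly allowed. Superposition uses SVD-based least squares
(`scipy` rotation alignment); two fitting passes against the window mean.

## Problem sizes

Default verification sizes are 5000-frame fixtures (10⁴ for RMSF and OU-SD
recovery) on toy systems of ~600–900 atoms, chosen so the full suite and
the acceptance script each run in minutes on a single CPU while keeping
every tolerance comfortably above Monte-Carlo noise.

## Known limitations

- Deposited-structure metrics (ionic lock, insertion depth, ICL2 helicity
  of 3SN6/5DGY/6U1N/6TKO) need the entries fetched from the PDB; the
  presets naming chains, lock residues, TM ranges and N-lobe strands are
  best-effort defaults and must be reviewed against each entry.
- Energetics are short-range only; absolute kJ/mol values are not
  comparable to PME-based pipelines.
- The dihedral-window helicity assignment is not DSSP; counts can differ
  by ±1 residue.
- The toy generator's independence assumptions (above) mean cross-observable
  correlations seen in real trajectories are out of its scope.
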