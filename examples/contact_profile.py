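"""Per-residue membrane-contact probability of the receptor's ICL3.

A residue counts as membrane-bound in a frame when any of its atoms lies
within 0.5 nm of any lipid atom -- close enough for direct contact or a
single bridging water.  The toy generator scripts the TM6-proximal half of
ICL3 to a two-state contact process with stationary probability 0.8, so the
profile should recover that plateau.
"""

from arrbind import contact_probability_profile, make_windows
from arrbind.synth import (SELECTIONS, ToySystemSpec, build_toy_complex,
                           default_dynamics, simulate_trajectory)

toy = build_toy_complex(ToySystemSpec(), seed=2)
bundle = simulate_trajectory(toy, default_dynamics(n_frames=2000, seed=2))

s = toy.structure
residues = s.select(SELECTIONS["icl3"]).split_by_residue()
membrane = s.select(SELECTIONS["membrane"])
windows = make_windows(bundle.trajectory, length=50.0)

profile = contact_probability_profile(bundle.trajectory, residues, membrane,
                                      windows, cutoff=0.5)
print("resid  P(contact)  SEM")
for (chain, resid), p, sem in zip(profile.residue_keys,
                                  profile.probabilities, profile.sems):
    bar = "#" * int(p * 40)
    print(f"{resid:5d}  {p:10.3f}  {sem:.3f}  {bar}")
# Residues 250-266 (TM6-proximal) should plateau near 0.8; the TM5-proximal
# half stays mostly detached (0.15). The SEM is taken over the 50-ns
# analysis windows.
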