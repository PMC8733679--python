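"""Single-structure metrics: ionic lock, insertion depth, ICL2 helicity.

Writes a toy complex to PDB and runs the structure-metrics pipeline on it,
the same battery that can be pointed at deposited receptor/arrestin entries
(3SN6, 5DGY, 6U1N, 6TKO) via ``arrbind.presets`` once they are fetched.
"""

import tempfile
from pathlib import Path

from arrbind.config import load_run_config
from arrbind.core import write_structure
from arrbind.pipeline import run_structure_metrics
from arrbind.synth import ToySystemSpec, build_toy_complex

toy = build_toy_complex(ToySystemSpec(), seed=5)
tmp = Path(tempfile.mkdtemp())
write_structure(toy.structure, tmp / "toy_complex.pdb")

config = load_run_config({
    "structures": [{"path": str(tmp / "toy_complex.pdb"),
                    "receptor_chain": "R"}],
    "output_dir": str(tmp / "out"),
})
table = run_structure_metrics(config)
print(table.to_string(index=False))
# ionic_lock_nm: Calpha distance of the TM3/TM6 lock pair (R131-E268 here);
# d_nm: arrestin N-lobe insertion depth along the membrane normal;
# icl2_helical_residues: dihedral-window helix count of the ICL2 segment.
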