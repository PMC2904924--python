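"""Simulate a WALP16 helix in vacuum and verify it maintains itself.

The helix is held together by the i,i+4 hydrogen-bond wells of the
LJHB potential (minimum at 0.61 nm) and by the 91.25 deg backbone angle
well; neither is imposed as a constraint, so surviving 0.6 ns of
thermal motion at 324 K is a real test of the force field.
"""

import numpy as np

import cgmemsim as cg
from cgmemsim.analysis import (
    crms_alpha,
    hbond_pair_distributions,
    histogram_mode,
)

ff = cg.default_forcefield()
system = cg.build_walp(cg.PeptideSpec(cg.walp_sequence(16)), ff)
print(f"WALP16 ({cg.walp_sequence(16)}): {system.n_particles} beads")

config = cg.SimulationConfig(n_steps=50_000, temperature=324.0, seed=7,
                             output_stride=500)
frames = cg.run_md(system, ff, config)

bb = system.backbone_indices()
ref = frames[0].positions[bb]
late = [f for f in frames if f.time >= frames[-1].time / 2]
crms = np.mean([crms_alpha(f.positions[bb], ref) for f in late])
bonds = np.mean([np.linalg.norm(f.positions[bb][1:] - f.positions[bb][:-1],
                                axis=1).mean() for f in late])
hists = hbond_pair_distributions([f.positions[bb] for f in late])
mode4 = histogram_mode(*hists[4])

print(f"simulated {frames[-1].time:.0f} ps at 324 K")
print(f"  CRMS vs start      : {crms:.3f} nm   (< 0.384 nm = stable fold)")
print(f"  mean backbone bond : {bonds:.3f} nm  (target 0.384 nm)")
print(f"  i,i+4 distance mode: {mode4:.3f} nm  (H-bond well at 0.61 nm)")
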