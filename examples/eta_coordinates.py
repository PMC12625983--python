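"""η-coordinates: separating constrained from invisible weight directions.

Builds the extended basis Xext = [X | completion] for a random task, shows
that the first P η columns are exactly the input currents, and that moving
the remaining columns changes the weights without moving any current.
"""

import numpy as np

import driftlab as dl

cfg = dl.NetworkConfig()
task = dl.generate_task(cfg, seed=0)
frame = dl.build_extended_basis(task.X)

U = np.random.default_rng(1).normal(0, 1, (cfg.Ny, cfg.Nx))
state = dl.to_eta(U, frame)

print("first P eta columns equal U X:",
      np.allclose(state.eta[:, : cfg.P], U @ task.X))
print("per-column noise scales s_mu:", np.round(frame.scales, 3))

state.eta[:, cfg.P :] += 100.0  # huge move in the unconstrained block
U2 = dl.from_eta(state)
print("weights changed by:", float(np.linalg.norm(U2 - U)))
print("currents changed by:", float(np.max(np.abs(U2 @ task.X - U @ task.X))))

kb = dl.engaged_kernel(task.W, [0, 1, 2, 3])
print("engaged kernel of 4 neurons under a 1-D readout has", kb.dim, "dimensions")

# What to look for: the unconstrained block absorbs an enormous weight change
# with zero effect on any input current (the change lives in the kernel of
# X), and an engaged set of E neurons leaves E - Nz directions of activity
# change invisible to the readout.
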