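"""Relative strength variability on hand-sized networks.

Builds a unit-weight star and a ring lattice, computes relative node
strengths, RSV and sliding-window hRSV, and shows why the star (extreme
core-periphery mixing) scores high while the lattice (every node alike)
scores zero.
"""

import numpy as np

from rsvnet import GeneratorSpec, WeightedNetwork, generate, hrsv, relative_strengths, rsv

# a 6-node star: one hub tied to five leaves with unit weights
W = np.zeros((6, 6))
W[0, 1:] = W[1:, 0] = 1.0
star = WeightedNetwork.from_matrix(W)

prof = relative_strengths(star, corrected=False)
print("star relative strengths:", np.round(prof.r, 3))
print("star RSV (uncorrected): ", round(rsv(star, corrected=False).value, 4))

# ring lattice at the same size: every node has the same neighbourhood,
# so every relative strength is 1 and both measures vanish
lattice = generate(GeneratorSpec(family="lattice", n=20, density=0.2,
                                 weight_model="uniform", seed=0))
print("lattice RSV:            ", round(rsv(lattice, corrected=False).value, 6))
print("lattice hRSV (w=4):     ", round(hrsv(lattice, 4, corrected=False).value, 6))

# the hub's strength is 5x any leaf's, and each leaf's context is the hub:
# r_hub = 5, r_leaf = 1/5 -> the spread of r is what RSV quantifies.
# A value of 0 means perfectly homogeneous local context everywhere.
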