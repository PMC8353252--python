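"""Geometric hydrogen-bond counting and the stacked-ring maximum.

Counts H-bonds with the standard geometric criterion (donor–acceptor
distance ≤ 3.5 Å, donor–hydrogen–acceptor angle ≥ 150°) on a small
constructed frame, and evaluates the theoretical maximum of inter-ring
backbone H-bonds for a tube of eight stacked cyclic peptides where each
adjacent ring pair can form 12 bonds.
"""

import numpy as np

from poredyn import HBondCriteria, count_hbonds, theoretical_max_hbonds

# a linear bond, a bent (rejected) geometry, and a too-distant acceptor
positions = np.array([
    [0.0, 0.0, 0.0],   # donor N
    [1.0, 0.0, 0.0],   # its H
    [2.9, 0.0, 0.0],   # acceptor O, linear → counts
    [0.0, 2.9, 0.0],   # acceptor O, 90° at H → rejected
    [6.0, 0.0, 0.0],   # acceptor O, 5 Å away → rejected
])
n, bonds = count_hbonds(positions, donors=[(0, 1)], acceptors=[2, 3, 4],
                        criteria=HBondCriteria(3.5, 150.0))
print(f"bonds found            : {n} -> {bonds}")

max_bonds = theoretical_max_hbonds(n_rings=8, bonds_per_interface=12)
print(f"8-ring theoretical max : {max_bonds} inter-ring H-bonds")
# 7 ring-ring interfaces × 12 bonds each = 84: the ceiling against which a
# channel's measured backbone H-bond count is judged.
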