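"""Jarvis-Patrick conformational clustering on a planted two-state ensemble.

Builds frames jittering around two well-separated conformers, clusters the
pairwise-RMSD matrix and extracts the representative (medoid) structure of
the largest cluster.
"""

import numpy as np

from rindyn.cluster import jarvis_patrick, representative, rmsd_matrix
from rindyn.synth import gen_multistate_traj

traj, labels = gen_multistate_traj(k=2, per_state_frames=30,
                                   intra_spread=0.01, inter_state_rmsd=1.0,
                                   seed=5)
mat = rmsd_matrix(traj, np.arange(traj.n_atoms))
assignment = jarvis_patrick(mat, m_neighbors=10, p_shared=3)

print(f"clusters found: {assignment.n_clusters}, sizes {assignment.sizes}")
biggest = int(np.argmax(assignment.sizes))
rep = representative(assignment, mat, biggest)
print(f"largest cluster: label {biggest}, representative frame {rep}, "
      f"true state of that frame: {labels[rep]}")
print("Two frames join a cluster when each is among the other's 10 nearest")
print("neighbours and they share >= 3 common neighbours; the medoid is the")
print("member closest to all others, used as the cluster's structure.")
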