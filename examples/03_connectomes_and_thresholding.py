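"""Build raw and microstructure-weighted connectomes; apply the two
supplementary thresholding schemes.

The raw connectome counts streamlines per node pair; the weighted one
uses the bundle's total intra-axonal signal fraction
a_ij = sum_k(x_k l_k) / mean bundle length.
"""

import numpy as np

import tractofit as tf
from tractofit.connectome import (consistency_threshold,
                                  proportional_threshold,
                                  random_group_connectomes,
                                  smn_parcellation_spec)

scheme = tf.make_gradient_scheme(seed=0)
phantom, tractogram = tf.two_bundle_phantom(seed=0)
tractogram = tf.add_spurious_streamlines(tractogram, phantom, n=30, seed=0)
volume = tf.simulate_dwi(phantom, scheme)
sm = tf.build_system_matrix(tractogram, phantom.grid_dims,
                            phantom.voxel_size, scheme, phantom.params,
                            phantom.ec_orientation_source())
fit = tf.fit_weights(sm, volume.ravel())

parc = smn_parcellation_spec(phantom.label_volume)
pairs = tf.assign_endpoints(tractogram, parc, phantom.voxel_size)
raw = tf.build_raw_connectome(pairs, parc.n_nodes, parc.node_labels)
kept = fit.streamline_weights > 1e-10
commit = tf.build_commit_connectome(
    pairs, np.where(kept, fit.streamline_weights, 0.0),
    tractogram.lengths(), parc.n_nodes, parc.node_labels)

print(f"parcellation: {parc.n_nodes} sensory-motor nodes, "
      f"{parc.n_nodes * (parc.n_nodes - 1) // 2} possible connections")
ij = np.transpose(np.nonzero(np.triu(raw.matrix, 1)))
for i, j in ij:
    print(f"  {parc.node_labels[i]} - {parc.node_labels[j]}: "
          f"count {raw.matrix[i, j]:.0f}, "
          f"signal fraction {commit.matrix[i, j]:.4f}")

# thresholding on a synthetic 10-subject cohort of 14-node connectomes
subjects = random_group_connectomes(10, seed=0)
prop = proportional_threshold(subjects[0], 0.5)
cons = consistency_threshold(subjects, target_density=0.30)
print(f"proportional 50%: {subjects[0].n_edges} -> {prop.n_edges} edges")
print(f"consistency 30%: every subject at density "
      f"{cons[0].binary_density() * 100:.2f}% "
      f"(28 of 91 possible edges, common group mask)")
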