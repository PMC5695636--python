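"""Two dimensionality questions, answered on constructions with known truth.

1. Global dimension by the sliver scan: a flat 2-D patch embedded in 6-D
   should be called 2-dimensional for most tolerance values.
2. Per-cluster component count against a Gaussian-noise null: an exactly
   planar cluster spans 2 genuine axes, hence 3 simplex vertices; isotropic
   noise should rarely support more than 2.
"""
import numpy as np

from scunmix import (estimate_cluster_components, estimate_global_dimension,
                     pca_embed)

rng = np.random.default_rng(0)

B = np.linalg.qr(rng.normal(size=(6, 2)))[0]
plane = rng.uniform(size=(400, 2)) @ B.T
dims = estimate_global_dimension(pca_embed(plane, 6))
print(f"sliver scan, planar patch in 6-D -> candidate dims {sorted(dims)}")
print(f"  (each with a representative tolerance delta: {dims})")

k_planar = estimate_cluster_components(rng.uniform(-3, 3, (200, 2)) @ B.T,
                                       rng=rng)
k_noise = estimate_cluster_components(rng.standard_normal((200, 6)), rng=rng)
print(f"cluster component count, planar cluster  : {k_planar} (expected 3)")
print(f"cluster component count, isotropic noise : {k_noise} (expected <= 2)")
print()
print("A cluster with q genuine axes of variation is modelled as a"
      "\nq-simplex, i.e. q+1 mixture components.")
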