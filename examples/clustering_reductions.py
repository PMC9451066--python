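"""Relate Archetypal Analysis to K-Means and K-Medoids on 2-D blobs.

Restricting the alpha rows to one-hot vectors (and freeing the centers)
gives Lloyd's K-Means; restricting both alpha and beta to one-hot gives
K-Medoids, whose centers must be observed points.  Full AA instead puts
its archetypes at the extremes of the point cloud and describes every
sample as a mixture of them.
"""

import numpy as np

from archepop import AAConfig, fit, kmeans_binary_alpha, kmedoids_binary

rng = np.random.default_rng(0)
blobs = np.vstack([rng.normal(c, 0.4, size=(40, 2)) for c in ([0, 0], [6, 0], [3, 5])])

km = kmeans_binary_alpha(blobs, K=3, seed=2)
kmed = kmedoids_binary(blobs, K=3, seed=2)
aa = fit(blobs, AAConfig(K=3, seed=1))

print(f"K-Means   : inertia={km.inertia:8.2f}, centers are cluster means")
print(f"K-Medoids : inertia={kmed.inertia:8.2f}, centers are observed points")
print(f"AA        : RSS    ={aa.rss:8.2f}, archetypes are convex combos of points")
print()
frac_mixed = float((aa.alpha.max(axis=1) < 0.95).mean())
print(f"fraction of samples AA treats as mixtures (max alpha < 0.95): {frac_mixed:.2f}")
print("-> the hard methods give one label per point; AA additionally grades")
print("   every point between the extremes, which is what admixture analysis needs.")
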