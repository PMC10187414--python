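"""Topographic primitives: average reference, GFP, spatial correlation.

Builds a tiny 12-channel topography and shows the quantities every later
stage is built from.
"""
import numpy as np

import ernstates as es

montage = es.make_montage(12)
rng = np.random.default_rng(0)
u = es.average_reference(rng.standard_normal(12))
v = es.average_reference(rng.standard_normal(12))

print(f"GFP(u)  = {es.compute_gfp(u):.4f} uV   (spatial SD of the map)")
print(f"corr(u, v, variant)   = {es.spatial_correlation(u, v, 'variant'):+.4f}")
print(f"corr(u, -u, variant)  = {es.spatial_correlation(u, -u, 'variant'):+.4f}")
print(f"corr(u, -u, invariant)= {es.spatial_correlation(u, -u, 'invariant'):+.4f}")
print("Polarity-invariant correlation treats a map and its mirror as the same state.")
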