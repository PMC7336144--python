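"""Compute the weighted graph-metric panel of a connectome.

Six global measures (modularity, global efficiency, clustering,
mean strength, assortativity, density) plus nodal strength and local
efficiency per node, in the standard weighted formulations (edge length
= 1/weight, Onnela clustering).
"""

from tractofit.connectome import degrade_connectome, random_group_connectomes
from tractofit.metrics import metric_panel

healthy = random_group_connectomes(1, seed=5)[0]
patient_like = degrade_connectome(healthy, scale_fraction=0.3,
                                  scale_factor=0.5, delete_fraction=0.15,
                                  seed=5)

for name, c in (("healthy-like", healthy), ("degraded", patient_like)):
    p = metric_panel(c, seed=0)
    print(f"{name}: density={p.density:.3f} "
          f"mean_strength={p.mean_strength:.3f} "
          f"global_efficiency={p.global_efficiency:.3f} "
          f"clustering={p.clustering_coefficient:.3f} "
          f"modularity={p.modularity:.3f} "
          f"assortativity={p.assortativity:.3f}")
# Lesion-like degradation (weaker + fewer edges) lowers strength and
# efficiency and raises modularity: the expected disease direction.
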