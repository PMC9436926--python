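"""Seed-based structural covariance mapping.

Correlates the left-NBM qT1 seed with every cortical and subcortical
vertex across subjects; FDR is applied within each structure (q < 0.10).
"""

from bftx.simulate import SurfaceConfig, generate_cohort, generate_surfaces
from bftx.covariance import map_covariance, summarize_map

subjects, roi, _ = generate_cohort(seed=2)
surface = generate_surfaces(subjects, roi,
                            SurfaceConfig(n_vertices_per_hemi=600),
                            seed=3)

cov = map_covariance(surface, roi, seed_region="NBM_L", metric="qt1")
print(f"{len(cov)} vertices mapped; "
      f"{int(cov.passes_fdr.sum())} pass FDR q < 0.10 "
      "(q computed within each structure separately)")

cortex = cov[cov.structure == "cortex-L"]
summary = summarize_map(cortex)
print("\nleft-cortex label summary (mean seed-vertex correlation):")
print(summary[["label", "n_units", "mean_r", "n_passing_fdr"]]
      .to_string(index=False))
print("\n  -> the 'frontal' patch carries the positive lobe of the planted")
print("     projection field, so it ranks first by mean r, mirroring how")
print("     real BF-cortical covariance follows cholinergic projections")
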