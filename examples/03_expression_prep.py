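"""Expression preprocessing: probe collapsing, sample QC and
sample-to-vertex matching with the 10 mm rule.
"""

from bftx.ahba import (SampleQCRules, match_samples_to_vertices, qc_samples,
                       select_probes)
from bftx.pipeline import BF_CENTERS
from bftx.simulate import (ExpressionConfig, SurfaceConfig, generate_cohort,
                           generate_expression, generate_surfaces, GroundTruth)

subjects, roi, truth = generate_cohort(seed=4)
surface = generate_surfaces(subjects, roi,
                            SurfaceConfig(n_vertices_per_hemi=600), seed=5)
bundle = generate_expression(surface, ExpressionConfig(n_genes=800), seed=6,
                             truth=truth)

gene_expr, mapping, dropped = select_probes(bundle.probes, bundle.expression)
print(f"probes: {len(bundle.probes)} -> genes: {len(gene_expr)} "
      f"({len(dropped)} genes had no QC-passing probe)")

rules = SampleQCRules(bounding_spheres={
    lab: (ctr, 15.0) for lab, ctr in BF_CENTERS.items()})
samples_qc, log = qc_samples(bundle.samples, rules)
print(f"sample QC: removed {log['removed']['out_of_region_Ch1-3']} "
      f"(the planted mislabelled BF sample); retained "
      f"{log['counts_by_label']['NBM']} NBM + "
      f"{log['counts_by_label']['Ch1-3']} Ch1-3 samples")

cortical = samples_qc[(samples_qc.structure_label == "cortex")
                      & (samples_qc.x < 0)]
matches, summary = match_samples_to_vertices(cortical, surface.vertices)
print(f"matching: {summary['n_retained']} of {summary['n_samples']} left-"
      f"cortical samples retained "
      f"(mean distance {summary['mean_distance']:.2f} mm, "
      f"{summary['n_over_distance']} removed by the 10 mm rule, "
      f"{summary['n_duplicate_vertex']} lost vertex dedup)")
print("  -> each retained sample is matched one-to-one to its nearest "
      "cortical vertex")
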