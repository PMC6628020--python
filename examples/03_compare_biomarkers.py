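"""Rank candidate biomarkers by pooled diagnostic performance.

Runs the full pipeline (normalize -> classify -> pool -> SROC) for the
simulated marker and a handful of noise genes over one study set, producing
one comparable report row per gene.
"""

from dtameta import PipelineConfig, generate_paperlike_set, reports_to_frame, run_pipeline

studyset = generate_paperlike_set(seed=5, n_noise_genes=20)
genes = ["CHGA"] + [f"NOISE{g:04d}" for g in range(5)]

reports = run_pipeline(studyset, genes, PipelineConfig(min_samples=30))
df = reports_to_frame(reports).sort_values("dor", ascending=False)
print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nThe shifted marker tops the table by DOR and AUC; noise genes sit")
print("near DOR 1 / AUC 0.5-0.6, the no-discrimination regime.")
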