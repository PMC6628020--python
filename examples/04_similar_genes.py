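"""Rank genes by expression similarity to a target biomarker.

Pearson correlation of every gene against the target, computed within each
cohort and averaged across cohorts; co-expressed genes are candidates for
further biomarker screening.  Also exports boxplot-style group summaries of
the target gene.
"""

from dtameta import generate_paperlike_set, group_summaries, similar_genes

studyset = generate_paperlike_set(seed=2, n_noise_genes=30)

top = similar_genes(studyset, "CHGA", k=5)
print("genes most correlated with CHGA (mean within-cohort Pearson r):")
print(top.to_string(index=False, float_format=lambda v: f"{v:+.3f}"))

print("\nCHGA per-cohort five-number summaries:")
df = group_summaries(studyset, "CHGA")
print(df.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print("\nCase medians sit below control medians in every cohort: the")
print("simulated marker is down-regulated in disease, as configured.")
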