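"""Generate a paired tumor/normal multi-omics cohort with planted signal.

Builds the default synthetic study — 60 patients, 30 with matched
normals, three omics layers plus copy-number segments, targets and a
PPI graph — and prints what was planted where.
"""

from omicshub import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(seed=1))
t = cohort.truth

print("expression matrix:", cohort.expression.values.shape, "(genes x samples)")
print("miRNA matrix:     ", cohort.mirna.values.shape)
print("methylation sites:", cohort.methylation.values.shape)
print("copy-number segments:", len(cohort.segments.df))
print("PPI edges:", len(cohort.ppi_edges), " target pairs:", len(cohort.targets.df))
print()
print(f"planted DE genes: {len(t.de_genes_up)} up, {len(t.de_genes_down)} down")
print(f"planted miRNA repression pairs: {len(t.planted_pairs)}")
print(f"planted methylation genes: {len(t.planted_meth)}")
print(f"planted copy-number genes: {len(t.planted_cna)}")
print("planted key (hub) genes:", dict(t.key_gene_mechanism))

# The key genes are wired as PPI hubs; downstream stages should recover
# them as top-ranked nodes of their mechanism's subnetwork.
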