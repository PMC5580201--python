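"""PCA differentiation: do the significant genes separate the two groups?

Builds a samples x genes matrix (per-sample mean log2 ratio over each
BH-significant gene), projects the 12 samples on the top two principal
components, and prints each sample's PC1 score plus one per-gene loading
profile.  By convention the case group's mean PC1 score is non-negative.
"""

from snpscan import (
    SyntheticSpec,
    build_gene_snp_index,
    gene_feature_matrix,
    gene_pc1_profile,
    generate_dataset,
    normalize_intensities,
    principal_components,
    scan_genome,
)

raw, snp_map, genes, groups, truth = generate_dataset(SyntheticSpec(seed=1))
norm = normalize_intensities(raw)
index = build_gene_snp_index(snp_map, genes)
results, _ = scan_genome(norm, index, groups)
significant = {r.gene_id for r in results if r.bh_significant_mean}

fm = gene_feature_matrix(norm, index, significant)
pca = principal_components(fm, d=2, case_samples=groups.case_samples)
evr = pca.explained_variance_ratio
print(f"PCA over {len(fm.features)} significant genes; "
      f"PC1 explains {100 * evr[0]:.1f}%, PC2 {100 * evr[1]:.1f}% of variance")
for sample, score in zip(pca.samples, pca.scores[:, 0]):
    print(f"  {sample:10s} PC1 = {score:+.3f}  ({groups.group_of(sample)})")
# Positive PC1 scores for cases and negative for controls means a single
# threshold separates the groups.

planted = sorted(truth.effect_genes)[0]
gene = next(g for g in index if g.gene_id == planted)
profile = gene_pc1_profile(gene, norm, groups)
print(f"\nPC1 loading profile for planted gene {planted} (unit max, ascending):")
for sample, value in profile.items():
    print(f"  {sample:10s} {value:+.3f}")
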