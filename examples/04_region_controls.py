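"""Region-level controls: arbitrary regions, flanks, CNV filtering, coverage.

Shows the negative controls that frame a gene scan: a random intergenic
region should test null; a gene's flanking markers should test null even
when the gene itself is significant; segment calls must clear the
3-marker / 1-kb declaration filter; pathway coverage summarizes how much
of a pathway the eligible genes reach.
"""

from snpscan import (
    Region,
    SegmentCall,
    SyntheticSpec,
    build_gene_snp_index,
    cnv_declaration_filter,
    generate_dataset,
    mean_flanking_pvalue,
    normalize_intensities,
    pathway_coverage,
    region_length,
    region_test,
    scan_genome,
)

raw, snp_map, genes, groups, truth = generate_dataset(SyntheticSpec(seed=1))
norm = normalize_intensities(raw)
index = build_gene_snp_index(snp_map, genes)
results, _ = scan_genome(norm, index, groups)

# test a planted gene's span, then its flanking markers
planted = sorted(truth.effect_genes)[0]
hit = next(r for r in results if r.gene_id == planted)
region = Region(hit.chrom, hit.start, hit.end)
p_var, p_mean, n = region_test(region, snp_map, norm, groups)
print(f"{planted} span ({region_length(region)} bp, {n} markers): "
      f"p_mean = {p_mean:.2e} (significant: planted effect)")
p_flank = mean_flanking_pvalue(region, snp_map, norm, groups, k=5)
print(f"mean p of 5-marker flanks around {planted}: {p_flank:.2f} "
      f"(null: the effect stops at the gene boundary)")

# an intergenic stretch between genes is a built-in negative control
null_region = Region(hit.chrom, hit.end + 100, hit.end + 5000)
try:
    _, p_null, n_null = region_test(null_region, snp_map, norm, groups)
    print(f"intergenic control region ({n_null} markers): p_mean = {p_null:.2f}")
except Exception as e:
    print(f"intergenic control region: {e}")

# copy-number segment declaration: >=3 adjacent markers and >=1 kb
calls = [
    SegmentCall(Region("chr1", 10_000, 11_000), "loss", 3),   # boundary: kept
    SegmentCall(Region("chr1", 20_000, 70_000), "gain", 2),   # too few markers
    SegmentCall(Region("chr2", 5_000, 5_800), "loss", 6),     # too short
]
kept = cnv_declaration_filter(calls)
print(f"CNV declaration filter kept {len(kept)} of {len(calls)} calls")

# pathway coverage arithmetic over eligible / significant genes
eligible = {r.gene_id for r in results}
significant = {r.gene_id for r in results if r.bh_significant_mean}
pathway = set(list(eligible)[:40]) | {"EXT_1", "EXT_2"}  # 2 genes not on array
row = pathway_coverage("demo_pathway", pathway, eligible, significant)
print(f"pathway of {row.kegg_genes} genes: {row.total_genes} eligible "
      f"({row.coverage_pct}% coverage), {row.significant} significant "
      f"+ {row.non_significant} not")
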