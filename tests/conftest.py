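"""Shared fixtures: small seeded synthetic datasets."""

import pytest

from snpscan import (
    ScanConfig,
    SyntheticSpec,
    build_gene_snp_index,
    generate_dataset,
    normalize_intensities,
    scan_genome,
)


@pytest.fixture(scope="session")
def small_dataset():
    """60 genes, 6 vs 6 samples, 10% planted mean-shift effects."""
    spec = SyntheticSpec(n_genes=60, n_chromosomes=3, seed=11)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_scan(small_dataset):
    raw, snp_map, genes, groups, truth = small_dataset
    norm = normalize_intensities(raw)
    index = build_gene_snp_index(snp_map, genes)
    results, skips = scan_genome(norm, index, groups, ScanConfig())
    return {
        "raw": raw,
        "snp_map": snp_map,
        "genes": genes,
        "groups": groups,
        "truth": truth,
        "norm": norm,
        "index": index,
        "results": results,
        "skips": skips,
    }
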