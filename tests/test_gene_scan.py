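"""Gene-windowed scan: indexing, group vectors, tests, BH correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from snpscan import (
    DegenerateGeneError,
    GeneSet,
    ScanConfig,
    SnpMap,
    SyntheticSpec,
    UndefinedTestError,
    ValidationError,
    benjamini_hochberg,
    build_gene_snp_index,
    build_group_vectors,
    generate_dataset,
    normalize_intensities,
    scan_genome,
    select_eligible_genes,
    two_sample_tests,
)
from snpscan.normalization import NormalizedMatrix


def _snp_map(rows):
    return SnpMap(pd.DataFrame(rows, columns=["marker_id", "chrom", "pos"]))


def _genes(rows):
    return GeneSet(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "category"])
    )


class TestGeneSnpIndex:
    def test_boundary_inclusion(self):
        snps = _snp_map(
            [(f"M{p}", "chr1", p) for p in (99, 100, 150, 200, 201)]
        )
        genes = _genes([("G1", "chr1", 100, 200, "RefSeq")])
        idx = build_gene_snp_index(snps, genes)
        assert list(idx[0].positions) == [100, 150, 200]

    def test_overlapping_genes_share_markers(self):
        snps = _snp_map([("Ma", "chr1", 150)])
        genes = _genes(
            [("G1", "chr1", 100, 200, "x"), ("G2", "chr1", 120, 300, "x")]
        )
        idx = build_gene_snp_index(snps, genes)
        assert idx[0].markers == ["Ma"] and idx[1].markers == ["Ma"]

    def test_zero_snp_genes_kept_with_empty_lists(self):
        snps = _snp_map([("Ma", "chr2", 5)])
        genes = _genes([("G1", "chr1", 1, 10, "x")])
        idx = build_gene_snp_index(snps, genes)
        assert idx[0].n_snps == 0

    def test_matches_brute_force_all_pairs_scan(self):
        rng = np.random.default_rng(5)
        positions = rng.choice(10_000, size=50, replace=False) + 1
        chroms = rng.choice(["chr1", "chr2"], size=50)
        snps = _snp_map(
            [(f"M{i}", chroms[i], int(positions[i])) for i in range(50)]
        )
        gene_rows = []
        for g in range(5):
            s = int(rng.integers(1, 9000))
            gene_rows.append((f"G{g}", rng.choice(["chr1", "chr2"]), s, s + 1500, "x"))
        genes = _genes(gene_rows)
        idx = build_gene_snp_index(snps, genes)
        for g_row, entry in zip(gene_rows, idx):
            expected = {
                f"M{i}"
                for i in range(50)
                if chroms[i] == g_row[1] and g_row[2] <= positions[i] <= g_row[3]
            }
            assert set(entry.markers) == expected
            assert list(entry.positions) == sorted(entry.positions)


class TestEligibility:
    def test_threshold_boundary(self):
        snps = _snp_map(
            [(f"M{g}_{i}", "chr1", 1000 * g + i) for g in (1, 2, 3) for i in range(1, 14 + g)]
        )
        genes = _genes(
            [(f"G{g}", "chr1", 1000 * g, 1000 * g + 999, "x") for g in (1, 2, 3)]
        )
        idx = build_gene_snp_index(snps, genes)
        assert [e.n_snps for e in idx] == [14, 15, 16]
        kept = select_eligible_genes(idx, ScanConfig(min_snps=15))
        assert [e.gene_id for e in kept] == ["G2", "G3"]

    def test_empty_index(self):
        assert select_eligible_genes([], ScanConfig()) == []

    def test_straddling_range_matches_recount(self):
        spec = SyntheticSpec(
            n_genes=50, snps_per_gene_range=(10, 20), seed=23
        )
        _, snp_map, genes, *_ = generate_dataset(spec)
        idx = build_gene_snp_index(snp_map, genes)
        kept = {e.gene_id for e in select_eligible_genes(idx, ScanConfig())}
        # independent recount from the raw tables
        m = snp_map.table
        expected = set()
        for row in genes.table.itertuples():
            n = (
                (m["chrom"] == row.chrom)
                & (m["pos"] >= row.start)
                & (m["pos"] <= row.end)
            ).sum()
            if n >= 15:
                expected.add(row.gene_id)
        assert kept == expected


class TestGroupVectors:
    def test_full_gene_lengths(self, small_scan):
        gene = next(e for e in small_scan["index"] if e.n_snps == 15)
        case, control = build_group_vectors(
            gene, small_scan["norm"], small_scan["groups"]
        )
        assert len(case) == 90 and len(control) == 90

    def test_masked_cell_dropped(self, small_scan):
        gene = next(e for e in small_scan["index"] if e.n_snps == 15)
        norm = small_scan["norm"]
        groups = small_scan["groups"]
        masked = NormalizedMatrix(
            snps=list(norm.snps),
            samples=list(norm.samples),
            value=norm.value.copy(),
            mask=norm.mask.copy(),
            reference=norm.reference,
        )
        row = masked.snp_index(gene.markers)[0]
        col = masked.sample_index([groups.case_samples[0]])[0]
        masked.mask[row, col] = True
        case, control = build_group_vectors(gene, masked, groups)
        assert len(case) == 89 and len(control) == 90

    def test_matches_nested_loop_gather(self, small_scan):
        gene = small_scan["index"][3]
        norm = small_scan["norm"]
        groups = small_scan["groups"]
        case, control = build_group_vectors(gene, norm, groups)
        for vec, sample_ids in ((case, groups.case_samples), (control, groups.control_samples)):
            expected = []
            for marker in gene.markers:  # positional order
                i = norm.snps.index(marker)
                for s in sample_ids:  # input sample order
                    j = norm.samples.index(s)
                    if not norm.mask[i, j]:
                        expected.append(norm.value[i, j])
            np.testing.assert_array_equal(vec, expected)

    def test_too_few_values_is_degenerate(self, small_scan):
        gene = small_scan["index"][0]
        norm = small_scan["norm"]
        groups = small_scan["groups"]
        fully_masked = NormalizedMatrix(
            snps=list(norm.snps),
            samples=list(norm.samples),
            value=norm.value.copy(),
            mask=np.ones_like(norm.mask),
            reference=norm.reference,
        )
        with pytest.raises(DegenerateGeneError):
            build_group_vectors(gene, fully_masked, groups)


class TestTwoSampleTests:
    def test_identical_vectors_give_p_one(self):
        p_var, p_mean = two_sample_tests([1, 2, 3], [1, 2, 3])
        assert p_mean == 1.0 and p_var == 1.0

    def test_f_tail_matches_quadrature_oracle(self):
        # (1,2,3) vs (2,4,6): F = 1/4 on (2, 2) df
        p_var, _ = two_sample_tests([1, 2, 3], [2, 4, 6])
        f_obs = 0.25

        def f_pdf(x):
            return stats.f.pdf(x, 2, 2)

        lower, _ = integrate.quad(f_pdf, 0, f_obs)
        upper, _ = integrate.quad(f_pdf, f_obs, np.inf)
        expected = 2 * min(lower, upper)
        assert p_var == pytest.approx(expected, rel=1e-8)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 2, 9)
        assert two_sample_tests(x, y) == pytest.approx(two_sample_tests(y, x))

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            x = rng.normal(0, 1, int(rng.integers(3, 40)))
            y = rng.normal(0.3, 1.7, int(rng.integers(3, 40)))
            _, p_mean = two_sample_tests(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False).pvalue
            assert p_mean == pytest.approx(ref, rel=1e-10)

    def test_both_variances_zero_undefined(self):
        with pytest.raises(UndefinedTestError):
            two_sample_tests([1.0, 1.0], [2.0, 2.0])

    def test_short_vector_rejected(self):
        with pytest.raises(DegenerateGeneError):
            two_sample_tests([1.0], [1.0, 2.0])


def _bh_oracle(p, alpha):
    """Test every threshold index directly (step-up rule, brute force)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= alpha * i / m:
            k = i
    flags = [False] * m
    for i in range(k):
        flags[order[i]] = True
    return flags, k


class TestBenjaminiHochberg:
    def test_worked_example(self):
        # thresholds (0.0125, 0.025, 0.0375, 0.05) -> k = 2
        flags, k = benjamini_hochberg([0.01, 0.02, 0.04, 0.8], alpha=0.05)
        assert k == 2
        assert list(flags) == [True, True, False, False]

    def test_all_ones_nothing_significant(self):
        flags, k = benjamini_hochberg([1.0] * 7, alpha=0.05)
        assert k == 0 and not flags.any()

    def test_uniform_boundary_everything_significant(self):
        m = 9
        flags, k = benjamini_hochberg([0.05 / m] * m, alpha=0.05)
        assert k == m and flags.all()

    def test_step_up_jump(self):
        # P(3) qualifies even though P(2) does not: step-up keeps all three
        flags, k = benjamini_hochberg([0.001, 0.030, 0.035, 0.9], alpha=0.05)
        assert k == 3

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(100):
            p = rng.uniform(1e-6, 1.0, int(rng.integers(1, 40)))
            flags, _ = benjamini_hochberg(p, 0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(flags, ref)

    @given(
        st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=20),
        st.floats(min_value=0.01, max_value=0.5),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_matches_brute_force_oracle(self, p, alpha):
        flags, k = benjamini_hochberg(p, alpha)
        exp_flags, exp_k = _bh_oracle(p, alpha)
        assert k == exp_k and list(flags) == exp_flags

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_significant_count_monotone_in_alpha(self, p):
        counts = [benjamini_hochberg(p, a)[1] for a in (0.01, 0.05, 0.1, 0.25)]
        assert counts == sorted(counts)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([], 0.05)
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.0, 0.5], 0.05)
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.5], 1.5)


class TestScanGenome:
    def test_every_eligible_gene_tested(self, small_scan):
        eligible = select_eligible_genes(small_scan["index"], ScanConfig())
        assert len(small_scan["results"]) + len(small_scan["skips"]) == len(eligible)
        for r in small_scan["results"]:
            assert 0 < r.p_mean <= 1 and 0 < r.p_variance <= 1

    def test_strongly_shifted_gene_is_argmin_and_flagged(self):
        spec = SyntheticSpec(
            n_genes=40,
            effect_gene_fraction=1 / 40,  # exactly one planted gene
            mean_shift_delta=2.0,
            sample_noise_sd=0.2,
            seed=17,
        )
        raw, snp_map, genes, groups, truth = generate_dataset(spec)
        norm = normalize_intensities(raw)
        idx = build_gene_snp_index(snp_map, genes)
        results, _ = scan_genome(norm, idx, groups)
        (planted,) = truth.effect_genes
        best = min(results, key=lambda r: r.p_mean)
        assert best.gene_id == planted
        assert best.bh_significant_mean

    def test_zero_eligible_genes_empty_result(self, small_scan):
        results, skips = scan_genome(
            small_scan["norm"],
            small_scan["index"],
            small_scan["groups"],
            ScanConfig(min_snps=1000),
        )
        assert results == [] and skips == []

    def test_bh_flags_consistent_with_rule(self, small_scan):
        results = small_scan["results"]
        flags, _ = benjamini_hochberg([r.p_mean for r in results], 0.05)
        assert [r.bh_significant_mean for r in results] == list(flags)
        flags_v, _ = benjamini_hochberg([r.p_variance for r in results], 0.05)
        assert [r.bh_significant_variance for r in results] == list(flags_v)

    def test_null_pvalues_approximately_uniform(self):
        """Pooled mean-test p-values under the complete null pass a KS check."""
        pooled = []
        for seed in range(10):
            spec = SyntheticSpec(
                n_genes=300,
                n_chromosomes=3,
                effect_gene_fraction=0.0,
                seed=100 + seed,
            )
            raw, snp_map, genes, groups, _ = generate_dataset(spec)
            norm = normalize_intensities(raw)
            idx = build_gene_snp_index(snp_map, genes)
            results, _ = scan_genome(norm, idx, groups)
            pooled.extend(r.p_mean for r in results)
        assert len(pooled) >= 2000
        d = stats.kstest(pooled, "uniform").statistic
        assert d < 0.05

    def test_power_monotone_in_mean_shift(self):
        """Average power over matched seeds is non-decreasing in the shift."""
        from snpscan import evaluate_recovery

        powers = []
        for shift in (0.25, 0.5, 1.0):
            vals = []
            for seed in range(20):
                spec = SyntheticSpec(
                    n_genes=100,
                    n_chromosomes=2,
                    mean_shift_delta=shift,
                    seed=500 + seed,
                )
                raw, snp_map, genes, groups, truth = generate_dataset(spec)
                norm = normalize_intensities(raw)
                idx = build_gene_snp_index(snp_map, genes)
                results, _ = scan_genome(norm, idx, groups)
                vals.append(evaluate_recovery(results, truth).power)
            powers.append(np.mean(vals))
        assert powers == sorted(powers)
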