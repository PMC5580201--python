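"""Synthetic two-group SNP-array intensity datasets with planted effects.

The generator emulates the study design the pipeline targets: two groups of
samples (diseased vs healthy), hundreds of thousands of biallelic markers,
and gene windows of variable marker counts.  Each marker's total
log2-intensity is a per-marker baseline plus Gaussian sample noise; in a
chosen fraction of genes the case group receives a log2 mean shift and/or a
noise-sd inflation.  The total intensity T = 2^t is split into allele
intensities A = u·T (u ~ Uniform(0.05, 0.95)) and B = T − A, so A + B
reconstructs T bit-for-bit and all intensities are strictly positive.

Effects are planted on T, not on the A/B split, because the analysis uses
only T.  One seed drives one ``numpy.random.default_rng`` stream; the draw
order is fixed (baselines, then effect-gene choice, then noise, then the
A/B split), so identical specs give bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ValidationError
from .gene_scan import GeneScanResult
from .io_formats import (
    CASE,
    CONTROL,
    GeneSet,
    GroupAssignment,
    RawIntensitySet,
    SnpMap,
)

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "RecoveryMetrics",
    "generate_dataset",
    "evaluate_recovery",
    "write_truth_table",
]

_CATEGORIES = ("RefSeq", "mRNA", "maseq", "protein-coding")

# intra-gene marker spacing and inter-gene gap, in bp
_SNP_SPACING = 100
_GENE_GAP = 10_000


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters.  Defaults are the study conditions:

    6 diseased vs 6 healthy samples, log2-scale sample noise sd 0.3, 10% of
    genes carrying a +1.0 log2 mean shift in the case group, all genes
    meeting the 15-marker eligibility threshold.
    """

    n_case: int = 6
    n_control: int = 6
    n_chromosomes: int = 5
    n_genes: int = 1000
    snps_per_gene_range: tuple[int, int] = (15, 20)
    intergenic_snps_per_gene: int = 5
    baseline_log_mean: float = 10.0
    baseline_log_sd: float = 0.5
    sample_noise_sd: float = 0.3
    effect_gene_fraction: float = 0.1
    mean_shift_delta: float = 1.0
    variance_inflation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValidationError("need at least 2 samples per group")
        if self.n_chromosomes < 1 or self.n_genes < 1:
            raise ValidationError("need at least one chromosome and one gene")
        lo, hi = self.snps_per_gene_range
        if not (1 <= lo <= hi):
            raise ValidationError("snps_per_gene_range must satisfy 1 <= min <= max")
        if self.intergenic_snps_per_gene < 0:
            raise ValidationError("intergenic_snps_per_gene must be >= 0")
        if self.sample_noise_sd < 0 or self.baseline_log_sd < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        if not 0.0 <= self.effect_gene_fraction <= 1.0:
            raise ValidationError("effect_gene_fraction must be in [0, 1]")
        if self.variance_inflation < 1.0:
            raise ValidationError("variance_inflation must be >= 1")


@dataclass
class SyntheticTruth:
    """Planted ground truth: which genes carry an effect, and how large."""

    effect_genes: set[str]
    mean_shift: dict[str, float] = field(default_factory=dict)
    variance_inflation: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class RecoveryMetrics:
    """Detection quality of a scan against planted truth."""

    tp: int
    fp: int
    fn: int
    fdr: float
    power: float


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[RawIntensitySet, SnpMap, GeneSet, GroupAssignment, SyntheticTruth]:
    """Generate one seeded dataset plus its planted truth.

    Genes are laid out as non-overlapping intervals along the chromosomes
    (round-robin), markers at a fixed 100-bp spacing inside genes and a
    block of intergenic markers after each gene; marker counts per gene are
    drawn uniformly from ``snps_per_gene_range``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.snps_per_gene_range
    snps_per_gene = rng.integers(lo, hi + 1, size=spec.n_genes)

    n_effect = int(round(spec.effect_gene_fraction * spec.n_genes))
    effect_idx = set(
        rng.choice(spec.n_genes, size=n_effect, replace=False).tolist()
    )

    gene_rows = []
    marker_rows = []
    snp_gene_of: list[int] = []  # -1 for intergenic
    cursors = {c: 0 for c in range(spec.n_chromosomes)}
    for g in range(spec.n_genes):
        chrom_i = g % spec.n_chromosomes
        chrom = f"chr{chrom_i + 1}"
        n = int(snps_per_gene[g])
        start = cursors[chrom_i] + _GENE_GAP
        end = start + (n - 1) * _SNP_SPACING + _SNP_SPACING // 2
        gene_id = f"G{g + 1:05d}"
        gene_rows.append(
            {
                "gene_id": gene_id,
                "chrom": chrom,
                "start": start,
                "end": end,
                "category": _CATEGORIES[g % len(_CATEGORIES)],
            }
        )
        for i in range(n):
            marker_rows.append(
                {
                    "marker_id": f"SNP_{chrom}_{start + i * _SNP_SPACING}",
                    "chrom": chrom,
                    "pos": start + i * _SNP_SPACING,
                }
            )
            snp_gene_of.append(g)
        inter_start = end + _GENE_GAP // 2
        for i in range(spec.intergenic_snps_per_gene):
            marker_rows.append(
                {
                    "marker_id": f"SNP_{chrom}_{inter_start + i * _SNP_SPACING}",
                    "chrom": chrom,
                    "pos": inter_start + i * _SNP_SPACING,
                }
            )
            snp_gene_of.append(-1)
        cursors[chrom_i] = inter_start + spec.intergenic_snps_per_gene * _SNP_SPACING

    genes = GeneSet(pd.DataFrame(gene_rows))
    snp_map = SnpMap(pd.DataFrame(marker_rows))
    n_snps = len(snp_map)
    snp_gene = np.asarray(snp_gene_of)

    samples = [f"case_{i + 1}" for i in range(spec.n_case)] + [
        f"control_{i + 1}" for i in range(spec.n_control)
    ]
    groups = GroupAssignment(
        pd.DataFrame(
            {
                "sample_id": samples,
                "group": [CASE] * spec.n_case + [CONTROL] * spec.n_control,
            }
        )
    )

    baseline = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, size=n_snps)
    noise = rng.normal(0.0, 1.0, size=(n_snps, len(samples)))

    sd = np.full((n_snps, len(samples)), spec.sample_noise_sd)
    shift = np.zeros((n_snps, len(samples)))
    if effect_idx:
        in_effect = np.isin(snp_gene, list(effect_idx))
        case_cols = np.arange(spec.n_case)  # case samples occupy the first columns
        shift[np.ix_(in_effect, case_cols)] = spec.mean_shift_delta
        sd[np.ix_(in_effect, case_cols)] *= spec.variance_inflation

    log_total = baseline[:, None] + shift + sd * noise
    total = np.exp2(log_total)
    u = rng.uniform(0.05, 0.95, size=(n_snps, len(samples)))
    # Split so A + B reconstructs T bit-for-bit: the larger share is >= T/2,
    # which makes the complementary subtraction exact in floating point.
    w = np.maximum(u, 1.0 - u)
    big = w * total
    small = total - big
    a = np.where(u >= 0.5, big, small)
    b = np.where(u >= 0.5, small, big)
    raw = RawIntensitySet(
        samples=samples,
        snps=snp_map.table["marker_id"].tolist(),
        a=a,
        b=b,
    )

    truth = SyntheticTruth(
        effect_genes={f"G{g + 1:05d}" for g in effect_idx},
        mean_shift={f"G{g + 1:05d}": spec.mean_shift_delta for g in effect_idx},
        variance_inflation={
            f"G{g + 1:05d}": spec.variance_inflation for g in effect_idx
        },
    )
    return raw, snp_map, genes, groups, truth


def evaluate_recovery(
    results: list[GeneScanResult],
    truth: SyntheticTruth,
    eligible: set[str] | None = None,
    family: str = "mean",
) -> RecoveryMetrics:
    """Score BH-significant calls against the planted effect genes.

    ``family`` selects which BH flag counts as a detection ("mean" or
    "variance").  ``eligible`` restricts the planted genes scored (planted
    genes below the marker-count threshold are not recoverable and are not
    counted as misses); it defaults to the genes present in ``results``.
    An eligible planted gene missing from the results is an inconsistency.
    """
    if family not in ("mean", "variance"):
        raise ValidationError("family must be 'mean' or 'variance'")
    result_ids = {r.gene_id for r in results}
    if eligible is None:
        eligible = result_ids
    else:
        missing = (truth.effect_genes & eligible) - result_ids
        if missing:
            raise ConsistencyError(
                f"planted eligible genes absent from results: {sorted(missing)[:5]}"
            )
    flag = (
        (lambda r: r.bh_significant_mean)
        if family == "mean"
        else (lambda r: r.bh_significant_variance)
    )
    significant = {r.gene_id for r in results if flag(r)}
    planted = truth.effect_genes & eligible
    tp = len(significant & planted)
    fp = len(significant - truth.effect_genes)
    fn = len(planted - significant)
    fdr = fp / max(1, fp + tp)
    power = tp / len(planted) if planted else 0.0
    return RecoveryMetrics(tp=tp, fp=fp, fn=fn, fdr=fdr, power=power)


def write_truth_table(truth: SyntheticTruth, path) -> None:
    """TSV of planted effects: gene_id, mean_shift, variance_inflation."""
    rows = [
        {
            "gene_id": g,
            "mean_shift": truth.mean_shift.get(g, 0.0),
            "variance_inflation": truth.variance_inflation.get(g, 1.0),
        }
        for g in sorted(truth.effect_genes)
    ]
    pd.DataFrame(
        rows, columns=["gene_id", "mean_shift", "variance_inflation"]
    ).to_csv(path, sep="\t", index=False)
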