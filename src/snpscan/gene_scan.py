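"""Gene-windowed two-sample scan of normalized signal intensities.

Markers are assigned to every gene whose interval contains their position
(inclusive on both ends; a marker inside two overlapping genes counts for
both).  Genes with at least ``min_snps`` markers are eligible.  For each
eligible gene two observation vectors are built — one per group — by
concatenating the unmasked normalized values over the gene's markers (in
positional order) and the group's samples (in input order).  An F-test for
equality of variance and a Welch t-test for equality of means compare the
two vectors, and the Benjamini–Hochberg step-up rule is applied separately
to the mean-test and variance-test p-value families.

The observations within a gene are treated as exchangeable; no correction
for marker-level correlation is attempted, by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .errors import DegenerateGeneError, UndefinedTestError, ValidationError
from .io_formats import GeneSet, GroupAssignment, SnpMap, natural_chrom_key
from .normalization import NormalizedMatrix

__all__ = [
    "ScanConfig",
    "GeneSnpIndex",
    "GeneScanResult",
    "build_gene_snp_index",
    "select_eligible_genes",
    "build_group_vectors",
    "two_sample_tests",
    "benjamini_hochberg",
    "scan_genome",
]

logger = logging.getLogger(__name__)

_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters: marker-count eligibility threshold and BH level."""

    min_snps: int = 15
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.min_snps < 2:
            raise ValidationError("min_snps must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")


@dataclass
class GeneSnpIndex:
    """Markers located inside one gene, ordered by genomic position."""

    gene_id: str
    chrom: str
    start: int
    end: int
    category: str
    markers: list[str]
    positions: np.ndarray = field(repr=False)

    @property
    def n_snps(self) -> int:
        return len(self.markers)


@dataclass
class GeneScanResult:
    gene_id: str
    chrom: str
    start: int
    end: int
    n_snps: int
    p_variance: float
    p_mean: float
    bh_significant_mean: bool = False
    bh_significant_variance: bool = False


def build_gene_snp_index(snp_map: SnpMap, genes: GeneSet) -> list[GeneSnpIndex]:
    """Assign markers to genes by inclusive interval containment.

    Returns one entry per gene, in the gene table's order, including genes
    with zero markers (empty list).  A marker inside overlapping genes is
    listed under each of them.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    t = snp_map.table
    for chrom, sub in t.groupby("chrom", sort=False):
        order = np.argsort(sub["pos"].to_numpy(), kind="stable")
        by_chrom[chrom] = (
            sub["pos"].to_numpy()[order],
            sub["marker_id"].to_numpy()[order],
        )
    out: list[GeneSnpIndex] = []
    for row in genes.table.itertuples(index=False):
        pos, ids = by_chrom.get(row.chrom, (np.array([], dtype=np.int64), np.array([])))
        lo = np.searchsorted(pos, row.start, side="left")
        hi = np.searchsorted(pos, row.end, side="right")
        out.append(
            GeneSnpIndex(
                gene_id=row.gene_id,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                category=row.category,
                markers=list(ids[lo:hi]),
                positions=pos[lo:hi].copy(),
            )
        )
    return out


def select_eligible_genes(
    index: list[GeneSnpIndex], config: ScanConfig
) -> list[GeneSnpIndex]:
    """Keep exactly the genes with at least ``config.min_snps`` markers."""
    return [g for g in index if g.n_snps >= config.min_snps]


def build_group_vectors(
    gene: GeneSnpIndex, norm: NormalizedMatrix, groups: GroupAssignment
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate unmasked normalized values into case/control vectors.

    Order: the gene's markers by position, then the group's samples in
    their input order.  Masked cells are dropped.  Fewer than two usable
    values in either group is a degenerate gene.
    """
    rows = norm.snp_index(gene.markers)
    out = []
    for sample_ids in (groups.case_samples, groups.control_samples):
        cols = norm.sample_index(sample_ids)
        block = norm.value[np.ix_(rows, cols)]
        keep = ~norm.mask[np.ix_(rows, cols)]
        out.append(block[keep])  # C-order ravel: marker-major, then samples
    case_vec, control_vec = out
    if len(case_vec) < 2 or len(control_vec) < 2:
        raise DegenerateGeneError(
            f"gene {gene.gene_id!r}: fewer than 2 usable values in a group "
            f"(case {len(case_vec)}, control {len(control_vec)})"
        )
    return case_vec, control_vec


def two_sample_tests(case_vector, control_vector) -> tuple[float, float]:
    """Two-sided F-test of variance equality and Welch t-test of means.

    The F statistic is s²_case / s²_control on (n_case − 1, n_control − 1)
    degrees of freedom; its two-sided p-value doubles the smaller tail and
    is capped at 1.  The mean test is Welch's unequal-variance t-test.
    """
    x = np.asarray(case_vector, dtype=float)
    y = np.asarray(control_vector, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DegenerateGeneError("each vector needs at least 2 observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        raise UndefinedTestError("both group variances are zero")
    if vx == 0.0 or vy == 0.0:
        p_variance = _TINY  # degenerate ratio: smallest representable tail
    else:
        f = vx / vy
        dfn, dfd = len(x) - 1, len(y) - 1
        # F cdf and sf via the regularized incomplete beta, each computed in
        # its own well-conditioned form
        cdf = special.betainc(dfn / 2.0, dfd / 2.0, dfn * f / (dfn * f + dfd))
        sf = special.betainc(dfd / 2.0, dfn / 2.0, dfd / (dfn * f + dfd))
        p_variance = min(1.0, max(2.0 * min(cdf, sf), _TINY))
    # Welch unequal-variance t-test
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p_mean = 2.0 * special.stdtr(df, -abs(t))
    p_mean = min(1.0, max(float(p_mean), _TINY))
    return float(p_variance), float(p_mean)


def benjamini_hochberg(pvalues, alpha: float) -> tuple[np.ndarray, int]:
    """Step-up false-discovery-rate rule.

    Order the m p-values ascending; k is the largest index i (1-based) with
    P(i) ≤ alpha·i/m.  The k smallest p-values are declared significant
    (ties broken by the stable order of the sorted sequence); k = 0 when no
    index qualifies.  Returns flags aligned with the input order, and k.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value list")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must be in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = alpha * np.arange(1, m + 1) / m
    qualifies = p[order] <= thresholds
    k = int(np.nonzero(qualifies)[0][-1] + 1) if qualifies.any() else 0
    flags = np.zeros(m, dtype=bool)
    flags[order[:k]] = True
    return flags, k


def scan_genome(
    norm: NormalizedMatrix,
    index: list[GeneSnpIndex],
    groups: GroupAssignment,
    config: ScanConfig = ScanConfig(),
) -> tuple[list[GeneScanResult], list[tuple[str, str]]]:
    """Run the full per-gene scan with per-family BH correction.

    Returns (results, skip_log); the skip log lists (gene_id, reason) for
    genes whose tests could not be computed.  Results are ordered by
    (chromosome, start, gene id).
    """
    eligible = select_eligible_genes(index, config)
    if not eligible:
        logger.warning("no eligible genes (min_snps=%d)", config.min_snps)
        return [], []
    results: list[GeneScanResult] = []
    skip_log: list[tuple[str, str]] = []
    for gene in eligible:
        try:
            case_vec, control_vec = build_group_vectors(gene, norm, groups)
            p_var, p_mean = two_sample_tests(case_vec, control_vec)
        except (DegenerateGeneError, UndefinedTestError) as e:
            skip_log.append((gene.gene_id, str(e)))
            logger.info("skipping gene %s: %s", gene.gene_id, e)
            continue
        results.append(
            GeneScanResult(
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                start=gene.start,
                end=gene.end,
                n_snps=gene.n_snps,
                p_variance=p_var,
                p_mean=p_mean,
            )
        )
    if results:
        mean_flags, _ = benjamini_hochberg([r.p_mean for r in results], config.alpha)
        var_flags, _ = benjamini_hochberg([r.p_variance for r in results], config.alpha)
        for r, fm, fv in zip(results, mean_flags, var_flags):
            r.bh_significant_mean = bool(fm)
            r.bh_significant_variance = bool(fv)
    results.sort(key=lambda r: (natural_chrom_key(r.chrom), r.start, r.gene_id))
    return results, skip_log
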