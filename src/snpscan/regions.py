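"""Region-level controls and comparisons.

Covers the control analyses around the gene scan: testing an arbitrary
genomic region, flanking-marker groups around a gene, the copy-number
segment declaration filter (≥3 adjacent markers and ≥1 kb), pairwise region
overlap, pathway coverage arithmetic, and haplotype group-consistency.

Conventions: a region's length is end − start; marker containment is
inclusive on both endpoints; two regions overlap iff they share a
chromosome and max(starts) < min(ends) (touching intervals do not overlap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateGeneError, ValidationError
from .gene_scan import two_sample_tests
from .io_formats import GroupAssignment, SnpMap
from .normalization import NormalizedMatrix

__all__ = [
    "Region",
    "SegmentCall",
    "CoverageRow",
    "HaplotypeTable",
    "region_length",
    "region_test",
    "snp_group_test",
    "flanking_snp_groups",
    "mean_flanking_pvalue",
    "cnv_declaration_filter",
    "region_overlap",
    "pathway_coverage",
    "haplotype_group_consistency",
    "read_regions",
    "read_segment_calls",
    "read_haplotypes",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"region {self.chrom}:{self.start}-{self.end} has start >= end"
            )


@dataclass(frozen=True)
class SegmentCall:
    """A putative copy-number segment: region, state, supporting markers."""

    region: Region
    state: str  # "loss" | "gain"
    n_snps: int

    def __post_init__(self) -> None:
        if self.state not in ("loss", "gain"):
            raise ValidationError(f"state must be 'loss' or 'gain', got {self.state!r}")
        if self.n_snps < 1:
            raise ValidationError("n_snps must be >= 1")


@dataclass(frozen=True)
class CoverageRow:
    """Pathway coverage arithmetic over the eligible/significant gene sets."""

    pathway_id: str
    kegg_genes: int
    total_genes: int
    coverage_pct: float
    non_significant: int
    significant: int


@dataclass
class HaplotypeTable:
    """Two equal-length haplotype strings per sample, plus group label."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = ["sample_id", "hap1", "hap2", "group"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValidationError(f"haplotype table missing columns: {missing}")
        t = t[required].copy().astype(str)
        lengths = set(t["hap1"].str.len()) | set(t["hap2"].str.len())
        if len(lengths) != 1:
            raise ValidationError("all haplotype strings must share one length")
        alphabet = set("ACGT")
        for col in ("hap1", "hap2"):
            bad = ~t[col].map(lambda h: set(h) <= alphabet)
            if bad.any():
                s = t.loc[bad, "sample_id"].iloc[0]
                raise ValidationError(f"sample {s!r}: haplotype not over {{A,C,G,T}}")
        if not set(t["group"]) <= {"case", "control"}:
            raise ValidationError("group labels must be 'case' or 'control'")
        if t["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample in haplotype table")
        self.table = t.reset_index(drop=True)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def region_length(region: Region) -> int:
    """Span of the region in bp, defined as end − start."""
    return region.end - region.start


def _markers_in(region: Region, snp_map: SnpMap) -> pd.DataFrame:
    t = snp_map.table
    hit = (
        (t["chrom"] == region.chrom)
        & (t["pos"] >= region.start)
        & (t["pos"] <= region.end)
    )
    return t.loc[hit].sort_values("pos", kind="stable")


def snp_group_test(
    markers: list[str],
    norm: NormalizedMatrix,
    groups: GroupAssignment,
) -> tuple[float, float]:
    """Two-sample tests on an explicit marker group (flank or region).

    Builds case/control vectors exactly as the gene scan does (markers in
    the given order, samples in input order, masked cells dropped).
    """
    if not markers:
        raise DegenerateGeneError("empty marker group")
    rows = norm.snp_index(markers)
    vectors = []
    for sample_ids in (groups.case_samples, groups.control_samples):
        cols = norm.sample_index(sample_ids)
        block = norm.value[np.ix_(rows, cols)]
        keep = ~norm.mask[np.ix_(rows, cols)]
        vectors.append(block[keep])
    if len(vectors[0]) < 2 or len(vectors[1]) < 2:
        raise DegenerateGeneError("fewer than 2 usable values in a group")
    return two_sample_tests(vectors[0], vectors[1])


def region_test(
    region: Region,
    snp_map: SnpMap,
    norm: NormalizedMatrix,
    groups: GroupAssignment,
) -> tuple[float, float, int]:
    """Run the gene-scan tests on all markers inside a region.

    Returns (p_variance, p_mean, n_snps).  Containment is inclusive on
    both endpoints, so a region matching a gene's exact span reproduces
    the scan's p-values for that gene.
    """
    hits = _markers_in(region, snp_map)
    if hits.empty:
        raise DegenerateGeneError(
            f"region {region.chrom}:{region.start}-{region.end} contains no markers"
        )
    p_var, p_mean = snp_group_test(hits["marker_id"].tolist(), norm, groups)
    return p_var, p_mean, len(hits)


def flanking_snp_groups(
    gene: Region, snp_map: SnpMap, k: int
) -> tuple[list[str], list[str]]:
    """The k markers nearest each side of a gene, outside it.

    Left: the k markers with the largest positions strictly below
    gene.start on the gene's chromosome; right: the k smallest strictly
    above gene.end.  Fewer than k available on a side returns what exists,
    with a warning.  Marker lists are ordered by ascending position.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    t = snp_map.table
    on_chrom = t.loc[t["chrom"] == gene.chrom].sort_values("pos", kind="stable")
    left = on_chrom.loc[on_chrom["pos"] < gene.start, "marker_id"].tolist()[-k:]
    right = on_chrom.loc[on_chrom["pos"] > gene.end, "marker_id"].tolist()[:k]
    if len(left) < k or len(right) < k:
        logger.warning(
            "gene %s:%d-%d: only %d left / %d right flanking markers (k=%d)",
            gene.chrom,
            gene.start,
            gene.end,
            len(left),
            len(right),
            k,
        )
    return left, right


def mean_flanking_pvalue(
    gene: Region,
    snp_map: SnpMap,
    norm: NormalizedMatrix,
    groups: GroupAssignment,
    k: int,
) -> float:
    """Arithmetic mean of the mean-test p-values of the two flanks."""
    left, right = flanking_snp_groups(gene, snp_map, k)
    for side, markers in (("left", left), ("right", right)):
        if not markers:
            raise DegenerateGeneError(f"{side} flank of {gene.chrom} gene is empty")
    _, p_left = snp_group_test(left, norm, groups)
    _, p_right = snp_group_test(right, norm, groups)
    return (p_left + p_right) / 2.0


def cnv_declaration_filter(calls: list[SegmentCall]) -> list[SegmentCall]:
    """Retain calls supported by ≥3 adjacent markers spanning ≥1 kb."""
    return [
        c for c in calls if c.n_snps >= 3 and region_length(c.region) >= 1000
    ]


def region_overlap(
    query: list[Region], reference: list[Region]
) -> list[tuple[Region, Region, int]]:
    """All overlapping (query, reference) pairs with overlap lengths.

    A pair overlaps iff on the same chromosome and max(starts) < min(ends);
    the overlap length is min(ends) − max(starts).  Touching intervals do
    not overlap.
    """
    by_chrom: dict[str, list[Region]] = {}
    for r in reference:
        by_chrom.setdefault(r.chrom, []).append(r)
    out = []
    for q in query:
        for r in by_chrom.get(q.chrom, []):
            lo = max(q.start, r.start)
            hi = min(q.end, r.end)
            if lo < hi:
                out.append((q, r, hi - lo))
    return out


def pathway_coverage(
    pathway_id: str,
    pathway_genes: set[str],
    eligible_genes: set[str],
    significant_genes: set[str],
) -> CoverageRow:
    """Coverage arithmetic for one pathway.

    total = |pathway ∩ eligible|; coverage_pct = 100·total/|pathway|
    truncated (not rounded) at two decimals; significant counts the
    pathway's eligible genes that passed the BH test.
    """
    if not pathway_genes:
        raise ValidationError(f"pathway {pathway_id!r} has no genes")
    if not significant_genes <= eligible_genes:
        raise ValidationError("significant genes must be a subset of eligible genes")
    total = len(pathway_genes & eligible_genes)
    # integer arithmetic keeps the truncation exact (floor of 100·pct)
    coverage_pct = (10000 * total // len(pathway_genes)) / 100.0
    significant = len(pathway_genes & significant_genes)
    return CoverageRow(
        pathway_id=pathway_id,
        kegg_genes=len(pathway_genes),
        total_genes=total,
        coverage_pct=coverage_pct,
        non_significant=total - significant,
        significant=significant,
    )


def haplotype_group_consistency(table: HaplotypeTable) -> dict[str, str]:
    """Haplotype strings carried by every member of one group and nobody else.

    Returns {haplotype: group} for each string present in at least one
    copy of *every* sample of that group and in no copy of any sample of
    the other group; empty when no pattern is group-exclusive.
    """
    t = table.table
    per_sample = {
        row.sample_id: ({row.hap1, row.hap2}, row.group)
        for row in t.itertuples(index=False)
    }
    out: dict[str, str] = {}
    for group in ("case", "control"):
        members = [h for h, (hs, g) in per_sample.items() if g == group]
        others = [h for h, (hs, g) in per_sample.items() if g != group]
        if not members:
            continue
        shared = set.intersection(*(per_sample[m][0] for m in members))
        foreign = set().union(*(per_sample[o][0] for o in others)) if others else set()
        for hap in sorted(shared - foreign):
            out[hap] = group
    return out


# ---------------------------------------------------------------------------
# BED-like readers
# ---------------------------------------------------------------------------


def read_regions(path) -> list[Region]:
    """BED-like TSV with header: chrom, start, end."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [Region(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()]


def read_segment_calls(path) -> list[SegmentCall]:
    """TSV with header: chrom, start, end, state, n_snps."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "state": str})
    return [
        SegmentCall(Region(r.chrom, int(r.start), int(r.end)), r.state, int(r.n_snps))
        for r in df.itertuples()
    ]


def read_haplotypes(path) -> HaplotypeTable:
    """TSV with header: sample_id, hap1, hap2, group."""
    return HaplotypeTable(pd.read_csv(path, sep="\t", dtype=str))
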