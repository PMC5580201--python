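"""PCA differentiation of samples from normalized intensities.

Two views are supported: a genome-wide samples × genes matrix (one feature
per selected gene, the per-sample mean of the gene's normalized values)
whose first two components display the group separation; and a per-gene
samples × markers matrix whose first component gives one loading bar per
sample.

The decomposition is covariance PCA: features are centered by their mean
and the covariance matrix is eigen-decomposed (computed via SVD of the
centered matrix for numerical stability).  The eigenvector sign is fixed so
that the case group's mean PC1 score is non-negative, making plots
reproducible run to run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .gene_scan import GeneSnpIndex
from .io_formats import GroupAssignment
from .normalization import NormalizedMatrix

__all__ = [
    "FeatureMatrix",
    "PcaResult",
    "gene_feature_matrix",
    "principal_components",
    "gene_pc1_profile",
    "plot_pc_scatter",
    "plot_gene_profile",
]

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Complete (no missing cells) samples × features matrix of log2 ratios."""

    samples: list[str]
    features: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = (len(self.samples), len(self.features))
        if self.values.shape != shape:
            raise ValidationError(f"feature matrix must have shape {shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature matrix contains non-finite cells")


@dataclass
class PcaResult:
    """Scores on the retained components plus the full variance spectrum.

    ``eigenvalues`` are the covariance-matrix eigenvalues sorted
    non-increasing; their sum equals the total variance of the centered
    matrix.  ``components`` holds the retained eigenvectors (d × features).
    """

    samples: list[str]
    scores: np.ndarray
    eigenvalues: np.ndarray
    components: np.ndarray = field(repr=False)
    d: int = 0

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total


def gene_feature_matrix(
    norm: NormalizedMatrix,
    genes: list[GeneSnpIndex],
    selection: set[str] | None = None,
) -> FeatureMatrix:
    """One feature per selected gene: per-sample mean over the gene's markers.

    Masked cells are excluded from each mean; a gene with no usable value
    for some sample is dropped with a warning so the matrix stays complete.
    """
    chosen = [
        g
        for g in genes
        if (selection is None or g.gene_id in selection) and g.n_snps > 0
    ]
    if not chosen:
        raise ValidationError("no genes selected for the feature matrix")
    cols = []
    kept = []
    for g in chosen:
        rows = norm.snp_index(g.markers)
        vals = norm.value[rows]  # (n_gene_snps × n_samples)
        ok = ~norm.mask[rows]
        counts = ok.sum(axis=0)
        if np.any(counts == 0):
            logger.warning(
                "dropping gene %s from feature matrix: sample(s) fully masked",
                g.gene_id,
            )
            continue
        sums = np.where(ok, vals, 0.0).sum(axis=0)
        cols.append(sums / counts)
        kept.append(g.gene_id)
    if not kept:
        raise ValidationError("every selected gene was dropped (masking)")
    return FeatureMatrix(
        samples=list(norm.samples), features=kept, values=np.column_stack(cols)
    )


def principal_components(
    matrix: FeatureMatrix, d: int, case_samples: list[str] | None = None
) -> PcaResult:
    """Covariance PCA of the feature matrix, retaining the top d components.

    When ``case_samples`` is given, each component's sign is chosen so the
    case group's mean score on it is non-negative (ties fall back to making
    the largest-magnitude loading positive); otherwise the loading rule
    alone applies.  A constant matrix yields all-zero eigenvalues and
    scores — not an error.
    """
    n, p = matrix.values.shape
    if n < 2:
        raise ValidationError("PCA needs at least 2 samples")
    if not 1 <= d <= min(n, p):
        raise ValidationError(f"d must be in [1, {min(n, p)}]")
    centered = matrix.values - matrix.values.mean(axis=0)
    # SVD of the centered matrix: eigenvalues of C are s² / (n − 1)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    scores = u * s  # projections on all eigenvectors
    case_idx = None
    if case_samples is not None:
        lookup = {smp: i for i, smp in enumerate(matrix.samples)}
        case_idx = np.array([lookup[smp] for smp in case_samples], dtype=int)
    for j in range(len(s)):
        flip = 0.0
        if case_idx is not None and len(case_idx):
            flip = scores[case_idx, j].mean()
        if flip == 0.0:
            lead = vt[j, np.argmax(np.abs(vt[j]))]
            flip = lead
        if flip < 0:
            scores[:, j] *= -1.0
            vt[j] *= -1.0
    return PcaResult(
        samples=list(matrix.samples),
        scores=scores[:, :d],
        eigenvalues=eigenvalues,
        components=vt[:d],
        d=d,
    )


def gene_pc1_profile(
    gene: GeneSnpIndex,
    norm: NormalizedMatrix,
    groups: GroupAssignment,
) -> pd.Series:
    """Per-sample PC1 loading profile for one gene, unit-normalized.

    Builds the gene's samples × markers matrix (markers with any masked
    cell are dropped), takes PC1 scores with the case-group sign
    convention, rescales to unit maximum absolute value and returns a
    Series indexed by sample id, sorted ascending by value.
    """
    rows = norm.snp_index(gene.markers)
    vals = norm.value[rows]
    ok_marker = ~norm.mask[rows].any(axis=1)
    usable = vals[ok_marker].T  # samples × markers
    if usable.shape[1] == 0:
        raise ValidationError(f"gene {gene.gene_id!r}: no fully observed markers")
    fm = FeatureMatrix(
        samples=list(norm.samples),
        features=[gene.markers[i] for i in np.nonzero(ok_marker)[0]],
        values=usable,
    )
    res = principal_components(fm, d=1, case_samples=groups.case_samples)
    pc1 = res.scores[:, 0]
    peak = np.max(np.abs(pc1))
    if peak > 0:
        pc1 = pc1 / peak
    return pd.Series(pc1, index=norm.samples, name=gene.gene_id).sort_values(
        kind="stable"
    )


# ---------------------------------------------------------------------------
# figure helpers (the two styles the pipeline reports)
# ---------------------------------------------------------------------------


def plot_pc_scatter(result: PcaResult, groups: GroupAssignment, path) -> None:
    """PC1-vs-PC2 scatter colored by group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result.scores.shape[1] < 2:
        raise ValidationError("scatter needs at least 2 retained components")
    fig, ax = plt.subplots(figsize=(5, 4))
    evr = result.explained_variance_ratio
    for group, color in (("case", "tab:red"), ("control", "tab:blue")):
        idx = [i for i, s in enumerate(result.samples) if groups.group_of(s) == group]
        ax.scatter(
            result.scores[idx, 0], result.scores[idx, 1], c=color, label=group
        )
        for i in idx:
            ax.annotate(result.samples[i], result.scores[i, :2], fontsize=7)
    ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}% var)")
    ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}% var)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_gene_profile(profile: pd.Series, groups: GroupAssignment, path) -> None:
    """Bar chart of a gene's sorted per-sample PC1 loadings."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = [
        "tab:red" if groups.group_of(s) == "case" else "tab:blue"
        for s in profile.index
    ]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(range(len(profile)), profile.to_numpy(), color=colors)
    ax.set_xticks(range(len(profile)))
    ax.set_xticklabels(profile.index, rotation=60, fontsize=7)
    ax.set_ylabel("PC1 loading (unit max)")
    ax.set_title(str(profile.name))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
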