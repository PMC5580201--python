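"""Replicated synthetic experiments over the full pipeline.

Runs independent seeded replicates of generate → normalize → scan → PCA and
summarizes operating characteristics: the empirical false discovery rate of
the BH-corrected mean-test family, power against the planted genes, and
whether PC1 of the significant-gene feature matrix linearly separates the
two groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gene_scan import ScanConfig, build_gene_snp_index, scan_genome
from .normalization import normalize_intensities
from .pca import gene_feature_matrix, principal_components
from .synthetic_data import SyntheticSpec, evaluate_recovery, generate_dataset

__all__ = ["ReplicateOutcome", "run_replicate", "fdr_experiment"]


@dataclass(frozen=True)
class ReplicateOutcome:
    seed: int
    fdr: float
    power: float
    n_significant: int
    pc1_separates: bool


def _pc1_separates(norm, index, groups, significant: set[str]) -> bool:
    """True iff some threshold on PC1 splits cases from controls exactly."""
    if not significant:
        return False
    fm = gene_feature_matrix(norm, index, significant)
    d = min(2, len(fm.samples), len(fm.features))
    res = principal_components(fm, d=d, case_samples=groups.case_samples)
    pc1 = dict(zip(res.samples, res.scores[:, 0]))
    case = np.array([pc1[s] for s in groups.case_samples])
    control = np.array([pc1[s] for s in groups.control_samples])
    return bool(case.min() > control.max() or control.min() > case.max())


def run_replicate(
    spec: SyntheticSpec, config: ScanConfig = ScanConfig()
) -> ReplicateOutcome:
    """One full-pipeline replicate at the given spec."""
    raw, snp_map, genes, groups, truth = generate_dataset(spec)
    norm = normalize_intensities(raw)
    index = build_gene_snp_index(snp_map, genes)
    results, _ = scan_genome(norm, index, groups, config)
    metrics = evaluate_recovery(results, truth)
    significant = {r.gene_id for r in results if r.bh_significant_mean}
    return ReplicateOutcome(
        seed=spec.seed,
        fdr=metrics.fdr,
        power=metrics.power,
        n_significant=len(significant),
        pc1_separates=_pc1_separates(norm, index, groups, significant),
    )


def fdr_experiment(
    n_replicates: int = 50,
    base_seed: int = 1,
    spec: SyntheticSpec | None = None,
    config: ScanConfig = ScanConfig(),
) -> list[ReplicateOutcome]:
    """Independent replicates with seeds derived from one base seed.

    Derived seeds are (base_seed * 100003 + r) mod 2^31, r = 0..n-1, so two
    experiments never share a replicate stream unless their base seeds do.
    """
    import dataclasses

    spec = spec or SyntheticSpec()
    out = []
    for r in range(n_replicates):
        seed = (base_seed * 100_003 + r) % 2**31
        out.append(run_replicate(dataclasses.replace(spec, seed=seed), config))
    return out
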