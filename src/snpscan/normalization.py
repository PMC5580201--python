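"""Log2-ratio normalization of raw biallelic intensities.

For each marker the per-sample total intensity is T = A + B; the marker's
reference is M = median(T) across all samples (cases and controls pooled;
for even sample counts the median is the arithmetic mean of the two middle
values).  The normalized value is log2(T / M).  Entries with T = 0, and
whole markers whose reference M = 0, are masked rather than imputed: any
pseudo-count floor would silently bias the log ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import RawIntensitySet

__all__ = ["NormalizedMatrix", "normalize_intensities", "write_normalized_table"]


@dataclass
class NormalizedMatrix:
    """Per-SNP, per-sample log2(T/M) values with a QC mask.

    ``mask`` is True where an entry is unusable (it then carries no numeric
    value downstream).  ``reference`` holds each marker's median total
    intensity M in the original fluorescence units.
    """

    snps: list[str]
    samples: list[str]
    value: np.ndarray
    mask: np.ndarray
    reference: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = (len(self.snps), len(self.samples))
        if self.value.shape != shape or self.mask.shape != shape:
            raise ValidationError("normalized matrix shape mismatch")
        if self.reference.shape != (len(self.snps),):
            raise ValidationError("reference vector shape mismatch")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def _lookup(self, attr: str, items: list[str]) -> dict[str, int]:
        # lazy, cached: the scan queries these once per gene
        cache = self.__dict__.setdefault("_lookup_cache", {})
        if attr not in cache:
            cache[attr] = {s: i for i, s in enumerate(items)}
        return cache[attr]

    def sample_index(self, ids) -> np.ndarray:
        lookup = self._lookup("samples", self.samples)
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as e:
            raise ValidationError(f"unknown sample id {e.args[0]!r}") from e

    def snp_index(self, ids) -> np.ndarray:
        lookup = self._lookup("snps", self.snps)
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as e:
            raise ValidationError(f"unknown marker id {e.args[0]!r}") from e


def normalize_intensities(raw: RawIntensitySet) -> NormalizedMatrix:
    """Compute log2(T/M) per marker and sample, masking zero totals.

    The reference median is taken over *all* samples, including any whose
    total is zero (they are masked in the output but still inform M).
    """
    if raw.n_snps == 0 or raw.n_samples == 0:
        raise ValidationError("cannot normalize an empty intensity set")
    total = raw.a + raw.b  # (snp × sample)
    reference = np.median(total, axis=1)
    mask = total == 0.0
    dead_snp = reference == 0.0
    mask |= dead_snp[:, None]
    value = np.zeros_like(total)
    ok = ~mask
    with np.errstate(divide="ignore", invalid="ignore"):
        value[ok] = np.log2(total[ok] / reference[np.nonzero(ok)[0]])
    value[mask] = np.nan
    return NormalizedMatrix(
        snps=list(raw.snps),
        samples=list(raw.samples),
        value=value,
        mask=mask,
        reference=reference,
    )


def write_normalized_table(norm: NormalizedMatrix, path) -> None:
    """Long-format TSV: marker_id, sample_id, log2_ratio, masked."""
    df = pd.DataFrame(
        {
            "marker_id": np.repeat(norm.snps, norm.n_samples),
            "sample_id": np.tile(norm.samples, norm.n_snps),
            "log2_ratio": norm.value.ravel(),
            "masked": norm.mask.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
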