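"""Tabular file formats and validated in-memory containers.

All files are plain tab-separated text with a header row.  Intensities are
stored in *long* format (one row per marker × sample), which stays readable
and streamable at the scale of hundreds of thousands of markers.  Gene and
region coordinates are 1-based and inclusive on both ends unless a function
documents otherwise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DuplicateRecordError,
    MissingRecordError,
    ParseError,
    ValidationError,
)

__all__ = [
    "RawIntensitySet",
    "SnpMap",
    "GeneSet",
    "GroupAssignment",
    "natural_chrom_key",
    "read_intensity_table",
    "write_intensity_table",
    "read_snp_map",
    "write_snp_map",
    "read_gene_table",
    "write_gene_table",
    "read_groups",
    "write_groups",
    "write_scan_results",
    "read_scan_results",
]

CASE = "case"
CONTROL = "control"


def natural_chrom_key(label: str) -> tuple:
    """Sort key for chromosome labels: numeric runs compare numerically.

    'chr2' < 'chr10', and purely lexicographic otherwise.  Labels are
    otherwise opaque strings.
    """
    parts = re.split(r"(\d+)", str(label))
    return tuple(int(p) if p.isdigit() else p for p in parts)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class RawIntensitySet:
    """Per-SNP, per-sample biallelic fluorescence intensities.

    ``a`` and ``b`` are (n_snps × n_samples) arrays of non-negative,
    finite values in arbitrary fluorescence units, one row per marker in
    ``snps`` and one column per id in ``samples``.
    """

    samples: list[str]
    snps: list[str]
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.samples = [str(s) for s in self.samples]
        self.snps = [str(s) for s in self.snps]
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        shape = (len(self.snps), len(self.samples))
        if self.a.shape != shape or self.b.shape != shape:
            raise ValidationError(
                f"intensity matrices must have shape {shape}, "
                f"got A {self.a.shape} and B {self.b.shape}"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("sample ids are not unique")
        if len(set(self.snps)) != len(self.snps):
            raise ValidationError("marker ids are not unique")
        for name, m in (("A", self.a), ("B", self.b)):
            if not np.all(np.isfinite(m)):
                raise ValidationError(f"{name} intensities contain non-finite values")
            if np.any(m < 0):
                raise ValidationError(f"{name} intensities contain negative values")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class SnpMap:
    """Genomic location of each marker: id, chromosome label, 1-based position."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = ["marker_id", "chrom", "pos"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValidationError(f"SNP map missing columns: {missing}")
        t = t[required].copy()
        t["marker_id"] = t["marker_id"].astype(str)
        t["chrom"] = t["chrom"].astype(str)
        pos = pd.to_numeric(t["pos"], errors="coerce")
        if pos.isna().any() or not np.allclose(pos, pos.round()):
            raise ParseError("SNP positions must be integers")
        t["pos"] = pos.astype(np.int64)
        if (t["pos"] <= 0).any():
            raise ValidationError("SNP positions must be strictly positive")
        if t["marker_id"].duplicated().any():
            dup = t.loc[t["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise DuplicateRecordError(f"duplicate marker id in SNP map: {dup!r}")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GeneSet:
    """Gene annotation: id, chromosome, [start, end] (1-based inclusive), category."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = ["gene_id", "chrom", "start", "end", "category"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValidationError(f"gene table missing columns: {missing}")
        t = t[required].copy()
        t["gene_id"] = t["gene_id"].astype(str)
        t["chrom"] = t["chrom"].astype(str)
        t["category"] = t["category"].astype(str)
        for col in ("start", "end"):
            v = pd.to_numeric(t[col], errors="coerce")
            if v.isna().any() or not np.allclose(v, v.round()):
                raise ParseError(f"gene coordinate column {col!r} must be integer")
            t[col] = v.astype(np.int64)
        bad = t["start"] >= t["end"]
        if bad.any():
            g = t.loc[bad, "gene_id"].iloc[0]
            raise ValidationError(f"gene {g!r} has start >= end")
        if t["gene_id"].duplicated().any():
            dup = t.loc[t["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise DuplicateRecordError(f"duplicate gene id: {dup!r}")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GroupAssignment:
    """Sample → group ('case' / 'control') mapping; both groups non-empty."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = ["sample_id", "group"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValidationError(f"groups table missing columns: {missing}")
        t = t[required].copy()
        t["sample_id"] = t["sample_id"].astype(str)
        t["group"] = t["group"].astype(str)
        bad = ~t["group"].isin([CASE, CONTROL])
        if bad.any():
            raise ValidationError(
                f"group labels must be '{CASE}' or '{CONTROL}', "
                f"got {sorted(t.loc[bad, 'group'].unique())}"
            )
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise DuplicateRecordError(f"sample {dup!r} assigned more than once")
        if not (t["group"] == CASE).any() or not (t["group"] == CONTROL).any():
            raise ValidationError("both groups must be non-empty")
        self.table = t.reset_index(drop=True)

    @property
    def case_samples(self) -> list[str]:
        t = self.table
        return t.loc[t["group"] == CASE, "sample_id"].tolist()

    @property
    def control_samples(self) -> list[str]:
        t = self.table
        return t.loc[t["group"] == CONTROL, "sample_id"].tolist()

    def group_of(self, sample: str) -> str:
        t = self.table
        hit = t.loc[t["sample_id"] == sample, "group"]
        if hit.empty:
            raise ValidationError(f"unknown sample {sample!r}")
        return hit.iloc[0]

    def validate_against(self, raw: RawIntensitySet) -> None:
        """Every sample of *raw* must appear exactly once in the assignment."""
        assigned = set(self.table["sample_id"])
        missing = [s for s in raw.samples if s not in assigned]
        if missing:
            raise ValidationError(f"samples without group assignment: {missing}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8")
    except pd.errors.ParserError as e:  # pragma: no cover - pandas message varies
        raise ParseError(f"cannot parse {path}: {e}") from e
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def read_intensity_table(path) -> RawIntensitySet:
    """Read a long-format intensity TSV (marker_id, sample_id, A, B).

    The file must contain every (marker, sample) combination exactly once;
    a missing combination or duplicate row is an error, as is a negative or
    unparseable intensity.
    """
    df = _read_tsv(path, ["marker_id", "sample_id", "A", "B"])
    for col in ("A", "B"):
        probe = pd.to_numeric(df[col], errors="coerce")
        bad = probe.isna()
        if bad.any():
            line = int(df.index[bad][0]) + 2  # 1-based, counting the header
            raise ParseError(f"{path}: malformed {col} value at line {line}")
        # numpy's parser is correctly rounded, so %.17g output round-trips
        df[col] = df[col].to_numpy(dtype="U").astype(np.float64)
    dup = df.duplicated(subset=["marker_id", "sample_id"])
    if dup.any():
        m, s = df.loc[dup, ["marker_id", "sample_id"]].iloc[0]
        raise DuplicateRecordError(f"duplicate record for marker {m!r}, sample {s!r}")

    snps = list(dict.fromkeys(df["marker_id"]))  # first-appearance order
    samples = list(dict.fromkeys(df["sample_id"]))
    expected = len(snps) * len(samples)
    if len(df) != expected:
        have = set(zip(df["marker_id"], df["sample_id"]))
        for m in snps:
            for s in samples:
                if (m, s) not in have:
                    raise MissingRecordError(
                        f"missing record for marker {m!r}, sample {s!r}"
                    )
    snp_idx = {m: i for i, m in enumerate(snps)}
    smp_idx = {s: j for j, s in enumerate(samples)}
    a = np.empty((len(snps), len(samples)))
    b = np.empty_like(a)
    rows = df["marker_id"].map(snp_idx).to_numpy()
    cols = df["sample_id"].map(smp_idx).to_numpy()
    a[rows, cols] = df["A"].to_numpy()
    b[rows, cols] = df["B"].to_numpy()
    return RawIntensitySet(samples=samples, snps=snps, a=a, b=b)


def write_intensity_table(raw: RawIntensitySet, path) -> None:
    rows = {
        "marker_id": np.repeat(raw.snps, raw.n_samples),
        "sample_id": np.tile(raw.samples, raw.n_snps),
        "A": raw.a.ravel(),
        "B": raw.b.ravel(),
    }
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_snp_map(path) -> SnpMap:
    return SnpMap(_read_tsv(path, ["marker_id", "chrom", "pos"]))


def write_snp_map(snp_map: SnpMap, path) -> None:
    snp_map.table.to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> GeneSet:
    """Read a gene annotation TSV (gene_id, chrom, start, end, category)."""
    return GeneSet(_read_tsv(path, ["gene_id", "chrom", "start", "end", "category"]))


def write_gene_table(genes: GeneSet, path) -> None:
    genes.table.to_csv(path, sep="\t", index=False)


def read_groups(path) -> GroupAssignment:
    return GroupAssignment(_read_tsv(path, ["sample_id", "group"]))


def write_groups(groups: GroupAssignment, path) -> None:
    groups.table.to_csv(path, sep="\t", index=False)


_RESULT_COLUMNS = [
    "gene_id",
    "chrom",
    "start",
    "end",
    "n_snps",
    "p_variance",
    "p_mean",
    "bh_significant_mean",
    "bh_significant_variance",
]


def write_scan_results(results, path) -> None:
    """Write scan results as TSV, ordered by (chromosome, start, gene id).

    Chromosome order is natural (chr2 before chr10).  P-values keep 17
    significant digits so a round-trip preserves them past 1e-12.
    """
    if not len(results):
        raise ValidationError("no scan results to write")
    rows = [
        {
            "gene_id": r.gene_id,
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "n_snps": r.n_snps,
            "p_variance": r.p_variance,
            "p_mean": r.p_mean,
            "bh_significant_mean": r.bh_significant_mean,
            "bh_significant_variance": r.bh_significant_variance,
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    order = sorted(
        range(len(df)),
        key=lambda i: (
            natural_chrom_key(df["chrom"].iloc[i]),
            df["start"].iloc[i],
            df["gene_id"].iloc[i],
        ),
    )
    df.iloc[order].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_scan_results(path) -> pd.DataFrame:
    df = _read_tsv(path, _RESULT_COLUMNS)
    for col in ("p_variance", "p_mean"):
        df[col] = df[col].astype(float)
    for col in ("start", "end", "n_snps"):
        df[col] = df[col].astype(np.int64)
    for col in ("bh_significant_mean", "bh_significant_variance"):
        df[col] = df[col].map({"True": True, "False": False}).astype(bool)
    return df
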