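"""Count-table I/O, read-density normalisation and fold changes.

Bulk RNA-seq reads are summarised per gene into exonic and intronic
counts.  Densities are expressed as RPM (reads per million uniquely
mapped reads) and, for length normalisation, RPM per kilobase of
feature length.  Fold changes between a case and a control group are
computed on group means after adding a small pseudo-RPM (default 0.1)
to stabilise ratios at low expression.

Conventions
-----------
* Genomic coordinates are 0-based half-open (BED).
* A gene is represented by two feature rows, ``exon`` and ``intron``,
  whose lengths are the summed spans of the respective intervals.
* Gene-level mRNA abundance uses the exon row's plain RPM; intron
  "read density" uses RPM per kilobase of intronic length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

FEATURE_TYPES = ("exon", "intron")

DEFAULT_PSEUDO_RPM = 0.1
DEFAULT_MIN_MEAN_READS = 1.0


class CountTableError(ValueError):
    """Raised when a count table or sample sheet violates its contract."""


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

@dataclass
class SampleSheet:
    """Sample metadata: group labels and optional library sizes.

    Parameters
    ----------
    samples : pandas.DataFrame
        Columns ``sample_id``, ``group`` and optionally ``library_size``
        (uniquely mapped reads).  Sample ids must be unique and every
        sample must carry a group label.
    """

    samples: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.samples).copy()
        required = {"sample_id", "group"}
        missing = required - set(df.columns)
        if missing:
            raise CountTableError(f"sample sheet missing columns: {sorted(missing)}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise CountTableError(f"duplicate sample ids: {dups}")
        if df["group"].isna().any() or (df["group"].astype(str) == "").any():
            raise CountTableError("every sample needs a non-empty group label")
        if "library_size" in df.columns:
            sizes = pd.to_numeric(df["library_size"], errors="coerce")
            bad = sizes.notna() & (sizes <= 0)
            if bad.any():
                raise CountTableError("library_size must be positive where given")
            df["library_size"] = sizes
        else:
            df["library_size"] = np.nan
        self.samples = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    @property
    def groups(self) -> list[str]:
        return sorted(self.samples["group"].unique())

    def samples_in_group(self, group: str) -> list[str]:
        ids = self.samples.loc[self.samples["group"] == group, "sample_id"]
        if ids.empty:
            raise CountTableError(f"unknown or empty group: {group!r}")
        return ids.tolist()

    @classmethod
    def read_csv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path))

    def write_csv(self, path: str | Path) -> None:
        out = self.samples.sort_values("sample_id")
        out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# feature count table
# ---------------------------------------------------------------------------

ID_COLUMNS = ["gene_id", "feature_type", "length_bp"]


@dataclass
class FeatureCountTable:
    """Per-(gene, feature-type) read counts across samples.

    ``frame`` holds one row per (gene_id, feature_type) with a positive
    ``length_bp`` and one non-negative integer count column per sample.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.frame).copy()
        missing = [c for c in ID_COLUMNS if c not in df.columns]
        if missing:
            raise CountTableError(f"count table missing columns: {missing}")
        bad_ft = ~df["feature_type"].isin(FEATURE_TYPES)
        if bad_ft.any():
            raise CountTableError(
                f"feature_type must be one of {FEATURE_TYPES}; "
                f"got {df.loc[bad_ft, 'feature_type'].unique().tolist()}"
            )
        keys = df[["gene_id", "feature_type"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise CountTableError(f"duplicate (gene_id, feature_type) key: {dup}")
        lengths = pd.to_numeric(df["length_bp"], errors="raise")
        if (lengths <= 0).any():
            raise CountTableError("length_bp must be positive")
        df["length_bp"] = lengths.astype(np.int64)
        for col in self._sample_columns(df):
            vals = pd.to_numeric(df[col], errors="raise")
            if (vals < 0).any():
                row = int(np.flatnonzero(vals.to_numpy() < 0)[0])
                raise CountTableError(
                    f"negative count in column {col!r} at data row {row + 1}"
                )
            df[col] = vals
        self.frame = df.reset_index(drop=True)

    @staticmethod
    def _sample_columns(df: pd.DataFrame) -> list[str]:
        return [c for c in df.columns if c not in ID_COLUMNS]

    @property
    def sample_ids(self) -> list[str]:
        return self._sample_columns(self.frame)

    @property
    def gene_ids(self) -> list[str]:
        return self.frame["gene_id"].unique().tolist()

    def counts(self) -> pd.DataFrame:
        """Counts indexed by (gene_id, feature_type), samples as columns."""
        return self.frame.set_index(["gene_id", "feature_type"])[self.sample_ids]

    def lengths(self) -> pd.Series:
        return self.frame.set_index(["gene_id", "feature_type"])["length_bp"]


def read_count_table(path: str | Path) -> FeatureCountTable:
    """Read a TSV count table (gene_id, feature_type, length_bp, samples...)."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CountTableError(f"cannot parse {path}: {exc}") from exc
    try:
        return FeatureCountTable(df)
    except CountTableError as exc:
        raise CountTableError(f"{path}: {exc}") from exc


def write_count_table(table: FeatureCountTable, path: str | Path) -> None:
    """Write a count table TSV with deterministic row and column order."""
    df = table.frame.copy()
    df = df.sort_values(["gene_id", "feature_type"])
    cols = ID_COLUMNS + sorted(table.sample_ids)
    df[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interval counting (desk-scale replacement for feature quantification)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval attached to a gene feature."""

    chrom: str
    start: int
    end: int
    gene_id: str = ""
    feature_type: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise CountTableError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )


def read_bed(path: str | Path, feature_type: str = "") -> list[GenomicInterval]:
    """Read a BED file; the name field carries the gene id."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise CountTableError(f"{path}:{lineno}: fewer than 3 BED columns")
            name = parts[3] if len(parts) > 3 else ""
            out.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]), name, feature_type)
            )
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    rows = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end, iv.gene_id))
    with open(path, "w") as fh:
        for iv in rows:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.gene_id}\t0\t.\n")


def count_feature_reads(
    reads: Iterable[GenomicInterval],
    features: Sequence[GenomicInterval],
    sample_id: str = "sample",
) -> FeatureCountTable:
    """Assign reads to exon/intron features by 1-bp overlap, exon first.

    A read overlapping >=1 bp of any exon of a gene counts as exonic for
    that gene; otherwise an intronic overlap counts as intronic.  A read
    can hit several genes but at most one feature type per gene.  Strand
    is ignored.  Feature lengths are the summed interval spans.
    """
    features = list(features)
    if not features:
        return FeatureCountTable(
            pd.DataFrame(columns=ID_COLUMNS + [sample_id])
        )
    trees: dict[tuple[str, str], IntervalTree] = {}
    lengths: dict[tuple[str, str], int] = {}
    for iv in features:
        if iv.feature_type not in FEATURE_TYPES:
            raise CountTableError(
                f"feature interval for {iv.gene_id!r} lacks exon/intron type"
            )
        trees.setdefault((iv.chrom, iv.feature_type), IntervalTree()).addi(
            iv.start, iv.end, iv.gene_id
        )
        key = (iv.gene_id, iv.feature_type)
        lengths[key] = lengths.get(key, 0) + (iv.end - iv.start)

    counts: dict[tuple[str, str], int] = {key: 0 for key in lengths}
    for read in reads:
        exon_hits = {
            hit.data for hit in trees.get((read.chrom, "exon"), IntervalTree())[read.start:read.end]
        }
        intron_hits = {
            hit.data for hit in trees.get((read.chrom, "intron"), IntervalTree())[read.start:read.end]
        }
        for gene in exon_hits:
            counts[(gene, "exon")] = counts.get((gene, "exon"), 0) + 1
        for gene in intron_hits - exon_hits:
            counts[(gene, "intron")] = counts.get((gene, "intron"), 0) + 1

    genes = sorted({g for g, _ in lengths})
    rows = []
    for gene in genes:
        for ftype in FEATURE_TYPES:
            key = (gene, ftype)
            if key in lengths:
                rows.append(
                    {
                        "gene_id": gene,
                        "feature_type": ftype,
                        "length_bp": lengths[key],
                        sample_id: counts.get(key, 0),
                    }
                )
    return FeatureCountTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# filtering, densities, fold changes
# ---------------------------------------------------------------------------

def filter_low_expression(
    table: FeatureCountTable, threshold: float = DEFAULT_MIN_MEAN_READS
) -> FeatureCountTable:
    """Drop genes whose mean reads/sample (exon + intron) is below ``threshold``.

    The exclusion is strict (< threshold): a gene averaging exactly the
    threshold is retained.  Both feature rows of a gene are kept or
    dropped together.
    """
    if threshold < 0:
        raise CountTableError("threshold must be non-negative")
    samples = table.sample_ids
    if not samples:
        raise CountTableError("count table has no sample columns")
    per_gene = table.frame.groupby("gene_id")[samples].sum().sum(axis=1)
    mean_per_sample = per_gene / len(samples)
    keep = set(mean_per_sample.index[mean_per_sample >= threshold])
    kept = table.frame[table.frame["gene_id"].isin(keep)]
    return FeatureCountTable(kept.reset_index(drop=True))


def compute_density(table: FeatureCountTable, sheet: SampleSheet) -> pd.DataFrame:
    """RPM and RPM/kb per (gene, feature, sample), tidy long format.

    Library sizes come from the sample sheet; missing ones fall back to
    the per-sample total assigned reads (with a warning, because the
    intended normaliser is uniquely mapped reads).
    """
    samples = table.sample_ids
    sheet_ids = set(sheet.sample_ids)
    unknown = [s for s in samples if s not in sheet_ids]
    if unknown:
        raise CountTableError(f"samples missing from sample sheet: {unknown}")
    lib = sheet.samples.set_index("sample_id")["library_size"].reindex(samples)
    if (lib == 0).any():
        raise CountTableError("library_size of 0 is invalid")
    if lib.isna().any():
        fallback = table.frame[samples].sum()
        warnings.warn(
            "library_size missing for some samples; using per-sample total "
            "assigned reads instead of uniquely mapped reads",
            stacklevel=2,
        )
        lib = lib.fillna(fallback)

    long = table.frame.melt(
        id_vars=ID_COLUMNS, var_name="sample_id", value_name="count"
    )
    long["library_size"] = long["sample_id"].map(lib)
    long["rpm"] = long["count"] * 1e6 / long["library_size"]
    long["density_per_kb"] = long["rpm"] / (long["length_bp"] / 1000.0)
    return long[
        ["gene_id", "feature_type", "sample_id", "count", "library_size", "rpm", "density_per_kb"]
    ]


def fold_change(
    density: pd.DataFrame,
    sheet: SampleSheet,
    case: str,
    control: str,
    pseudo: float = DEFAULT_PSEUDO_RPM,
    feature: str = "gene",
) -> pd.DataFrame:
    """Per-feature log2 fold change of group means with a pseudo-RPM.

    ``feature='gene'`` compares gene-level mRNA abundance (exon-row RPM);
    ``feature='intron'`` / ``'exon'`` compare length-normalised read
    density (RPM/kb) of that feature type.  log2fc =
    log2((mean_case + pseudo) / (mean_control + pseudo)).
    """
    if pseudo <= 0:
        raise CountTableError("pseudo must be positive")
    case_ids = sheet.samples_in_group(case)
    control_ids = sheet.samples_in_group(control)
    if feature == "gene":
        sub = density[density["feature_type"] == "exon"]
        value_col = "rpm"
    elif feature in FEATURE_TYPES:
        sub = density[density["feature_type"] == feature]
        value_col = "density_per_kb"
    else:
        raise CountTableError(f"feature must be gene/exon/intron, got {feature!r}")

    wide = sub.pivot_table(index="gene_id", columns="sample_id", values=value_col)
    missing = [s for s in case_ids + control_ids if s not in wide.columns]
    if missing:
        raise CountTableError(f"samples absent from density table: {missing}")
    case_mean = wide[case_ids].mean(axis=1)
    control_mean = wide[control_ids].mean(axis=1)
    log2fc = np.log2((case_mean + pseudo) / (control_mean + pseudo))
    out = pd.DataFrame(
        {
            "gene_id": wide.index,
            "feature": feature,
            "case_mean": case_mean.to_numpy(),
            "control_mean": control_mean.to_numpy(),
            "log2fc": log2fc.to_numpy(),
        }
    ).reset_index(drop=True)
    out.attrs.update(
        {"case_group": case, "control_group": control, "pseudo": pseudo}
    )
    return out
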