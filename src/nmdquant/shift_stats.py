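"""Distribution-shift statistics for fold-change tables.

Three analyses share this module: intron-retention summaries (histogram
plus a one-sided Mann-Whitney test of intron fold changes against a
reference distribution), gene-set ECDF shift tests (two-sided
Mann-Whitney of set members against the background), and per-gene group
comparisons normalised to control means with unpaired t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .counts_io import SampleSheet

EXACT_MAX_PRODUCT = 400  # exact Mann-Whitney p up to n_a * n_b of this size

HIST_BINS = 50
HIST_RANGE = (-4.0, 4.0)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (e.g. published NMD-target lists)."""

    name: str
    members: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


def read_gene_set(path: str | Path, name: str | None = None, source: str = "") -> GeneSet:
    """Read a plain-text gene list, one identifier per line."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    return GeneSet(name or Path(path).stem, frozenset(ids), source)


class ECDF:
    """Right-continuous empirical CDF of a finite sample."""

    def __init__(self, values) -> None:
        arr = np.asarray(values, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size == 0:
            raise ValueError("ECDF needs at least one finite value")
        self.x = np.sort(arr)
        self.n = arr.size

    def __call__(self, q) -> np.ndarray | float:
        out = np.searchsorted(self.x, np.asarray(q, dtype=float), side="right") / self.n
        return out if np.ndim(q) else float(out)

    def steps(self) -> pd.DataFrame:
        """(x, F(x)) at the distinct sample values, for plotting."""
        ux, counts = np.unique(self.x, return_counts=True)
        return pd.DataFrame({"x": ux, "F": np.cumsum(counts) / self.n})


def ecdf(values) -> ECDF:
    return ECDF(values)


def mann_whitney(
    sample_a, sample_b, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U (midrank ties) with exact p for small tie-free samples.

    The exact null distribution is used when n_a * n_b <= 400 and there
    are no ties; otherwise the normal approximation with tie and
    continuity corrections.  Returns (U of sample_a, p).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples need at least one value")
    combined = np.concatenate([a, b])
    if np.unique(combined).size == 1:
        warnings.warn("all values identical across both samples; p = 1", stacklevel=2)
        return a.size * b.size / 2.0, 1.0
    has_ties = np.unique(combined).size < combined.size
    if a.size * b.size <= EXACT_MAX_PRODUCT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class ShiftTestResult:
    """Mann-Whitney comparison of a gene set (or intron set) vs background."""

    set_name: str
    n_set: int
    n_background: int
    U: float
    p_value: float
    alternative: str
    median_set: float
    median_background: float
    median_shift: float
    ecdf_set: pd.DataFrame = field(repr=False)
    ecdf_background: pd.DataFrame = field(repr=False)
    n_requested: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "set_name": self.set_name,
                    "n_set": self.n_set,
                    "n_background": self.n_background,
                    "U": self.U,
                    "p_value": self.p_value,
                    "alternative": self.alternative,
                    "median_set": self.median_set,
                    "median_background": self.median_background,
                    "median_shift": self.median_shift,
                }
            ]
        )


def _shift_result(
    name: str,
    set_values: np.ndarray,
    background_values: np.ndarray,
    alternative: str,
    n_requested: int | None = None,
) -> ShiftTestResult:
    U, p = mann_whitney(set_values, background_values, alternative=alternative)
    med_set = float(np.median(set_values))
    med_bg = float(np.median(background_values))
    return ShiftTestResult(
        set_name=name,
        n_set=int(set_values.size),
        n_background=int(background_values.size),
        U=U,
        p_value=p,
        alternative=alternative,
        median_set=med_set,
        median_background=med_bg,
        median_shift=med_set - med_bg,
        ecdf_set=ECDF(set_values).steps(),
        ecdf_background=ECDF(background_values).steps(),
        n_requested=n_requested,
    )


def intron_retention_summary(
    intron_fc: pd.DataFrame,
    reference,
    alternative: str = "greater",
    bins: int = HIST_BINS,
    hist_range: tuple[float, float] = HIST_RANGE,
) -> tuple[ShiftTestResult, pd.DataFrame]:
    """Summarise intron fold changes against a reference distribution.

    ``reference`` is either the matching exonic fold-change table for
    the same contrast or an explicit array of log2 fold changes.
    Returns the shift test (one-sided by default: introns shifted up)
    and a histogram table of the intron log2 fold changes, clipped to
    ``hist_range``.
    """
    values = np.asarray(intron_fc["log2fc"], dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 10:
        raise ValueError("need at least 10 introns for a retention summary")
    if isinstance(reference, pd.DataFrame):
        ref = np.asarray(reference["log2fc"], dtype=float)
    else:
        ref = np.asarray(reference, dtype=float)
    ref = ref[np.isfinite(ref)]
    if ref.size == 0:
        raise ValueError("reference distribution is empty")

    result = _shift_result("introns", values, ref, alternative)
    clipped = np.clip(values, *hist_range)
    edges = np.linspace(*hist_range, bins + 1)
    hist, _ = np.histogram(clipped, bins=edges)
    hist_df = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "n_introns": hist}
    )
    hist_df.attrs["median_log2fc"] = float(np.median(values))
    hist_df.attrs["median_fold_change"] = float(2 ** np.median(values))
    return result, hist_df


def geneset_shift_test(
    gene_fc: pd.DataFrame,
    gene_set: GeneSet,
    alternative: str = "two-sided",
    background: str = "complement",
) -> ShiftTestResult:
    """Compare set-member fold changes against the background distribution.

    The background defaults to all genes not in the set; ``'all'`` uses
    every gene including set members (the all-genes curve of a CDF plot).
    """
    fc = gene_fc.dropna(subset=["log2fc"])
    in_set = fc["gene_id"].isin(gene_set.members)
    set_values = fc.loc[in_set, "log2fc"].to_numpy(dtype=float)
    if set_values.size < 2:
        found = set(fc.loc[in_set, "gene_id"])
        missing = sorted(gene_set.members - found)
        raise ValueError(
            f"gene set {gene_set.name!r}: only {set_values.size} member(s) found "
            f"in the fold-change table; missing e.g. {missing[:10]}"
        )
    if background == "complement":
        bg_values = fc.loc[~in_set, "log2fc"].to_numpy(dtype=float)
    elif background == "all":
        bg_values = fc["log2fc"].to_numpy(dtype=float)
    else:
        raise ValueError("background must be 'complement' or 'all'")
    return _shift_result(
        gene_set.name, set_values, bg_values, alternative, n_requested=len(gene_set)
    )


@dataclass
class GeneCompareResult:
    """Control-mean-normalised expression of one gene with a group t-test."""

    gene_id: str
    case_group: str
    control_group: str
    normalized: pd.DataFrame  # sample_id, group, normalized value
    case_mean: float
    control_mean: float
    t_statistic: float
    p_value: float
    boxplot: pd.DataFrame  # per group: median, q1, q3, whisker_low, whisker_high


def _boxplot_stats(values: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
    }


def per_gene_group_compare(
    density: pd.DataFrame,
    sheet: SampleSheet,
    genes,
    case: str,
    control: str,
    equal_var: bool = True,
) -> list[GeneCompareResult]:
    """Compare per-sample gene RPM between groups, normalised to controls.

    Gene abundance is the exon-row RPM.  Each sample's value is divided
    by the control-group mean (so the control normalised mean is 1) and
    groups are compared with a two-sided unpaired t-test (pooled
    variance by default; Welch with ``equal_var=False``).
    """
    case_ids = sheet.samples_in_group(case)
    control_ids = sheet.samples_in_group(control)
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise ValueError("need at least 2 samples per group for a t-test")
    exon = density[density["feature_type"] == "exon"]
    wide = exon.pivot_table(index="gene_id", columns="sample_id", values="rpm")

    results: list[GeneCompareResult] = []
    for gene in genes:
        if gene not in wide.index:
            warnings.warn(f"gene {gene!r} absent from density table; skipped", stacklevel=2)
            continue
        row = wide.loc[gene]
        control_mean = float(row[control_ids].mean())
        if control_mean == 0:
            warnings.warn(f"gene {gene!r}: zero control mean; skipped", stacklevel=2)
            continue
        norm = row / control_mean
        case_vals = norm[case_ids].to_numpy(dtype=float)
        control_vals = norm[control_ids].to_numpy(dtype=float)
        t_res = stats.ttest_ind(case_vals, control_vals, equal_var=equal_var)
        if np.isnan(t_res.pvalue):  # both groups constant and equal
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = float(t_res.statistic), float(t_res.pvalue)
        box = pd.DataFrame(
            [
                {"group": case, **_boxplot_stats(case_vals)},
                {"group": control, **_boxplot_stats(control_vals)},
            ]
        )
        tidy = pd.DataFrame(
            {
                "sample_id": list(case_ids) + list(control_ids),
                "group": [case] * len(case_ids) + [control] * len(control_ids),
                "normalized": np.concatenate([case_vals, control_vals]),
            }
        )
        results.append(
            GeneCompareResult(
                gene_id=gene,
                case_group=case,
                control_group=control,
                normalized=tidy,
                case_mean=float(case_vals.mean()),
                control_mean=float(control_vals.mean()),
                t_statistic=t_stat,
                p_value=p,
                boxplot=box,
            )
        )
    return results


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; raw p is the default)."""
    return stats.false_discovery_control(np.asarray(p_values, dtype=float), method="bh")
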