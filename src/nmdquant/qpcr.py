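"""RT-qPCR relative quantification from Ct values.

Implements the comparative-Ct (delta-delta-Ct) workflow: technical
replicates are averaged first, each target is normalised to a reference
transcript (GAPDH by default), and each condition is expressed relative
to the control condition.  Fold change = 2^(-ddCt), assuming 100%
amplification efficiency (a doubling per cycle); a per-target
efficiency override is available.

The "ratio t-test" reported alongside fold changes is a one-sample
two-sided t-test of the per-replicate log2 fold changes against zero,
i.e. a test of ratio = 1 on the log scale.

Nuclear/cytoplasmic fractionation: per-fraction abundance is 2^(-Ct)
and the nuclear fraction is N / (N + C); transcripts with strongly
compartmentalised controls (U1 snRNA nuclear, GAPDH mRNA cytoplasmic)
anchor the scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_REFERENCE = "GAPDH"
CT_RANGE = (5.0, 40.0)
REPLICATE_SPREAD_WARN = 0.5  # cycles


class QpcrError(ValueError):
    pass


@dataclass
class QpcrPlate:
    """Ct wells plus the reference target and control condition.

    ``wells`` columns: sample_id, condition, target, replicate, ct.
    A sample is one biological replicate (one transfection/experiment);
    ``replicate`` indexes technical replicates within a well.
    """

    wells: pd.DataFrame
    reference_target: str = DEFAULT_REFERENCE
    control_condition: str = "control"

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.wells).copy()
        required = ["sample_id", "condition", "target", "replicate", "ct"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise QpcrError(f"plate missing columns: {missing}")
        ct = pd.to_numeric(df["ct"], errors="coerce")
        if not np.isfinite(ct).all():
            raise QpcrError("non-finite Ct value in plate")
        outside = (ct < CT_RANGE[0]) | (ct > CT_RANGE[1])
        if outside.any():
            warnings.warn(
                f"{int(outside.sum())} Ct value(s) outside the typical "
                f"{CT_RANGE[0]}-{CT_RANGE[1]} range",
                stacklevel=2,
            )
        df["ct"] = ct
        self.wells = df.reset_index(drop=True)

    @classmethod
    def read_csv(
        cls,
        path: str | Path,
        reference_target: str = DEFAULT_REFERENCE,
        control_condition: str = "control",
    ) -> "QpcrPlate":
        return cls(pd.read_csv(path), reference_target, control_condition)

    def write_csv(self, path: str | Path) -> None:
        out = self.wells.sort_values(["condition", "sample_id", "target", "replicate"])
        out.to_csv(path, index=False)


def average_technical_replicates(plate: QpcrPlate) -> QpcrPlate:
    """Collapse technical replicates to one mean Ct per (sample, target)."""
    df = plate.wells
    grouped = df.groupby(["sample_id", "condition", "target"], sort=True)["ct"]
    spread = grouped.max() - grouped.min()
    wide_spread = spread[spread > REPLICATE_SPREAD_WARN]
    for key, delta in wide_spread.items():
        warnings.warn(
            f"technical replicate spread {delta:.2f} cycles for {key}", stacklevel=2
        )
    averaged = grouped.mean().reset_index()
    averaged["replicate"] = 1
    return replace(plate, wells=averaged)


@dataclass
class RelativeExpression:
    """Per-(condition, target) fold changes relative to the control condition.

    ``summary`` columns: condition, target, n, fold_change (geometric
    mean of per-replicate 2^(-ddCt)), log2_sd, t, p_value.
    ``replicates`` holds the per-biological-replicate log2 fold changes.
    """

    summary: pd.DataFrame
    replicates: pd.DataFrame
    reference_target: str
    control_condition: str


def relative_expression(plate: QpcrPlate, efficiency: dict[str, float] | None = None) -> RelativeExpression:
    """Comparative-Ct quantification against reference target and control.

    Per biological replicate: dCt = Ct(target) - Ct(reference);
    ddCt = dCt - mean dCt over control-condition replicates;
    fold change = E^(-ddCt) with E = 2 (or a per-target efficiency).
    """
    averaged = average_technical_replicates(plate)
    df = averaged.wells
    ref = plate.reference_target
    control = plate.control_condition
    if control not in set(df["condition"]):
        raise QpcrError(f"control condition {control!r} absent from plate")

    ref_ct = df[df["target"] == ref].set_index("sample_id")["ct"]
    targets = df[df["target"] != ref]
    missing_ref = sorted(set(targets["sample_id"]) - set(ref_ct.index))
    if missing_ref:
        raise QpcrError(f"reference target {ref!r} missing for samples: {missing_ref}")

    work = targets.copy()
    work["dct"] = work["ct"].to_numpy() - ref_ct.reindex(work["sample_id"]).to_numpy()

    rep_rows = []
    for target, sub in work.groupby("target", sort=True):
        ctrl = sub[sub["condition"] == control]
        if ctrl.empty:
            raise QpcrError(f"no control-condition wells for target {target!r}")
        ctrl_mean_dct = ctrl["dct"].mean()
        eff = 2.0 if efficiency is None else float(efficiency.get(target, 2.0))
        for _, row in sub.iterrows():
            ddct = row["dct"] - ctrl_mean_dct
            log2fc = -ddct * np.log2(eff)
            rep_rows.append(
                {
                    "condition": row["condition"],
                    "target": target,
                    "sample_id": row["sample_id"],
                    "ddct": ddct,
                    "log2_fold_change": log2fc,
                    "fold_change": 2.0 ** log2fc,
                }
            )
    replicates = pd.DataFrame(rep_rows)

    summary_rows = []
    for (condition, target), sub in replicates.groupby(["condition", "target"], sort=True):
        log2fc = sub["log2_fold_change"].to_numpy(dtype=float)
        mean_log2 = float(log2fc.mean())
        sd = float(log2fc.std(ddof=1)) if log2fc.size > 1 else np.nan
        if condition == control or log2fc.size < 2 or sd == 0 or not np.isfinite(sd):
            t = p = np.nan
        else:
            t, _, p = ratio_t_test(log2fc)
        summary_rows.append(
            {
                "condition": condition,
                "target": target,
                "n": int(log2fc.size),
                "fold_change": float(2.0 ** mean_log2),
                "log2_fold_change": mean_log2,
                "log2_sd": sd,
                "t": t,
                "p_value": p,
            }
        )
    summary = pd.DataFrame(summary_rows)
    return RelativeExpression(summary, replicates, ref, control)


def ratio_t_test(log2_fold_changes) -> tuple[float, int, float]:
    """One-sample two-sided t of per-replicate log2 fold changes vs 0.

    Returns (t, df, p).  Testing the mean log-ratio against zero is the
    standard reading of a "ratio t-test" (ratio = 1 on the raw scale).
    """
    x = np.asarray(log2_fold_changes, dtype=float)
    if x.size < 2:
        raise QpcrError("ratio t-test needs at least 2 replicates")
    if np.all(x == x[0]):  # zero spread
        if x[0] == 0:
            return 0.0, int(x.size - 1), 1.0
        raise QpcrError("degenerate replicate set")
    res = stats.ttest_1samp(x, popmean=0.0)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)


@dataclass
class NuclearFractionResult:
    """Nuclear fraction per transcript with condition comparisons.

    ``fractions``: per (condition, target, sample) nuclear fraction in
    [0, 1].  ``summary``: per (condition, target) mean, sd, n and a
    two-sided unpaired t-test p-value against the control condition.
    """

    fractions: pd.DataFrame
    summary: pd.DataFrame
    control_condition: str


def nuclear_fraction(plate_nuc: QpcrPlate, plate_cyt: QpcrPlate) -> NuclearFractionResult:
    """Nuclear fraction N/(N+C) from per-fraction abundances 2^(-Ct).

    Equal fraction volumes are assumed; no cross-fraction normaliser is
    applied (compartment-restricted transcripts such as U1 snRNA and
    GAPDH mRNA serve as internal controls).
    """
    nuc = average_technical_replicates(plate_nuc).wells
    cyt = average_technical_replicates(plate_cyt).wells
    key = ["sample_id", "condition", "target"]
    merged = nuc.merge(cyt, on=key, suffixes=("_nuc", "_cyt"), how="outer", indicator=True)
    unmatched = merged[merged["_merge"] != "both"]
    for _, row in unmatched.iterrows():
        warnings.warn(
            f"target {row['target']!r} in sample {row['sample_id']!r} measured in "
            "only one fraction; skipped",
            stacklevel=2,
        )
    merged = merged[merged["_merge"] == "both"].drop(columns="_merge")
    a_nuc = 2.0 ** (-merged["ct_nuc"].to_numpy(dtype=float))
    a_cyt = 2.0 ** (-merged["ct_cyt"].to_numpy(dtype=float))
    merged["nuclear_fraction"] = a_nuc / (a_nuc + a_cyt)
    fractions = merged[key + ["nuclear_fraction"]].sort_values(key).reset_index(drop=True)

    control = plate_nuc.control_condition
    rows = []
    for (condition, target), sub in fractions.groupby(["condition", "target"], sort=True):
        vals = sub["nuclear_fraction"].to_numpy(dtype=float)
        ctrl_vals = fractions.query(
            "condition == @control and target == @target"
        )["nuclear_fraction"].to_numpy(dtype=float)
        if condition == control or vals.size < 2 or ctrl_vals.size < 2:
            p = np.nan
        else:
            p = float(stats.ttest_ind(vals, ctrl_vals).pvalue)
        rows.append(
            {
                "condition": condition,
                "target": target,
                "n": int(vals.size),
                "mean_nuclear_fraction": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                "p_value": p,
            }
        )
    return NuclearFractionResult(fractions, pd.DataFrame(rows), control)
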