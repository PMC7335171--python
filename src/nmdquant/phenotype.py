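"""Phenotype statistics: neuronal survival and stress-granule fractions.

Survival: longitudinally imaged fluorescently labelled neurons counted
before (t0) and 48 h after peptide treatment; the survival fraction is
n_t48 / n_t0.  Conditions are compared to the control within each
independent experiment (the pairing unit), the per-experiment ratio
S_condition / S_control is averaged, and a two-sided paired t-test is
run on the per-experiment log ratios.

Stress granules: per experiment, the fraction of transfected cells with
granules; conditions are compared to control with two-sided unpaired
t-tests on the per-experiment fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SURVIVAL_COLUMNS = ["condition", "experiment_id", "n_t0", "n_t48"]
SG_COLUMNS = ["condition", "experiment_id", "n_transfected", "n_sg_positive"]


class PhenotypeError(ValueError):
    pass


def validate_survival(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise PhenotypeError(f"survival table missing columns: {missing}")
    if (df["n_t0"] <= 0).any():
        raise PhenotypeError("n_t0 must be positive")
    if (df["n_t48"] < 0).any():
        raise PhenotypeError("n_t48 must be non-negative")
    over = df["n_t48"] > df["n_t0"]
    if over.any():
        warnings.warn(
            f"{int(over.sum())} record(s) with n_t48 > n_t0 (survival > 1)",
            stacklevel=2,
        )
    return df


def survival_fraction(n_t0: int, n_t48: int) -> float:
    """S = surviving / initial neurons."""
    if n_t0 <= 0:
        raise PhenotypeError("n_t0 must be positive")
    if n_t48 < 0:
        raise PhenotypeError("n_t48 must be non-negative")
    return n_t48 / n_t0


@dataclass
class RelativeSurvivalResult:
    """Per-condition change in survival relative to control.

    ``summary`` columns: condition, n_experiments, mean_ratio,
    percent_change (100 * (mean per-experiment ratio - 1)),
    percent_change_ratio_of_means (alternative aggregation), t, p_value
    (paired t on per-experiment log ratios).
    """

    summary: pd.DataFrame
    ratios: pd.DataFrame  # condition, experiment_id, survival, control_survival, ratio
    control: str


def relative_survival(records: pd.DataFrame, control: str) -> RelativeSurvivalResult:
    df = validate_survival(pd.DataFrame(records)).copy()
    df["survival"] = df["n_t48"] / df["n_t0"]
    conditions = [c for c in df["condition"].unique() if c != control]
    if control not in set(df["condition"]):
        raise PhenotypeError(f"control condition {control!r} absent")
    ctrl = df[df["condition"] == control].set_index("experiment_id")["survival"]
    if ctrl.index.duplicated().any():
        raise PhenotypeError("multiple control records for one experiment")

    ratio_rows = []
    summary_rows = []
    for condition in conditions:
        sub = df[df["condition"] == condition]
        paired = sub[sub["experiment_id"].isin(ctrl.index)]
        dropped = sub[~sub["experiment_id"].isin(ctrl.index)]
        for _, row in dropped.iterrows():
            warnings.warn(
                f"experiment {row['experiment_id']} of {condition!r} has no "
                "control pair; excluded",
                stacklevel=2,
            )
        if paired.empty:
            continue
        ratios = (
            paired["survival"].to_numpy(dtype=float)
            / ctrl.reindex(paired["experiment_id"]).to_numpy(dtype=float)
        )
        for (_, row), ratio in zip(paired.iterrows(), ratios):
            ratio_rows.append(
                {
                    "condition": condition,
                    "experiment_id": row["experiment_id"],
                    "survival": row["survival"],
                    "control_survival": ctrl[row["experiment_id"]],
                    "ratio": ratio,
                }
            )
        log_ratios = np.log2(ratios)
        if ratios.size >= 2 and log_ratios.std(ddof=1) > 0:
            res = stats.ttest_1samp(log_ratios, 0.0)
            t, p = float(res.statistic), float(res.pvalue)
        elif np.allclose(log_ratios, 0):
            t, p = 0.0, 1.0
        else:
            t = p = np.nan
        summary_rows.append(
            {
                "condition": condition,
                "n_experiments": int(ratios.size),
                "mean_ratio": float(ratios.mean()),
                "percent_change": float(100.0 * (ratios.mean() - 1.0)),
                "percent_change_ratio_of_means": float(
                    100.0
                    * (
                        paired["survival"].mean()
                        / ctrl.reindex(paired["experiment_id"]).mean()
                        - 1.0
                    )
                ),
                "t": t,
                "p_value": p,
            }
        )
    return RelativeSurvivalResult(
        pd.DataFrame(summary_rows), pd.DataFrame(ratio_rows), control
    )


@dataclass
class SGStatsResult:
    """Per-condition stress-granule-positive fractions vs control."""

    summary: pd.DataFrame  # condition, n_experiments, mean_fraction, sd, t, p_value
    fractions: pd.DataFrame  # condition, experiment_id, fraction
    control: str


def sg_positive_stats(records: pd.DataFrame, control: str) -> SGStatsResult:
    df = pd.DataFrame(records).copy()
    missing = [c for c in SG_COLUMNS if c not in df.columns]
    if missing:
        raise PhenotypeError(f"SG table missing columns: {missing}")
    if (df["n_transfected"] <= 0).any():
        raise PhenotypeError("n_transfected must be positive")
    if (df["n_sg_positive"] > df["n_transfected"]).any():
        raise PhenotypeError("n_sg_positive cannot exceed n_transfected")
    if control not in set(df["condition"]):
        raise PhenotypeError(f"control condition {control!r} absent")
    df["fraction"] = df["n_sg_positive"] / df["n_transfected"]

    ctrl_vals = df.loc[df["condition"] == control, "fraction"].to_numpy(dtype=float)
    rows = []
    for condition, sub in df.groupby("condition", sort=True):
        vals = sub["fraction"].to_numpy(dtype=float)
        if condition == control or vals.size < 2 or ctrl_vals.size < 2:
            t = p = np.nan
        else:
            res = stats.ttest_ind(vals, ctrl_vals)
            if np.isnan(res.pvalue):  # zero variance in both groups
                t, p = (0.0, 1.0) if np.isclose(vals.mean(), ctrl_vals.mean()) else (np.nan, np.nan)
            else:
                t, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "condition": condition,
                "n_experiments": int(vals.size),
                "mean_fraction": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                "t": t,
                "p_value": p,
            }
        )
    return SGStatsResult(
        pd.DataFrame(rows),
        df[["condition", "experiment_id", "fraction"]].copy(),
        control,
    )
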