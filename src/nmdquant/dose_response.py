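"""Decomposition of NMD inhibition into translational repression.

The core quantitative idea: treat cells with increasing doses of either
an arginine-rich dipeptide peptide (PR20) or cycloheximide (CHX, a pure
translation-elongation inhibitor), measure for every sample both

* translational repression x = -log2(translation activity), where
  activity is the luciferase-activity / luciferase-mRNA ratio
  normalised to the vehicle control, and
* NMD-target accumulation y = log2(target abundance / control mean),

and fit, per compound and target, a zero-intercept line y = beta * x in
log2-log2 space.  Because CHX inhibits NMD only through translation,
the slope ratio F = 100 * beta_PR / beta_CHX is the percentage of
PR20-induced target accumulation explained by translational repression.
Concentration enters only through the measured repression; dose units
never appear in the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VEHICLE_LABELS = frozenset({"DMSO", "vehicle", "untreated", "control"})
BETA_TOLERANCE = 1e-9
BOOTSTRAP_DRAWS = 2000

REQUIRED_COLUMNS = [
    "compound",
    "concentration",
    "replicate",
    "luc_activity",
    "luc_mrna",
    "target",
    "target_abundance",
]


class DoseResponseError(ValueError):
    pass


def read_dose_response(path: str | Path) -> pd.DataFrame:
    """Read a tidy dose-response CSV (one row per compound/dose/replicate/target)."""
    df = pd.read_csv(path)
    return validate_points(df)


def validate_points(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DoseResponseError(f"dose-response table missing columns: {missing}")
    for col in ("luc_activity", "luc_mrna", "target_abundance"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if not (np.isfinite(vals) & (vals > 0)).all():
            raise DoseResponseError(f"{col} must be positive and finite")
    if not is_control(df).any():
        raise DoseResponseError("no vehicle-control points (concentration 0 or DMSO)")
    return df


def is_control(df: pd.DataFrame) -> pd.Series:
    """Vehicle-control rows: zero concentration or a vehicle compound label."""
    return (pd.to_numeric(df["concentration"]) == 0) | df["compound"].isin(VEHICLE_LABELS)


def translation_activity(points: pd.DataFrame) -> pd.DataFrame:
    """Normalised translation activity and repression per point.

    activity = (luc_activity / luc_mrna) / mean control ratio;
    repression = -log2(activity).  The control rows themselves average
    to activity 1 (geometrically in repression, arithmetically in the
    ratio used for normalisation).
    """
    df = validate_points(points).copy()
    ratio = df["luc_activity"] / df["luc_mrna"]
    control = is_control(df)
    control_mean = ratio[control].mean()
    df["translation_activity"] = ratio / control_mean
    df["repression"] = -np.log2(df["translation_activity"])
    return df


@dataclass
class ZeroInterceptFit:
    """Least-squares line through the origin, y = beta * x."""

    compound: str
    target: str
    slope: float
    n: int
    rss: float
    stderr: float
    x: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)


def fit_zero_intercept(x, y, compound: str = "", target: str = "") -> ZeroInterceptFit:
    """Fit y = beta * x by least squares: beta = sum(xy) / sum(x^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise DoseResponseError("x and y must be equal-length with n >= 2")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise DoseResponseError("all x values are 0; slope undefined")
    beta = float(np.sum(x * y) / sxx)
    resid = y - beta * x
    rss = float(np.sum(resid**2))
    stderr = float(np.sqrt(rss / (x.size - 1) / sxx))
    return ZeroInterceptFit(compound, target, beta, int(x.size), rss, stderr, x, y)


@dataclass
class FractionExplained:
    """Percent of PR-driven target accumulation explained by repression."""

    target: str
    fraction_percent: float
    beta_pr: float
    beta_chx: float
    ci_low: float | None = None
    ci_high: float | None = None


def fraction_explained(
    fit_pr: ZeroInterceptFit,
    fit_chx: ZeroInterceptFit,
    bootstrap: bool = False,
    n_boot: int = BOOTSTRAP_DRAWS,
    seed: int | None = None,
) -> FractionExplained:
    """F = 100 * beta_PR / beta_CHX, optionally with a bootstrap CI.

    The CI resamples (x, y) points with replacement within each
    compound and reports the percentile interval of the refit ratio.
    """
    if fit_pr.target != fit_chx.target:
        raise DoseResponseError(
            f"target mismatch: {fit_pr.target!r} vs {fit_chx.target!r}"
        )
    if abs(fit_chx.slope) < BETA_TOLERANCE:
        raise DoseResponseError("reference (CHX) slope is ~0; fraction undefined")
    frac = 100.0 * fit_pr.slope / fit_chx.slope
    ci_low = ci_high = None
    if bootstrap:
        if fit_pr.x is None or fit_chx.x is None:
            raise DoseResponseError("fits must retain their points for bootstrap")
        rng = np.random.default_rng(seed)
        draws = np.empty(n_boot)
        for i in range(n_boot):
            ip = rng.integers(0, fit_pr.n, fit_pr.n)
            ic = rng.integers(0, fit_chx.n, fit_chx.n)
            bp = fit_zero_intercept(fit_pr.x[ip], fit_pr.y[ip]).slope
            bc = fit_zero_intercept(fit_chx.x[ic], fit_chx.y[ic]).slope
            draws[i] = 100.0 * bp / bc if abs(bc) >= BETA_TOLERANCE else np.nan
        draws = draws[np.isfinite(draws)]
        ci_low, ci_high = (float(v) for v in np.percentile(draws, [2.5, 97.5]))
    return FractionExplained(
        fit_pr.target, float(frac), fit_pr.slope, fit_chx.slope, ci_low, ci_high
    )


@dataclass
class DoseResponseResult:
    """Output of the full decomposition: fits, fractions and plot data."""

    fits: dict[tuple[str, str], ZeroInterceptFit]  # (compound, target) -> fit
    fractions: dict[str, FractionExplained]  # target -> F
    coordinates: pd.DataFrame  # compound, target, concentration, repression, log2_target_fc

    def fits_frame(self) -> pd.DataFrame:
        rows = [
            {
                "compound": f.compound,
                "target": f.target,
                "slope": f.slope,
                "stderr": f.stderr,
                "n": f.n,
                "rss": f.rss,
            }
            for f in self.fits.values()
        ]
        return pd.DataFrame(rows).sort_values(["target", "compound"]).reset_index(drop=True)

    def fractions_frame(self) -> pd.DataFrame:
        rows = [
            {
                "target": fr.target,
                "fraction_explained_percent": fr.fraction_percent,
                "beta_pr": fr.beta_pr,
                "beta_chx": fr.beta_chx,
                "ci_low": fr.ci_low,
                "ci_high": fr.ci_high,
            }
            for fr in self.fractions.values()
        ]
        return pd.DataFrame(rows).sort_values("target").reset_index(drop=True)


def dose_response_pipeline(
    raw: pd.DataFrame,
    targets: list[str] | None = None,
    test_compound: str = "PR20",
    reference_compound: str = "CHX",
    per_replicate: bool = False,
    bootstrap: bool = False,
    seed: int | None = None,
) -> DoseResponseResult:
    """Chain activity normalisation, per-target fold changes and fits.

    Target abundances (already reference-normalised, relative units) are
    converted to log2 fold changes against the mean of vehicle-control
    points; treated points of each compound are then regressed on
    measured repression through the origin.  ``per_replicate=True``
    fits each replicate series separately and averages the slopes
    instead of pooling all points.
    """
    df = translation_activity(raw)
    control = is_control(df)
    present = set(df.loc[~control, "compound"])
    for compound in (test_compound, reference_compound):
        sub = df[~control & (df["compound"] == compound)]
        if sub.empty:
            raise DoseResponseError(f"missing compound: {compound!r}")
        if sub["concentration"].nunique() < 2:
            raise DoseResponseError(
                f"compound {compound!r} needs >= 2 non-control concentrations"
            )
    if targets is None:
        targets = sorted(df["target"].unique())

    fits: dict[tuple[str, str], ZeroInterceptFit] = {}
    coord_rows = []
    for target in targets:
        tsub = df[df["target"] == target]
        if tsub.empty:
            raise DoseResponseError(f"target {target!r} absent from table")
        ctrl_mean = tsub.loc[is_control(tsub), "target_abundance"].mean()
        for compound in (test_compound, reference_compound):
            csub = tsub[~is_control(tsub) & (tsub["compound"] == compound)]
            x = csub["repression"].to_numpy(dtype=float)
            y = np.log2(csub["target_abundance"].to_numpy(dtype=float) / ctrl_mean)
            if per_replicate:
                slopes = []
                for _, rsub in csub.assign(_y=y, _x=x).groupby("replicate"):
                    slopes.append(
                        fit_zero_intercept(rsub["_x"], rsub["_y"], compound, target).slope
                    )
                pooled = fit_zero_intercept(x, y, compound, target)
                pooled.slope = float(np.mean(slopes))
                fits[(compound, target)] = pooled
            else:
                fits[(compound, target)] = fit_zero_intercept(x, y, compound, target)
            coord_rows.append(
                pd.DataFrame(
                    {
                        "compound": compound,
                        "target": target,
                        "concentration": csub["concentration"].to_numpy(),
                        "replicate": csub["replicate"].to_numpy(),
                        "repression": x,
                        "log2_target_fc": y,
                    }
                )
            )

    fractions = {
        target: fraction_explained(
            fits[(test_compound, target)],
            fits[(reference_compound, target)],
            bootstrap=bootstrap,
            seed=seed,
        )
        for target in targets
    }
    coordinates = pd.concat(coord_rows, ignore_index=True)
    return DoseResponseResult(fits, fractions, coordinates)
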