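"""Seeded generators for every analysis stage, with recorded ground truth.

Each generator is a pure function of its configuration (which carries
the seed): the same config yields bit-identical output.  Defaults mimic
the study conditions each analysis was designed for:

* counts: two groups of bulk RNA-seq samples with per-gene exon/intron
  counts.  Case-group intron counts are inflated by gene-specific
  log-normal factors whose median is the configured intron fold change
  (2.1 for a c9ALS-like contrast; 0.87 mimics the sporadic-ALS
  contrast); exon counts of NMD-target set members are shifted by a
  configured log2 distribution.  Counts are negative-binomial
  (dispersion 0.1) around the group means.
* qPCR: Ct values from known fold changes with Gaussian cycle noise,
  constant reference target, two technical replicates per well.
* dose-response: a monotone Hill-shaped dose-to-repression map per
  compound; target log2 fold changes follow the zero-intercept model
  y = beta * repression plus log-scale noise.
* survival / stress granules: binomial counts per experiment at
  configured per-condition probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd

from .counts_io import FeatureCountTable, SampleSheet
from .shift_stats import GeneSet


@dataclass
class SimulationConfig:
    """Knobs for every generator; defaults are the study conditions."""

    seed: int = 0

    # count matrix
    n_genes: int = 5000
    n_set: int = 275
    n_samples_per_group: int = 4
    case_group: str = "c9ALS"
    control_group: str = "control"
    baseline_log_mean: float = np.log(200.0)  # exon counts at nominal depth
    baseline_log_sd: float = 1.0
    library_size_nominal: int = 2_000_000  # uniquely mapped reads per sample
    library_size_log_sd: float = 0.05
    nb_dispersion: float = 0.1
    intron_fraction_baseline: float = 0.3
    exon_length_bp: int = 1500
    intron_length_bp: int = 5000
    intron_median_log2_shift: float = np.log2(2.1)
    intron_log2_shift_sd: float = 0.5
    set_shift_mean: float = 0.5  # log2, applied to set-member exon counts
    set_shift_sd: float = 0.2

    # qPCR
    qpcr_fold_changes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "GR": {"ATF4": 3.0, "UPF3B": 2.0, "HIST1H2AC": 2.5},
            "PR": {"ATF4": 3.5, "UPF3B": 2.2, "HIST1H2AC": 2.8},
        }
    )
    qpcr_control_condition: str = "GFP"
    qpcr_reference_target: str = "GAPDH"
    qpcr_ct_noise_sd: float = 0.2
    qpcr_n_replicates: int = 3  # biological (independent experiments)
    qpcr_baseline_ct: float = 26.0
    qpcr_reference_ct: float = 18.0

    # dose-response
    beta_pr: float = 1.0
    beta_chx: float = 1.0
    dose_log_noise_sd: float = 0.1
    pr_concentrations: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)  # uM
    chx_concentrations: tuple[float, ...] = (0.03, 0.06, 0.12, 0.24)  # ug/mL
    dose_n_replicates: int = 3
    dose_targets: tuple[str, ...] = ("ATF4", "UPF3B", "HIST1H2AC")
    max_repression_log2: float = 3.0  # Hill plateau of the dose->repression map

    # survival
    survival_probs: dict[str, float] = field(
        default_factory=lambda: {"vector": 0.200, "UPF1": 0.342, "UPF1-mut": 0.210}
    )
    survival_control: str = "vector"
    survival_n_experiments: int = 6
    survival_n_t0: int = 200

    # stress granules
    sg_probs: dict[str, float] = field(
        default_factory=lambda: {"GFP": 0.02, "GR": 0.45, "PR": 0.24}
    )
    sg_control: str = "GFP"
    sg_n_experiments: int = 4
    sg_n_transfected: int = 100

    def __post_init__(self) -> None:
        if self.n_set > self.n_genes:
            raise ValueError("n_set cannot exceed n_genes")
        if not 0 < self.intron_fraction_baseline < 1:
            raise ValueError("intron_fraction_baseline must be in (0, 1)")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(
    config: SimulationConfig,
) -> tuple[FeatureCountTable, SampleSheet, GeneSet, pd.DataFrame]:
    """Two-group exon/intron count matrix with known per-gene effects.

    Returns (counts, sample sheet, NMD-target-like gene set, truth).
    The truth table records each gene's intron inflation factor and
    exon (gene-set) shift factor in the case group.

    Sequencing depth (uniquely mapped reads) is drawn per sample around
    a nominal value and written to the sample sheet; per-gene count
    means scale with each sample's depth, so the configured factors are
    exactly the expected RPM fold changes the pipeline should recover.
    Annotated exon/intron counts are deliberately only a fraction of
    the library, as in real data.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(n)])

    baseline_exon = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n)
    baseline_intron = baseline_exon * config.intron_fraction_baseline

    intron_factor = 2.0 ** rng.normal(
        config.intron_median_log2_shift, config.intron_log2_shift_sd, n
    )
    set_idx = rng.choice(n, size=config.n_set, replace=False)
    exon_factor = np.ones(n)
    exon_factor[set_idx] = 2.0 ** rng.normal(
        config.set_shift_mean, config.set_shift_sd, config.n_set
    )

    n_per = config.n_samples_per_group
    samples, groups, lib_sizes, columns = [], [], [], {}
    for group, ex_mu, in_mu in [
        (config.control_group, baseline_exon, baseline_intron),
        (config.case_group, baseline_exon * exon_factor, baseline_intron * intron_factor),
    ]:
        for j in range(n_per):
            sid = f"{group}_{j + 1}"
            samples.append(sid)
            groups.append(group)
            depth = int(
                config.library_size_nominal
                * rng.lognormal(0.0, config.library_size_log_sd)
            )
            lib_sizes.append(depth)
            scale = depth / config.library_size_nominal
            exon_counts = _nb_counts(rng, ex_mu * scale, config.nb_dispersion)
            intron_counts = _nb_counts(rng, in_mu * scale, config.nb_dispersion)
            columns[sid] = (exon_counts, intron_counts)

    rows = {
        "gene_id": np.repeat(gene_ids, 2),
        "feature_type": np.tile(["exon", "intron"], n),
        "length_bp": np.tile([config.exon_length_bp, config.intron_length_bp], n),
    }
    frame = pd.DataFrame(rows)
    for sid, (ex, intr) in columns.items():
        interleaved = np.empty(2 * n, dtype=np.int64)
        interleaved[0::2] = ex
        interleaved[1::2] = intr
        frame[sid] = interleaved

    table = FeatureCountTable(frame)
    sheet = SampleSheet(
        pd.DataFrame(
            {"sample_id": samples, "group": groups, "library_size": lib_sizes}
        )
    )
    gene_set = GeneSet("simulated_nmd_targets", frozenset(gene_ids[set_idx]), "synthetic")
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "baseline_exon_mean": baseline_exon,
            "intron_factor": intron_factor,
            "exon_factor": exon_factor,
            "in_set": np.isin(np.arange(n), set_idx),
        }
    )
    truth.attrs["median_intron_fold_change"] = float(
        2.0 ** config.intron_median_log2_shift
    )
    return table, sheet, gene_set, truth


def simulate_fold_changes(
    n_background: int,
    n_set: int,
    shift_log2: float,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, GeneSet]:
    """Gene-level log2 fold changes with an injected set shift.

    Lightweight generator for calibration/power studies of the gene-set
    shift test: background fold changes are Normal(0, noise_sd) and set
    members get ``shift_log2`` added.
    """
    rng = np.random.default_rng(seed)
    total = n_background + n_set
    gene_ids = [f"G{i:05d}" for i in range(total)]
    log2fc = rng.normal(0.0, noise_sd, total)
    set_ids = frozenset(gene_ids[:n_set])
    log2fc[:n_set] += shift_log2
    fc = pd.DataFrame({"gene_id": gene_ids, "feature": "gene", "log2fc": log2fc})
    return fc, GeneSet("simulated_set", set_ids, "synthetic")


def simulate_qpcr(config: SimulationConfig):
    """Ct plate generated from known fold changes.

    Ct(target) = baseline - log2(relative abundance) + Normal(0, sd)
    per technical replicate; the reference target is condition
    independent.  Returns (QpcrPlate, truth frame).
    """
    from .qpcr import QpcrPlate

    rng = np.random.default_rng(config.seed)
    conditions = [config.qpcr_control_condition] + sorted(config.qpcr_fold_changes)
    targets = sorted({t for fcs in config.qpcr_fold_changes.values() for t in fcs})
    rows = []
    truth_rows = []
    for condition in conditions:
        for rep in range(1, config.qpcr_n_replicates + 1):
            sample_id = f"{condition}_rep{rep}"
            for target in targets + [config.qpcr_reference_target]:
                if target == config.qpcr_reference_target:
                    base = config.qpcr_reference_ct
                    fc = 1.0
                else:
                    base = config.qpcr_baseline_ct
                    fc = (
                        1.0
                        if condition == config.qpcr_control_condition
                        else config.qpcr_fold_changes[condition][target]
                    )
                true_ct = base - np.log2(fc)
                for tech in (1, 2):
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "condition": condition,
                            "target": target,
                            "replicate": tech,
                            "ct": true_ct + rng.normal(0.0, config.qpcr_ct_noise_sd),
                        }
                    )
        for target in targets:
            truth_rows.append(
                {
                    "condition": condition,
                    "target": target,
                    "true_fold_change": 1.0
                    if condition == config.qpcr_control_condition
                    else config.qpcr_fold_changes[condition][target],
                }
            )
    plate = QpcrPlate(
        pd.DataFrame(rows),
        reference_target=config.qpcr_reference_target,
        control_condition=config.qpcr_control_condition,
    )
    return plate, pd.DataFrame(truth_rows)


def _hill_repression(conc: np.ndarray, ec50: float, plateau: float) -> np.ndarray:
    """Monotone dose-to-repression map (shape is free; only the
    repression-to-abundance relation matters to the fitted model)."""
    conc = np.asarray(conc, dtype=float)
    return plateau * conc / (conc + ec50)


def simulate_dose_response(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dose-response table obeying the zero-intercept log-log model.

    Per compound, true repression follows a Hill curve over the dose
    grid; measured luciferase activity and target abundances carry
    independent log2 noise.  Returns (points, truth) where truth holds
    the generating slopes and their ratio.
    """
    rng = np.random.default_rng(config.seed)
    compounds = {
        "PR20": (np.asarray(config.pr_concentrations), config.beta_pr, "uM"),
        "CHX": (np.asarray(config.chx_concentrations), config.beta_chx, "ug/mL"),
    }
    sd = config.dose_log_noise_sd
    rows = []
    for rep in range(1, config.dose_n_replicates + 1):
        # vehicle control point
        act = 2.0 ** rng.normal(0.0, sd)
        mrna = 2.0 ** rng.normal(0.0, sd)
        for target in config.dose_targets:
            rows.append(
                {
                    "compound": "DMSO",
                    "concentration": 0.0,
                    "conc_units": "",
                    "replicate": rep,
                    "luc_activity": act * mrna,
                    "luc_mrna": mrna,
                    "target": target,
                    "target_abundance": 2.0 ** rng.normal(0.0, sd),
                }
            )
        for compound, (concs, beta, units) in compounds.items():
            ec50 = float(np.median(concs))
            repression = _hill_repression(concs, ec50, config.max_repression_log2)
            for conc, r in zip(concs, repression):
                activity = 2.0 ** (-r + rng.normal(0.0, sd))
                mrna = 2.0 ** rng.normal(0.0, sd)
                for target in config.dose_targets:
                    y = beta * r + rng.normal(0.0, sd)
                    rows.append(
                        {
                            "compound": compound,
                            "concentration": float(conc),
                            "conc_units": units,
                            "replicate": rep,
                            "luc_activity": activity * mrna,
                            "luc_mrna": mrna,
                            "target": target,
                            "target_abundance": 2.0 ** y,
                        }
                    )
    truth = pd.DataFrame(
        {
            "target": list(config.dose_targets),
            "beta_pr": config.beta_pr,
            "beta_chx": config.beta_chx,
            "true_fraction_percent": 100.0 * config.beta_pr / config.beta_chx,
        }
    )
    return pd.DataFrame(rows), truth


def simulate_survival(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binomial survival counts per condition and experiment."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for exp in range(1, config.survival_n_experiments + 1):
        for condition, p in config.survival_probs.items():
            n_t0 = config.survival_n_t0
            rows.append(
                {
                    "condition": condition,
                    "experiment_id": exp,
                    "n_t0": n_t0,
                    "n_t48": int(rng.binomial(n_t0, p)),
                }
            )
    truth = pd.DataFrame(
        [
            {
                "condition": c,
                "true_survival": p,
                "true_percent_change": 100.0
                * (p / config.survival_probs[config.survival_control] - 1.0),
            }
            for c, p in config.survival_probs.items()
        ]
    )
    return pd.DataFrame(rows), truth


def simulate_sg(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binomial stress-granule-positive counts per condition/experiment."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for exp in range(1, config.sg_n_experiments + 1):
        for condition, p in config.sg_probs.items():
            rows.append(
                {
                    "condition": condition,
                    "experiment_id": exp,
                    "n_transfected": config.sg_n_transfected,
                    "n_sg_positive": int(rng.binomial(config.sg_n_transfected, p)),
                }
            )
    truth = pd.DataFrame(
        [{"condition": c, "true_fraction": p} for c, p in config.sg_probs.items()]
    )
    return pd.DataFrame(rows), truth
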