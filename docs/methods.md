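# Methods

`nmdquant` quantifies inhibition of UPF1-mediated RNA decay — including
nonsense-mediated decay (NMD) — from bulk RNA-seq count tables, RT-qPCR
plates, dose-response assays and imaging-derived phenotype counts. This
note records the models, the defaults and why, the numerical choices,
and what the synthetic-data generators do and do not emulate.

## Read densities and fold changes (`counts_io`)

Inputs are per-gene exonic and intronic read counts (one `exon` and one
`intron` row per gene) with feature lengths, plus a sample sheet with
group labels and library sizes (uniquely mapped reads). The pipeline:

1. **Expression filter.** Genes averaging fewer than 1 read/sample
   (exon + intron combined) are excluded. The exclusion is strict:
   a mean of exactly 1 is retained. The filter is idempotent.
2. **Densities.** RPM = count × 10⁶ / library size. Intron (and exon)
   *read density* is operationalised as RPM per kilobase of feature
   length; gene-level mRNA abundance is the exon row's plain RPM.
   If library sizes are missing the per-sample total of assigned reads
   is used instead, with a warning — assigned-feature totals understate
   uniquely mapped reads and couple the normaliser to the biology being
   measured (see the generator section below).
3. **Fold changes.** log₂((mean_case + p)/(mean_control + p)) with a
   pseudo-RPM p = 0.1 added to all values (configurable). The pseudo
   count keeps ratios finite and shrinks fold changes of barely
   expressed features toward zero; it makes fold change antisymmetric
   under a case/control swap.

Interval counting (`count_feature_reads`) is a desk-scale substitute
for genome-arithmetic tools: reads overlap features by ≥ 1 bp in
0-based half-open coordinates, strand is ignored, and a read touching
both an exon and an intron of the same gene is counted as exonic
(junction reads come from spliced molecules more often than not, and a
deterministic priority prevents double counting). A read may count for
several overlapping genes but at most one feature type per gene.
Intronic signal is aggregated per gene, not per individual intron.

## Distribution-shift statistics (`shift_stats`)

* **Mann–Whitney U** uses midranks for ties, the exact null
  distribution when n₁·n₂ ≤ 400 and no ties are present, and otherwise
  the normal approximation with tie and continuity corrections. If all
  values are identical across both samples the test degenerates; p = 1
  is returned with a warning.
* **Intron-retention summary**: median intron log₂ fold change, a
  histogram over [−4, 4] (50 bins, clipped; presentational only), and
  a one-sided (greater) test of intron fold changes against a reference
  distribution. The default reference is the same contrast's exonic
  fold changes — exons share all sample-level artefacts but not the
  retention signal. An explicit reference array is accepted instead
  (e.g. the same statistic from a different contrast).
* **Gene-set shift test**: set members' gene-level fold changes vs the
  complement of the set (default) or vs all genes; two-sided by
  default. It is a rank test, hence invariant under monotone transforms
  of the fold changes. Calibration at the design size used here
  (275-gene set vs 10 000 background) is checked by simulation: type-I
  error 0.05 ± 0.02 at α = 0.05.
* **Per-gene comparisons** divide each sample's gene RPM by the
  control-group mean (so the control normalised mean is 1 by
  construction) and use a classical pooled-variance two-sided unpaired
  t-test; Welch is available by flag. Genes with a zero control mean
  are skipped with a warning. Box stats use whiskers at 1.5 × IQR.
* No multiple-testing correction is applied by default (per-set raw p
  values are reported); Benjamini–Hochberg is available.

## qPCR relative quantification (`qpcr`)

Comparative-Ct with 100% assumed amplification efficiency (a doubling
per cycle; per-target efficiencies can be supplied). Technical
replicates are always averaged first; a spread above 0.5 cycles is
flagged. Per biological replicate, ΔCt = Ct(target) − Ct(reference
transcript, GAPDH by default) and ΔΔCt subtracts the mean control ΔCt;
fold change = 2^(−ΔΔCt). Condition-level fold changes are geometric
means of per-replicate values, which makes the control condition's
reported fold change exactly 1.

The *ratio t-test* is a one-sample two-sided t-test of per-replicate
log₂ fold changes against zero, i.e. a test of ratio = 1. The log scale
is chosen because ratios are multiplicative and their logs are closer
to normal at n = 3; this is the standard construction but it is a
modelling decision, stated here because the term alone does not pin it
down. A degenerate replicate set (identical non-zero log-ratios) is an
error rather than p = 0.

Nuclear fractionation: per-fraction abundance is 2^(−Ct) and the
nuclear fraction is N/(N + C), assuming equal fraction volumes and no
cross-fraction normaliser; compartment-restricted transcripts (U1
snRNA, GAPDH mRNA) act as internal controls. The fraction is bounded
in [0, 1] and monotone decreasing in the nuclear Ct.

## Dose-response decomposition (`dose_response`)

Translation activity = (luciferase activity / luciferase mRNA),
normalised to the mean over vehicle-control points; repression
x = −log₂(activity) so that inhibitors have positive x. Per compound
and NMD-target transcript, target log₂ fold change y (vs the control
mean) is regressed on x through the origin: β = Σxy/Σx², with
se(β) = √(RSS/(n−1)/Σx²). The zero intercept encodes the boundary
condition that no repression means no accumulation.

The **fraction explained** for a target is F = 100 · β_PR/β_CHX, with
cycloheximide (CHX) as the pure-translation-inhibition reference: it is
the accumulation per unit repression under the peptide relative to that
under a compound acting only through translation. Concentrations never
enter the fit — only measured repression does — so F is invariant to
rescaling the dose axes and to the shape of the dose→repression map.
|β_CHX| < 10⁻⁹ is an error. Points are pooled across replicates by
default; a per-replicate mode fits each replicate series and averages
slopes. An optional bootstrap CI resamples points with replacement
within each compound (2000 draws, percentile interval, seeded).

## Phenotype statistics (`phenotype`)

Survival fraction S = n(48 h)/n(0 h) per condition and independent
experiment; S > 1 warns but is kept (late divisions or segmentation
drift). The experiment is the pairing unit: per experiment the ratio
S_condition/S_control is formed, the headline percent change is
100 × (mean ratio − 1) (the ratio-of-means aggregation is also
reported), and the paired two-sided t-test runs on per-experiment log₂
ratios. Unpaired experiments are excluded with a warning.

Stress-granule statistics are per-experiment positive fractions with
two-sided unpaired t-tests against control on untransformed
proportions — appropriate at the small replicate counts involved
(an arcsine transform is a documented alternative left to the caller).

## Synthetic data (`simulate`)

Every generator is a pure function of its `SimulationConfig` (which
carries the seed); identical configs give bit-identical outputs.

* **Counts.** Two groups × 4 samples. Per-gene baseline exon means are
  log-normal (median 200 reads at nominal depth, log-sd 1); intron
  means are a fixed fraction (0.3) of the exon mean. Case-group intron
  means are multiplied by gene-specific log-normal factors whose median
  is the configured intron fold change (default 2.1, the magnitude of
  a strong retention phenotype; 0.87 reproduces a near-null contrast);
  NMD-target set members (275 genes of 5000) get exon shifts drawn from
  Normal(0.5, 0.2) in log₂. Counts are negative-binomial with
  dispersion 0.1 — typical bulk RNA-seq over-dispersion. Sequencing
  depth is drawn per sample around 2 × 10⁶ uniquely mapped reads
  (log-sd 0.05) and written to the sample sheet, and per-gene means
  scale with depth. Annotated exon+intron counts are deliberately only
  part of the library, as in real data; normalising by the supplied
  depth rather than by the assigned-read total is what makes the
  configured factors the exact expected RPM fold changes (dividing by
  the assigned total would deflate case samples by the very intron
  signal being measured — a composition artefact the generator is
  designed not to bake into its truth).
* **qPCR.** Ct = baseline − log₂(true relative abundance) + Gaussian
  cycle noise (sd 0.2) independently per technical replicate (two per
  well, three biological replicates); the reference target is
  condition-independent.
* **Dose-response.** Dose grids inside the assay's working ranges
  (PR₂₀ 1–8 μM, CHX 0.03–0.24 μg/mL, 4 doses × 3 replicates plus
  vehicle controls). True repression follows a monotone Hill curve of
  dose (plateau 3 log₂ units, EC₅₀ at the median dose) — the shape is
  arbitrary because only the repression→abundance relation is fitted.
  Measured activity and target abundances carry independent log₂ noise
  (sd 0.1); target log₂ fold change is β · repression + noise.
* **Phenotypes.** Binomial counts at configured per-condition
  probabilities (survival: 0.200 control, 0.342 wild-type-UPF1 rescue,
  i.e. a +71% relative increase; stress granules: 45%/24%/2% for
  poly(GR)/poly(PR)/control), with 200 neurons or 100 transfected cells
  per experiment at the defaults.

What the generators do **not** emulate: gene-length and GC biases,
spliced-alignment ambiguity, correlated noise between introns and exons
of a gene, batch effects, amplification-efficiency drift across a qPCR
plate, compound toxicity breaking dose monotonicity, or segmentation
error in the imaging counts. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated noise
models, not robustness to these real-data complications.

## Problem sizes and numerical choices

Simulation-based checks use 5000 genes × 8 samples for count analyses,
2000/200 replicate simulations for gene-set calibration/power, 500
simulations at 4 doses × 3 replicates for the dose-response recovery,
and large-count binomials (2 × 10⁴ per condition) for phenotype
convergence — sizes at which the Monte-Carlo error is comfortably
below the tolerances being asserted while a full run stays in the
tens of seconds. Exact Mann–Whitney enumeration is capped at
n₁·n₂ ≤ 400; seeded `numpy` `Generator` streams are used throughout,
spawned via `SeedSequence` so that sub-analyses are independent.

## Known limitations

* Intron retention is quantified per gene (aggregate intronic density),
  not per intron; a per-interval mode exists in the interval counter
  but the statistics operate on gene-level rows.
* The expression filter and pseudo-count interact: features whose
  density is of the order of the pseudo-count (0.1 RPM-equivalents)
  have fold changes shrunk toward zero by construction.
* The ΔΔCt model assumes equal efficiency for target and reference;
  the efficiency override mitigates but does not remove this.
* The fraction-explained statistic inherits the zero-intercept
  assumption; targets whose accumulation saturates at high repression
  will show dose-dependent slopes that the single-β model averages.
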