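# nmdquant

Quantitative analysis of UPF1-mediated RNA-decay inhibition, the kind
of deficit seen in C9orf72 ALS/FTD, where arginine-rich dipeptide
repeat proteins (poly(GR), poly(PR)) suppress nonsense-mediated decay
(NMD). The package is for computational biologists who have count
tables, qPCR plates or imaging-derived counts in hand and want the
downstream statistics as a tested, scriptable pipeline:

* **Intron retention** — exon/intron read densities (RPM, RPM/kb) from
  per-gene count tables, a strict <1-read/sample expression filter,
  pseudo-count-stabilised log₂ fold changes
  (log₂((μ_case + 0.1)/(μ_ctrl + 0.1))), and one-sided Mann–Whitney
  tests of intron vs reference fold-change distributions.
* **Gene-set shifts** — ECDFs of gene-level fold changes for published
  NMD-target sets against the background, with exact or tie-corrected
  asymptotic two-sided Mann–Whitney *U* tests.
* **qPCR** — comparative-Ct (ΔΔCt) relative quantification: technical
  replicate averaging, reference-gene (GAPDH) and control-condition
  normalisation, fold change = 2^(−ΔΔCt), one-sample *ratio t-tests*
  on per-replicate log₂ fold changes, and nuclear fractions
  N/(N + C) from fractionated samples.
* **Dose-response decomposition** — translation activity from
  luciferase activity/mRNA ratios, repression x = −log₂(activity),
  zero-intercept log–log fits y = βx per compound and target
  (β = Σxy/Σx²), and the fraction of peptide-induced NMD-target
  accumulation explained by translational repression,
  F = 100 · β_PR/β_CHX, with cycloheximide as the
  pure-translation-inhibition reference.
* **Phenotypes** — neuronal survival fractions with paired t-tests on
  per-experiment log ratios, and stress-granule-positive fractions
  with unpaired t-tests.
* **Synthetic data** — seeded generators for every stage with recorded
  ground truth, so the full pipeline is verifiable end to end without
  any external download.

## Worked example

```python
import numpy as np
from nmdquant import *

cfg = SimulationConfig(seed=42)
table, sheet, nmd_set, truth = simulate_counts(cfg)
table = filter_low_expression(table)            # drop genes < 1 read/sample
density = compute_density(table, sheet)         # RPM and RPM/kb
intron = fold_change(density, sheet, "c9ALS", "control", feature="intron")
exon = fold_change(density, sheet, "c9ALS", "control", feature="exon")
result, hist = intron_retention_summary(intron, exon)
print(f"median intron fold change: {hist.attrs['median_fold_change']:.2f}")
print(f"one-sided Mann-Whitney p:  {result.p_value:.3g}")

gene = fold_change(density, sheet, "c9ALS", "control", feature="gene")
shift = geneset_shift_test(gene, nmd_set)
print(f"NMD-target set shift: {shift.median_shift:+.2f} log2, p = {shift.p_value:.3g}")

points, _ = simulate_dose_response(cfg)
decomp = dose_response_pipeline(points)
for target, fr in decomp.fractions.items():
    print(f"{target}: fraction explained = {fr.fraction_percent:.0f}%")
```

prints

```
median intron fold change: 2.09
one-sided Mann-Whitney p:  0
NMD-target set shift: +0.52 log2, p = 6.33e-84
ATF4: fraction explained = 97%
HIST1H2AC: fraction explained = 96%
UPF3B: fraction explained = 97%
```

The generator was configured with a true median intron fold change of
2.1 and a +0.5 log₂ NMD-target shift, both recovered here; the
dose-response series were generated with equal PR₂₀ and CHX slopes
(true fraction 100%), and the fitted per-target fractions land within
a few percent of it. A fraction near 100% means the target's
accumulation under the peptide is fully accounted for by the measured
loss of translation.

The same stages are available from a shell via the `nmdquant` CLI
(`simulate`, `quant`, `retention`, `setshift`, `qpcr`, `dose`,
`phenotype`, `report`); every run writes a `manifest.json` with input
hashes and parameters. See `docs/methods.md` for models, defaults and
limitations.

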