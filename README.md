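# zeitprot

Time-of-day interaction proteomics and circadian analysis for plant clock
biology.

Affinity purification coupled with mass spectrometry (APMS) performed at two
Zeitgeber times (e.g. ZT5 and ZT9, hours after lights-on) can reveal protein
interactions that exist only at a particular time of day — for instance
evening-specific partners of the Arabidopsis RVE8–LNK1/LNK2 circadian
transcription complex such as COR27 and COR28. `zeitprot` implements the
complete computational chain for such a study as a tested, reusable library:

* **Interactor calling** from spectral-count matrices: peptide-evidence
  filtering (≥2 unique peptides, or 1 peptide seen in >1 replicate),
  presence-based negative-control subtraction (one spectrum in a GFP/untagged
  control excludes a protein), parsimony grouping of proteins with shared
  peptide evidence, per-bait×timepoint calls, and early-only / late-only /
  shared classification keyed on AGI locus.
* **Term enrichment** of interactor sets by the one-sided hypergeometric
  test over a flat gene→term map, with optional Benjamini–Hochberg control.
* **Circadian rhythm analysis** of luciferase reporter traces: FFT-seeded
  nonlinear least-squares (FFT-NLLS) estimation of period τ, amplitude A and
  acrophase φ of `y(t) = c₀ + c₁t + Σᵢ Aᵢ·cos(2π(t − φᵢ)/τᵢ)`, with the
  relative amplitude error RAE = (95% CI half-width of A)/A as the
  rhythmicity measure; daily acrophase extraction under entrainment; the
  Rayleigh statistic R = |Σ e^{iθ}|/n with its analytic p-value; one-way
  ANOVA with Tukey HSD letter groupings for period comparisons; and
  Welch-test resynchronization analysis for temperature/photo entrainment.
* **Quantification**: western-blot densitometry normalization
  (background-subtracted inverted density, loading-control ratio, per-biorep
  max = 100) and dual-luciferase firefly/renilla fold changes with per-leaf
  no-effector normalization.
* **Sequence alignment**: global affine-gap alignment (gap of length L costs
  open + L·extend; free end gaps; identity over the full alignment length)
  with BLOSUM62, matching EMBOSS `needle` semantics with open 10.0 /
  extend 0.5.
* **Synthetic data** for every input class, with known ground truth, so the
  whole pipeline is testable without any external download.

## Worked example

Three curated interactor tables ship with the package: `table1` (clock baits
at ZT5, 31 proteins × 6 runs), `table2` (clock baits at ZT9, 32 × 6) and
`table3` (COR27/COR28 baits at ZT9, 21 × 8).

```python
import zeitprot as zp

t1 = zp.load_table_fixture("table1")   # ZT5
t2 = zp.load_table_fixture("table2")   # ZT9

# bait capture is strongest at each protein's time of peak abundance
zp.bait_max_spectra(t2, "LNK1-HFC", 9, "AT5G64170")   # -> 621
zp.bait_max_spectra(t1, "LNK2-HFC", 5, "AT3G54500")   # -> 497

from zeitprot.interactors import call_all_interactors, classify_timepoints
cls = classify_timepoints(call_all_interactors(t1), call_all_interactors(t2))
cls.counts          # -> {'early_only': 9, 'late_only': 10, 'shared': 22}
cls.labels["AT5G42900"]   # -> 'late_only'  (COR27 is an evening-specific interactor)
cls.labels["AT3G55580"]   # -> 'shared'     (TCF1 coprecipitates at both times)
```

Rhythm fitting on a synthetic reporter trace:

```python
import numpy as np
from zeitprot.rhythm import LuminescenceTrace, fit_fft_nlls

t = np.arange(0, 120.0, 1.0)            # 5 days, hourly imaging
y = 5 + 2 * np.cos(2 * np.pi * (t - 4) / 24.0)
fit = fit_fft_nlls(LuminescenceTrace(times=t, values=y))
(fit.period_h, fit.amplitude, fit.acrophase_ct, fit.rhythmic)
# -> (24.0, 2.0, 4.0, True)
```

The same stages are available from the shell (`zeitprot --help`):
`simulate`, `call-interactors`, `classify`, `enrich`, `rhythm`, `entrain`,
`blot`, `dualluc`, `align`, and `run` for a full pipeline from a YAML config:

```yaml
# config.yaml
counts: [table1, table2]     # fixture names or paths to wide-format TSVs
out_dir: out
seed: 1
```

```sh
zeitprot run config.yaml     # writes interactor_calls.tsv, classification.tsv,
                             # venn_counts.json, manifest.json under out/
```

### Input formats

Spectral counts are tab-separated, wide format: `protein_name`, `agi_locus`,
optional `mw_kda`/`cycling` columns, then one column per purification run
named `BAIT_ZT<t>_<rep>` (controls use bait `none`); a long dialect with a
sidecar run-metadata table handles free-form run ids. Luminescence traces
are CSV with `time_h, luminescence, plant_id, genotype, condition_segment`.
Annotation and cycling maps are two-column TSVs; sequences are FASTA. The
`zeitprot simulate` subcommand writes an example of every format together
with its ground-truth JSON.

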