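# Methods

This note records the models and procedures `zeitprot` implements, the
defaults that matter, and the choices made where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Interactor calling from spectral counts

The unit of evidence is the spectral count: the number of MS/MS spectra
assigned to a protein in one purification run. Runs carry a bait, a
Zeitgeber time (ZT, hours after lights-on), a replicate index and a control
flag; control runs are purifications from untagged or free-fluorophore
material.

The calling chain is:

1. **Evidence filter.** Within each bait×timepoint group, a protein passes
   if some replicate identifies it with ≥ 2 unique peptides, or if it has
   ≥ 1 unique peptide in ≥ 2 replicates of that group (the single-peptide
   rescue). Proteins passing in no group are dropped. Peptide-level
   probability/FDR thresholds (peptide probability > 0.95, FDR < 1%,
   protein probability > 99.9%) are applied only when a peptide-level table
   is supplied; curated count tables have already been through an
   identification engine's thresholds, so on such input the filter is a
   logged no-op. All five thresholds are configurable
   (`EvidenceThresholds`).
2. **Control subtraction.** Presence-based: a single spectrum in any
   control run excludes the protein globally, across baits and timepoints.
   This is deliberately conservative — spectral counts in controls are not
   compared quantitatively to bait counts, because sticky background binds
   beads regardless of the bait. The operation is idempotent.
3. **Parsimony grouping.** Proteins with identical peptide sets merge;
   a protein whose peptide set is a strict subset of another's is absorbed
   into the superset protein's group (smallest, then lexicographically
   first superset — deterministic); groups that still share peptides are
   linked into a cluster without merging identities. Every protein lands in
   exactly one group.
4. **Calls and classification.** An interactor call per bait×timepoint is
   the set of proteins with ≥ 1 spectrum in ≥ 1 replicate, reported in
   descending order of maximum spectra (ties by locus). Classification
   pools calls across baits within each of two timepoints and partitions
   the union into early-only / late-only / shared, keyed on AGI locus
   rather than protein name (the same locus can be named differently in
   different exports). Per-bait partitions are also reported.

The cycling cross-reference is a plain fraction: of the called loci that
appear in a locus→cycling map, the share flagged as having rhythmic mRNA;
unannotated loci are excluded from the denominator and reported separately.

## Enrichment

One-sided hypergeometric enrichment of a study set against a population
with a flat term→loci map: for a term with K annotated loci in the
population (size N) and k in the study (effective size n),
p = P(X ≥ k), X ~ Hypergeom(N, K, n). Raw p-values are the default output
(Benjamini–Hochberg adjustment by flag). No ontology-graph propagation is
performed; if ancestor terms should count, propagate upstream. The
recommended population is every protein detected across all runs before
filtering — the detected-proteome background.

## FFT-NLLS rhythm fitting

The model is a sum of cosines over a linear baseline:

    y(t) = c₀ + c₁·t + Σᵢ Aᵢ · cos(2π(t − φᵢ)/τᵢ)

fit by bounded nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective, ftol = xtol = gtol = 1e-12). The trend
coefficients are estimated jointly with the components: subtracting a
pre-fit trend instead leaves a linear leakage term the cosine model cannot
absorb whenever the span is not an integer number of periods, which biases
the period and inflates the residual.

Components are added greedily: the residual's zero-padded FFT amplitude
spectrum proposes candidate periods (local maxima inside the search
window, strongest first, seeded with the residual's quadrature
projections), and a component is kept only if the nested-model F-test on
the SSE improvement (3 extra parameters, α = 0.05) accepts it, up to
`max_components` (default 5). Two safeguards matter in practice:

* **Spectral-resolution separation.** Candidate frequencies closer than
  half the Rayleigh resolution (0.5/span) to an existing component are
  rejected, and a refit that drives two components within that distance is
  discarded. Without this, a damped oscillation is modelled as a beat of
  two near-identical frequencies with enormous cancelling amplitudes, and
  every derived statistic is meaningless.
* **Perfect-fit stop.** Iteration stops when the SSE falls below 1e-12 of
  the signal's variance, so noiseless input does not accumulate junk
  components.

The relative amplitude error of a component is
RAE = t₀.₉₇₅,dof · se(A) / A, with se(A) from the linearized covariance
s²(JᵀJ)⁻¹ at the optimum via the delta method on A = √(a² + b²). The
reported fit is the in-window component with the smallest RAE; a trace is
rhythmic when that RAE is below the threshold (default 0.6, the
conventional cutoff). Acrophase is φ = atan2(b, a)·τ/2π mapped into
[0, τ), in hours after trace start. Defaults: period window (15, 35) h;
the trace must span at least twice the window minimum. A constant trace
returns `rhythmic=False` with NaN period rather than raising.

The window/threshold internals of the classic desktop implementations of
this scheme are not published in detail; the formulation above is an
independent one with the same structure, and its accuracy is established
against generated truth (noiseless recovery to machine precision; damped
noisy recovery within ±0.2 h — both computed in the test suite).

## Acrophase, Rayleigh and entrainment statistics

Daily acrophase: within consecutive cycle-length windows (default 24 h)
anchored at the start of the relevant condition segment, the acrophase is
the time (mod cycle) of the maximum of the moving-average-smoothed trace
(default 3 h window, centered); an all-equal window yields NaN. Hourly
sampling bounds the single-day precision at ±0.5 h.

Rayleigh statistic: phases map to angles θ = 2π·phase/cycle;
R = |Σ e^{iθ}|/n, the mean phase is the resultant's argument, and
p = exp(√(1 + 4n + 4(n² − (nR)²)) − (1 + 2n)) — the standard analytic
approximation, exact at the R = 0 and R = 1 boundaries.

Period comparisons use one-way ANOVA with Tukey's HSD post hoc
(studentized-range distribution, via scipy) and a compact letter display:
one letter per maximal clique of the "not significantly different at
α = 0.05" graph, ordered by group mean.

Acrophase comparisons between genotypes are linear Welch tests after
unwrapping each day's phases into the half-cycle neighborhood of the
reference genotype's circular mean — appropriate because within-day phase
spread is small relative to the cycle; fully circular two-sample tests are
out of scope. The resynchronization day is the first testable day with
p ≥ 0.05 such that every later testable day also has p ≥ 0.05. Note the
definition's consequence: once two genotypes are truly aligned, each later
day still rejects with probability α, so single-run resynchronization
calls carry that irreducible error.

## Quantification

Densitometry (per lane): inverted density = (2^bits − 1) − mean gray
(8-bit default, configurable); net band and net loading subtract their
local background ROIs; abundance = net band / net loading; within each
(genotype, biorep) the values are rescaled so the maximum is 100. A
non-positive net loading density is an error for that lane. Equal-area
ROIs are an upstream contract, not checked here. Genotype contrasts are
per-timepoint Welch tests across bioreps at α = 0.05.

Dual-luciferase: per reading, ratio = (firefly − firefly background) /
(renilla − renilla background); readings with non-positive net renilla are
excluded with a warning. Fold change divides each ratio by the mean
no-effector ratio of the same leaf when leaf ids are present (else the
experiment mean), so per-leaf infection efficiency — which scales firefly
and renilla alike — cancels exactly, and the no-effector mean fold is 1 by
construction. Contrasts are Welch tests on folds, by default each effector
combination against the no-effector control.

`welch_t` itself is the textbook statistic with Satterthwaite degrees of
freedom; degenerate zero-variance input returns t = 0, p = 1 for equal
means and |t| = ∞, p = 0 otherwise, rather than NaN.

## Global affine-gap alignment

Three-state dynamic programming (aligned / gap-in-first / gap-in-second)
with gap cost open + L·extend for a gap of length L (defaults 10.0 / 0.5,
BLOSUM62), end gaps free by default — the convention of the EMBOSS
`needle` tool, including percent identity computed over the full alignment
length with gap columns in the denominator. Traceback is deterministic: on
score ties the diagonal move is preferred, then a gap in the first
sequence, then a gap in the second; the score itself is tie-break
invariant. Correctness is established against a DP-free oracle that
enumerates and scores every global alignment of short sequence pairs, and
against an independent aligner for the end-gap-penalized variant.

## Synthetic data: what it emulates, and what it does not

`simulate_apms` emulates the design of a two-timepoint APMS study: baits ×
timepoints × replicates plus control runs; planted interactors receive
negative-binomial counts (dispersion 0.5 — overdispersion is the norm in
spectral counting) proportional to capture strength, only in runs whose ZT
falls in their expression window (an evening-specific interactor is planted
by default); sticky background proteins receive counts in bait and control
runs alike. Two deliberate constructions make ground truth exact rather
than probabilistic: in-window planted counts are drawn as 1 + NB (never
zero), and each background protein is guaranteed at least one spectrum in
a control run. Consequently planted recall = 1 and background survival = 0
are invariants of the generator, and the corresponding checks test the
pipeline's bookkeeping, not its statistical power on marginal interactors —
real data, where true interactors can drop below detection in a replicate,
is harder than this simulation.

`simulate_traces` emulates free-run-then-entrainment imaging: a damped
cosine at the genotype's free-running period (default damping constant
96 h), then a 24 h cosine whose phase offset from the entrainer target
shrinks by the genotype's relock rate once per cycle (clamped at zero),
with per-plant phase jitter and multiplicative Gaussian noise (5%). The
per-cycle linear pull is a caricature of oscillator entrainment — there is
no phase-response curve and no amplitude dynamics — sufficient to exercise
the acrophase/resynchronization statistics, not to model clock physics.
Defaults: 16 plants per genotype, hourly sampling, 3 free-run days + 5
entrainment days, wild-type-like (24.6 h, fast relock) and mutant-like
(26.5 h, slow relock) genotypes.

`simulate_quant` emulates a diurnal western-blot series (tabulated
abundance curve peaking at ZT6 with a deep evening trough, 3-h sampling, 4
bioreps, 10% lognormal noise, linear mapping into 8-bit gray values) with
an optional evening-stabilization effect (default ×2 at ZT ≥ 9) on the
mutant genotype, and dual-luciferase plates (8 leaves, per-leaf lognormal
infection efficiency, multiplicative effector effects, additive plate
background). The trough-shaped curve matters: it keeps each biorep's
maximum at ZT6 in both genotypes, so the max = 100 normalization anchor is
unaffected by the evening effect and genotype contrasts at morning
timepoints stay null.

All generators take a seed and are byte-reproducible given it.

## Problem sizes used in the automated checks

Simulation-based checks run at sizes chosen to make their expected
variation small relative to the asserted tolerance: 20 seeds for damped
period recovery (tolerance ±0.2 h), 100 generator seeds for planted-truth
recovery, 10⁴ replicates for the 5% ± 1% null calibration of Welch and
ANOVA, 10⁴ permutations for the Tukey cross-check (±0.02), and a few
hundred short pairs for the alignment enumeration oracle (whose cost grows
as the Delannoy numbers, ~5·10⁴ alignments for a 7×7 pair).

## Known limitations

- Identification-engine internals (peptide/protein probability models) are
  consumed as input columns, never recomputed; raw spectrum processing and
  database search are out of scope.
- Control subtraction is presence-based by design; a quantitative
  enrichment-vs-control model (SAINT-style) is a non-goal.
- Enrichment treats annotation as flat; no ontology ancestor propagation.
- Acrophase statistics are linear-after-unwrapping, valid for concentrated
  phase distributions; heavily dispersed phases need circular methods.
- The alignment module is protein-only, global-only.
- Imaging gaps around lights-off transitions are ignored; sampling is
  treated as exactly uniform (the trace reader enforces uniformity to 1 s).
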