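"""Synthetic data generators with known ground truth.

Every input class the analysis stages consume can be generated here with a
seed and a truth record, so the whole pipeline is testable without any
external data: APMS spectral-count matrices with planted interactors and
sticky background proteins, luciferase traces under free run and temperature
entrainment, densitometry series, dual-luciferase plates, and flat
annotation/cycling maps.

The generators are deliberately caricatures: spectral counts are negative
binomial (overdispersed, as spectral counting is in practice) and phase
relocking under entrainment is a linear per-cycle pull rather than an
oscillator model. They exercise the analysis contracts, not the physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import CONTROL_BAIT, SpectralCountMatrix
from .quantify import DensitometryMeasurement, LuciferasePlateReading, NO_EFFECTOR
from .rhythm import LL, TEMP_CYCLE, LuminescenceTrace


def _nb_counts(rng: np.random.Generator, mean, dispersion: float, size=None):
    """Negative binomial draws parameterized by mean and dispersion k
    (variance = mean + mean^2 / k)."""
    mean = np.asarray(mean, dtype=float)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


# ---------------------------------------------------------------------------
# APMS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedInteractor:
    """A true interactor of a bait: capture strength (expected spectra per
    run at full capture) and the ZT window in which it is expressed."""

    locus: str
    capture_strength: float
    expression_window: tuple[float, float] = (0.0, 24.0)

    def expressed_at(self, zt: float) -> bool:
        lo, hi = self.expression_window
        return lo <= zt < hi


@dataclass
class ApmsSimConfig:
    """Design of a simulated APMS experiment.

    Defaults emulate a two-timepoint (ZT5/ZT9), two-replicate design with
    three tagged baits, negative-control purifications, a handful of planted
    interactors (one of them evening-specific), and sticky background
    proteins that precipitate in every run including the controls.
    """

    baits: tuple[str, ...] = ("RVE8-HFC", "LNK1-HFC", "LNK2-HFC")
    timepoints: tuple[float, ...] = (5.0, 9.0)
    replicates: int = 2
    true_interactome: dict[str, tuple[PlantedInteractor, ...]] | None = None
    n_background_proteins: int = 30
    background_stickiness_mean: float = 3.0
    bait_abundance: float = 20.0
    dispersion: float = 0.5
    control_runs: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_interactome is None:
            shared = (
                PlantedInteractor("AT1G10000", 1.5),
                PlantedInteractor("AT1G20000", 0.8),
            )
            evening = (PlantedInteractor("AT1G30000", 1.0, (7.0, 24.0)),)
            self.true_interactome = {bait: shared + evening for bait in self.baits}
        for bait, planted in self.true_interactome.items():
            for p in planted:
                if p.capture_strength <= 0:
                    raise ValueError(f"{bait}/{p.locus}: capture strength must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


def simulate_apms(config: ApmsSimConfig) -> tuple[SpectralCountMatrix, dict]:
    """Simulate a spectral-count matrix with planted ground truth.

    True interactors receive counts only in runs of their bait whose ZT lies
    inside their expression window; every replicate of such a run gets at
    least one spectrum, so planted interactors are recoverable by
    construction. Background proteins are sticky: they receive counts in
    bait and control runs alike, and are guaranteed at least one spectrum in
    some control run, so presence-based control subtraction removes them all.
    """
    rng = np.random.default_rng(config.seed)

    planted_loci = sorted(
        {p.locus for planted in config.true_interactome.values() for p in planted}
    )
    background_loci = [f"AT5G{80000 + i:05d}" for i in range(config.n_background_proteins)]
    loci = planted_loci + background_loci

    runs = {}
    for bait in config.baits:
        for zt in config.timepoints:
            for rep in range(1, config.replicates + 1):
                runs[f"{bait}_ZT{zt:g}_{rep}"] = {
                    "bait": bait,
                    "timepoint_zt": float(zt),
                    "replicate": rep,
                    "is_control": False,
                }
    for c in range(1, config.control_runs + 1):
        zt = config.timepoints[(c - 1) % len(config.timepoints)]
        runs[f"{CONTROL_BAIT}_ZT{zt:g}_{c}"] = {
            "bait": CONTROL_BAIT,
            "timepoint_zt": float(zt),
            "replicate": c,
            "is_control": True,
        }
    run_df = pd.DataFrame.from_dict(runs, orient="index")
    run_df.index.name = "run_id"

    planted_by_bait = {
        bait: {p.locus: p for p in planted} for bait, planted in config.true_interactome.items()
    }
    stickiness = rng.exponential(config.background_stickiness_mean, size=len(background_loci))

    total = np.zeros((len(loci), len(run_df)), dtype=np.int64)
    unique = np.zeros_like(total)
    for j, (run_id, run) in enumerate(run_df.iterrows()):
        for i, locus in enumerate(loci):
            if locus in planted_loci:
                p = planted_by_bait.get(run["bait"], {}).get(locus)
                if p is not None and p.expressed_at(run["timepoint_zt"]):
                    mean = p.capture_strength * config.bait_abundance / 10.0
                    total[i, j] = 1 + _nb_counts(rng, mean, config.dispersion)
            else:
                s = stickiness[i - len(planted_loci)]
                count = _nb_counts(rng, s, config.dispersion)
                if run["is_control"] and run["replicate"] == 1:
                    count = max(count, 1)  # sticky by construction
                total[i, j] = count
    # unique peptides: grows sublinearly with spectra, at least one per
    # identified protein, capped by the spectral count
    with np.errstate(divide="ignore"):
        unique = np.where(total > 0, np.minimum(total, 1 + np.floor(np.sqrt(total)).astype(np.int64) // 1), 0)

    proteins = pd.DataFrame(
        {
            "name": [f"SIM{i:03d}" for i in range(len(loci))],
            "mw_kda": np.round(rng.uniform(10, 150, size=len(loci)), 0),
            "cycling": [None] * len(loci),
        },
        index=pd.Index(loci, name="agi_locus"),
    )
    matrix = SpectralCountMatrix(
        proteins=proteins,
        runs=run_df,
        total_spectra=pd.DataFrame(total, index=proteins.index, columns=run_df.index),
        unique_peptides=pd.DataFrame(unique, index=proteins.index, columns=run_df.index),
    )
    truth = {
        "interactors": {
            bait: {p.locus: list(p.expression_window) for p in planted}
            for bait, planted in config.true_interactome.items()
        },
        "background": background_loci,
    }
    return matrix, truth


def simulate_annotations(
    truth: dict, seed: int = 0, n_terms: int = 5
) -> tuple[dict[str, set[str]], dict[str, bool]]:
    """Flat gene->term and gene->cycling maps consistent with an APMS truth.

    One term (``GO:PLANTED``) annotates exactly the planted interactors, so
    enrichment of a recovered interactor set against the full protein
    population must rank it first; the remaining terms annotate random
    subsets. Planted interactors are flagged cycling, background genes
    mostly not.
    """
    rng = np.random.default_rng(seed)
    planted = sorted({l for per_bait in truth["interactors"].values() for l in per_bait})
    background = list(truth["background"])
    all_loci = planted + background
    annotation: dict[str, set[str]] = {"GO:PLANTED": set(planted)}
    for k in range(n_terms - 1):
        size = rng.integers(2, max(3, len(all_loci) // 3))
        annotation[f"GO:RAND{k:02d}"] = set(rng.choice(all_loci, size=min(size, len(all_loci)), replace=False))
    cycling = {l: True for l in planted}
    cycling.update({l: bool(rng.random() < 0.3) for l in background})
    return annotation, cycling


# ---------------------------------------------------------------------------
# luciferase traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeClock:
    """Free-running clock parameters of one genotype."""

    period_h: float
    initial_phase_h: float = 0.0
    relock_rate_h_per_day: float = 6.0
    damping_h: float = 96.0

    def __post_init__(self) -> None:
        if not 15 < self.period_h < 35:
            raise ValueError(f"period {self.period_h} outside the plausible (15, 35) h range")
        if self.relock_rate_h_per_day < 0:
            raise ValueError("relock rate must be >= 0")


@dataclass
class TraceSimConfig:
    """Free-run-then-entrainment luciferase imaging experiment.

    Defaults emulate a temperature-entrainment design: 3 days of constant
    light free run followed by 5 days of 12 h cool : 12 h warm temperature
    cycles, 16 plants per genotype, hourly sampling, 5% multiplicative
    noise. The wild-type-like genotype relocks quickly; a mutant genotype
    can be given a slow relock rate.
    """

    genotypes: dict[str, GenotypeClock] = field(
        default_factory=lambda: {
            "wt": GenotypeClock(period_h=24.6, initial_phase_h=4.0, relock_rate_h_per_day=6.0),
            "mutant": GenotypeClock(period_h=26.5, initial_phase_h=4.0, relock_rate_h_per_day=2.0),
        }
    )
    freerun_days: int = 3
    entrain_days: int = 5
    entrainment: str = TEMP_CYCLE
    entrainer_peak_zt: float = 4.0
    noise_sd_frac: float = 0.05
    n_plants: int = 16
    sampling_min: float = 60.0
    plant_phase_sd_h: float = 0.3
    baseline: float = 100.0
    amplitude: float = 40.0
    seed: int = 0


def simulate_traces(config: TraceSimConfig) -> tuple[list[LuminescenceTrace], dict]:
    """Simulate per-plant luminescence traces with known phase truth.

    Free-run segment: damped cosine at the genotype's period. Entrainment
    segment: a 24 h cosine whose phase offset from the entrainer target
    shrinks by the genotype's relock rate each day (clamped at zero).
    Multiplicative Gaussian noise, floored at zero.
    """
    rng = np.random.default_rng(config.seed)
    dt = config.sampling_min / 60.0
    t_free = config.freerun_days * 24.0
    t_total = t_free + config.entrain_days * 24.0
    times = np.arange(0.0, t_total, dt)
    segments = [(0.0, t_free, LL), (t_free, t_total, config.entrainment)]

    traces = []
    truth: dict = {"offsets": {}, "config": {"entrainer_peak_zt": config.entrainer_peak_zt}}
    for genotype, clock in config.genotypes.items():
        # offset of the free-run peak relative to the entrainer target at onset
        free_peak = clock.initial_phase_h + clock.period_h * np.ceil((t_free - clock.initial_phase_h) / clock.period_h)
        onset_offset = ((free_peak - t_free) - config.entrainer_peak_zt + 12.0) % 24.0 - 12.0
        # the pull acts within each cycle, so day 0 already reflects one step
        offsets = []
        off = onset_offset
        for _d in range(config.entrain_days):
            step = min(abs(off), clock.relock_rate_h_per_day)
            off = off - np.sign(off) * step
            offsets.append(off)
        truth["offsets"][genotype] = list(map(float, offsets))

        for plant in range(config.n_plants):
            jitter = rng.normal(0.0, config.plant_phase_sd_h)
            y = np.empty_like(times)
            free = times < t_free
            y[free] = config.baseline + config.amplitude * np.exp(-times[free] / clock.damping_h) * np.cos(
                2 * np.pi * (times[free] - clock.initial_phase_h - jitter) / clock.period_h
            )
            ent = ~free
            te = times[ent] - t_free
            day = np.minimum((te // 24.0).astype(int), config.entrain_days - 1)
            peak = config.entrainer_peak_zt + np.asarray(offsets)[day] + jitter
            y[ent] = config.baseline + config.amplitude * np.exp(-t_free / clock.damping_h) * np.cos(
                2 * np.pi * (te - peak) / 24.0
            )
            noise = rng.normal(1.0, config.noise_sd_frac, size=len(times))
            y = np.maximum(y * noise, 0.0)
            traces.append(
                LuminescenceTrace(
                    times=times.copy(),
                    values=y,
                    plant_id=f"{genotype}_{plant:02d}",
                    genotype=genotype,
                    segments=list(segments),
                )
            )
    return traces, truth


# ---------------------------------------------------------------------------
# quantification inputs
# ---------------------------------------------------------------------------

@dataclass
class QuantEffectSpec:
    """Effect sizes for the quantification generator.

    ``evening_stabilization``: multiplier applied to the mutant genotype's
    band abundance at ZT >= ``evening_start_zt`` (1.0 = no effect).
    ``effector_effects``: multiplicative effect of each effector combination
    on the firefly reporter relative to the no-effector control.
    """

    evening_stabilization: float = 2.0
    evening_start_zt: float = 9.0
    timepoints: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0)
    bioreps: int = 4
    noise_sd_frac: float = 0.10
    effector_effects: dict[str, float] = field(
        default_factory=lambda: {"activator": 3.0, "activator+repressor": 1.5}
    )
    plate_n: int = 8
    seed: int = 0


def simulate_quant(
    seed: int | None = None, spec: QuantEffectSpec | None = None
) -> tuple[list[DensitometryMeasurement], list[LuciferasePlateReading], dict]:
    """Simulate densitometry lanes and dual-luciferase plate readings.

    Densitometry: both genotypes share a diurnal abundance curve peaking at
    ZT6; the mutant's abundance is multiplied by ``evening_stabilization``
    at ZT >= ``evening_start_zt``. Abundances map linearly into inverted
    gray values with lognormal noise. Plates: each leaf carries a random
    infection-efficiency factor that scales firefly and renilla alike (so
    the ratio cancels it); effector combinations multiply the firefly signal.
    """
    spec = spec or QuantEffectSpec()
    if seed is not None:
        spec.seed = seed
    rng = np.random.default_rng(spec.seed)

    # densitometry ---------------------------------------------------------
    # diurnal abundance profile peaking at ZT6 with a deep evening trough,
    # as typical for a morning-phased clock protein
    lanes = []
    base_curve = {0.0: 0.4, 3.0: 0.8, 6.0: 1.0, 9.0: 0.35, 12.0: 0.15, 15.0: 0.1, 18.0: 0.1, 21.0: 0.2}
    curve = {
        zt: base_curve.get(
            zt, 0.1 + 0.9 * max(0.0, float(np.cos(2 * np.pi * (zt - 6.0) / 24.0))) ** 3
        )
        for zt in spec.timepoints
    }
    for genotype in ("wt", "mutant"):
        for rep in range(1, spec.bioreps + 1):
            for zt in spec.timepoints:
                abundance = curve[zt]
                if genotype == "mutant" and zt >= spec.evening_start_zt:
                    abundance *= spec.evening_stabilization
                abundance *= rng.lognormal(0.0, spec.noise_sd_frac)
                band_bg = 240.0 + rng.normal(0, 2)
                band = np.clip(band_bg - 150.0 * abundance, 0, 255)
                load_bg = 235.0 + rng.normal(0, 2)
                load = np.clip(load_bg - 100.0 * rng.lognormal(0.0, spec.noise_sd_frac / 2), 0, 255)
                lanes.append(
                    DensitometryMeasurement(
                        band_mean_gray=float(band),
                        band_bg_mean_gray=float(band_bg),
                        loading_mean_gray=float(load),
                        loading_bg_mean_gray=float(load_bg),
                        timepoint_zt=float(zt),
                        genotype=genotype,
                        biorep=rep,
                    )
                )

    # dual-luciferase plates ----------------------------------------------
    readings = []
    combos = [NO_EFFECTOR] + sorted(spec.effector_effects)
    ff_bg, ren_bg = 50.0, 40.0
    for i in range(spec.plate_n):
        leaf = f"leaf{i:02d}"
        efficiency = rng.lognormal(0.0, 0.5)
        for combo in combos:
            effect = spec.effector_effects.get(combo, 1.0)
            ff = 1000.0 * effect * efficiency * rng.lognormal(0.0, spec.noise_sd_frac)
            ren = 800.0 * efficiency * rng.lognormal(0.0, spec.noise_sd_frac)
            readings.append(
                LuciferasePlateReading(
                    firefly_intensity=ff + ff_bg,
                    renilla_intensity=ren + ren_bg,
                    firefly_bg=ff_bg,
                    renilla_bg=ren_bg,
                    effector_combination=combo,
                    leaf_id=leaf,
                    experiment_id="exp1",
                )
            )
    truth = {
        "evening_stabilization": spec.evening_stabilization,
        "evening_start_zt": spec.evening_start_zt,
        "affected_timepoints": [zt for zt in spec.timepoints if zt >= spec.evening_start_zt],
        "effector_effects": dict(spec.effector_effects),
    }
    return lanes, readings, truth
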