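"""Circadian time-series analysis for luciferase reporter traces.

Period estimation follows the FFT-NLLS scheme: the linearly detrended trace
is Fourier-analysed to seed candidate periods, cosine components are added by
nonlinear least squares while an F-test says the fit improves, and each
component's relative amplitude error (RAE: half-width of the 95% amplitude
confidence interval divided by the amplitude) measures rhythmic robustness.
A trace is called rhythmic when its best in-window component has RAE below a
threshold (default 0.6).

The module also provides per-day acrophase extraction, Rayleigh circular
statistics, one-way ANOVA with Tukey HSD letter groupings for period
comparisons, and Welch-test-based resynchronization analysis for entrainment
experiments.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .quantify import welch_t

LL = "LL"
LD = "LD"
TEMP_CYCLE = "temp_cycle"
TEMP_RAMP = "temp_ramp"


@dataclass
class LuminescenceTrace:
    """A uniformly sampled luminescence time series for one plant.

    ``segments`` lists non-overlapping (start_h, end_h, label) condition
    windows, e.g. constant light (``LL``) followed by a temperature cycle.
    """

    times: np.ndarray
    values: np.ndarray
    plant_id: str = "plant"
    genotype: str = "wt"
    segments: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if len(self.times) > 1 and (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        for (s0, e0, _), (s1, e1, _) in itertools.combinations(self.segments, 2):
            if max(s0, s1) < min(e0, e1):
                raise ValueError("condition segments overlap")

    @property
    def span_h(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def dt_h(self) -> float:
        return float(self.times[1] - self.times[0])

    def segment_labels(self) -> list[str]:
        labels = []
        for t in self.times:
            label = ""
            for s, e, lab in self.segments:
                if s <= t < e or (t == e == self.times[-1] + 0):
                    label = lab
                    break
            labels.append(label)
        return labels

    def segment(self, label: str) -> tuple[float, float, str]:
        for seg in self.segments:
            if seg[2] == label:
                return seg
        raise KeyError(f"no segment labelled {label!r}; have {[s[2] for s in self.segments]}")

    def window(self, start_h: float, end_h: float) -> "LuminescenceTrace":
        mask = (self.times >= start_h) & (self.times < end_h)
        return LuminescenceTrace(
            times=self.times[mask],
            values=self.values[mask],
            plant_id=self.plant_id,
            genotype=self.genotype,
            segments=[s for s in self.segments if s[0] < end_h and s[1] > start_h],
        )


@dataclass
class RhythmFit:
    """Result of an FFT-NLLS fit for one trace."""

    period_h: float
    amplitude: float
    acrophase_ct: float
    rae: float
    n_components: int
    residual_sse: float
    rhythmic: bool


@dataclass
class AcrophaseSeries:
    """Per-(genotype, day) acrophase samples, circular modulo ``cycle_h``."""

    cycle_h: float
    data: dict[str, dict[int, np.ndarray]]

    def __post_init__(self) -> None:
        for genotype, days in self.data.items():
            idx = sorted(days)
            if idx and idx != list(range(idx[0], idx[-1] + 1)):
                raise ValueError(f"{genotype}: day indices not consecutive: {idx}")
            for d in idx:
                arr = np.asarray(days[d], dtype=float)
                if ((arr < 0) | (arr >= self.cycle_h)).any():
                    raise ValueError(f"{genotype} day {d}: acrophase outside [0, {self.cycle_h})")
                days[d] = arr

    def genotypes(self) -> list[str]:
        return sorted(self.data)


# ---------------------------------------------------------------------------
# FFT-NLLS
# ---------------------------------------------------------------------------

def _model(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Linear trend plus cosine components: params = [c0, c1, (a, b, tau)*]."""
    y = params[0] + params[1] * t
    for k in range((len(params) - 2) // 3):
        a, b, tau = params[2 + 3 * k : 5 + 3 * k]
        w = 2 * np.pi / tau
        y = y + a * np.cos(w * t) + b * np.sin(w * t)
    return y


def _spectral_peaks(t: np.ndarray, resid: np.ndarray, window: tuple[float, float]) -> list[float]:
    """Candidate periods: local maxima of the zero-padded amplitude spectrum
    inside the period window, strongest first."""
    n = len(t)
    dt = t[1] - t[0]
    npad = max(4096, 8 * n)
    amp = np.abs(np.fft.rfft(resid - resid.mean(), n=npad))
    freq = np.fft.rfftfreq(npad, d=dt)
    with np.errstate(divide="ignore"):
        period = np.where(freq > 0, 1.0 / freq, np.inf)
    inside = (period >= window[0]) & (period <= window[1])
    idx = np.where(inside)[0]
    if len(idx) == 0:
        return []
    peaks = [
        i
        for i in idx
        if 0 < i < len(amp) - 1 and amp[i] >= amp[i - 1] and amp[i] >= amp[i + 1]
    ]
    if not peaks:  # plateau or edge: fall back to the in-window maximum
        peaks = [idx[np.argmax(amp[idx])]]
    peaks.sort(key=lambda i: -amp[i])
    return [float(period[i]) for i in peaks]


def _fit_components(
    t: np.ndarray, y: np.ndarray, params0: np.ndarray, window: tuple[float, float]
):
    k = (len(params0) - 2) // 3
    lo = np.full_like(params0, -np.inf)
    hi = np.full_like(params0, np.inf)
    for i in range(k):
        lo[4 + 3 * i] = window[0] / 2
        hi[4 + 3 * i] = window[1] * 2
    params0 = np.clip(params0, lo, hi)
    res = optimize.least_squares(
        lambda p: _model(p, t) - y,
        params0,
        bounds=(lo, hi),
        method="trf",
        ftol=1e-12,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=5000,
    )
    return res


def fit_fft_nlls(
    trace: LuminescenceTrace,
    window: tuple[float, float] = (15.0, 35.0),
    rae_threshold: float = 0.6,
    max_components: int = 5,
    f_alpha: float = 0.05,
) -> RhythmFit:
    """Estimate period, amplitude, acrophase and RAE by FFT-seeded NLLS.

    A linear trend (estimated jointly with the components, seeded by least
    squares) absorbs baseline drift; cosine components seeded at residual
    spectral peaks are added one at a time and refit jointly while the
    nested-model F-test accepts the improvement (and at most
    ``max_components``). The reported component is the in-window component
    with the smallest RAE; ``rhythmic`` holds when that RAE is below
    ``rae_threshold``. A constant trace yields ``rhythmic=False`` with NaN
    period. The trace must span at least twice the minimum window period.
    """
    t = trace.times - trace.times[0]
    y = trace.values.astype(float)
    if trace.span_h < 2 * window[0]:
        raise ValueError(
            f"trace span {trace.span_h:.1f} h is shorter than twice the minimum period {window[0]} h"
        )
    if np.ptp(y) == 0:
        return RhythmFit(np.nan, np.nan, np.nan, np.inf, 0, 0.0, False)

    trend = np.polynomial.Polynomial.fit(t, y, 1).convert()
    n = len(t)

    best_res = None
    params = np.asarray(trend.coef if len(trend.coef) == 2 else [trend.coef[0], 0.0])
    sse_prev = float(np.sum((y - _model(params, t)) ** 2))
    scale = float(np.sum((y - y.mean()) ** 2)) or 1.0
    # two components closer in frequency than half the spectral resolution
    # are not separable and only mimic amplitude modulation
    min_df = 0.5 / (t[-1] - t[0])
    for _k in range(1, max_components + 1):
        resid = y - _model(params, t)
        existing = [1.0 / params[4 + 3 * i] for i in range((len(params) - 2) // 3)]
        peaks = [
            p
            for p in _spectral_peaks(t, resid, window)
            if all(abs(1.0 / p - f) >= min_df for f in existing)
        ]
        if not peaks:
            break
        tau0 = peaks[0]
        w0 = 2 * np.pi / tau0
        a0 = 2 * np.mean(resid * np.cos(w0 * t))
        b0 = 2 * np.mean(resid * np.sin(w0 * t))
        res = _fit_components(t, y, np.concatenate([params, [a0, b0, tau0]]), window)
        sse_new = float(2 * res.cost)
        p_new = len(res.x)
        freqs = sorted(1.0 / res.x[4 + 3 * i] for i in range((p_new - 2) // 3))
        if any(f2 - f1 < min_df for f1, f2 in zip(freqs, freqs[1:])):
            break  # refit collapsed two components together; reject it
        if _k > 1:
            dof = n - p_new
            if dof <= 0 or sse_new <= 0:
                break
            f_stat = ((sse_prev - sse_new) / 3.0) / (sse_new / dof)
            if f_stat <= 0 or stats.f.sf(f_stat, 3, dof) > f_alpha:
                break
        params = res.x
        best_res = res
        sse_prev = sse_new
        if sse_new < 1e-12 * scale:  # numerically perfect fit
            break

    if best_res is None:
        return RhythmFit(np.nan, np.nan, np.nan, np.inf, 0, sse_prev, False)

    params = best_res.x
    n_comp = (len(params) - 2) // 3
    sse = float(2 * best_res.cost)
    dof = max(n - len(params), 1)
    s2 = sse / dof
    jtj = best_res.jac.T @ best_res.jac
    cov = s2 * np.linalg.pinv(jtj)
    tcrit = stats.t.ppf(0.975, dof)

    best = None  # (rae, period, amplitude, acrophase)
    for k in range(n_comp):
        a, b, tau = params[2 + 3 * k : 5 + 3 * k]
        if not (window[0] <= tau <= window[1]):
            continue
        amp = math.hypot(a, b)
        if amp == 0:
            continue
        g = np.zeros(len(params))
        g[2 + 3 * k] = a / amp
        g[3 + 3 * k] = b / amp
        var_amp = float(g @ cov @ g)
        rae = tcrit * math.sqrt(max(var_amp, 0.0)) / amp
        if best is None or rae < best[0]:
            acro = (math.atan2(b, a) / (2 * np.pi) * tau) % tau
            best = (rae, float(tau), float(amp), float(acro))

    if best is None:
        return RhythmFit(np.nan, np.nan, np.nan, np.inf, n_comp, sse, False)
    rae, period, amplitude, acrophase = best
    return RhythmFit(
        period_h=period,
        amplitude=amplitude,
        acrophase_ct=acrophase,
        rae=rae,
        n_components=n_comp,
        residual_sse=sse,
        rhythmic=bool(rae < rae_threshold),
    )


# ---------------------------------------------------------------------------
# acrophase extraction and circular statistics
# ---------------------------------------------------------------------------

def daily_acrophase(
    trace: LuminescenceTrace,
    cycle_h: float = 24.0,
    smooth_window_h: float = 3.0,
    segment_label: str | None = None,
) -> list[tuple[int, float]]:
    """Time of peak smoothed signal within each consecutive cycle.

    Windows of length ``cycle_h`` are anchored at the start of the segment
    labelled ``segment_label`` (or at the trace start); within each complete
    window the acrophase is the time (mod ``cycle_h``) of the maximum of the
    moving-average-smoothed trace. Windows whose values are all equal yield
    NaN (acrophase undefined there).
    """
    if segment_label is not None:
        start, end, _ = trace.segment(segment_label)
    else:
        start, end = trace.times[0], trace.times[-1] + trace.dt_h
    dt = trace.dt_h
    w = max(1, int(round(smooth_window_h / dt)))
    if w % 2 == 0:
        w += 1
    smoothed = (
        pd.Series(trace.values).rolling(w, center=True, min_periods=1).mean().to_numpy()
    )
    out = []
    day = 0
    while start + (day + 1) * cycle_h <= end + dt / 2:
        lo = start + day * cycle_h
        hi = lo + cycle_h
        mask = (trace.times >= lo) & (trace.times < hi)
        if not mask.any():
            break
        vals = smoothed[mask]
        ts = trace.times[mask]
        if np.ptp(vals) == 0:
            out.append((day, float("nan")))
        else:
            peak_t = ts[int(np.argmax(vals))]
            out.append((day, float((peak_t - start) % cycle_h)))
        day += 1
    return out


def rayleigh(phases, cycle_h: float = 24.0) -> tuple[float, float, float]:
    """Rayleigh test of phase concentration.

    Phases (hours) are mapped to angles on the ``cycle_h`` circle. Returns
    ``(R, mean_phase_h, p)`` where R is the mean resultant length (1 =
    perfect agreement, 0 = dispersed) and p uses the standard analytic
    approximation to the Rayleigh distribution.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("no phases given")
    theta = 2 * np.pi * (phases % cycle_h) / cycle_h
    z = np.exp(1j * theta).mean()
    r = float(np.abs(z))
    mean_phase = float((np.angle(z) / (2 * np.pi) * cycle_h) % cycle_h)
    n = phases.size
    big_r = n * r
    inner = 1 + 4 * n + 4 * (n**2 - big_r**2)
    p = math.exp(math.sqrt(max(inner, 0.0)) - (1 + 2 * n))
    return r, mean_phase, float(min(max(p, 0.0), 1.0))


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def compact_letter_display(names: list[str], pmatrix: np.ndarray, alpha: float = 0.05, means=None) -> dict[str, str]:
    """Letters such that groups sharing a letter are not significantly
    different: one letter per maximal clique of the non-significance graph."""
    g = nx.Graph()
    g.add_nodes_from(range(len(names)))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if pmatrix[i, j] >= alpha:
                g.add_edge(i, j)
    cliques = list(nx.find_cliques(g))
    order = means if means is not None else list(range(len(names)))
    cliques.sort(key=lambda c: min(order[i] for i in c))
    letters = {name: "" for name in names}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for i in clique:
            letters[names[i]] += letter
    return {name: "".join(sorted(s)) for name, s in letters.items()}


def compare_periods(groups: dict[str, list[float]], alpha: float = 0.05, posthoc: bool = True):
    """One-way ANOVA plus Tukey HSD over per-genotype period estimates.

    Returns ``(F, p, tukey_table, letters)``: the ANOVA F and p, a DataFrame
    of pairwise Tukey honest-significant-difference p-values, and a compact
    letter display at ``alpha``. With ``posthoc=False`` only the ANOVA is
    computed (tukey_table and letters are None), e.g. for simulation loops.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    names = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    for name, s in zip(names, samples):
        if s.size < 2:
            raise ValueError(f"group {name!r} has fewer than two observations")
    means = [float(s.mean()) for s in samples]

    all_vals = np.concatenate(samples)
    if np.ptp(all_vals) == 0:  # degenerate: every observation identical
        k = len(names)
        pmat = np.ones((k, k))
        if not posthoc:
            return 0.0, 1.0, None, None
        tukey = _tukey_table(names, means, pmat)
        return 0.0, 1.0, tukey, compact_letter_display(names, pmat, alpha, means)

    f_stat, p = stats.f_oneway(*samples)
    if not posthoc:
        return float(f_stat), float(p), None, None
    res = stats.tukey_hsd(*samples)
    pmat = np.asarray(res.pvalue)
    tukey = _tukey_table(names, means, pmat)
    letters = compact_letter_display(names, pmat, alpha, means)
    return float(f_stat), float(p), tukey, letters


def _tukey_table(names, means, pmat) -> pd.DataFrame:
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": means[i] - means[j],
                    "p_adj": float(pmat[i, j]),
                }
            )
    return pd.DataFrame(rows)


def _unwrap_to(phases: np.ndarray, center: float, cycle_h: float) -> np.ndarray:
    """Shift each phase by a whole number of cycles into the half-cycle
    neighborhood of ``center``."""
    return center + ((phases - center + cycle_h / 2) % cycle_h) - cycle_h / 2


def compare_acrophases(
    series: AcrophaseSeries, reference_genotype: str, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, int | None]]:
    """Per-day Welch tests of each genotype's acrophase against a reference.

    Each day's phases are unwrapped to the reference mean's half-cycle
    neighborhood before the (linear) Welch test. The resynchronization day
    of a genotype is the first testable day with p >= alpha such that every
    later testable day also has p >= alpha (None when never resynchronized).
    Days with fewer than two observations in either group are flagged
    untestable (p = NaN).
    """
    if reference_genotype not in series.data:
        raise KeyError(f"reference genotype {reference_genotype!r} not in series")
    ref_days = series.data[reference_genotype]
    rows = []
    resync: dict[str, int | None] = {}
    for genotype in series.genotypes():
        if genotype == reference_genotype:
            continue
        days = sorted(set(series.data[genotype]) & set(ref_days))
        if not days:
            raise ValueError(f"genotype {genotype!r} shares no days with the reference")
        pvals: dict[int, float] = {}
        for d in days:
            ref = np.asarray(ref_days[d], dtype=float)
            obs = np.asarray(series.data[genotype][d], dtype=float)
            testable = ref.size >= 2 and obs.size >= 2
            if testable:
                _, ref_center, _ = rayleigh(ref, series.cycle_h)
                ref_u = _unwrap_to(ref, ref_center, series.cycle_h)
                obs_u = _unwrap_to(obs, ref_center, series.cycle_h)
                t, _df, p = welch_t(obs_u, ref_u)
                mean_offset = float(obs_u.mean() - ref_u.mean())
                pvals[d] = p
            else:
                t, p, mean_offset = np.nan, np.nan, np.nan
            rows.append(
                {
                    "genotype": genotype,
                    "day": d,
                    "n": obs.size,
                    "n_ref": ref.size,
                    "mean_offset_h": mean_offset,
                    "t": t,
                    "p": p,
                    "testable": testable,
                }
            )
        day_r = None
        tested = [d for d in days if d in pvals]
        for d in tested:
            if all(pvals[e] >= alpha for e in tested if e >= d):
                day_r = d
                break
        resync[genotype] = day_r
    return pd.DataFrame(rows), resync
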