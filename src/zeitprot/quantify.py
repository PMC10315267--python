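"""Densitometry and dual-luciferase quantification.

``normalize_blot`` converts ROI mean-gray-value readings from western-blot
scans into loading-normalized, per-biorep max-100 abundances.
``dualluc_fold_change`` computes firefly/renilla fold changes relative to the
no-effector control. Both use the shared Welch unequal-variance t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

logger = logging.getLogger(__name__)

NO_EFFECTOR = "no effector"


@dataclass(frozen=True)
class DensitometryMeasurement:
    """Mean gray values for one lane: band and loading-control ROIs with
    their local backgrounds (equal-area ROIs assumed upstream)."""

    band_mean_gray: float
    band_bg_mean_gray: float
    loading_mean_gray: float
    loading_bg_mean_gray: float
    timepoint_zt: float
    genotype: str
    biorep: int


@dataclass(frozen=True)
class LuciferasePlateReading:
    """Integrated firefly/renilla intensities for one leaf-disc quadrant,
    with the plate's non-transfected background readings."""

    firefly_intensity: float
    renilla_intensity: float
    firefly_bg: float
    renilla_bg: float
    effector_combination: str
    leaf_id: str | None = None
    experiment_id: str = "exp1"


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unpaired t-test.

    Returns ``(t, df, p)`` with Satterthwaite degrees of freedom and a
    two-sided p-value. Degenerate zero-variance inputs give t=0, p=1 when
    the means are equal and |t|=inf, p=0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t needs at least two observations per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, float(na + nb - 2), 1.0
        return math.copysign(math.inf, diff), float(na + nb - 2), 0.0
    t = diff / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return float(t), float(df), min(p, 1.0)


def normalize_blot(series: list[DensitometryMeasurement], max_gray: float = 255.0) -> pd.DataFrame:
    """Background-subtracted, loading-normalized band abundances.

    Pixel densities are inverted (``max_gray - gray``; 8-bit scans by
    default), local background is subtracted to give net band and net
    loading densities, the band/loading ratio is taken, and within each
    (genotype, biorep) the ratios are rescaled so the maximum is 100.
    """
    if not series:
        raise ValueError("empty densitometry series")
    rows = []
    for i, m in enumerate(series):
        for attr in ("band_mean_gray", "band_bg_mean_gray", "loading_mean_gray", "loading_bg_mean_gray"):
            v = getattr(m, attr)
            if not 0 <= v <= max_gray:
                raise ValueError(f"lane {i}: {attr}={v} outside [0, {max_gray}]")
        net_band = (max_gray - m.band_mean_gray) - (max_gray - m.band_bg_mean_gray)
        net_loading = (max_gray - m.loading_mean_gray) - (max_gray - m.loading_bg_mean_gray)
        if net_loading <= 0:
            raise ValueError(
                f"lane {i} (genotype={m.genotype}, ZT{m.timepoint_zt}, biorep {m.biorep}): "
                f"net loading density {net_loading} is not positive"
            )
        rows.append(
            {
                "genotype": m.genotype,
                "biorep": m.biorep,
                "timepoint_zt": m.timepoint_zt,
                "net_band": net_band,
                "net_loading": net_loading,
                "ratio": net_band / net_loading,
            }
        )
    out = pd.DataFrame(rows)
    out["normalized"] = out.groupby(["genotype", "biorep"])["ratio"].transform(
        lambda r: 100.0 * r / r.max()
    )
    return out


def compare_blot_timepoints(
    normalized: pd.DataFrame, genotype_a: str, genotype_b: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-timepoint Welch comparison of normalized abundances across bioreps."""
    rows = []
    for zt, grp in normalized.groupby("timepoint_zt"):
        a = grp.loc[grp["genotype"] == genotype_a, "normalized"].to_numpy()
        b = grp.loc[grp["genotype"] == genotype_b, "normalized"].to_numpy()
        if a.size < 2 or b.size < 2:
            rows.append({"timepoint_zt": zt, "t": np.nan, "p": np.nan, "significant": False})
            continue
        t, _df, p = welch_t(a, b)
        rows.append({"timepoint_zt": zt, "t": t, "p": p, "significant": p < alpha})
    return pd.DataFrame(rows)


def dualluc_fold_change(
    readings: list[LuciferasePlateReading],
    no_effector: str = NO_EFFECTOR,
    contrasts: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Firefly/renilla fold change relative to the no-effector control.

    Per reading: ``ratio = (firefly - firefly_bg) / (renilla - renilla_bg)``;
    readings with non-positive net renilla are excluded with a warning. The
    fold change divides each ratio by the mean no-effector ratio of the same
    leaf when leaf ids are present (falling back to the experiment mean), so
    infection-efficiency differences between leaves cancel. By construction
    the mean no-effector fold is 1 per normalization unit.

    Returns ``(per_reading_table, contrast_table)``; contrasts default to
    every effector combination versus the no-effector control, tested by
    Welch's t on the folds.
    """
    rows = []
    for i, r in enumerate(readings):
        net_ff = r.firefly_intensity - r.firefly_bg
        net_ren = r.renilla_intensity - r.renilla_bg
        if net_ren <= 0:
            logger.warning("reading %d (%s): net renilla %.3g <= 0, excluded", i, r.effector_combination, net_ren)
            continue
        rows.append(
            {
                "experiment_id": r.experiment_id,
                "leaf_id": r.leaf_id,
                "effector_combination": r.effector_combination,
                "ratio": net_ff / net_ren,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty or not (table["effector_combination"] == no_effector).any():
        raise ValueError(f"no usable {no_effector!r} readings; cannot normalize")

    fold = pd.Series(np.nan, index=table.index)
    for _exp, exp_grp in table.groupby("experiment_id"):
        ref = exp_grp[exp_grp["effector_combination"] == no_effector]
        if ref.empty:
            raise ValueError(f"experiment {_exp!r} lacks {no_effector!r} readings")
        exp_mean = ref["ratio"].mean()
        if ref["leaf_id"].notna().any():
            leaf_means = ref.groupby("leaf_id")["ratio"].mean()
            denom = exp_grp["leaf_id"].map(leaf_means).fillna(exp_mean)
        else:
            denom = pd.Series(exp_mean, index=exp_grp.index)
        fold.loc[exp_grp.index] = exp_grp["ratio"] / denom
    table["fold"] = fold
    if contrasts is None:
        combos = sorted(set(table["effector_combination"]) - {no_effector})
        contrasts = [(c, no_effector) for c in combos]
    crows = []
    for a_name, b_name in contrasts:
        a = table.loc[table["effector_combination"] == a_name, "fold"].to_numpy()
        b = table.loc[table["effector_combination"] == b_name, "fold"].to_numpy()
        if a.size < 2 or b.size < 2:
            t = df = p = float("nan")  # contrast untestable at n < 2
        else:
            t, df, p = welch_t(a, b)
        crows.append(
            {
                "combination": a_name,
                "reference": b_name,
                "mean_fold": a.mean(),
                "mean_fold_ref": b.mean(),
                "t": t,
                "df": df,
                "p": p,
            }
        )
    return table, pd.DataFrame(crows)
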