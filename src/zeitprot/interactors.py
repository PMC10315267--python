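"""Interactor calling from APMS spectral counts.

The calling chain mirrors standard curated APMS practice: identifications are
first filtered by peptide evidence (at least two unique peptides, or a single
peptide seen in more than one replicate), every protein detected in a
negative-control purification is excluded outright, and the survivors are
called per bait x timepoint group and classified by time of day (early-only /
late-only / shared) across baits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io_tables import SpectralCountMatrix

logger = logging.getLogger(__name__)

EARLY_ONLY = "early_only"
LATE_ONLY = "late_only"
SHARED = "shared"


@dataclass(frozen=True)
class EvidenceThresholds:
    """Identification-evidence thresholds.

    ``min_peptide_probability`` / ``max_peptide_fdr`` / ``min_protein_probability``
    apply only when a peptide-level table is supplied (curated count tables are
    already post-threshold). ``min_unique_peptides`` is the main evidence rule;
    ``replicate_exception_min_runs`` is the number of replicates in which a
    single-peptide identification must recur to be rescued.
    """

    min_peptide_probability: float = 0.95
    max_peptide_fdr: float = 0.01
    min_protein_probability: float = 0.999
    min_unique_peptides: int = 2
    replicate_exception_min_runs: int = 2

    def __post_init__(self) -> None:
        for name in ("min_peptide_probability", "max_peptide_fdr", "min_protein_probability"):
            p = getattr(self, name)
            if not 0 < p <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {p}")
        if self.min_unique_peptides < 1 or self.replicate_exception_min_runs < 1:
            raise ValueError("count thresholds must be >= 1")


@dataclass
class InteractorCall:
    """Proteins called as interactors for one bait at one timepoint."""

    bait: str
    timepoint_zt: float
    proteins: set[str]
    per_replicate_counts: dict[str, list[int]]

    def ordered_loci(self) -> list[str]:
        """Loci sorted by descending maximum spectra, then locus."""
        return sorted(self.proteins, key=lambda l: (-max(self.per_replicate_counts[l]), l))


@dataclass
class TimeClassification:
    """Partition of the pooled interactor union into early/late/shared."""

    early_zt: float
    late_zt: float
    labels: dict[str, str]
    per_bait: dict[str, dict[str, str]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        out = {EARLY_ONLY: 0, LATE_ONLY: 0, SHARED: 0}
        for label in self.labels.values():
            out[label] += 1
        return out

    def loci(self, label: str) -> set[str]:
        return {l for l, lab in self.labels.items() if lab == label}


def _group_runs(matrix: SpectralCountMatrix) -> pd.core.groupby.DataFrameGroupBy:
    noncontrol = matrix.runs[~matrix.runs["is_control"].astype(bool)]
    return noncontrol.groupby(["bait", "timepoint_zt"], sort=False)


def apply_evidence_filter(
    matrix: SpectralCountMatrix,
    thresholds: EvidenceThresholds | None = None,
    peptide_table: pd.DataFrame | None = None,
) -> SpectralCountMatrix:
    """Drop proteins without sufficient peptide evidence.

    Within each bait x timepoint group, a protein passes if some replicate has
    ``>= min_unique_peptides`` unique peptides, or it has at least one unique
    peptide in ``>= replicate_exception_min_runs`` replicates of that group.
    Proteins passing in no group are removed.

    ``peptide_table`` (columns ``run_id``, ``peptide``, ``agi_locus``,
    ``probability``, ``fdr``, optional ``protein_probability``) lets the
    peptide-level probability/FDR thresholds be applied before counting unique
    peptides. Without it, the ``unique_peptides`` matrix is used; if that is
    also absent the matrix is returned unchanged (curated tables are already
    evidence-filtered) and the skip is logged.
    """
    thresholds = thresholds or EvidenceThresholds()
    if peptide_table is not None:
        unique = _unique_peptides_from_table(matrix, thresholds, peptide_table)
    elif matrix.unique_peptides is not None:
        unique = matrix.unique_peptides
    else:
        logger.info("no peptide-level evidence available; evidence filtering skipped")
        return matrix.copy()

    keep: set[str] = set()
    for (_bait, _zt), runs in _group_runs(matrix):
        up = unique[list(runs.index)]
        strong = (up >= thresholds.min_unique_peptides).any(axis=1)
        rescued = (up >= 1).sum(axis=1) >= thresholds.replicate_exception_min_runs
        keep |= set(up.index[strong | rescued])
    out = matrix.subset_proteins(keep)
    if peptide_table is not None:
        out.unique_peptides = unique.loc[out.proteins.index]
    return out


def _unique_peptides_from_table(
    matrix: SpectralCountMatrix,
    thresholds: EvidenceThresholds,
    peptide_table: pd.DataFrame,
) -> pd.DataFrame:
    required = {"run_id", "peptide", "agi_locus", "probability", "fdr"}
    missing = required - set(peptide_table.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")
    unknown = set(peptide_table["run_id"]) - set(matrix.runs.index)
    if unknown:
        raise ValueError(f"peptide table references unknown runs: {sorted(unknown)}")
    ok = (peptide_table["probability"] > thresholds.min_peptide_probability) & (
        peptide_table["fdr"] < thresholds.max_peptide_fdr
    )
    if "protein_probability" in peptide_table.columns:
        ok &= peptide_table["protein_probability"] > thresholds.min_protein_probability
    accepted = peptide_table[ok]
    counts = (
        accepted.groupby(["agi_locus", "run_id"])["peptide"].nunique().unstack(fill_value=0)
    )
    unique = pd.DataFrame(0, index=matrix.proteins.index, columns=matrix.runs.index, dtype=np.int64)
    common = counts.index.intersection(unique.index)
    unique.loc[common, counts.columns] = counts.loc[common].to_numpy()
    # a spectral count implies at least one spectrum; cap at total_spectra
    return unique.where(unique <= matrix.total_spectra, matrix.total_spectra)


def subtract_controls(matrix: SpectralCountMatrix) -> SpectralCountMatrix:
    """Remove every protein seen in any negative-control run.

    A single spectrum in any control purification excludes the protein
    globally (presence-based exclusion); control runs are dropped from the
    output. With no control runs present, the input is returned unchanged
    with a logged warning. The operation is idempotent.
    """
    control_runs = matrix.runs.index[matrix.runs["is_control"].astype(bool)]
    if len(control_runs) == 0:
        logger.warning("no control runs present; control subtraction is a no-op")
        return matrix.copy()
    in_control = (matrix.total_spectra[list(control_runs)] >= 1).any(axis=1)
    kept = matrix.subset_proteins(set(matrix.proteins.index[~in_control]))
    return kept.subset_runs(set(matrix.runs.index) - set(control_runs))


def group_by_parsimony(evidence: dict[str, set[str]]) -> list[list[tuple[str, ...]]]:
    """Group proteins by shared peptide evidence under parsimony.

    ``evidence`` maps peptide sequence -> set of loci the peptide matches.
    Proteins with identical peptide sets merge into one group; a protein whose
    peptide set is a strict subset of another's is absorbed into that
    protein's group; remaining (non-nested) overlap links groups into the
    same cluster without merging them.

    Returns a list of clusters, each a list of groups (sorted locus tuples);
    every protein appears in exactly one group.
    """
    if not evidence:
        raise ValueError("empty peptide evidence map")
    peptides_of: dict[str, set[str]] = {}
    for pep, loci in evidence.items():
        for locus in loci:
            peptides_of.setdefault(locus, set()).add(pep)

    # identical sets merge
    by_set: dict[frozenset, set[str]] = {}
    for locus, peps in peptides_of.items():
        by_set.setdefault(frozenset(peps), set()).add(locus)

    # strict subsets are absorbed into (the smallest, then lexicographically
    # first) strict superset -- deterministic, and minimal sets absorb last
    sets = sorted(by_set, key=lambda s: (len(s), sorted(s)))
    absorbed_into: dict[frozenset, frozenset] = {}
    for i, s in enumerate(sets):
        supersets = [t for t in sets[i + 1 :] if s < t]
        if supersets:
            absorbed_into[s] = min(supersets, key=lambda t: (len(t), sorted(t)))

    def root(s: frozenset) -> frozenset:
        while s in absorbed_into:
            s = absorbed_into[s]
        return s

    groups: dict[frozenset, set[str]] = {}
    for s, members in by_set.items():
        groups.setdefault(root(s), set()).update(members)

    # overlap (shared peptides) links groups into clusters
    g = nx.Graph()
    keys = list(groups)
    g.add_nodes_from(range(len(keys)))
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            if keys[i] & keys[j]:
                g.add_edge(i, j)
    clusters = []
    for comp in nx.connected_components(g):
        cluster = sorted(tuple(sorted(groups[keys[i]])) for i in comp)
        clusters.append(cluster)
    return sorted(clusters)


def available_groups(matrix: SpectralCountMatrix) -> list[tuple[str, float]]:
    return list(_group_runs(matrix).groups.keys())


def call_interactors(matrix: SpectralCountMatrix, bait: str, timepoint_zt: float) -> InteractorCall:
    """Call interactors for one bait x timepoint group.

    A protein is called if it has at least one spectrum in at least one
    replicate of the group. The matrix is expected to be control-subtracted
    and evidence-filtered already.
    """
    groups = dict(_group_runs(matrix).groups)
    key = (bait, float(timepoint_zt))
    if key not in groups:
        raise KeyError(f"no runs for bait={bait!r} at ZT{timepoint_zt}; available: {sorted(groups)}")
    runs = matrix.runs.loc[groups[key]].sort_values("replicate")
    counts = matrix.total_spectra[list(runs.index)]
    called = counts.index[(counts >= 1).any(axis=1)]
    return InteractorCall(
        bait=bait,
        timepoint_zt=float(timepoint_zt),
        proteins=set(called),
        per_replicate_counts={l: [int(c) for c in counts.loc[l]] for l in called},
    )


def call_all_interactors(matrix: SpectralCountMatrix) -> list[InteractorCall]:
    return [call_interactors(matrix, bait, zt) for bait, zt in available_groups(matrix)]


def classify_timepoints(
    early: list[InteractorCall], late: list[InteractorCall]
) -> TimeClassification:
    """Classify pooled interactors as early-only, late-only, or shared.

    ``early`` and ``late`` are interactor calls at exactly two distinct
    timepoints (possibly several baits each); loci are pooled across baits
    within each timepoint. Classification keys on the AGI locus. Per-bait
    partitions are computed for baits present at both timepoints.
    """
    if not early or not late:
        raise ValueError("need at least one interactor call per timepoint")
    early_zts = {c.timepoint_zt for c in early}
    late_zts = {c.timepoint_zt for c in late}
    if len(early_zts) != 1 or len(late_zts) != 1:
        raise ValueError("each side must contain calls at a single timepoint")
    (early_zt,), (late_zt,) = early_zts, late_zts
    if early_zt == late_zt:
        raise ValueError(f"timepoints must differ, both are ZT{early_zt}")

    def partition(e_set: set[str], l_set: set[str]) -> dict[str, str]:
        labels = {}
        for locus in e_set | l_set:
            if locus in e_set and locus in l_set:
                labels[locus] = SHARED
            elif locus in e_set:
                labels[locus] = EARLY_ONLY
            else:
                labels[locus] = LATE_ONLY
        return labels

    early_union = set().union(*(c.proteins for c in early))
    late_union = set().union(*(c.proteins for c in late))
    per_bait = {}
    early_by_bait = {c.bait: c.proteins for c in early}
    late_by_bait = {c.bait: c.proteins for c in late}
    for bait in sorted(set(early_by_bait) & set(late_by_bait)):
        per_bait[bait] = partition(early_by_bait[bait], late_by_bait[bait])
    return TimeClassification(
        early_zt=early_zt,
        late_zt=late_zt,
        labels=partition(early_union, late_union),
        per_bait=per_bait,
    )


def bait_max_spectra(
    matrix: SpectralCountMatrix, bait: str, timepoint_zt: float, target_locus: str
) -> int:
    """Maximum total spectra for ``target_locus`` across a group's replicates."""
    if target_locus not in matrix.proteins.index:
        raise KeyError(f"locus {target_locus!r} absent from matrix")
    call = call_interactors(matrix, bait, timepoint_zt)
    counts = call.per_replicate_counts.get(target_locus)
    if counts is None:
        runs = matrix.runs
        group = runs[(runs["bait"] == bait) & (runs["timepoint_zt"] == float(timepoint_zt))]
        counts = [int(c) for c in matrix.total_spectra.loc[target_locus, list(group.index)]]
    return max(counts)


def cycling_fraction(
    proteins: set[str], cycling: dict[str, bool]
) -> tuple[int, int, float | None]:
    """Fraction of a locus set flagged as having cycling mRNA.

    Loci absent from the cycling map are counted as unknown and excluded from
    the denominator. Returns ``(n_cycling, n_annotated, fraction)``; the
    fraction is None when no locus is annotated.
    """
    annotated = [l for l in proteins if l in cycling]
    n_cycling = sum(bool(cycling[l]) for l in annotated)
    n_annotated = len(annotated)
    fraction = n_cycling / n_annotated if n_annotated else None
    return n_cycling, n_annotated, fraction
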