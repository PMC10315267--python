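"""End-to-end APMS pipeline orchestration.

``run_pipeline`` executes the full interactor-calling chain -- read counts,
evidence filter, control subtraction, per-group interactor calls, time-of-day
classification, cycling cross-reference, and (optionally) term enrichment --
writing each stage's table plus a JSON manifest that records the seed,
package version, and per-stage row counts needed to reproduce the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .enrichment import enrich_terms
from .interactors import (
    EvidenceThresholds,
    apply_evidence_filter,
    call_interactors,
    classify_timepoints,
    cycling_fraction,
    subtract_controls,
)
from .io_tables import (
    load_table_fixture,
    read_annotation_map,
    read_cycling_map,
    read_spectral_counts,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    ``counts`` entries are either paths to wide-dialect count tables or
    packaged fixture names (``table1``/``table2``/``table3``). The first
    table is taken at the early timepoint and the second at the late one.
    """

    counts: list[str]
    out_dir: str = "zeitprot_out"
    dialect: str = "wide"
    run_tables: list[str] | None = None
    cycling_map: str | None = None
    annotation_map: str | None = None
    thresholds: EvidenceThresholds = field(default_factory=EvidenceThresholds)
    enrichment_correction: str = "none"
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        thresholds = EvidenceThresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thresholds, **raw)


def _load_counts(entry: str, config: RunConfig, index: int):
    if entry in ("table1", "table2", "table3"):
        return load_table_fixture(entry)
    path = Path(entry)
    if not path.exists():
        raise FileNotFoundError(f"count table not found: {path}")
    run_table = None
    if config.run_tables:
        run_table = config.run_tables[index]
    return read_spectral_counts(path, dialect=config.dialect, run_table=run_table)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run the interactor-calling chain and write all stage outputs.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    matrices = [
        _stage("read")(_load_counts, entry, config, i) for i, entry in enumerate(config.counts)
    ]
    manifest["stages"]["read"] = {
        "tables": list(config.counts),
        "proteins": [m.n_proteins for m in matrices],
        "runs": [m.n_runs for m in matrices],
    }
    population = set().union(*(set(m.proteins.index) for m in matrices))

    filtered = [
        _stage("evidence_filter")(apply_evidence_filter, m, config.thresholds) for m in matrices
    ]
    manifest["stages"]["evidence_filter"] = {"proteins": [m.n_proteins for m in filtered]}

    subtracted = [_stage("control_subtraction")(subtract_controls, m) for m in filtered]
    manifest["stages"]["control_subtraction"] = {"proteins": [m.n_proteins for m in subtracted]}

    calls = []
    for m in subtracted:
        groups = m.runs[~m.runs["is_control"].astype(bool)]
        for (bait, zt), _ in groups.groupby(["bait", "timepoint_zt"], sort=False):
            calls.append(_stage("interactor_calls")(call_interactors, m, bait, zt))
    call_rows = [
        {
            "bait": c.bait,
            "timepoint_zt": c.timepoint_zt,
            "agi_locus": locus,
            "counts": ",".join(map(str, c.per_replicate_counts[locus])),
        }
        for c in calls
        for locus in c.ordered_loci()
    ]
    pd.DataFrame(call_rows).to_csv(out / "interactor_calls.tsv", sep="\t", index=False)
    manifest["stages"]["interactor_calls"] = {"groups": len(calls), "rows": len(call_rows)}

    zts = sorted({c.timepoint_zt for c in calls})
    if len(zts) == 2:
        early = [c for c in calls if c.timepoint_zt == zts[0]]
        late = [c for c in calls if c.timepoint_zt == zts[1]]
        classification = _stage("classification")(classify_timepoints, early, late)
        rows = [
            {
                "agi_locus": locus,
                "label": label,
                **{
                    bait: part.get(locus, "")
                    for bait, part in classification.per_bait.items()
                },
            }
            for locus, label in sorted(classification.labels.items())
        ]
        pd.DataFrame(rows).to_csv(out / "classification.tsv", sep="\t", index=False)
        (out / "venn_counts.json").write_text(json.dumps(classification.counts, indent=2))
        manifest["stages"]["classification"] = classification.counts

        cycling = {}
        for m in matrices:
            cycling.update(m.cycling_map())
        if config.cycling_map:
            cycling.update(read_cycling_map(config.cycling_map))
        if cycling:
            frac = {}
            for label in ("early_only", "late_only", "shared"):
                n_cyc, n_ann, fraction = cycling_fraction(classification.loci(label), cycling)
                frac[label] = {"n_cycling": n_cyc, "n_annotated": n_ann, "fraction": fraction}
            (out / "cycling_fraction.json").write_text(json.dumps(frac, indent=2))
            manifest["stages"]["cycling_fraction"] = frac

        if config.annotation_map:
            annotation = read_annotation_map(config.annotation_map)
            study = set(classification.labels)
            table = _stage("enrichment")(
                enrich_terms, study, population, annotation, config.enrichment_correction
            )
            table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            manifest["stages"]["enrichment"] = {"terms": len(table)}
    else:
        logger.warning("found %d timepoints, classification needs exactly 2; skipped", len(zts))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
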