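"""Readers and writers for spectral-count tables, luminescence traces, and flat maps.

The central container is :class:`SpectralCountMatrix`: proteins x purification
runs, with per-run metadata (bait, Zeitgeber time, replicate, control flag).
Two serializations are supported:

* ``wide`` -- one row per protein, one column per run; run columns are named
  ``BAIT_ZT<t>_<rep>`` (e.g. ``LNK1-HFC_ZT9_2``), the layout used by curated
  interactor tables.
* ``long`` -- one row per (protein, run) pair plus a sidecar run-metadata
  table, for exports whose run names do not follow the wide convention.

Three curated affinity-purification tables (clock-bait purifications at ZT5
and ZT9, and COR27/COR28 purifications at ZT9) ship with the package as
``load_table_fixture`` fixtures, including their per-gene cycling flags.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AGI_PATTERN = re.compile(r"^AT[1-5CM]G\d{5}$")
RUN_COLUMN_PATTERN = re.compile(r"^(?P<bait>.+)_ZT(?P<zt>\d+(?:\.\d+)?)_(?P<rep>\d+)$")

#: bait name marking a negative-control purification (no tagged bait)
CONTROL_BAIT = "none"

_META_COLUMNS = ("protein_name", "agi_locus", "mw_kda", "cycling")
_FIXTURE_NAMES = ("table1", "table2", "table3")


class TableFormatError(ValueError):
    """A count table or sidecar violates the expected layout or invariants."""


def _check_locus(locus: str) -> str:
    locus = str(locus).strip().upper()
    if not AGI_PATTERN.match(locus):
        raise TableFormatError(f"not a valid AGI locus identifier: {locus!r}")
    return locus


@dataclass
class SpectralCountMatrix:
    """Proteins x runs spectral counts with run metadata.

    Attributes
    ----------
    proteins : pandas.DataFrame
        Indexed by AGI locus; columns ``name``, ``mw_kda`` and ``cycling``
        (True/False, or None when the cycling status is unknown).
    runs : pandas.DataFrame
        Indexed by run id; columns ``bait``, ``timepoint_zt``, ``replicate``
        and ``is_control``.
    total_spectra : pandas.DataFrame
        Integer MS/MS spectral counts, rows aligned with ``proteins`` and
        columns with ``runs``.
    unique_peptides : pandas.DataFrame or None
        Optional matrix of unique-peptide counts of the same shape.
    """

    proteins: pd.DataFrame
    runs: pd.DataFrame
    total_spectra: pd.DataFrame
    unique_peptides: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        loci = self.proteins.index
        if loci.duplicated().any():
            dup = loci[loci.duplicated()][0]
            raise TableFormatError(f"duplicate AGI locus: {dup}")
        for locus in loci:
            _check_locus(locus)
        if self.runs.index.duplicated().any():
            raise TableFormatError("duplicate run ids in run metadata")
        for run_id, run in self.runs.iterrows():
            is_control = bool(run["is_control"])
            if is_control != (run["bait"] == CONTROL_BAIT):
                raise TableFormatError(
                    f"run {run_id}: is_control must hold exactly when bait is "
                    f"{CONTROL_BAIT!r} (bait={run['bait']!r})"
                )
            if not 0 <= float(run["timepoint_zt"]) < 24:
                raise TableFormatError(f"run {run_id}: timepoint_zt outside [0, 24)")
        noncontrol = self.runs[~self.runs["is_control"].astype(bool)]
        key = noncontrol[["bait", "timepoint_zt", "replicate"]].apply(tuple, axis=1)
        if key.duplicated().any():
            raise TableFormatError(
                f"duplicate (bait, timepoint, replicate) among runs: {key[key.duplicated()].iloc[0]}"
            )
        if list(self.total_spectra.index) != list(loci):
            raise TableFormatError("total_spectra rows do not match protein list")
        if list(self.total_spectra.columns) != list(self.runs.index):
            raise TableFormatError("total_spectra columns do not match run list")
        if (self.total_spectra.to_numpy() < 0).any():
            raise TableFormatError("negative spectral count")
        if self.unique_peptides is not None:
            if self.unique_peptides.shape != self.total_spectra.shape:
                raise TableFormatError("unique_peptides shape mismatch")
            if (self.unique_peptides.to_numpy() > self.total_spectra.to_numpy()).any():
                raise TableFormatError("unique_peptides exceeds total_spectra")

    # -- conveniences -----------------------------------------------------
    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def copy(self) -> "SpectralCountMatrix":
        return SpectralCountMatrix(
            proteins=self.proteins.copy(),
            runs=self.runs.copy(),
            total_spectra=self.total_spectra.copy(),
            unique_peptides=None if self.unique_peptides is None else self.unique_peptides.copy(),
        )

    def subset_proteins(self, loci) -> "SpectralCountMatrix":
        loci = [l for l in self.proteins.index if l in set(loci)]
        return SpectralCountMatrix(
            proteins=self.proteins.loc[loci],
            runs=self.runs.copy(),
            total_spectra=self.total_spectra.loc[loci],
            unique_peptides=None if self.unique_peptides is None else self.unique_peptides.loc[loci],
        )

    def subset_runs(self, run_ids) -> "SpectralCountMatrix":
        run_ids = [r for r in self.runs.index if r in set(run_ids)]
        return SpectralCountMatrix(
            proteins=self.proteins.copy(),
            runs=self.runs.loc[run_ids],
            total_spectra=self.total_spectra[run_ids],
            unique_peptides=None if self.unique_peptides is None else self.unique_peptides[run_ids],
        )

    def cycling_map(self) -> dict[str, bool]:
        """Cycling flags for the proteins whose status is known."""
        return {
            locus: bool(flag)
            for locus, flag in self.proteins["cycling"].items()
            if flag is not None and not (isinstance(flag, float) and np.isnan(flag))
        }


def parse_run_id(run_id: str) -> dict:
    """Parse a ``BAIT_ZT<t>_<rep>`` run column name into run metadata."""
    m = RUN_COLUMN_PATTERN.match(run_id)
    if m is None:
        raise TableFormatError(
            f"run column {run_id!r} does not match BAIT_ZT<t>_<rep>; "
            "use the 'long' dialect with a sidecar run table for free-form run ids"
        )
    bait = m.group("bait")
    return {
        "bait": bait,
        "timepoint_zt": float(m.group("zt")),
        "replicate": int(m.group("rep")),
        "is_control": bait == CONTROL_BAIT,
    }


def _parse_count(value, locus: str, column: str, what: str = "count") -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise TableFormatError(f"unparseable {what} {value!r} at ({locus}, {column})") from None
    if not float(f).is_integer():
        raise TableFormatError(f"non-integer {what} {value!r} at ({locus}, {column})")
    i = int(f)
    if i < 0:
        raise TableFormatError(f"negative {what} {value!r} at ({locus}, {column})")
    return i


def _coerce_cycling(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip().lower()
    if s in ("", "na", "nan", "unknown", "none"):
        return None
    if s in ("1", "true", "yes", "y"):
        return True
    if s in ("0", "false", "no", "n"):
        return False
    raise TableFormatError(f"unparseable cycling flag {value!r}")


def read_spectral_counts(
    path,
    dialect: str = "wide",
    run_table=None,
) -> SpectralCountMatrix:
    """Read a spectral-count table.

    Parameters
    ----------
    path : path-like
        The count table (tab-separated).
    dialect : {"wide", "long"}
        ``wide``: columns are ``protein_name``, ``agi_locus``, optional
        ``mw_kda``/``cycling``, then one ``BAIT_ZT<t>_<rep>`` column per run.
        ``long``: columns ``agi_locus``, ``protein_name``, ``run_id``,
        ``total_spectra`` and optionally ``unique_peptides``, ``mw_kda``,
        ``cycling``; run metadata comes from the sidecar ``run_table``.
    run_table : path-like, optional
        Sidecar TSV (``run_id``, ``bait``, ``timepoint_zt``, ``replicate``,
        ``is_control``), required for the long dialect.
    """
    path = Path(path)
    if dialect == "wide":
        return _read_wide(path)
    if dialect == "long":
        if run_table is None:
            raise TableFormatError("long dialect requires a sidecar run_table")
        return _read_long(path, Path(run_table))
    raise TableFormatError(f"unknown dialect {dialect!r}; expected 'wide' or 'long'")


def _read_wide(path: Path) -> SpectralCountMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "agi_locus" not in df.columns or "protein_name" not in df.columns:
        raise TableFormatError(f"{path}: wide table needs 'protein_name' and 'agi_locus' columns")
    run_cols = [c for c in df.columns if c not in _META_COLUMNS]
    runs = {}
    for col in run_cols:
        runs[col] = parse_run_id(col)  # raises on unknown columns
    run_df = pd.DataFrame.from_dict(runs, orient="index")
    run_df.index.name = "run_id"

    loci = [_check_locus(l) for l in df["agi_locus"]]
    proteins = pd.DataFrame(
        {
            "name": df["protein_name"].astype(str).to_numpy(),
            "mw_kda": pd.to_numeric(df["mw_kda"], errors="coerce").to_numpy()
            if "mw_kda" in df
            else np.full(len(df), np.nan),
            "cycling": [_coerce_cycling(v) for v in df["cycling"]]
            if "cycling" in df
            else [None] * len(df),
        },
        index=pd.Index(loci, name="agi_locus"),
    )
    counts = np.zeros((len(df), len(run_cols)), dtype=np.int64)
    for i, locus in enumerate(loci):
        for j, col in enumerate(run_cols):
            counts[i, j] = _parse_count(df[col].iloc[i], locus, col)
    total = pd.DataFrame(counts, index=proteins.index, columns=run_cols)
    return SpectralCountMatrix(proteins=proteins, runs=run_df, total_spectra=total)


def _read_long(path: Path, run_table: Path) -> SpectralCountMatrix:
    runs = pd.read_csv(run_table, sep="\t")
    required = {"run_id", "bait", "timepoint_zt", "replicate", "is_control"}
    if not required.issubset(runs.columns):
        raise TableFormatError(f"{run_table}: run table must have columns {sorted(required)}")
    runs["is_control"] = runs["is_control"].map(lambda v: bool(_coerce_cycling(v)))
    runs = runs.set_index("run_id")

    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("agi_locus", "protein_name", "run_id", "total_spectra"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: long table missing column {col!r}")
    unknown = set(df["run_id"]) - set(runs.index)
    if unknown:
        raise TableFormatError(f"counts reference unknown run ids: {sorted(unknown)}")

    df["agi_locus"] = df["agi_locus"].map(_check_locus)
    loci = list(dict.fromkeys(df["agi_locus"]))
    meta = df.drop_duplicates("agi_locus").set_index("agi_locus")
    proteins = pd.DataFrame(
        {
            "name": meta["protein_name"].astype(str),
            "mw_kda": pd.to_numeric(meta["mw_kda"], errors="coerce") if "mw_kda" in meta else np.nan,
            "cycling": [_coerce_cycling(v) for v in meta["cycling"]] if "cycling" in meta else None,
        }
    ).loc[loci]

    total = pd.DataFrame(0, index=pd.Index(loci, name="agi_locus"), columns=runs.index, dtype=np.int64)
    has_up = "unique_peptides" in df.columns
    unique = total.copy() if has_up else None
    seen = set()
    for _, row in df.iterrows():
        key = (row["agi_locus"], row["run_id"])
        if key in seen:
            raise TableFormatError(f"duplicate (locus, run) entry: {key}")
        seen.add(key)
        total.loc[key] = _parse_count(row["total_spectra"], *key)
        if has_up:
            unique.loc[key] = _parse_count(row["unique_peptides"], *key, what="unique peptides")
    return SpectralCountMatrix(proteins=proteins, runs=runs, total_spectra=total, unique_peptides=unique)


def write_spectral_counts(matrix: SpectralCountMatrix, path, dialect: str = "wide", run_table=None) -> None:
    """Serialize a matrix; the wide dialect requires parseable run ids."""
    path = Path(path)
    if dialect == "wide":
        for run_id in matrix.runs.index:
            parse_run_id(run_id)
        out = matrix.proteins.reset_index().rename(columns={"name": "protein_name"})
        out["cycling"] = [
            "" if c is None or (isinstance(c, float) and np.isnan(c)) else int(bool(c))
            for c in out["cycling"]
        ]
        out = pd.concat([out, matrix.total_spectra.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep="\t", index=False)
    elif dialect == "long":
        if run_table is None:
            raise TableFormatError("long dialect requires a run_table path")
        matrix.runs.reset_index().assign(is_control=lambda d: d["is_control"].astype(int)).to_csv(
            run_table, sep="\t", index=False
        )
        long = matrix.total_spectra.stack().rename("total_spectra").reset_index()
        long.columns = ["agi_locus", "run_id", "total_spectra"]
        long["protein_name"] = matrix.proteins["name"].reindex(long["agi_locus"]).to_numpy()
        if matrix.unique_peptides is not None:
            up = matrix.unique_peptides.stack().to_numpy()
            long["unique_peptides"] = up
        long.to_csv(path, sep="\t", index=False)
    else:
        raise TableFormatError(f"unknown dialect {dialect!r}")


def load_table_fixture(name: str) -> SpectralCountMatrix:
    """Load one of the packaged curated interactor tables.

    ``table1``: clock baits at ZT5 (31 proteins x 6 runs); ``table2``: clock
    baits at ZT9 (32 x 6); ``table3``: COR27/COR28 baits at ZT9 (21 x 8).
    Cycling flags come from the tables' constant-light cycling annotations.
    """
    if name not in _FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; valid names: {', '.join(_FIXTURE_NAMES)}")
    ref = resources.files("zeitprot") / "data" / f"{name}.tsv"
    with resources.as_file(ref) as p:
        return _read_wide(p)


# ---------------------------------------------------------------------------
# luminescence traces
# ---------------------------------------------------------------------------

#: sampling-interval uniformity tolerance, hours (1 s)
SAMPLING_TOL_H = 1.0 / 3600.0

TRACE_COLUMNS = ("time_h", "luminescence", "plant_id", "genotype", "condition_segment")


def read_traces(path) -> list:
    """Read per-plant luminescence time series from a trace CSV.

    Columns: ``time_h``, ``luminescence``, ``plant_id``, ``genotype``,
    ``condition_segment``. Rows are grouped by plant; time must be strictly
    increasing and uniformly sampled within one second per plant.
    """
    from .rhythm import LuminescenceTrace

    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise TableFormatError(f"trace file missing columns: {sorted(missing)}")
    traces = []
    for plant_id, grp in df.groupby("plant_id", sort=False):
        t = grp["time_h"].to_numpy(dtype=float)
        if (np.diff(t) <= 0).any():
            raise TableFormatError(f"plant {plant_id}: time not strictly increasing (duplicate or reversed rows)")
        dt = np.diff(t)
        if len(dt) and (np.abs(dt - dt[0]) > SAMPLING_TOL_H).any():
            raise TableFormatError(f"plant {plant_id}: mixed sampling intervals")
        genotypes = grp["genotype"].unique()
        if len(genotypes) != 1:
            raise TableFormatError(f"plant {plant_id}: multiple genotypes {list(genotypes)}")
        segments = []
        labels = grp["condition_segment"].to_numpy()
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                end_h = t[i] if i < len(labels) else t[-1] + (dt[0] if len(dt) else 0.0)
                segments.append((float(t[start]), float(end_h), str(labels[start])))
                start = i
        traces.append(
            LuminescenceTrace(
                times=t,
                values=grp["luminescence"].to_numpy(dtype=float),
                plant_id=str(plant_id),
                genotype=str(genotypes[0]),
                segments=segments,
            )
        )
    return traces


def write_traces(traces, path) -> None:
    rows = []
    for tr in traces:
        labels = tr.segment_labels()
        for t, v, lab in zip(tr.times, tr.values, labels):
            rows.append((t, v, tr.plant_id, tr.genotype, lab))
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# flat maps and FASTA
# ---------------------------------------------------------------------------

def read_annotation_map(path) -> dict[str, set[str]]:
    """Two-column TSV (``agi_locus``, ``term``) -> mapping term -> locus set."""
    df = pd.read_csv(path, sep="\t")
    if not {"agi_locus", "term"}.issubset(df.columns):
        raise TableFormatError("annotation map needs columns 'agi_locus' and 'term'")
    out: dict[str, set[str]] = {}
    for locus, term in zip(df["agi_locus"], df["term"]):
        out.setdefault(str(term), set()).add(_check_locus(locus))
    return out


def write_annotation_map(annotation: dict[str, set[str]], path) -> None:
    rows = [(locus, term) for term in sorted(annotation) for locus in sorted(annotation[term])]
    pd.DataFrame(rows, columns=["agi_locus", "term"]).to_csv(path, sep="\t", index=False)


def read_cycling_map(path) -> dict[str, bool]:
    """Two-column TSV (``agi_locus``, ``cycling``) -> locus -> bool."""
    df = pd.read_csv(path, sep="\t")
    if not {"agi_locus", "cycling"}.issubset(df.columns):
        raise TableFormatError("cycling map needs columns 'agi_locus' and 'cycling'")
    return {_check_locus(l): bool(_coerce_cycling(v)) for l, v in zip(df["agi_locus"], df["cycling"])}


def write_cycling_map(cycling: dict[str, bool], path) -> None:
    rows = [(locus, int(flag)) for locus, flag in sorted(cycling.items())]
    pd.DataFrame(rows, columns=["agi_locus", "cycling"]).to_csv(path, sep="\t", index=False)


def read_peptide_evidence(path) -> dict[str, set[str]]:
    """Two-column TSV (``peptide``, ``agi_locus``) -> peptide -> locus set."""
    df = pd.read_csv(path, sep="\t")
    if not {"peptide", "agi_locus"}.issubset(df.columns):
        raise TableFormatError("peptide evidence needs columns 'peptide' and 'agi_locus'")
    out: dict[str, set[str]] = {}
    for pep, locus in zip(df["peptide"], df["agi_locus"]):
        pep = str(pep).strip().upper()
        if not pep or not pep.isalpha():
            raise TableFormatError(f"invalid peptide sequence {pep!r}")
        out.setdefault(pep, set()).add(_check_locus(locus))
    return out


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> ordered mapping record id -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
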