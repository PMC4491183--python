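"""OTU tables and cohort metadata: containers, readers, writers, alignment.

The package's common currency is an :class:`OtuTable` — an integer count
matrix (samples x OTUs) with a taxonomy lineage per OTU — joined against a
:class:`CohortMetadata` table of per-sample design variables (mouse, cage,
treatment group, day of life, timepoint index, diet phase).

Two file dialects are supported for count tables:

* ``classic_tsv`` — the legacy QIIME convention: rows are OTUs, the header
  line starts with ``#OTU ID``, and an optional final ``taxonomy`` column
  carries the semicolon-delimited lineage.
* ``biom_json`` — a dense BIOM v1 JSON document.

Internally everything is oriented samples x OTUs; readers transpose on
ingest. Counts are strictly integers at I/O; relative abundances are always
derived downstream, never stored in files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("control", "amoxicillin", "tylosin", "mixture")
DIETS = ("normal_chow", "high_fat")

METADATA_COLUMNS = (
    "sample_id",
    "mouse_id",
    "cage_id",
    "group",
    "day_of_life",
    "timepoint_index",
    "diet",
)


class ValidationError(ValueError):
    """A table or metadata file violates a structural invariant."""


@dataclass
class OtuTable:
    """Integer OTU count matrix, samples x OTUs, with taxonomy lineages.

    Parameters
    ----------
    sample_ids : list of str
        Ordered, unique sample identifiers (rows of ``counts``).
    otu_ids : list of str
        Ordered, unique OTU identifiers (columns of ``counts``).
    counts : ndarray of int, shape (n_samples, n_otus)
        Non-negative read counts.
    taxonomy : dict
        Maps every otu_id to a ranked semicolon-delimited lineage string
        (kingdom .. genus); lower ranks may be empty or "Unclassified".
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        counts = np.asarray(self.counts)
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("counts must be integral")
            counts = np.round(counts).astype(np.int64)
        self.counts = counts.astype(np.int64).reshape(
            len(self.sample_ids), len(self.otu_ids)
        )
        if self.counts.size and self.counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        for name, ids in (("sample", self.sample_ids), ("OTU", self.otu_ids)):
            if len(set(ids)) != len(ids):
                dup = sorted({i for i in ids if ids.count(i) > 1})
                raise ValidationError(f"duplicate {name} ids: {dup}")
        # every OTU gets a taxonomy entry, defaulting to Unclassified
        self.taxonomy = {
            o: str(self.taxonomy.get(o, "Unclassified")) for o in self.otu_ids
        }

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame indexed by sample, columns are OTUs."""
        return pd.DataFrame(
            self.counts, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.otu_ids,
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        keep = list(sample_ids)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in keep if s not in pos]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        idx = [pos[s] for s in keep]
        return OtuTable(keep, list(self.otu_ids), self.counts[idx], dict(self.taxonomy))

    def subset_otus(self, otu_ids: Iterable[str]) -> "OtuTable":
        keep = list(otu_ids)
        pos = {o: i for i, o in enumerate(self.otu_ids)}
        missing = [o for o in keep if o not in pos]
        if missing:
            raise KeyError(f"OTUs not in table: {missing}")
        idx = [pos[o] for o in keep]
        return OtuTable(
            list(self.sample_ids), keep, self.counts[:, idx],
            {o: self.taxonomy[o] for o in keep},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
            and self.taxonomy == other.taxonomy
        )


@dataclass
class CohortMetadata:
    """Per-sample design variables for a longitudinal cohort.

    Wraps a DataFrame with one row per sample and the columns
    ``mouse_id, cage_id, group, day_of_life, timepoint_index, diet``,
    indexed by ``sample_id``. Validated invariants:

    * (mouse_id, timepoint_index) is unique, and day_of_life is strictly
      increasing within a mouse along timepoint_index;
    * ``group`` is one of control / amoxicillin / tylosin / mixture;
    * ``diet`` is high_fat exactly when day_of_life >= diet_switch_day.
    """

    frame: pd.DataFrame
    diet_switch_day: int = 41

    def __post_init__(self) -> None:
        df = self.frame
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            else:
                raise ValidationError("metadata needs a sample_id column or index")
        required = set(METADATA_COLUMNS) - {"sample_id"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        df = df.copy()
        df["day_of_life"] = df["day_of_life"].astype(int)
        df["timepoint_index"] = df["timepoint_index"].astype(int)

        bad_group = sorted(set(df["group"]) - set(GROUPS))
        if bad_group:
            raise ValidationError(
                f"unknown group labels {bad_group}; allowed: {list(GROUPS)}"
            )
        bad_diet = sorted(set(df["diet"]) - set(DIETS))
        if bad_diet:
            raise ValidationError(
                f"unknown diet labels {bad_diet}; allowed: {list(DIETS)}"
            )
        if df.duplicated(subset=["mouse_id", "timepoint_index"]).any():
            raise ValidationError("(mouse_id, timepoint_index) pairs must be unique")
        for mouse, sub in df.groupby("mouse_id", sort=False):
            days = sub.sort_values("timepoint_index")["day_of_life"].to_numpy()
            if np.any(np.diff(days) <= 0):
                raise ValidationError(
                    f"day_of_life not strictly increasing for mouse {mouse}: "
                    f"{days.tolist()}"
                )
        expect_hfd = df["day_of_life"] >= self.diet_switch_day
        actual_hfd = df["diet"] == "high_fat"
        if not (expect_hfd == actual_hfd).all():
            bad = df.index[expect_hfd != actual_hfd].tolist()
            raise ValidationError(
                f"diet inconsistent with diet_switch_day={self.diet_switch_day} "
                f"for samples {bad[:5]}"
            )
        self.frame = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def subset(self, sample_ids: Iterable[str]) -> "CohortMetadata":
        return CohortMetadata(
            self.frame.loc[list(sample_ids)].copy(), self.diet_switch_day
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortMetadata):
            return NotImplemented
        return self.frame.equals(other.frame)


# ---------------------------------------------------------------------------
# count-table I/O


def read_otu_table(path: str | Path, dialect: str = "classic_tsv") -> OtuTable:
    """Read an OTU table in the ``classic_tsv`` or ``biom_json`` dialect.

    Classic tables store OTUs as rows and samples as columns; the returned
    object is transposed to the package's samples x OTUs orientation.
    """
    path = Path(path)
    if dialect == "classic_tsv":
        return _read_classic(path)
    if dialect == "biom_json":
        return _read_biom_json(path)
    raise ValueError(f"unsupported dialect {dialect!r}")


def write_otu_table(
    table: OtuTable, path: str | Path, dialect: str = "classic_tsv"
) -> None:
    """Write ``table`` so that :func:`read_otu_table` round-trips it exactly."""
    path = Path(path)
    try:
        if dialect == "classic_tsv":
            _write_classic(table, path)
        elif dialect == "biom_json":
            _write_biom_json(table, path)
        else:
            raise ValueError(f"unsupported dialect {dialect!r}")
    except OSError as exc:
        raise OSError(f"failed writing OTU table to {path}: {exc}") from exc


def _read_classic(path: Path) -> OtuTable:
    header = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if header is None:
                if line.startswith("#OTU ID"):
                    header = line.split("\t")
                elif line.startswith("#"):
                    continue  # e.g. "# Constructed from biom file"
                else:
                    raise ValidationError(
                        f"{path}: expected '#OTU ID' header before data "
                        f"(line {lineno})"
                    )
            else:
                rows.append(line.split("\t"))
    if header is None:
        raise ValidationError(f"{path}: no '#OTU ID' header found")
    has_tax = header[-1].strip().lower() == "taxonomy"
    sample_ids = header[1 : -1 if has_tax else None]
    n_cols = len(header)
    otu_ids: list[str] = []
    taxonomy: dict[str, str] = {}
    data = np.zeros((len(rows), len(sample_ids)), dtype=np.int64)
    for i, fields in enumerate(rows):
        if len(fields) != n_cols:
            raise ValidationError(
                f"{path}: row {i + 1} ('{fields[0]}') has {len(fields)} fields, "
                f"expected {n_cols}"
            )
        otu_ids.append(fields[0])
        values = fields[1 : -1 if has_tax else None]
        for j, v in enumerate(values):
            try:
                fv = float(v)
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: non-numeric count {v!r} in row '{fields[0]}'"
                ) from exc
            if fv < 0 or fv != int(fv):
                raise ValidationError(
                    f"{path}: count {v!r} in row '{fields[0]}' is not a "
                    "non-negative integer"
                )
            data[i, j] = int(fv)
        if has_tax:
            taxonomy[fields[0]] = fields[-1]
    # classic orientation is OTUs x samples; transpose to samples x OTUs
    return OtuTable(sample_ids, otu_ids, data.T, taxonomy)


def _write_classic(table: OtuTable, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# Constructed from biom file\n")
        fh.write("\t".join(["#OTU ID", *table.sample_ids, "taxonomy"]) + "\n")
        counts = table.counts.T  # OTUs x samples on disk
        for i, otu in enumerate(table.otu_ids):
            fields = [otu, *(str(int(c)) for c in counts[i]),
                      table.taxonomy[otu]]
            fh.write("\t".join(fields) + "\n")


def _read_biom_json(path: Path) -> OtuTable:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("matrix_type") != "dense":
        raise ValidationError(
            f"{path}: only dense BIOM-JSON is supported, got "
            f"{doc.get('matrix_type')!r}"
        )
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    taxonomy = {}
    for r in doc["rows"]:
        md = r.get("metadata") or {}
        tax = md.get("taxonomy", "Unclassified")
        if isinstance(tax, list):
            tax = "; ".join(tax)
        taxonomy[r["id"]] = tax
    data = np.asarray(doc["data"], dtype=float)
    if data.size == 0:
        data = data.reshape(len(otu_ids), len(sample_ids))
    if data.shape != (len(otu_ids), len(sample_ids)):
        raise ValidationError(
            f"{path}: data shape {data.shape} does not match "
            f"({len(otu_ids)}, {len(sample_ids)})"
        )
    if data.size and (np.any(data < 0) or not np.allclose(data, np.round(data))):
        raise ValidationError(f"{path}: counts must be non-negative integers")
    return OtuTable(sample_ids, otu_ids, data.astype(np.int64).T, taxonomy)


def _write_biom_json(table: OtuTable, path: Path) -> None:
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "patmb",
        "matrix_type": "dense",
        "matrix_element_type": "int",
        "shape": [table.n_otus, table.n_samples],
        "rows": [
            {"id": o, "metadata": {"taxonomy": table.taxonomy[o]}}
            for o in table.otu_ids
        ],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": table.counts.T.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# metadata I/O


def read_metadata(path: str | Path, diet_switch_day: int = 41) -> CohortMetadata:
    """Read and validate a cohort metadata TSV (columns per METADATA_COLUMNS)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "mouse_id": str,
                                            "cage_id": str})
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: metadata missing columns {sorted(missing)}")
    return CohortMetadata(df, diet_switch_day=diet_switch_day)


def write_metadata(meta: CohortMetadata, path: str | Path) -> None:
    meta.frame.reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# alignment


@dataclass
class AlignedView:
    """An OTU table and metadata subset to their shared samples, in metadata order."""

    table: OtuTable
    metadata: CohortMetadata
    dropped_table_samples: list[str]
    dropped_metadata_samples: list[str]


def align(table: OtuTable, meta: CohortMetadata) -> AlignedView:
    """Subset ``table`` and ``meta`` to their common samples, ordered by metadata.

    Raises
    ------
    ValidationError
        If the two artifacts share no sample ids.
    """
    table_set = set(table.sample_ids)
    shared = [s for s in meta.sample_ids if s in table_set]
    if not shared:
        raise ValidationError("OTU table and metadata share no sample ids")
    dropped_t = [s for s in table.sample_ids if s not in set(shared)]
    dropped_m = [s for s in meta.sample_ids if s not in table_set]
    if dropped_t or dropped_m:
        logger.warning(
            "align: dropped %d table-only and %d metadata-only samples",
            len(dropped_t), len(dropped_m),
        )
    return AlignedView(
        table=table.subset_samples(shared),
        metadata=meta.subset(shared),
        dropped_table_samples=dropped_t,
        dropped_metadata_samples=dropped_m,
    )
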