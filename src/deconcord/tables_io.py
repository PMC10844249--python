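"""Reading, validating and writing the tabular formats used by the pipeline.

All delimited files are TAB-separated UTF-8 with LF line endings and a
mandatory header row; lines starting with ``#`` are treated as comment
headers (used to echo run configuration) and skipped on read.  Feature
identifiers are matched case-sensitively everywhere: mapping mouse ``Klk5``
to human ``KLK5`` is the job of the ortholog map, never of case folding.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, ValidationError

logger = logging.getLogger(__name__)

#: canonical column order of a differential-expression summary table
DIFF_COLUMNS = ("feature_id", "log2fc", "p_raw", "p_adj")

#: allowed molecular layers of a DiffTable
LAYERS = ("mrna", "protein")


@dataclass
class DiffTable:
    """Per-feature differential summary (log2FC, raw and adjusted P) for one
    dataset and one molecular layer.

    ``records`` is a DataFrame with columns ``feature_id``, ``log2fc``,
    ``p_raw``, ``p_adj``.  When ``unadjusted`` is true the ``p_adj`` column is
    all-NaN and downstream steps that require adjusted P values refuse to run.
    """

    dataset_label: str
    layer: str
    records: pd.DataFrame
    unadjusted: bool = False
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ConfigurationError(
                f"layer must be one of {LAYERS}, got {self.layer!r}"
            )
        validate_diff_records(self.records, allow_missing_padj=self.unadjusted)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def feature_ids(self) -> set[str]:
        return set(self.records["feature_id"])


def validate_diff_records(records: pd.DataFrame, allow_missing_padj: bool = False) -> None:
    """Enforce the DiffTable invariants; raise ValidationError on violation."""
    missing = [c for c in DIFF_COLUMNS if c not in records.columns]
    if missing:
        raise ConfigurationError(f"missing required column(s): {', '.join(missing)}")
    if len(records) == 0:
        raise ValidationError("table is empty after filtering")
    dup = records["feature_id"][records["feature_id"].duplicated()]
    if len(dup):
        head = ", ".join(dup.unique()[:10])
        raise ValidationError(f"duplicate feature_id values (first 10): {head}")
    lfc = records["log2fc"]
    if not lfc.map(lambda v: isinstance(v, (int, float)) and math.isfinite(v)).all():
        raise ValidationError("non-finite log2fc present in validated records")
    for col in ("p_raw", "p_adj"):
        p = records[col].dropna()
        if col == "p_adj" and allow_missing_padj:
            if len(p):
                _check_p_range(p, col)
            continue
        if records[col].isna().any():
            raise ValidationError(f"{col} contains missing values")
        _check_p_range(p, col)


def _check_p_range(p: pd.Series, col: str) -> None:
    if ((p < 0) | (p > 1)).any():
        bad = p[(p < 0) | (p > 1)].iloc[0]
        raise ValidationError(f"{col} outside [0, 1]: {bad}")


def read_diff_table(
    path,
    dataset_label: str,
    layer: str,
    column_spec: dict[str, str] | None = None,
    allow_unadjusted: bool = False,
) -> DiffTable:
    """Read a TSV differential-expression summary into a validated DiffTable.

    ``column_spec`` remaps canonical column names to the file's header names,
    e.g. ``{"feature_id": "gene", "log2fc": "log2FoldChange"}``.  Records with
    missing or non-finite log2fc are dropped with a logged count.  A missing
    adjusted-P column is accepted only when ``allow_unadjusted`` is set.
    """
    spec = {c: c for c in DIFF_COLUMNS}
    if column_spec:
        spec.update(column_spec)
    try:
        raw = pd.read_csv(
            path, sep="\t", comment="#",
            dtype={spec["feature_id"]: str},
            float_precision="round_trip",
        )
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed delimited text
        raise ParseError(f"cannot parse {path}: {exc}") from exc

    unadjusted = False
    for canonical, name in spec.items():
        if name not in raw.columns:
            if canonical == "p_adj" and allow_unadjusted:
                unadjusted = True
                continue
            raise ConfigurationError(
                f"{path}: required column {name!r} (for {canonical}) not found"
            )
    records = pd.DataFrame({"feature_id": raw[spec["feature_id"]]})
    for canonical in ("log2fc", "p_raw", "p_adj"):
        if canonical == "p_adj" and unadjusted:
            records[canonical] = float("nan")
        else:
            records[canonical] = pd.to_numeric(raw[spec[canonical]], errors="coerce")

    n_before = len(records)
    keep = np.isfinite(records["log2fc"].to_numpy(dtype=float))
    n_dropped = int(n_before - keep.sum())
    records = records.loc[keep].reset_index(drop=True)
    logger.info(
        "%s: %d rows read, %d dropped (missing/non-finite log2fc), %d retained",
        path, n_before, n_dropped, len(records),
    )
    if len(records) == 0:
        raise ValidationError(f"{path}: no records remain after dropping non-finite log2fc")
    return DiffTable(
        dataset_label=dataset_label,
        layer=layer,
        records=records,
        unadjusted=unadjusted,
        n_dropped=n_dropped,
    )


def write_diff_table(table: DiffTable, path, header_lines: list[str] | None = None) -> None:
    """Write a DiffTable as canonical TSV (comment header lines optional)."""
    _write_tsv(table.records[list(DIFF_COLUMNS)], path, header_lines)


@dataclass
class OrthologMap:
    """Source-to-target feature-id pairs aligning two id namespaces."""

    pairs: pd.DataFrame  # columns source_id, target_id

    def __post_init__(self) -> None:
        for col in ("source_id", "target_id"):
            if col not in self.pairs.columns:
                raise ConfigurationError(f"ortholog map missing column {col!r}")
        if self.pairs.duplicated(subset=["source_id", "target_id"]).any():
            raise ValidationError("duplicated (source_id, target_id) pair in ortholog map")

    def __len__(self) -> int:
        return len(self.pairs)


def read_ortholog_map(path) -> OrthologMap:
    """Read a two-column TSV with header ``source_id<TAB>target_id``."""
    try:
        pairs = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ParseError(f"cannot parse ortholog map {path}: {exc}") from exc
    return OrthologMap(pairs=pairs)


def write_ortholog_map(omap: OrthologMap, path, header_lines: list[str] | None = None) -> None:
    out = omap.pairs[["source_id", "target_id"]].sort_values(
        ["source_id", "target_id"], kind="mergesort"
    )
    _write_tsv(out, path, header_lines)


@dataclass
class GeneSetCollection:
    """Named feature sets (term_id -> description + members)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term_id, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {term_id!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, term_id: str) -> frozenset[str]:
        return self.sets[term_id][1]

    def description(self, term_id: str) -> str:
        return self.sets[term_id][0]


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: ``term_id<TAB>description<TAB>member[<TAB>member...]``."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line has {len(fields)} field(s); need term, description "
                    "and at least one member",
                    line_number=lineno,
                )
            term_id, description = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise ParseError(f"gene set {term_id!r} has no members", line_number=lineno)
            if term_id in sets:
                raise ValidationError(f"duplicate term_id {term_id!r} in {path}")
            sets[term_id] = (description, members)
    return GeneSetCollection(sets=sets)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    """Write a GeneSetCollection as GMT; terms and members sorted for determinism."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for term_id in sorted(collection.sets):
            description, members = collection.sets[term_id]
            fh.write("\t".join([term_id, description, *sorted(members)]) + "\n")


def write_report(result, path, header_lines: list[str] | None = None, sort_by=None) -> None:
    """Write any flat-row result deterministically as TSV.

    Accepts a DataFrame, a list of dicts, or an object exposing ``to_frame()``.
    Rows are sorted by ``sort_by`` (default: the first column) with a stable
    sort, so re-running on equal input produces byte-identical files.
    """
    if hasattr(result, "to_frame") and not isinstance(result, pd.Series):
        frame = result.to_frame()
    elif isinstance(result, pd.DataFrame):
        frame = result.copy()
    else:
        frame = pd.DataFrame(list(result))
    if len(frame):
        keys = sort_by if sort_by is not None else [frame.columns[0]]
        frame = frame.sort_values(list(keys), kind="mergesort")
    _write_tsv(frame, path, header_lines)


def _write_tsv(frame: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    frame = frame.copy()
    for col in frame.columns:
        # shortest round-trip representation so read-back is bit-exact
        if pd.api.types.is_float_dtype(frame[col]):
            frame[col] = frame[col].map(
                lambda v: "" if pd.isna(v) else repr(float(v))
            )
    buf = io.StringIO()
    if header_lines:
        for line in header_lines:
            buf.write(f"# {line}\n")
    frame.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    try:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(buf.getvalue())
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc
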