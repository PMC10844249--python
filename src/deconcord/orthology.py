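"""Aligning two differential tables into paired fold-change vectors.

Cross-species alignment goes through an ortholog map; same-study layers
(mRNA vs protein of one dataset) share a feature-id namespace and are
joined by identity.  The default one-to-one policy discards any map entry
whose source or target id participates in more than one pair, since
ambiguous homology would duplicate y-values and inflate correlation n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tables_io import DiffTable, OrthologMap

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ("id_x", "id_y", "x", "y", "p_adj_x", "p_adj_y")


@dataclass
class PairedChanges:
    """Aligned log2 fold-change vectors for two tables.

    ``rows`` has columns ``id_x, id_y, x, y, p_adj_x, p_adj_y`` sorted
    lexicographically by (id_x, id_y).
    """

    pair_labels: tuple[str, str]
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.rows) < 1:
            raise ValidationError("PairedChanges needs at least one row")
        if self.rows.duplicated(subset=["id_x", "id_y"]).any():
            raise ValidationError("duplicate (id_x, id_y) pair")
        for col in ("x", "y"):
            if not np.isfinite(self.rows[col].to_numpy(dtype=float)).all():
                raise ValidationError(f"non-finite value in column {col!r}")

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def x(self) -> np.ndarray:
        return self.rows["x"].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.rows["y"].to_numpy(dtype=float)


def resolve_one_to_one(omap: OrthologMap) -> pd.DataFrame:
    """Drop every map pair whose source or target id occurs more than once."""
    pairs = omap.pairs
    src_ok = ~pairs["source_id"].duplicated(keep=False)
    tgt_ok = ~pairs["target_id"].duplicated(keep=False)
    resolved = pairs.loc[src_ok & tgt_ok]
    logger.info(
        "ortholog map: %d pairs, %d ambiguous dropped, %d one-to-one",
        len(pairs), len(pairs) - len(resolved), len(resolved),
    )
    return resolved


def pair_by_orthology(
    table_x: DiffTable,
    table_y: DiffTable,
    omap: OrthologMap,
    policy: str = "one_to_one_only",
) -> PairedChanges:
    """Join two tables through an ortholog map (x ids are sources, y ids targets)."""
    if len(omap) == 0:
        raise ValidationError("ortholog map is empty")
    if policy == "one_to_one_only":
        pairs = resolve_one_to_one(omap)
    elif policy == "first_match":
        pairs = omap.pairs.drop_duplicates(subset="source_id", keep="first")
        pairs = pairs.drop_duplicates(subset="target_id", keep="first")
    else:
        raise ValidationError(f"unknown pairing policy {policy!r}")

    left = table_x.records.rename(
        columns={"feature_id": "id_x", "log2fc": "x", "p_adj": "p_adj_x"}
    )[["id_x", "x", "p_adj_x"]]
    right = table_y.records.rename(
        columns={"feature_id": "id_y", "log2fc": "y", "p_adj": "p_adj_y"}
    )[["id_y", "y", "p_adj_y"]]
    merged = (
        pairs.rename(columns={"source_id": "id_x", "target_id": "id_y"})
        .merge(left, on="id_x", how="inner")
        .merge(right, on="id_y", how="inner")
    )
    merged = merged[list(PAIR_COLUMNS)].sort_values(
        ["id_x", "id_y"], kind="mergesort"
    ).reset_index(drop=True)
    logger.info(
        "orthology join %s vs %s: %d map pairs usable, %d matched",
        table_x.dataset_label, table_y.dataset_label, len(pairs), len(merged),
    )
    if len(merged) == 0:
        raise ValidationError("no ortholog pairs matched")
    return PairedChanges(
        pair_labels=(table_x.dataset_label, table_y.dataset_label), rows=merged
    )


def pair_by_identity(table_x: DiffTable, table_y: DiffTable) -> PairedChanges:
    """Inner-join two tables that share an id namespace, sorted by feature_id."""
    left = table_x.records.rename(
        columns={"feature_id": "id_x", "log2fc": "x", "p_adj": "p_adj_x"}
    )[["id_x", "x", "p_adj_x"]]
    right = table_y.records.rename(
        columns={"feature_id": "id_y", "log2fc": "y", "p_adj": "p_adj_y"}
    )[["id_y", "y", "p_adj_y"]]
    merged = left.merge(right, left_on="id_x", right_on="id_y", how="inner")
    merged = merged[list(PAIR_COLUMNS)].sort_values(
        ["id_x", "id_y"], kind="mergesort"
    ).reset_index(drop=True)
    if len(merged) == 0:
        raise ValidationError(
            f"no shared feature ids between {table_x.dataset_label} "
            f"and {table_y.dataset_label}"
        )
    return PairedChanges(
        pair_labels=(table_x.dataset_label, table_y.dataset_label), rows=merged
    )
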