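"""Pearson concordance between paired fold-change vectors and Fisher r-to-z
comparisons between dataset pairs.

Correlations are computed on all matched pairs by default (a restriction to
differentially expressed features is available via ``classify_deg`` +
``subset_correlation``).  The r-to-z comparison is applied as for
independent samples even when two correlations share a reference dataset —
the comparisons deliberately reproduce that procedure and log a caveat.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DegenerateInputError, ValidationError
from .orthology import PairedChanges, pair_by_identity, pair_by_orthology, resolve_one_to_one
from .tables_io import DiffTable, GeneSetCollection, OrthologMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    """Sample Pearson r with its two-sided t-test P (n-2 degrees of freedom)."""

    r: float
    n: int
    p: float
    subset_label: str = "global"


@dataclass(frozen=True)
class CorrelationComparison:
    """Two-sided z-test of r1 vs r2 via Fisher's variance-stabilizing transform.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); p is the
    two-sided normal tail.
    """

    label_1: str
    label_2: str
    r1: float
    r2: float
    n1: int
    n2: int
    z: float
    p: float


@dataclass(frozen=True)
class DegSets:
    """Differentially expressed feature ids, split by direction.

    Strict inequalities: up requires log2fc > lfc_cut and p_adj < p_cut;
    down requires log2fc < -lfc_cut and p_adj < p_cut.
    """

    up: frozenset[str]
    down: frozenset[str]
    thresholds: tuple[float, float]


@dataclass(frozen=True)
class DegOverlap:
    a_only_up: int
    shared_up: int
    b_only_up: int
    a_only_down: int
    shared_down: int
    b_only_down: int


def pearson(pairs: PairedChanges, subset_label: str = "global") -> CorrelationResult:
    """Sample Pearson correlation of the paired log2 fold changes."""
    return _pearson_arrays(pairs.x, pairs.y, subset_label)


def _pearson_arrays(x: np.ndarray, y: np.ndarray, subset_label: str) -> CorrelationResult:
    n = len(x)
    if n < 4:
        raise ValidationError(f"need at least 4 pairs for a correlation, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in one of the paired vectors")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, p=p, subset_label=subset_label)


def compare_correlations(
    c1: CorrelationResult,
    c2: CorrelationResult,
    label_1: str = "c1",
    label_2: str = "c2",
) -> CorrelationComparison:
    """Fisher r-to-z comparison of two (assumed independent) correlations."""
    for c in (c1, c2):
        if c.n <= 3:
            raise ValidationError(f"r-to-z needs n > 3, got n = {c.n}")
        if abs(c.r) >= 1.0:
            raise ValidationError(f"r-to-z undefined for |r| >= 1 (r = {c.r})")
    if c1.r == c2.r:
        z = 0.0
        p = 1.0
    else:
        se = math.sqrt(1.0 / (c1.n - 3) + 1.0 / (c2.n - 3))
        z = (math.atanh(c1.r) - math.atanh(c2.r)) / se
        p = 2.0 * float(stats.norm.sf(abs(z)))
    return CorrelationComparison(
        label_1=label_1, label_2=label_2,
        r1=c1.r, r2=c2.r, n1=c1.n, n2=c2.n, z=z, p=p,
    )


def classify_deg(table: DiffTable, lfc_cut: float = 1.0, p_cut: float = 0.05) -> DegSets:
    """Split a table into up/down differentially expressed feature sets."""
    if table.unadjusted:
        raise ConfigurationError(
            f"table {table.dataset_label!r} has no adjusted P values; "
            "DEG classification requires p_adj"
        )
    rec = table.records
    sig = rec["p_adj"] < p_cut
    up = frozenset(rec.loc[sig & (rec["log2fc"] > lfc_cut), "feature_id"])
    down = frozenset(rec.loc[sig & (rec["log2fc"] < -lfc_cut), "feature_id"])
    return DegSets(up=up, down=down, thresholds=(lfc_cut, p_cut))


def deg_overlap(sets_a: DegSets, sets_b: DegSets, omap: OrthologMap | None = None) -> DegOverlap:
    """Venn counts of a's DEGs (mapped into b's namespace) against b's DEGs."""
    if omap is not None:
        resolved = resolve_one_to_one(omap)
        mapping = dict(zip(resolved["source_id"], resolved["target_id"]))
    else:
        mapping = None

    def _counts(a: frozenset[str], b: frozenset[str]) -> tuple[int, int, int]:
        mapped = {mapping[i] for i in a if i in mapping} if mapping is not None else set(a)
        shared = mapped & b
        return len(a) - len(shared), len(shared), len(b) - len(shared)

    a_up, s_up, b_up = _counts(sets_a.up, sets_b.up)
    a_dn, s_dn, b_dn = _counts(sets_a.down, sets_b.down)
    return DegOverlap(
        a_only_up=a_up, shared_up=s_up, b_only_up=b_up,
        a_only_down=a_dn, shared_down=s_dn, b_only_down=b_dn,
    )


def subset_correlation(
    pairs: PairedChanges,
    member_set: set[str] | frozenset[str],
    side: str = "x_ids",
    subset_label: str = "subset",
) -> CorrelationResult:
    """Pearson correlation restricted to rows whose id (x or y side) is in
    ``member_set``; bit-identical to :func:`pearson` when the set covers all rows."""
    if side == "x_ids":
        mask = pairs.rows["id_x"].isin(member_set)
    elif side == "y_ids":
        mask = pairs.rows["id_y"].isin(member_set)
    else:
        raise ConfigurationError(f"side must be 'x_ids' or 'y_ids', got {side!r}")
    x = pairs.rows.loc[mask, "x"].to_numpy(dtype=float)
    y = pairs.rows.loc[mask, "y"].to_numpy(dtype=float)
    if len(x) < 4:
        raise ValidationError(
            f"subset {subset_label!r} leaves {len(x)} pairs; need at least 4"
        )
    return _pearson_arrays(x, y, subset_label)


def concordance_matrix(
    tables: list[DiffTable],
    reference: DiffTable,
    omap: OrthologMap | None = None,
    subsets: GeneSetCollection | None = None,
    policy: str = "one_to_one_only",
) -> tuple[list[tuple[str, CorrelationResult]], list[CorrelationComparison]]:
    """Correlate each table against the reference (globally and per gene set)
    and compare every pair of same-subset correlations via Fisher r-to-z.

    Returns ``(correlations, comparisons)`` where correlations are
    ``(table_label, CorrelationResult)`` tuples.  Comparisons carry no
    multiplicity correction (callers may Bonferroni-adjust over their count);
    sharing the reference dataset across comparisons violates the
    independence assumption of the z test, which is logged as a caveat.
    """
    if len(tables) < 2:
        raise ValidationError(f"need at least 2 tables to compare, got {len(tables)}")
    logger.warning(
        "r-to-z comparisons share the reference dataset %r; the independence "
        "assumption of the z test does not strictly hold",
        reference.dataset_label,
    )
    correlations: list[tuple[str, CorrelationResult]] = []
    for table in tables:
        if omap is not None:
            pairs = pair_by_orthology(table, reference, omap, policy=policy)
        else:
            pairs = pair_by_identity(table, reference)
        correlations.append((table.dataset_label, pearson(pairs)))
        if subsets is not None:
            for term_id in sorted(subsets.sets):
                try:
                    correlations.append(
                        (
                            table.dataset_label,
                            subset_correlation(
                                pairs, subsets.members(term_id),
                                side="x_ids", subset_label=term_id,
                            ),
                        )
                    )
                except ValidationError:
                    logger.info(
                        "subset %s too small for table %s; skipped",
                        term_id, table.dataset_label,
                    )
    comparisons: list[CorrelationComparison] = []
    by_subset: dict[str, list[tuple[str, CorrelationResult]]] = {}
    for label, corr in correlations:
        by_subset.setdefault(corr.subset_label, []).append((label, corr))
    for subset_label in sorted(by_subset):
        for (la, ca), (lb, cb) in combinations(by_subset[subset_label], 2):
            comparisons.append(
                compare_correlations(
                    ca, cb,
                    label_1=f"{la}@{subset_label}",
                    label_2=f"{lb}@{subset_label}",
                )
            )
    return correlations, comparisons
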