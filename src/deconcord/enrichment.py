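"""Gene-set over-representation testing.

Two one-tailed statistics are offered: the plain hypergeometric upper tail
P(X >= k) ("fisher") and the conservative variant that recomputes the same
tail with the observed overlap reduced by one ("ease"; overlaps of 0 or 1
score p = 1).  Term-level multiplicity is handled by Bonferroni over the
number of terms actually tested within the chosen background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .tables_io import GeneSetCollection

logger = logging.getLogger(__name__)

MODES = ("fisher", "ease")


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation of one term: overlap counts and P values.

    k = |query ∩ term|, K = |term ∩ background|, n = |query|, N = |background|.
    """

    term_id: str
    description: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_bonferroni: float
    significant: bool


def overrep_p(k, K, n, N, mode: str = "fisher"):
    """One-tailed over-representation P for overlap k of a size-n query with a
    size-K term inside a size-N background.

    Scalar or array-like inputs (broadcast together); returns a float for
    scalar input, an ndarray otherwise.
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")
    scalar = all(np.ndim(v) == 0 for v in (k, K, n, N))
    k = np.asarray(k, dtype=np.int64)
    K = np.asarray(K, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    N = np.asarray(N, dtype=np.int64)
    k, K, n, N = np.broadcast_arrays(k, K, n, N)
    lo = np.maximum(0, n + K - N)
    hi = np.minimum(K, n)
    bad = (N < 0) | (K < 0) | (n < 0) | (K > N) | (n > N) | (k < lo) | (k > hi)
    if bad.any():
        idx = np.argwhere(bad)[0]
        raise ValidationError(
            "inconsistent contingency counts "
            f"(k={k[tuple(idx)]}, K={K[tuple(idx)]}, n={n[tuple(idx)]}, N={N[tuple(idx)]})"
        )
    if mode == "ease":
        # tail at k-1; an overlap of 0 or 1 is never evidence
        p = np.where(k <= 1, 1.0, stats.hypergeom.sf(k - 2, N, K, n))
    else:
        p = stats.hypergeom.sf(k - 1, N, K, n)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if scalar else p


def enrich(
    query: set[str] | frozenset[str],
    background: set[str] | frozenset[str],
    sets: GeneSetCollection,
    mode: str = "ease",
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every term with at least one background member for over-representation
    of the query; Bonferroni-adjust over the tested terms.

    Results are sorted by raw P ascending, then term_id.
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        extra = sorted(query - background)[:5]
        raise ValidationError(f"query ids not in background (first few): {extra}")
    if len(sets) == 0:
        raise ValidationError("gene-set collection is empty")
    if not query:
        logger.warning("empty query; returning no enrichment results")
        return []
    N = len(background)
    n = len(query)
    tested: list[tuple[str, str, int, int]] = []
    for term_id in sorted(sets.sets):
        members = sets.members(term_id) & background
        K = len(members)
        if K == 0:
            continue
        k = len(query & members)
        tested.append((term_id, sets.description(term_id), k, K))
    if not tested:
        logger.warning("no term overlaps the background; nothing tested")
        return []
    m = len(tested)
    results = []
    for term_id, description, k, K in tested:
        p_raw = overrep_p(k, K, n, N, mode=mode)
        p_bonf = min(1.0, p_raw * m)
        results.append(
            EnrichmentResult(
                term_id=term_id, description=description,
                k=k, K=K, n=n, N=N,
                p_raw=p_raw, p_bonferroni=p_bonf,
                significant=p_bonf < alpha,
            )
        )
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results
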