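"""Four-stage transcriptome-proteome discordance screen.

For each dataset the protein log2 fold change is regressed on the mRNA
log2 fold change (ordinary least squares with intercept); the screen then
looks for features whose protein change falls away from the transcript
prediction:

  stage 1  standardized residual beyond +/-cut in the reference dataset AND
           in a comparison dataset, with consistent sign (direction up/down);
  stage 2  intersection of the stage-1 candidate sets across all
           reference-vs-other comparisons;
  stage 3  gene-set over-representation run separately on the up and down
           candidates; a candidate survives only through a significant term
           of its own direction;
  stage 4  thresholds on the reference mRNA statistics (and optionally
           protein adjusted P).

The funnel is monotone by construction: each stage retains a subset of the
previous one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult, enrich
from .errors import ConfigurationError, DegenerateInputError, ValidationError
from .orthology import PairedChanges, pair_by_identity, resolve_one_to_one
from .tables_io import DiffTable, GeneSetCollection, OrthologMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of protein log2FC on mRNA log2FC; residual_sd = sqrt(RSS/(n-2))."""

    slope: float
    intercept: float
    residual_sd: float
    n: int


@dataclass(frozen=True)
class Candidates:
    """Direction-split candidate feature ids surviving a screen stage."""

    up: frozenset[str]
    down: frozenset[str]

    def __len__(self) -> int:
        return len(self.up) + len(self.down)

    @property
    def all(self) -> frozenset[str]:
        return self.up | self.down


@dataclass(frozen=True)
class Stage4Criteria:
    """Final expression-statistics filter; thresholds use strict inequalities
    mirroring the DEG definition.  ``prot_padj_max=None`` disables the protein
    P filter."""

    mrna_padj_max: float = 0.05
    mrna_lfc_min_abs: float = 1.0
    prot_padj_max: float | None = None


@dataclass
class ScreenConfig:
    residual_cut: float = 1.0
    enrichment_mode: str = "ease"
    enrichment_alpha: float = 0.05
    stage4: Stage4Criteria = field(default_factory=Stage4Criteria)
    map_policy: str = "one_to_one_only"

    def echo(self) -> dict:
        d = asdict(self)
        stage4 = d.pop("stage4")
        d.update({f"stage4_{k}": v for k, v in stage4.items()})
        return d


@dataclass
class ScreenResult:
    """Full screen output: one row per reference mRNA-protein pair with the
    residual statistics and per-stage survival flags, plus the per-dataset
    regression fits, per-direction stage-3 enrichment and the echoed config."""

    rows: pd.DataFrame
    fits: dict[str, RegressionFit]
    enrichment: dict[str, list[EnrichmentResult]]
    config_echo: dict

    @property
    def final_candidates(self) -> pd.DataFrame:
        return self.rows.loc[self.rows["pass_stage4"]].reset_index(drop=True)

    def stage_sizes(self) -> tuple[int, int, int, int]:
        return tuple(int(self.rows[f"pass_stage{i}"].sum()) for i in (1, 2, 3, 4))


def fit_fc_regression(pairs: PairedChanges) -> RegressionFit:
    """Ordinary least squares of protein (y) on mRNA (x), intercept included."""
    x, y = pairs.x, pairs.y
    n = len(x)
    if n < 4:
        raise ValidationError(f"regression needs at least 4 pairs, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise DegenerateInputError("mRNA fold changes have zero variance")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    rss = float(np.sum((y - (intercept + slope * x)) ** 2))
    return RegressionFit(
        slope=slope, intercept=intercept,
        residual_sd=float(np.sqrt(rss / (n - 2))), n=n,
    )


def standardized_residuals(pairs: PairedChanges, fit: RegressionFit) -> pd.Series:
    """Raw OLS residual divided by the global residual SD, keyed by id_x."""
    if fit.residual_sd == 0.0:
        raise DegenerateInputError(
            "residual SD is zero (collinear data); screening undefined"
        )
    resid = (pairs.y - (fit.intercept + fit.slope * pairs.x)) / fit.residual_sd
    return pd.Series(resid, index=pairs.rows["id_x"].to_numpy(), name="std_residual")


def stage1_select(res_a: pd.Series, res_b: pd.Series, cut: float = 1.0) -> Candidates:
    """Keep pairs exceeding the residual cut in BOTH datasets with the same
    sign; mixed-sign pairs are excluded."""
    shared = res_a.index.intersection(res_b.index)
    if len(shared) == 0:
        raise ValidationError("no shared pair keys between residual vectors")
    a = res_a.loc[shared]
    b = res_b.loc[shared]
    up = frozenset(shared[(a > cut) & (b > cut)])
    down = frozenset(shared[(a < -cut) & (b < -cut)])
    return Candidates(up=up, down=down)


def stage2_intersect(candidates_1: Candidates, candidates_2: Candidates) -> Candidates:
    """Per-direction intersection of two comparison candidate sets."""
    shared = Candidates(
        up=candidates_1.up & candidates_2.up,
        down=candidates_1.down & candidates_2.down,
    )
    if len(shared) == 0:
        logger.warning("stage 2: no candidates shared between comparisons")
    return shared


def stage3_go_filter(
    candidates: Candidates,
    background: set[str] | frozenset[str],
    collections: list[GeneSetCollection],
    mode: str = "ease",
    alpha: float = 0.05,
) -> tuple[Candidates, dict[str, list[EnrichmentResult]]]:
    """Enrich up and down candidates separately over every provided gene-set
    collection; retain a candidate iff it belongs to at least one significant
    term from its own direction's analyses."""
    if not candidates.all <= set(background):
        raise ValidationError("stage 3 candidates must be a subset of the background")
    enrichments: dict[str, list[EnrichmentResult]] = {"up": [], "down": []}
    retained: dict[str, frozenset[str]] = {}
    for direction in ("up", "down"):
        members_of_significant: set[str] = set()
        query = getattr(candidates, direction)
        for collection in collections:
            results = enrich(query, set(background), collection, mode=mode, alpha=alpha)
            enrichments[direction].extend(results)
            for res in results:
                if res.significant:
                    members_of_significant |= collection.members(res.term_id)
        retained[direction] = frozenset(query & members_of_significant)
    return Candidates(up=retained["up"], down=retained["down"]), enrichments


def stage4_final_filter(rows: pd.DataFrame, criteria: Stage4Criteria) -> pd.Series:
    """Boolean mask over ``rows`` of pairs meeting every configured criterion.

    ``rows`` must carry ``mrna_lfc`` and ``mrna_padj`` columns (and
    ``prot_padj`` when the protein filter is enabled)."""
    for col in ("mrna_lfc", "mrna_padj"):
        if col not in rows.columns:
            raise ConfigurationError(f"stage 4 requires column {col!r}")
    if rows["mrna_padj"].isna().any():
        raise ConfigurationError(
            "stage 4 mRNA adjusted-P criterion requires p_adj; table was "
            "loaded as unadjusted"
        )
    keep = (rows["mrna_padj"] < criteria.mrna_padj_max) & (
        rows["mrna_lfc"].abs() > criteria.mrna_lfc_min_abs
    )
    if criteria.prot_padj_max is not None:
        if "prot_padj" not in rows.columns or rows["prot_padj"].isna().any():
            raise ConfigurationError(
                "stage 4 protein adjusted-P criterion enabled but protein "
                "p_adj is unavailable"
            )
        keep &= rows["prot_padj"] < criteria.prot_padj_max
    return keep


def run_screen(
    dataset_pairs: dict[str, tuple[DiffTable, DiffTable]],
    omap: OrthologMap | None,
    collections: list[GeneSetCollection] | GeneSetCollection,
    config: ScreenConfig | None = None,
) -> ScreenResult:
    """Execute the 4-stage screen.

    ``dataset_pairs`` maps a dataset label to its (mRNA, protein) table pair;
    the FIRST entry is the reference dataset whose feature-id namespace keys
    the whole result.  ``omap`` maps reference ids to every other dataset's
    ids (required when namespaces differ; pass None for shared namespaces).
    """
    if config is None:
        config = ScreenConfig()
    if isinstance(collections, GeneSetCollection):
        collections = [collections]
    if len(dataset_pairs) < 2:
        raise ValidationError(
            f"screen needs at least 2 dataset pairs, got {len(dataset_pairs)}"
        )

    labels = list(dataset_pairs)
    ref_label = labels[0]

    paired: dict[str, PairedChanges] = {}
    fits: dict[str, RegressionFit] = {}
    residuals: dict[str, pd.Series] = {}
    for label, (mrna, protein) in dataset_pairs.items():
        try:
            pairs = pair_by_identity(mrna, protein)
            fit = fit_fc_regression(pairs)
            paired[label] = pairs
            fits[label] = fit
            residuals[label] = standardized_residuals(pairs, fit)
        except (ValidationError, DegenerateInputError) as exc:
            raise type(exc)(f"stage 0 (dataset {label!r}): {exc}") from exc

    if omap is not None:
        resolved = resolve_one_to_one(omap) if config.map_policy == "one_to_one_only" \
            else omap.pairs
        ref_to_other = dict(zip(resolved["source_id"], resolved["target_id"]))
    else:
        ref_to_other = None

    ref_res = residuals[ref_label]

    def _to_ref_keys(series: pd.Series) -> pd.Series:
        # re-key a comparison dataset's residuals into the reference namespace
        if ref_to_other is None:
            return series
        back = {v: k for k, v in ref_to_other.items()}
        keep = series.index.isin(back)
        out = series[keep]
        out.index = [back[i] for i in out.index]
        return out

    comparison_sets: list[Candidates] = []
    for label in labels[1:]:
        other = _to_ref_keys(residuals[label])
        try:
            comparison_sets.append(stage1_select(ref_res, other, cut=config.residual_cut))
        except ValidationError as exc:
            raise ValidationError(f"stage 1 (vs dataset {label!r}): {exc}") from exc

    stage1 = Candidates(
        up=frozenset().union(*(c.up for c in comparison_sets)),
        down=frozenset().union(*(c.down for c in comparison_sets)),
    )
    stage2 = comparison_sets[0]
    for c in comparison_sets[1:]:
        stage2 = stage2_intersect(stage2, c)

    background = set(paired[ref_label].rows["id_x"])
    stage3, enrichments = stage3_go_filter(
        stage2, background, collections,
        mode=config.enrichment_mode, alpha=config.enrichment_alpha,
    )

    ref_pairs = paired[ref_label]
    fit = fits[ref_label]
    rows = pd.DataFrame(
        {
            "id_x": ref_pairs.rows["id_x"].to_numpy(),
            "id_y": ref_pairs.rows["id_y"].to_numpy(),
            "mrna_lfc": ref_pairs.x,
            "prot_lfc": ref_pairs.y,
            "mrna_padj": ref_pairs.rows["p_adj_x"].to_numpy(),
            "prot_padj": ref_pairs.rows["p_adj_y"].to_numpy(),
        }
    )
    rows["expected_prot_lfc"] = fit.intercept + fit.slope * rows["mrna_lfc"]
    rows["std_residual"] = ref_res.to_numpy()
    rows["direction"] = np.where(rows["std_residual"] > 0, "up", "down")
    ids = rows["id_x"]
    rows["pass_stage1"] = ids.isin(stage1.all).to_numpy()
    rows["pass_stage2"] = ids.isin(stage2.all).to_numpy()
    rows["pass_stage3"] = ids.isin(stage3.all).to_numpy()
    try:
        stage4_mask = stage4_final_filter(rows, config.stage4)
    except ConfigurationError as exc:
        raise ConfigurationError(f"stage 4: {exc}") from exc
    rows["pass_stage4"] = (rows["pass_stage3"] & stage4_mask).to_numpy()
    rows = rows.sort_values(["id_x", "id_y"], kind="mergesort").reset_index(drop=True)

    result = ScreenResult(
        rows=rows, fits=fits, enrichment=enrichments, config_echo=config.echo()
    )
    s1, s2, s3, s4 = result.stage_sizes()
    logger.info("screen funnel: stage1=%d stage2=%d stage3=%d stage4=%d", s1, s2, s3, s4)
    assert s1 >= s2 >= s3 >= s4, "funnel monotonicity violated"
    return result
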