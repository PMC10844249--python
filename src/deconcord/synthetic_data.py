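"""Synthetic differential-expression summaries with planted ground truth.

The generator works at the summary-statistic level (no read counts): each
gene carries a latent disease effect shared across datasets, every dataset
observes it with its own noise, and a protein layer is derived from each
transcriptome through a linear relationship.  A chosen subset of
transcriptionally regulated genes ("substrates") has its protein fold
change depressed below the regression prediction, and one planted gene set
covers them — so every stage of the screen has a known answer.

All randomness flows through ``numpy.random.default_rng`` seeded from the
config seed (sub-streams are derived per purpose), giving byte-identical
outputs across runs and platforms.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .tables_io import DiffTable, GeneSetCollection, OrthologMap


@dataclass
class SimConfig:
    """Parameters of the synthetic generator.

    ``sigma_dataset`` may be a single SD applied to every dataset or a
    sequence with one SD per dataset.  ``delta_shift`` is expressed in units
    of ``mrna_prot_noise_sd`` (residual SDs of the mRNA-protein regression).
    """

    n_genes: int = 5000
    pi_de: float = 0.3
    tau_effect: float = 2.0
    sigma_dataset: float | tuple[float, ...] = 0.5
    mrna_prot_slope: float = 0.8
    mrna_prot_noise_sd: float = 0.5
    n_substrates: int = 25
    delta_shift: float = 3.0
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 50)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if not (0 < self.pi_de < 1):
            raise ValidationError("pi_de must lie in (0, 1)")
        if self.tau_effect <= 0 or self.mrna_prot_noise_sd <= 0:
            raise ValidationError("effect and noise SDs must be > 0")
        sigmas = self.sigma_dataset if hasattr(self.sigma_dataset, "__len__") \
            else (self.sigma_dataset,)
        if any(s <= 0 for s in sigmas):
            raise ValidationError("every sigma_dataset must be > 0")
        if not (0 <= self.n_substrates <= self.n_genes):
            raise ValidationError("n_substrates must lie in [0, n_genes]")
        if self.delta_shift < 0:
            raise ValidationError("delta_shift must be >= 0")
        lo, hi = self.term_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise ValidationError(
                f"term_size_range {self.term_size_range} infeasible for "
                f"{self.n_genes} genes"
            )

    def sigma_for(self, d: int) -> float:
        if hasattr(self.sigma_dataset, "__len__"):
            return float(self.sigma_dataset[d % len(self.sigma_dataset)])
        return float(self.sigma_dataset)


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside the synthetic tables.

    Ids in ``de_genes``/``substrate_genes`` are in the base (reference,
    "mouse") namespace; ``id_aliases`` maps every dataset-local id back to
    its base id.
    """

    de_genes: frozenset[str]
    substrate_genes: frozenset[str]
    latent_effects: np.ndarray
    enriched_term_ids: frozenset[str] = frozenset()
    seed_used: int = 0
    id_aliases: dict[str, str] = field(default_factory=dict)

    def local_ids(self, base_ids, namespace_of: DiffTable) -> frozenset[str]:
        """Translate base ids into the namespace used by ``namespace_of``."""
        wanted = set(base_ids)
        return frozenset(
            local for local in namespace_of.records["feature_id"]
            if self.id_aliases.get(local) in wanted
        )


def _rng(seed: int, purpose: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(purpose.encode())])


def _bh(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def _base_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(n)]


def _humanize(base_id: str) -> str:
    return base_id.upper() + "_H"


def _normal_test_table(
    ids: list[str], values: np.ndarray, se: float, label: str, layer: str
) -> DiffTable:
    z = np.abs(values) / se
    p_raw = 2.0 * stats.norm.sf(z)
    return DiffTable(
        dataset_label=label,
        layer=layer,
        records=pd.DataFrame(
            {"feature_id": ids, "log2fc": values, "p_raw": p_raw, "p_adj": _bh(p_raw)}
        ),
    )


def simulate_paired_transcriptomes(
    cfg: SimConfig, n_datasets: int = 2
) -> tuple[list[DiffTable], OrthologMap, SimTruth]:
    """Generate ``n_datasets`` transcriptome summaries sharing one latent
    disease program, plus the ortholog map joining the two namespaces.

    Dataset 0 ("mouse") uses the base id namespace; datasets 1.. ("human_d")
    share a transformed copy of it.  Gene g is null with probability
    1 - pi_de, otherwise its latent effect is Normal(0, tau_effect^2);
    dataset d observes the effect plus Normal(0, sigma_d^2) noise, with
    sigma_d doubling as the standard error of the per-gene normal test.
    Substrate genes are drawn among genes passing strict DE cuts
    (|log2FC| > 1, BH-adjusted P < 0.05) in every dataset, so the planted
    discordance is recoverable by the screen's final expression filter.
    """
    if n_datasets < 1:
        raise ValidationError("need at least 1 dataset")
    base = _base_ids(cfg.n_genes)
    rng = _rng(cfg.seed, "latent")
    de_mask = rng.random(cfg.n_genes) < cfg.pi_de
    theta = np.where(de_mask, rng.normal(0.0, cfg.tau_effect, cfg.n_genes), 0.0)

    tables: list[DiffTable] = []
    observed: list[np.ndarray] = []
    aliases: dict[str, str] = {}
    for d in range(n_datasets):
        sigma = cfg.sigma_for(d)
        x = theta + _rng(cfg.seed, f"dataset{d}").normal(0.0, sigma, cfg.n_genes)
        observed.append(x)
        if d == 0:
            label, ids = "mouse", base
        else:
            label, ids = f"human_{d}", [_humanize(b) for b in base]
        aliases.update(zip(ids, base))
        tables.append(_normal_test_table(ids, x, sigma, label, "mrna"))

    omap = OrthologMap(
        pairs=pd.DataFrame(
            {"source_id": base, "target_id": [_humanize(b) for b in base]}
        )
    )

    # substrates must be strictly DE everywhere so the stage-4 filter keeps them
    eligible = de_mask.copy()
    for table, x in zip(tables, observed):
        padj = table.records["p_adj"].to_numpy()
        eligible &= (np.abs(x) > 1.0) & (padj < 0.05)
    eligible_idx = np.flatnonzero(eligible)
    if cfg.n_substrates > len(eligible_idx):
        raise ValidationError(
            f"cannot plant {cfg.n_substrates} substrates: only "
            f"{len(eligible_idx)} genes are DE in every dataset"
        )
    chosen = _rng(cfg.seed, "substrates").choice(
        eligible_idx, size=cfg.n_substrates, replace=False
    )
    truth = SimTruth(
        de_genes=frozenset(np.array(base)[de_mask]),
        substrate_genes=frozenset(np.array(base)[np.sort(chosen)]),
        latent_effects=theta,
        seed_used=cfg.seed,
        id_aliases=aliases,
    )
    return tables, omap, truth


def simulate_proteome(
    transcriptome: DiffTable, cfg: SimConfig, truth: SimTruth
) -> DiffTable:
    """Derive a protein-layer table from a simulated transcriptome.

    Non-substrates follow y = slope * x + Normal(0, noise_sd^2); substrate
    proteins are additionally shifted down by delta_shift * noise_sd.
    """
    ids = list(transcriptome.records["feature_id"])
    unknown = [i for i in ids if i not in truth.id_aliases]
    if unknown:
        raise ValidationError(
            f"transcriptome ids not generated by this truth (first few): {unknown[:5]}"
        )
    x = transcriptome.records["log2fc"].to_numpy(dtype=float)
    rng = _rng(cfg.seed, f"proteome:{transcriptome.dataset_label}")
    y = cfg.mrna_prot_slope * x + rng.normal(0.0, cfg.mrna_prot_noise_sd, len(x))
    substrate_local = {
        local for local, base in truth.id_aliases.items()
        if base in truth.substrate_genes
    }
    is_substrate = np.array([i in substrate_local for i in ids])
    y = y - is_substrate * cfg.delta_shift * cfg.mrna_prot_noise_sd
    return _normal_test_table(
        ids, y, cfg.mrna_prot_noise_sd,
        f"{transcriptome.dataset_label}_prot", "protein",
    )


def simulate_gene_sets(cfg: SimConfig, truth: SimTruth) -> GeneSetCollection:
    """Random gene sets over the base namespace plus one designated term
    covering every planted substrate (recorded in ``truth.enriched_term_ids``)."""
    if cfg.n_terms < 1:
        raise ValidationError("n_terms must be >= 1 (the screen needs gene sets)")
    base = np.array(_base_ids(cfg.n_genes))
    rng = _rng(cfg.seed, "genesets")
    lo, hi = cfg.term_size_range
    width = max(4, len(str(cfg.n_terms)))
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for t in range(cfg.n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(base, size=size, replace=False)
        sets[f"T{t:0{width}d}"] = ("random synthetic term", frozenset(members))

    substrates = sorted(truth.substrate_genes)
    n_fill = max(int(rng.integers(lo, hi + 1)) - len(substrates), min(5, cfg.n_genes - len(substrates)))
    non_substrates = np.array(sorted(set(base) - set(substrates)))
    fillers = rng.choice(non_substrates, size=min(n_fill, len(non_substrates)), replace=False)
    designated = f"T{cfg.n_terms:0{width}d}"
    sets[designated] = (
        "planted discordant-protein term",
        frozenset(substrates) | frozenset(fillers),
    )
    truth.enriched_term_ids = frozenset({designated})
    return GeneSetCollection(sets=sets)


def simulate_correlated_tables(
    rhos: tuple[float, ...], n: int, seed: int = 0, label_prefix: str = "sim"
) -> tuple[DiffTable, list[DiffTable]]:
    """Reference table plus one table per requested population correlation.

    Each table shares the reference id namespace; fold changes are bivariate
    normal with the planted correlation against the reference vector.
    """
    for rho in rhos:
        if not (-1.0 < rho < 1.0):
            raise ValidationError(f"planted correlation must be in (-1, 1), got {rho}")
    ids = _base_ids(n)
    rng = _rng(seed, "correlated")
    ref = rng.normal(0.0, 1.0, n)
    reference = _normal_test_table(ids, ref, 1.0, f"{label_prefix}_ref", "mrna")
    tables = []
    for i, rho in enumerate(rhos):
        noise = rng.normal(0.0, 1.0, n)
        x = rho * ref + np.sqrt(1.0 - rho * rho) * noise
        tables.append(_normal_test_table(ids, x, 1.0, f"{label_prefix}_{i}", "mrna"))
    return reference, tables
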