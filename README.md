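# deconcord

Cross-dataset differential-expression (DE) concordance analysis and a
transcriptome–proteome discordance screen for nominating candidate
protease substrates, exercised end-to-end on synthetic data with planted
ground truth.

The package consumes DE *summary* tables (feature id, log2 fold change,
raw and adjusted P) — it does not align reads or fit DE models. It
provides:

- **tables_io** — TSV DE tables, 2-column ortholog maps, GMT gene sets,
  deterministic report writing (byte-identical reruns, full float
  precision).
- **orthology** — aligning two tables into paired fold-change vectors,
  either through an ortholog map (cross-species, one-to-one resolution by
  default) or by shared feature ids (mRNA vs protein of one study).
- **concordance** — Pearson correlation (two-sided t test, n−2 df),
  Fisher r-to-z comparison of two correlations, DEG classification
  (strict `|log2FC| > cut`, `p_adj < cut`), Venn overlap counts, gene-set
  restricted correlations, and an all-vs-reference concordance matrix.
- **enrichment** — hypergeometric over-representation with either the
  plain one-tailed Fisher tail or the conservative variant computed at
  overlap k−1 ("ease" mode, the default), Bonferroni-corrected over the
  tested terms.
- **substrate_screen** — the 4-stage screen: (1) standardized OLS
  residuals of protein-on-mRNA fold-change regression beyond ±cut with
  consistent sign in the reference *and* a comparison dataset,
  (2) intersection across comparisons, (3) per-direction gene-set
  enrichment filter, (4) expression-statistics thresholds. The funnel is
  monotone by construction and all thresholds are echoed into outputs.
- **synthetic_data** — summary-level simulator: shared latent disease
  program across datasets, per-dataset noise, Benjamini–Hochberg adjusted
  P values, a linear mRNA→protein layer with planted "substrate" genes
  shifted below the regression prediction, and gene sets containing a
  designated term covering the substrates.
- **cli** — `deconcord` entry point with `simulate`, `concordance`,
  `enrich` and `screen` subcommands.

## CLI usage

Generate a synthetic benchmark (seed fully determines every byte of
output):

```sh
deconcord simulate --seed 1 --out sim/
```

This writes `mouse_mrna.tsv`, `mouse_protein.tsv`, `human_1_mrna.tsv`,
`human_1_protein.tsv`, `orthologs.tsv`, `gene_sets.gmt`, `truth.tsv`
(planted DE genes and substrates) and `run_manifest.json`. Simulator
parameters can be given as YAML via `--config` (keys = `SimConfig`
fields: `n_genes`, `pi_de`, `tau_effect`, `sigma_dataset`,
`mrna_prot_slope`, `mrna_prot_noise_sd`, `n_substrates`, `delta_shift`,
`n_terms`, `term_size_range`, `seed`); command-line flags win over the
config file.

Run the substrate screen (first `--mrna/--protein` pair is the reference
dataset; the ortholog map translates reference ids to the other
datasets):

```sh
deconcord screen \
  --mrna sim/mouse_mrna.tsv   --protein sim/mouse_protein.tsv \
  --mrna sim/human_1_mrna.tsv --protein sim/human_1_protein.tsv \
  --orthologs sim/orthologs.tsv --gene-sets sim/gene_sets.gmt \
  --out screen/
```

Outputs: `screen_result.tsv` (full funnel with per-stage flags),
`candidates_final.tsv`, `enrichment_stage3.tsv`, `fits.tsv`. Stage-4
criteria (`mrna_padj_max`, `mrna_lfc_min_abs`, `prot_padj_max`) can be
overridden with `--stage4-config criteria.yaml`.

Correlate tables against a reference and compare the correlations:

```sh
deconcord concordance --reference sim/human_1_mrna.tsv \
  --table sim/mouse_mrna.tsv --table sim/mouse_protein.tsv \
  --orthologs sim/orthologs.tsv --out conc/
```

Gene-set over-representation on id lists:

```sh
deconcord enrich --query up_ids.txt --background all_ids.txt \
  --gene-sets sets.gmt --mode ease --alpha 0.05 --out enrichment.tsv
```

Exit codes: 0 success, 2 validation/configuration error, 1 unexpected
failure. All result files start with `#`-prefixed header lines echoing
the thresholds used.

## File formats

- DE tables: TSV with header `feature_id  log2fc  p_raw  p_adj`
  (remappable via `read_diff_table(column_spec=...)`). Rows with
  missing/non-finite log2fc are dropped with a logged count; ids are
  case-sensitive.
- Ortholog map: TSV with header `source_id  target_id`.
- Gene sets: standard GMT (`term<TAB>description<TAB>member...`).

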