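# discoloc

A Python toolkit for dissecting genetic association signals that have
**discordant effects on two traits** — e.g. an allele that protects against
one disease while raising a correlated risk factor. It implements, as a
tested and reusable package over summary statistics:

* **I/O and harmonization** — GWAS/QTL summary-stat TSVs, BED chromatin-state
  annotations, plain-text LD matrices; cross-study allele alignment with
  strand-ambiguity handling (`discoloc.io_formats`).
* **Synthetic data** — LD, paired-trait z-scores drawn MVN(Rλ, R) under
  explicit colocalization hypotheses (H0–H4, concordant/discordant), QTL
  stats, annotation maps with planted enrichment, and expression /
  time-course matrices, all with ground-truth labels (`discoloc.simulate`).
* **Colocalization** — Wakefield log-ABFs, the five-hypothesis posterior
  decomposition with per-variant shared-causal posteriors and credible
  sets, a simplified all-traits-shared multi-trait posterior, and a
  two-of-three consensus rule (`discoloc.coloc`).
* **Fine-mapping** — sum-of-single-effects regression on (z, R) with
  empirical-Bayes effect priors, purity-filtered credible sets and a
  prior-variance sensitivity scan (`discoloc.finemap`).
* **Discordance** — ±500 kb analysis windows with rare-variant exclusion
  and window merging, per-variant discordance labels (opposite z signs,
  both p < 1e-5), greedy LD clumping (r² > 0.5) into signals, and a
  PheWAS-style lookup over local summary-stat files
  (`discoloc.discordance`).
* **QTL integration** — ABF colocalization (pass at PPH4 > 0.50) and the
  SMR chi-square statistic with BH FDR at 5%, reconciled into
  candidate-causal / horizontal-pleiotropy / locus-level categories, plus
  an eGene catalog (`discoloc.qtl`).
* **Enrichment & tissue-of-action** — one-causal-per-locus annotation
  enrichment over colocalization Bayes factors, and TOA scoring of
  credible sets with the 0.20 / 0.10 classification rule (`discoloc.toa`).
* **Expression statistics** — biweight midcorrelation screens with FDR
  control and likelihood-ratio tests of dynamic expression over a time
  course (`discoloc.exprstats`).
* **Pipeline** — a single-config, single-seed orchestration of all stages
  with TSV outputs and an auditable JSON run manifest
  (`discoloc.pipeline`).

## Tests

```bash
python -m pytest tests/            # unit + property + acceptance suites
```

`tests/test_acceptance.py` holds the desk-scale acceptance criteria
(oracle equivalence against quadrature and brute-force enumeration,
calibration, coverage, recall/precision, type-I error, parameter
recovery, determinism). The full run takes a few minutes on one CPU.

## CLI

Every stage is a subcommand of `discoloc`:

```bash
discoloc simulate  --config scenario.yaml --out sim_out --seed 1
discoloc coloc     --trait-a a.tsv --trait-b b.tsv --p12 5e-6 --threshold 0.70
discoloc discord   --trait-a a.tsv --trait-b b.tsv --ld ld.txt
discoloc finemap   --z z.tsv --ld ld.txt -L 5 --coverage 0.95 --purity 0.5
discoloc qtl-coloc --gwas gwas.tsv --qtl-dir qtls/ --pph4-thresh 0.50
discoloc phewas    --variant rs123 --study s1.tsv --study s2.tsv
discoloc expr-corr --expr expr.tsv --pheno pheno.tsv --fdr 0.05
discoloc adipo-lrt --expr tc.tsv --design design.tsv
discoloc pipeline  --config config.yaml --out run_out
```

Summary statistics are whitespace/tab-delimited with canonical columns
`SNP CHR POS EA NEA EAF BETA SE P N` (arbitrary names via a
`column_map`); LD matrices are whitespace-delimited square matrices with
a variant-id header row; annotations are standard BED with
tissue/state declared per file.

A minimal pipeline config:

```yaml
seed: 1
simulate:
  n_loci: 20
  mix: {H0: 0.3, H1: 0.1, H2: 0.1, H3: 0.1, H4: 0.2, H4_discordant: 0.2}
  p: 100
  decay: 0.9
  lam: 7.0
thresholds:          # all optional; defaults shown in discoloc.pipeline
  sig_p: 5.0e-8
  regional: 0.70
  discord_p: 1.0e-5
```

Outputs land in `windows/`, `coloc/`, `signals/`, `finemap/`, `qtl/`,
`toa/`, `expression/` plus `manifest.json`; reruns with the same config
and seed are byte-identical.

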