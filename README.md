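# azenet

A tested, reusable pipeline for two-condition transcriptome network
analysis and its companion measurements:

- **Differential expression** — median-of-ratios size factors, log2
  transform, a Welch-t/Benjamini–Hochberg stand-in caller (adjusted
  p < 0.05 and |log2 fold-change| ≥ 0.5), and per-pathway DE-fraction
  summaries with a direction sign.
- **Regulator impact scoring** — two differential-coexpression metrics per
  transcription factor against the DE gene set, z-standardized across
  regulators, flagged at |z| ≥ 1.96.
- **PCIT network pruning** — triad-wise partial-correlation elimination
  with an average |partial/direct| tolerance, an |r| ≥ 0.95 edge filter,
  degree centrality, hub first-neighbor subnetworks, and GraphML/SIF
  export for Cytoscape.
- **Isotope tracer model** — δ(¹³C) ↔ ¹³C atom-fraction conversion (VPDB,
  R = 0.0111802), a two-pool mixing model for the tracer-derived carbon
  fraction, and origin-constrained per-cell uptake-rate fits.
- **Community statistics** — observed/Chao1/Shannon/Simpson alpha
  diversity, Bray–Curtis distances, PCoA, one-factor PERMANOVA
  (seeded or exact-enumeration permutations), rank-sum tests, a
  differential-abundance stand-in, and per-ASV taxon-proportion ratios.
- **Synthetic data generators** — seeded negative-binomial expression
  matrices with planted "rewired" hub regulators, tracer enrichment
  curves with known uptake rate, and Dirichlet-multinomial ASV tables
  with planted family enrichment — each returning machine-readable ground
  truth for closed-loop testing.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence for PCIT, planted-signal recovery, null calibration,
closed-form checks, byte-level determinism); the other files are
per-module unit and property tests.

## CLI

All workflows are driven by a YAML config and write a `manifest.json`
echoing the resolved configuration:

```sh
azenet simulate      --config cfg.yaml --out outdir [--seed N]
azenet transcriptome --config cfg.yaml --out outdir
azenet tracer        --config cfg.yaml --out outdir
azenet mesocosm      --config cfg.yaml --out outdir
```

Example transcriptome config:

```yaml
seed: 1
inputs:
  counts: expression/counts.tsv        # genes x samples, first column = gene id
  conditions: expression/conditions.tsv  # sample <TAB> condition (1 or 2)
  tfs: expression/tfs.txt              # one gene id per line
  pathways: expression/pathways.tsv    # gene <TAB> pathway_id (long format)
padj_cut: 0.05
lfc_cut: 0.5
rif_z: 1.96
r_cut: 0.95
```

`azenet simulate` emits ready-to-run input sets (with `truth.json`
sidecars) for all three analysis workflows. Exit codes: 0 success,
2 validation error, 3 runtime error.

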