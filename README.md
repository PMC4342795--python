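# dgeprof

Tag-based digital gene expression (DGE) profiling pipeline for time-course
experiments on species with two merged progenitor genomes.

The pipeline covers:

- **`dgeprof.synthetic`** — ground-truthed simulator: paired "A"/"D" genomes
  with controllable homeolog divergence inside the tag region, per-gene
  trajectory patterns (down / up / peak / flat) across six time points, and
  multinomially sampled tag libraries with a per-base sequencing error model.
- **`dgeprof.taglib`** — virtual reference tag library: every `CATG` + 17 nt
  tag from the sense strand of each CDS, merged across the two genomes with
  A-genome priority and a 1-mismatch redundancy rule.
- **`dgeprof.mapping`** — observed-tag assignment with at most one mismatch,
  gene-level ambiguity filtering, per-gene unambiguous counting and TPM
  (tags per million clean tags) normalization.
- **`dgeprof.de`** — exact two-library count test (Audic–Claverie style),
  Benjamini–Hochberg FDR, fold-change and raw-count filters
  (defaults: FDR ≤ 0.001, |log2 ratio| ≥ 2, max raw ≥ 10), pairwise
  comparisons over all library pairs and the union DEG set.
- **`dgeprof.cluster`** — seeded k-means (default k = 42) and average-linkage
  hierarchical clustering of DEG profiles; cluster typing into
  down-trending (`type_I`), up-trending (`type_II`) and `complex` shapes.
- **`dgeprof.enrich`** — annotation-set over-representation (GMT-style
  term → gene tables) with one-sided hypergeometric tests and per-namespace
  BH correction, plus per-term up/down/complex direction summaries.
- **`dgeprof.qpcr`** — comparative 2^−ΔΔCt quantification from Ct tables and
  gene-wise Pearson correlation against the TPM profiles.
- **`dgeprof.pipeline` / `dgeprof.cli`** — orchestration with YAML config,
  provenance-stamped TSV outputs and a checksummed run manifest.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (statistic and FDR
oracles, quadratic merge oracle, mapping truth recovery, DE calibration and
power, clustering recovery, hypergeometric exactness, qPCR checks, and an
end-to-end byte-reproducibility smoke test).

## CLI

Everything is reachable through one executable:

```bash
# full synthetic run from a config file
dgeprof run-all --config config.yaml

# or stage by stage
dgeprof simulate --out run/ --seed 1 --genes 2000 --library-size 100000
dgeprof build-lib --genome-a run/genome_A.fasta --genome-d run/genome_D.fasta \
    --out run/library.tsv
dgeprof map --library run/library.tsv \
    --tags 15d run/tags_15d.tsv --tags 25d run/tags_25d.tsv \
    --out run/matrix.tsv
dgeprof de --matrix run/matrix.tsv --timepoints 15d,25d \
    --out-prefix run/de --fdr 0.001 --log2 2 --min-raw 10
```

A minimal `config.yaml`:

```yaml
outdir: run
seed: 1
synthetic:
  n_genes_a: 2000
  n_genes_d: 2000
  homeolog_fraction: 0.5
  divergence: 1
  library_size: 100000
  error_rate: 0.01
```

Outputs are TSVs with a `#`-comment provenance header; `manifest.json`
records per-stage checksums and wall clock.  Identical config + seed gives
byte-identical analysis outputs.

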