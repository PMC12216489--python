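# dmscreen

Analysis toolkit for deep-mutational-scanning (DMS) selection screens of the
kind used to engineer spacer-acquisition proteins: a codon-mutant library is
subjected to a survival selection, the selected and unselected populations are
sequenced with barcoded subamplicons, and per-site amino-acid preferences,
wild-type-relative differential selection, Shannon entropy and a composite
gain-of-function site score are computed to nominate candidate substitutions.
Validation-assay statistics (plating-rate fold changes with Welch tests,
phage-immunity folds, growth-competition analysis) are included, together with
a synthetic-data generator that plants known fitness effects so every stage of
the pipeline can be tested against ground truth without external data.

## Modules

| module | contents |
| --- | --- |
| `dmscreen.synthetic_data` | clone libraries (Poisson mutation load), selection screens with planted per-substitution multipliers, barcoded subamplicon reads with per-base errors, plating / phage-survival / competition simulations |
| `dmscreen.read_processing` | barcode grouping, strict-majority consensus (generic and vectorized routes), codon counting, library QC (load histogram, Poisson GOF, positional uniformity) |
| `dmscreen.dms_core` | RPM normalization, amino-acid aggregation, enrichment ratios, preferences, log2 differential selection, replicate aggregation and Pearson correlation |
| `dmscreen.site_scoring` | Shannon entropy, per-site diffsel summaries, per-protein min-max scaling, composite score, top-substitution ranking |
| `dmscreen.assay_stats` | CFU/dilution rate estimation, Welch t-tests, fold changes, phage-immunity folds, competition-ratio tests |
| `dmscreen.pipeline`, `dmscreen.cli` | end-to-end runner, declarative YAML/JSON config, run manifests, report rendering |

## CLI

```bash
dmscreen run-all --config config.yaml --out rundir
dmscreen report --run rundir
```

Example `config.yaml`:

```yaml
seed: 7
preset: {name: cas2-like, n_clones: 3000}
screen: {base_rate: 0.01, n_cells: 600000, reads_per_barcode: 2, seq_error_rate: 0.001}
depth: 8000            # sequencing molecules per segment and sample
n_replicates: 2
top_k: 8
effects:
  - {position: 20, aa: L, multiplier: 15.0}
assays:
  phage: {variants: [MYT-phage]}
```

Individual stages are exposed as `simulate-library`, `simulate-screen`,
`process-reads`, `dms-stats`, `score-sites`, `assay` and work on plain-text
FASTQ/FASTA/TSV files; `run-all` writes every table plus a `manifest.json`
recording config, derived stage seeds and read-conservation statistics.
Reruns with the same config are byte-identical. Exit codes: 0 success,
1 usage error, 2 data error.

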