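# chipdeg

Predict differentially expressed genes (DEGs) from histone-modification
ChIP-seq features. The pipeline quantifies normalized read signal over named
gene-anatomy segments (TSS1500, TSS200, TSS+200, TTS200, UTRs, exon/intron
anatomy, full transcript/gene), adds peak-derived gene features (peak count,
size, fold enrichment, distance) and differential-peak (M-value) features,
selects informative features (InfoGain / ReliefF / CFS), trains probabilistic
classifiers with stratified cross-validation, and selects candidate genes by
probability ranking with a cumulative-precision cutoff over fixed-size bins.

A synthetic-data generator plants mark-to-expression associations so the whole
pipeline is testable end-to-end without external data.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (split arithmetic,
top-fraction feature counts, oracle checks for InfoGain / ROC-AUC / metrics,
parameter recovery on synthetic data, and the end-to-end pipeline smoke).

## CLI

```bash
# generate a synthetic bundle (annotation, reads, peaks, expression, truth,
# plus a ready-to-run pipeline.yaml)
chipdeg simulate --out sim/ --n-genes 500 --seed 42

# run the full pipeline on it
chipdeg run --config sim/pipeline.yaml --out run/

# individual stages
chipdeg segments --annotation sim/annotation.gff3 --out segments.bed
chipdeg features --config sim/pipeline.yaml --out features.tsv
chipdeg label    --expression sim/expression_C.tsv --out labels.tsv
chipdeg train    --features run/features.tsv --labels run/labels.tsv \
                 --selector infogain --top-frac 0.05 --classifier logistic
chipdeg predict  --probabilities probs.tsv --labels labels.tsv \
                 --bin 200 --precision 0.95 --out ranked.tsv
chipdeg peaks    --peaks a.narrowPeak --annotation sim/annotation.bed12 \
                 --label CK9A --out peakfeat.tsv
```

The `run` output directory contains `features.tsv`, `labels.tsv`,
`predictions.tsv`, `precision_curve.tsv`, `report.json`, `provenance.json`
(config hash + seed + version) and `pipeline.log`. Reruns with identical
config and seed reproduce identical outputs.

Default thresholds: DEG fold change > 1.5 with RPKM > 1,
peak-to-gene distance ≤ 5 kb, differential peaks at |M| ≥ 0.4 and p ≤ 0.05,
80/20 stratified split, 10-fold CV, top-5% features, top-60% expressed
candidate pool, 200-gene bins and a 0.95 cumulative-precision cutoff.

## Layout

- `src/chipdeg/segments.py` — gene models and gene-anatomy segments
- `src/chipdeg/signal.py` — densities over segments, diff/log2FC, feature matrix
- `src/chipdeg/peaks.py` — peak assignment, per-gene peak features, M-value
  differential peaks
- `src/chipdeg/labels.py` — DEG labels, replicate correlation, candidate pools
- `src/chipdeg/ml/` — MDL discretization, InfoGain/ReliefF/CFS, classifiers,
  splits, cross-validation, metrics, ROC/AUC
- `src/chipdeg/prediction.py` — probability ranking, bin precision, cutoff,
  hypergeometric overlap test
- `src/chipdeg/simulate.py` — synthetic genomes, tracks, peaks, expression
- `src/chipdeg/pipeline.py`, `src/chipdeg/cli.py` — orchestration and CLI
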