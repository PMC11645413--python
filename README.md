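# cistromere

ARE-centric cistrome analysis toolkit: quantify canonical androgen
response element (ARE) content of AR ChIP-seq peak sets, profile motif
density and enhancer signal around peaks, segment chromatin states with
a Bernoulli-emission HMM, derive and score ARE-activation/repression
gene signatures, and associate signature scores with survival. A
synthetic-data module generates every input the pipeline consumes with
planted, recoverable ground truth, so the whole stack can be exercised
end-to-end without external datasets.

## Modules

| module | contents |
|---|---|
| `cistromere.intervals` | 0-based half-open genomic intervals, BED I/O, overlap / subtract / consensus algebra, peak-context annotation |
| `cistromere.motifs` | JASPAR-style PWM model, both-strand log-odds scanning with an FPR-calibrated threshold, fraction-with-motif statistics, density and differential-density profiles, background-matched enrichment |
| `cistromere.signal` | bedGraph tracks, RPKM normalization, anchored signal matrices, aggregate profiles, sample PCA over consensus regions |
| `cistromere.chromstates` | mark binarization, Baum–Welch EM for a multi-track Bernoulli HMM, Viterbi/posterior decoding, E1..EK state ordering with a numeric transform |
| `cistromere.signatures` | surrogate differential expression (Welch t + BH), signature derivation, z-score signature scoring, Fisher over-representation, quartile stratification, GMT I/O |
| `cistromere.clinical` | Kaplan–Meier curves, log-rank tests, Cox proportional-hazards fits (lifelines), Kruskal–Wallis, Spearman correlation with exact small-n permutation p |
| `cistromere.synthetic` | deterministic generators: genomes, peak sets with planted ARE fractions, matched tumor/normal cohorts, mark tracks from a known state model, expression cohorts, proportional-hazards survival times |
| `cistromere.cli` | `cistromere` command-line interface and the `run-all` pipeline with a JSON manifest |

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact-test
enumeration oracles, exhaustive scan and Fisher oracles, per-base
interval-algebra oracles, HMM parameter recovery at 50k bins, Cox
coverage and log-rank type-I simulations). The remaining files are unit
and property tests per module, including hypothesis-based invariants.

## CLI

```bash
# full synthetic demonstration pipeline (deterministic per seed)
cistromere run-all --out runs/demo --seed 1

# individual stages
cistromere simulate --out runs/inputs --seed 1
cistromere motif-fraction --genome g.fa --bed peaks.bed --out frac.tsv
cistromere density --genome g.fa --bed a.bed --compare b.bed --smooth --out dens.tsv
cistromere consensus --bed s1.bed --bed s2.bed --bed s3.bed --out consensus.bed
cistromere signal-profile --bedgraph t.bedgraph --bed peaks.bed --out prof.tsv
cistromere pca --bedgraph s1.bedgraph --bedgraph s2.bedgraph --regions c.bed --out pca.tsv
cistromere chromstate fit --mark H3K4me1=k4me1.bed --mark H3K27me3=k27me3.bed \
    --chrom-sizes sizes.tsv --states 6 --out model.json
cistromere score --expr expr.tsv --gmt signatures.gmt --out scores.tsv
cistromere survival --clinical clinical.tsv --covariates score_z --out surv.json
```

`run-all` writes a `manifest.json` recording the package version, seed,
all parameters and SHA-256 checksums of every output; reruns with the
same seed are byte-identical.

## Conventions and defaults

- Coordinates are 0-based half-open (BED) everywhere; 1-based inputs
  (GFF3) are converted at the boundary. Strand is carried but ignored by
  overlap math.
- Motif presence uses a 100 bp total window centered on the peak
  center; density profiles use a 2,400 bp window binned every 10 bp
  (both configurable). Motif-enrichment significance cutoff is
  p <= 1e-20.
- The default scan threshold is the log-odds score whose per-position
  background false-positive rate is 1e-4, computed from the exact
  discretized score distribution.
- Signature scores are sums of gene-wise z-scores (sample sd, n-1)
  computed within the scored cohort; up-genes minus down-genes.
- Chromatin states are ordered E1..EK by active-minus-repressive
  emission mass; the numeric transform assigns 1..K in that order.
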