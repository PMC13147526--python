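# poolscan

Pool-seq case-control power simulation and known-founder haplotype-imputation
genome scans.

Pooled sequencing estimates population allele frequencies from read counts,
so the error on a directly ascertained SNP frequency scales with sequence
coverage (`sqrt(pq/C)`), not with the number of pooled individuals.  In
case-control scans at realistic coverages this noise can swamp real
frequency shifts of a few percent, producing Manhattan plots that look
"polygenic" when the architecture is simple.  In populations descended from
a known set of founders, founder-haplotype frequencies can instead be
estimated by constrained least squares in sliding genetic-map windows, and
SNP frequencies imputed from them, with errors closer to the binomial limit
of the pool size — recovering localized association peaks that the direct
scan misses.

This package provides the complete simulation and analysis machinery to
demonstrate that mechanism:

- **`poolscan.data`** — core types (founder panels, pool counts, genetic
  maps, scan tables) and plain-text I/O (counts TSV, founder TSV, map TSV,
  popoolation2-style SYNC).
- **`poolscan.neutral`** — neutral coalescent haplotype panels (msprime)
  with MAF filtering and thinning.
- **`poolscan.powersim`** — case/control pools of haplotypes differing only
  at one focal SNP, overdispersed pool-seq counts (negative binomial
  coverage with variance twice the mean), per-SNP chi-square scans, and a
  coverage x effect-size power sweep.
- **`poolscan.xqtl`** — a synthetic known-founder advanced-intercross
  population: Poisson-breakpoint mosaic genomes, a planted additive QTL on
  a liability scale, truncation-selected case pools, replicate structure,
  and exact truth bookkeeping.
- **`poolscan.haplotypes`** — founder-frequency inference per sliding
  window (`min ||Hf - y||` s.t. `f >= 0`, `sum f = 1`), SNP-frequency
  imputation from the nearest window, and pseudo-counts (`freq x 2N x k`).
- **`poolscan.scans`** — Cochran-Mantel-Haenszel tests (2x2xK and the
  generalized 2xJxK statistic) on read counts or real-valued pseudo-counts,
  Bonferroni thresholds, and scan-comparison summaries (peak localization,
  peak-minus-background gap, cluster score).
- **`poolscan.pipeline` / `poolscan.cli`** — config-driven, seed-stable
  orchestration of the two headline experiments.

## CLI

All commands are deterministic given `--seed`.

```sh
# power sweep: coverage x focal-shift grid, power + false-signal summary
poolscan simulate-fig1 --coverage 400,1000,5000 --delta 0.04,0.08 \
    --pool-size 10000 --replicates 50 --seed 1 --out out/power

# synthetic known-founder selection dataset (counts TSV + SYNC + truth)
poolscan simulate-mpp --seed 1 --out out/mpp

# founder-frequency inference + SNP imputation from a counts table
poolscan infer-haplotypes --counts out/mpp/counts.tsv --meta out/mpp/samples.tsv \
    --founders out/mpp/founders.tsv --map out/mpp/map.tsv --out out/hap

# one of the three scans: direct | haplotype | imputed-snp
poolscan scan --mode direct --counts out/mpp/counts.tsv --meta out/mpp/samples.tsv \
    --founders out/mpp/founders.tsv --map out/mpp/map.tsv --out out/scan_direct.tsv

# localization comparison of several scans around a known QTL
poolscan compare --scans out/scan_direct.tsv --scans out/scan_hap.tsv \
    --qtl sim1:50.0 --window-cm 1.5 --threshold 5 --out out/report.tsv

# full end-to-end experiments from a YAML config
poolscan run-fig1 --seed 1 --out out/fig1
poolscan run-xqtl-compare --seed 1 --out out/xqtl
```

Config files are YAML with two sections (`fig1`, `xqtl`) mirroring
`poolscan.pipeline.Fig1Config` / `XQTLConfig`; unknown keys are hard
errors.  See those dataclasses for all parameters and defaults.

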