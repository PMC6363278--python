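# ladkit

Toolkit for analysing the dynamics of lamina-associated domains (LADs)
between two cellular conditions:

- **synthetic data** — planted LAD architectures realising an exact
  class-transition plan, negative-binomial binned ChIP/input counts,
  bead-on-string 3D structures with class-dependent radial bias, FPKM
  tables with transition-dependent effects, and 2D FISH spot tables.
  Every simulator is seeded and bit-reproducible, so each downstream
  stage has parameter-recovery tests against known ground truth.
- **genome tracks** — per-chromosome depth matching of ChIP/input count
  tracks (exact down-sampling without replacement) and binned
  log2(ChIP/input) ratio tracks, with BED/bedGraph readers and writers.
- **domain caller** — broad-domain calling by maximal-scoring-segment
  search (+1 for enriched bins, −GP for gaps), with auto-estimation of
  the bin size (BS) and gap penalty (GP), and a repeated-run stability
  protocol that reports variable subdomains and fixes final parameters
  to across-run averages.
- **LAD algebra** — partition of the genome into A-B / A-only / B-only /
  inter-LAD classes from two LAD sets, coverage summaries, Jaccard
  indices of base-pair coverage, base-pair fate-transition matrices
  between conditions, and per-class size comparisons (two-way ANOVA +
  Tukey HSD).
- **expression link** — gene-to-class assignment by TSS overlap, a
  stable-expression filter (|ΔFPKM| < 0.05), and per-fate-pair unpaired
  t-tests of expression.
- **radial positioning** — normalized radial distances (d/R, nucleus
  radius 5 µm by default) of LAD classes and probe loci over ensembles
  of bead structures, per-fate-pair repositioning statistics, and 2D
  FISH normalized positions (ray–ellipse geometry) with per-probe
  comparisons.

## Command-line interface

All stages are subcommands of a single `ladkit` entry point and operate
on plain-text formats (BED, bedGraph, TSV, YAML, JSON):

```sh
ladkit simulate  --seed 1 --out-dir sim/            # planted-truth inputs
ladkit tracks    --chip sim/chip_A_control.bedGraph \
                 --input sim/input_A_control.bedGraph \
                 --bin-size 10000 --out ratio_A.bedGraph
ladkit call-lads --track ratio_A.bedGraph --bin-size 10000 \
                 --runs 10 --seed 1 --out lads_A.bed --report stability.json
ladkit classify  --lads-a lads_A.bed --lads-b lads_B.bed \
                 --genome sim/genome.tsv --out-dir classes/
ladkit fate      --ctrl-a ... --ctrl-b ... --trt-a ... --trt-b ... \
                 --genome sim/genome.tsv --out-dir fate/
ladkit expression --expression sim/expression.tsv --alpha 0.01 ...
ladkit radial    --structures-ctrl ... --structures-trt ... ...
ladkit fish      --spots sim/fish_spots.tsv --out fish.tsv
ladkit run-all   --seed 1 --out-dir run/            # everything end-to-end
```

`run-all` executes the full synthetic pipeline (simulate → tracks →
call → classify → fate → expression → radial → FISH) and writes a
versioned machine-readable `summary.json` next to the per-stage tables;
rerunning with the same seed reproduces byte-identical outputs. A YAML
config (see `run-all --config`) can override seeds, the transition plan,
simulation parameters and test thresholds.

## Conventions

Genomic coordinates are 0-based half-open (BED) throughout. The four
class labels are ordered `A-B, A-only, B-only, iLAD`; fate pairs are
numbered 1–16 row-major in that order (control class → treated class).
Normalized radial position is 0 at the nucleus center and 1 at the
periphery.
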