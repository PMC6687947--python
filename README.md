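# ycnv

Toolkit for analysing copy-number variation of multi-copy gene families on
the human Y chromosome. It covers the full analysis chain:

1. **Read-depth copy numbers** (`ycnv.depth`, `ycnv.regions`) — windowed
   depth profiles over a survey interval, depth ratios of the gene-cluster
   regions against a nearby single-copy reference, rough integer copy
   numbers under the read-pooling model (reads mis-map freely among
   near-identical copies, so pooled depth scales with total copy number),
   and an automated flanking-depth constancy flag for sample curation.
2. **Calibration** (`ycnv.calibrate`) — OLS calibration of depth-derived
   values against gold-standard single-molecule (fibre) copy counts, a
   train/test concordance report, and a packaged 14-sample gold-standard
   table.
3. **Phylogenetic event counting** (`ycnv.events`) — tip copy numbers on a
   rooted Newick tree with SNV-count branch lengths; minimum-event
   (unit-cost parsimony) ancestral reconstruction with exact per-node
   ambiguity sets, a clade-modal heuristic for comparison, event
   classification by direction/magnitude/confidence, conservative filters,
   and largest-remainder scaling of confident-event size histograms.
4. **Mutation rates** (`ycnv.rates`) — SNV-clock conversion of branch
   lengths to generations (0.76e-9 /bp/yr over 10.3 Mb, 30-yr generations
   by default), per-transmission copy-number mutation rates with CIs by
   SNV-rate substitution, and exact Clopper–Pearson intervals for
   father–son transmission rates.
5. **Selection tests** (`ycnv.selection`) — exact binomial
   increase/decrease direction-bias test, and a neutral Monte-Carlo null
   that scatters a fixed signed-event set over the tree in proportion to
   branch length, with a variance percentile test for stabilizing
   selection.
6. **ddPCR quantification** (`ycnv.ddpcr`) — Poisson inversion of droplet
   counts to concentrations, target/reference copy-number ratios,
   replicate-concordance rules (third replicate at ≥0.8 copies
   discrepancy) and T+C assay totals.
7. **Synthetic data** (`ycnv.simulate`) — seeded generators for every
   input above (Yule/Kingman trees scaled to a generation budget with
   Poisson SNV counts, copy-number evolution with known event truth,
   pooled-depth profiles, droplet counts, father–son pairs), recording
   ground truth for parameter-recovery tests.
8. **Pipeline + CLI** (`ycnv.pipeline`, `ycnv.cli`) — a config-driven
   end-to-end run with a JSON report, exposed as the `ycnv` command.

## CLI

```bash
ycnv simulate --out sim/ --seed 1 --n-tips 100      # synthetic inputs + truth
ycnv depth --depth-table sim/depth/t1.tsv           # ratios, rough CN, curation flag
ycnv calibrate fit --table gold.tsv --x-col total_fibre_fish --y-col cn_ddpcr
ycnv events --tree sim/tree.nwk --states sim/cn.tsv --min-magnitude 2 --cn-range 5,12
ycnv rate tree --events 562 --snvs 60084
ycnv rate trio --mutations 1 --transmissions 77
ycnv selection direction --inc 77 --dec 99
ycnv selection simulate --tree sim/tree.nwk --replicates 1000 --seed 1 --out vars.tsv
ycnv selection var-test --empirical 1.65 --sim vars.tsv
ycnv ddpcr --in sim/wells.csv
ycnv run --seed 1 --out run/                        # full pipeline, JSON report
```

`ycnv run --show-config` prints every default. Region definitions default
to the GRCh37 chrY coordinates of the four gene clusters, the single-copy
reference interval and the 7 Mb survey window; override with a BED4 file
whose reserved name `REF` marks the reference interval.

## File formats

- Depth tables: TSV, either windowed (`chrom start0 end mean_depth`) or
  per-base (`chrom pos1 depth`); gzip accepted.
- Regions: BED4 (0-based half-open, converted exactly to the 1-based
  inclusive internal convention).
- Trees: rooted Newick, branch lengths in SNV counts; tip states as
  `sample_id<TAB>copy_number`.
- Droplet wells: CSV with `sample_id, assay, replicate, target_positive,
  target_total, ref_positive, ref_total`.
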