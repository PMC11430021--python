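# rloopkit

Strand-aware R-loop calling and annotation from ssDRIP-seq fragment
intervals, plus a synthetic-cohort generator with planted ground truth so
the whole pipeline is testable offline.

The pipeline consumes strand-split aligned fragments (BED6) from
immunoprecipitated (DRIP) replicates and RNase-H-treated controls and
produces:

- **Replicate PCA QC** — per-sample strand-split coverage in fixed-width
  bins (500 bp default), row-standardized, PCA by SVD, and a flag for
  whether DRIP and control samples occupy disjoint PC1 ranges.
- **Peak calling** — sliding-window (200 bp, step 100) Poisson enrichment
  tests against a local background: the maximum of the genome-wide control
  rate and 1/5/10 kb local control rates, rescaled to treatment depth plus
  a pseudocount. Window p-values are BH-adjusted genome-wide; significant
  windows are linked into narrow (q ≤ 0.05) and broad (q ≤ 0.10) peaks.
- **Consensus + classification** — union-merge of qualifying peaks
  (q ≤ 0.001, narrow or broad) supported by ≥ 3 replicates; each consensus
  R-loop is then classified *stranded* (one strand's fragments enriched
  over the other, same support filter, one strand only) or *unstranded*.
- **Annotation** — a priority-resolved feature map
  (promoter [TSS−2.5 kb, TSS+0.5 kb) > exon > intron >
  downstream [end−0.5 kb, end+2.5 kb) > pseudogene > intergenic),
  midpoint assignment, observed/expected enrichment with bootstrap CIs,
  expression-tertile gene overlap tables and gene-length associations.
- **Metaprofiles** — bedGraph signal averaged over fixed windows centered
  on R-loop midpoints, with optional strand orientation.
- **Set statistics** — Fisher-exact overlap enrichment between id lists
  over a fixed universe (log-space hypergeometric tail).

## CLI

```sh
# one-command synthetic demo: simulate -> qc -> call -> classify -> annotate
rloopkit all --seed 1 --outdir out/

# individual stages on real data (config lists samples and reference files)
rloopkit simulate --seed 1 --outdir sim/ [--config sim.yaml]
rloopkit qc       --config cohort.yaml --outdir out/
rloopkit call     --config cohort.yaml --outdir out/
rloopkit classify --config cohort.yaml --outdir out/ [--min-support 3 --qmax 0.001]
rloopkit annotate --config cohort.yaml --rloops out/rloops.bed --outdir out/
rloopkit profile  --track h3k4me3.bedgraph --rloops out/rloops.bed --outdir out/
rloopkit setstats --set1 a.txt --set2 b.txt --universe u.txt --out fisher.tsv
```

A cohort config is YAML:

```yaml
chrom_sizes: genome.chrom.sizes          # two-column TSV
genes: genes.tsv                         # gene_id chrom strand start end biotype expression
blacklist: blacklist.bed                 # optional; overlapping fragments dropped
samples:
  - {id: drip_1, condition: DRIP, path: drip_1.fragments.bed}
  - {id: rnaseh_1, condition: RNASEH, path: rnaseh_1.fragments.bed}
caller: {window: 200, step: 100}         # optional CallerParams overrides
```

All coordinates are 0-based half-open (BED). Fragment strand is mandatory.
Every subcommand writes a `manifest.json` with parameters, version and
input checksums; primary outputs are byte-deterministic under a fixed seed.

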