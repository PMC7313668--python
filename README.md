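# hybridscan

Population-genomic analysis of hybrid yeast cohorts from per-isolate variant
calls and read-depth tracks:

- **Ploidy inference** from the allele-balance distribution at heterozygous
  sites (diploids peak at 0.5; allotriploids — a heterozygous diploid
  subgenome plus a divergent haploid subgenome — peak at 1/3 and 2/3).
- **Loss-of-heterozygosity (LOH) detection**: 50-kb sliding windows with
  25-kb overlap, flagging windows with ≤ 10 het sites, merging them into
  regions and re-estimating heterozygosity with LOH excluded.
- **Diversity statistics**: windowed π, Watterson's θ_w and Tajima's D on
  IUPAC-encoded one-sequence-per-isolate alignments, with coding/noncoding
  partitions.
- **Phylogeny**: average-state (expected-mismatch) distances over the union
  of polymorphic positions and a BioNJ tree with newick output.
- **Copy-number analysis**: median-normalised 1-kb/200-bp depth-ratio
  segmentation with 6-kb scaffold-end exclusion, whole-scaffold aneuploidy
  calls from 20-kb windows, gene copy numbers by the > 50 %-overlap rule,
  subgenome attribution of triploid segments (3:1 / 2:2 / 1:1 / 2:0) from
  allele-balance shifts, and core/accessory classification.
- **Synthetic populations**: a call-level simulator (genotypes, depths,
  quality scores, truth BEDs) generating all of the above structure so the
  whole pipeline is testable without external data.

## CLI

```sh
# generate a synthetic cohort fixture set (FASTA, VCFs, depth TSVs, GFF3, truth BEDs)
hybridscan simulate --config cohort.yaml --outdir fixtures/ --seed 1

# build the BioNJ tree from a directory of single-sample VCFs
hybridscan tree --vcf-dir fixtures/ --ref fixtures/reference.fa --out tree.nwk

# run the full pipeline: filter -> ploidy -> LOH -> diversity -> tree -> CNV -> core/accessory
hybridscan run --config run.yaml
```

A `run.yaml` names the inputs and optional thresholds:

```yaml
reference: fixtures/reference.fa
vcf_dir: fixtures/            # {isolate}.vcf
depth_dir: fixtures/          # {isolate}.depth.tsv (optional; enables CNV stage)
gff: fixtures/genes.gff3
outdir: out/
params:
  min_depth: 10       # calls with coverage < 10x are removed
  min_qual: 25        # calls with quality < 25 are removed
  loh_window: 50000
  loh_step: 25000
  loh_max_het: 10
  diversity_window: 10000
  cnv_window: 1000
  cnv_step: 200
  cnv_edge_exclusion: 6000
  n_clusters: 5
```

Outputs: `report.tsv` / `report.json` (per-isolate ploidy, SNP counts, LOH
summary, CNV summary), `ploidy.tsv`, `diversity.tsv` (per-window, per
cluster), `distances.tsv`, `tree.nwk`, per-isolate `*.loh.bed` and
`*.cnv.bed`, `gene_cn_matrix.tsv`, `core_accessory.tsv`.

## Layout

```
src/hybridscan/
  synthetic_population.py  reference + isolate simulator, fixture writer
  variant_io.py            VCF/GFF3/BED/depth-TSV I/O, call filters, allele balance
  ploidy.py                balance histograms and diploid/triploid classification
  loh.py                   LOH window scan, het rate excluding LOH
  diversity.py             IUPAC alignments, pi / theta_w / Tajima's D windows
  phylo.py                 average-state distances, BioNJ, newick
  cnv.py                   depth-ratio segmentation, aneuploidy, gene CN, subgenomes
  pipeline.py              cohort orchestration, clustering, reports
  benchmarks.py            headline-metric recomputation used by scripts/acceptance.py
```
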