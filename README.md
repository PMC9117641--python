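# strvar

Population-scale short tandem repeat (STR) variability analysis:

- **Genotyping** — per-sample estimated repeat counts (ERC) from read-level
  repeat counts: reads at a locus are sorted by decreasing repeat size and
  the value at the top-25% position is the genotype, requiring at least 8×
  coverage. The high-rank (rather than median) position resists the
  undercount bias of long-read repeat callers.
- **Variability scoring** — the repeat dynamic index (RDI): per-locus
  population standard deviation of ERCs after two-sided nearest-rank
  5%/95% trimming; RDI ranks are normalized to nRDI in [0, 1] and cut into
  five equal-width tiers (vlSTR, lSTR, mSTR, hSTR, vhSTR).
- **Catalog handling** — repeat-unit canonicalization (cyclic rotations ∪
  rotations of the reverse complement), gene assignment within 10 kb,
  region classification (exonic / UTR / intronic proximal-distal /
  upstream / downstream), catalog intersection.
- **Subset profiling** — tier and nRDI-decile composition of named locus
  subsets and catalog strata (motif size, region, canonical unit).
- **Expression & enrichment** — per-tissue rank normalization of a
  genes × tissues matrix, gene-set tissue-preference profiles, and Fisher's
  exact over-representation with Benjamini–Hochberg correction.
- **Simulation** — fully seeded generators for every input (catalog with
  toy gene models, cohort read tables under Poisson depth and
  undercount-biased noise, expression matrices, term tables) with ground
  truth emitted for recovery testing.

All coordinates are 0-based half-open (BED convention); tables are TSV
with `NA` for missing values and transparent gzip by extension.

## CLI

```sh
# generate a complete synthetic bundle (catalog, gene models, reads,
# expression, terms, subsets, plus all ground-truth tables)
strvar simulate --n-loci 500 --n-samples 193 --seed 7 --outdir sim/

# individual stages
strvar genotype --reads sim/reads.tsv --catalog sim/catalog.bed \
    --min-coverage 8 --out genotypes.tsv
strvar score --genotypes genotypes.tsv --min-fraction 0.8 --out variability.tsv
strvar profile --genotypes genotypes.tsv --locus L000001 --mode upper_trim
strvar subsets --variability variability.tsv --subset sim/subsets/high_sigma.tsv \
    --catalog sim/catalog.bed --out summaries.tsv
strvar tissue --expression sim/expr.tsv --genes sim/variable_genes.txt \
    --out tissue_profile.tsv
strvar enrich --genes sim/variable_genes.txt --terms sim/terms.tsv \
    --universe sim/universe.txt --alpha 0.01 --out enrichment.tsv

# full chain from one YAML config (genotype → score → subsets → tissue →
# enrich), writing result tables plus a deterministic manifest.json
strvar report --config run.yaml
```

A report config names the inputs and thresholds (defaults shown):

```yaml
catalog: sim/catalog.bed
reads: sim/reads.tsv
outdir: run/
subsets: [sim/subsets/high_sigma.tsv]
expression: sim/expr.tsv
terms: sim/terms.tsv
genes: sim/variable_genes.txt
universe: sim/universe.txt
min_coverage: 8
erc_quantile: 0.25
trim_low: 0.05
trim_high: 0.95
min_fraction: 0.8
alpha: 0.01
seed: 0
```

## Conventions worth knowing

- **Percentiles** are nearest-rank (ascending 1-based index `ceil(q·n)`),
  returning observed integer repeat sizes. At the upper bound, when `q·n`
  is not an integer the index is capped at `n − 1` so a lone maximum
  outlier is trimmed even at small n. Trimming keeps all values inside
  `[p5, p95]` inclusive, so ties at the bounds are retained. (The source
  prose for the trimming rule is contradictory; the two-sided
  keep-`[p5, p95]` reading is implemented.)
- **RDI** uses divisor N (population SD), not N − 1.
- **nRDI** is `(rank − 1)/(L − 1)` with midranks for ties.
- Tier/decile bins are left-closed; 1.0 belongs to the top bin.
- One ERC per individual (no diploid allele splitting).
- Motif equivalence is strictly rotations ∪ rotations of the reverse
  complement (plain reversal is not included).
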