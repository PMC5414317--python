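# rdnakit

Tools for studying cluster-specific expression of multicopy 45S rRNA genes
from strand-split read counts. The package covers the full analysis chain:

- **iocore** — data model (strand counts, variant calls, filter thresholds,
  genotype segments) and TSV/CSV readers and writers.
- **simpop** — synthetic-data generator: rDNA cluster haplotypes with
  variant compositions over their tandem copies, dominance rule tables,
  crossing designs (inbred panel, F1, F2, multi-founder mosaics), and
  beta-binomial strand-split count noise with optional strand-bias decoys.
- **pilevar** — within-individual variant calling: copy-fraction
  estimation, strand-bias score filtering (cutoff 0.8), 5% frequency floor,
  transcribed-span restriction (positions 300–8009), reference-allele
  flipping, and RNA-level quantification (25-read cutoff, DNA validation).
- **clustermap** — assignment of variants to the chromosome-2 or
  chromosome-4 rDNA cluster by genome-wide linkage scans in founder-mosaic
  populations plus carrier/founder consistency checks; parental-specific
  markers and co-segregation assignment for biparental crosses.
- **rnageno** — F2 genotyping from RNA-seq allele counts: per-SNP calls
  (>90% rule), 10-fold bias filter, 50-SNP window classification (>85%
  rule), segment merging with deterministic breakpoint refinement, and
  genome-wide imputation.
- **exprdom** — RNA:DNA expression ratios, silenced/partial/expressed
  classification, dominance partial orders over haplotypes, and the 3×3
  two-locus genotype-class matrix.
- **qtlscan** — marker-regression QTL mapping: map reduction, single-locus
  and covariate scans with additive/dominance encodings, and
  permutation-based genome-wide thresholds.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the end-to-end property suite (filter
fidelity, estimator recovery, cluster-assignment recovery, genotyping
recovery, permutation calibration, epistasis-pattern reproduction,
dominance-order recovery).

## CLI

Every stage is exposed as a subcommand of `rdnakit`:

```sh
rdnakit simulate --design f2 --n-individuals 100 \
    --dominance two_locus_recessive --seed 1 --out-dir sim/

rdnakit call-variants --sites sim/sites_dna.tsv \
    --reference sim/reference.tsv --out variants.csv

rdnakit assign-clusters --truth sim/truth.json \
    --abundance variants.csv --seed 2 --out clusters.csv

rdnakit genotype-rna --snp-counts sim/snp_counts.tsv --out-prefix geno

rdnakit expression --sites-dna sim/sites_dna.tsv \
    --sites-rna sim/sites_rna.tsv --reference sim/reference.tsv \
    --out expression.csv

rdnakit qtl-scan --genotypes geno_genotypes.tsv --phenotype pheno.csv \
    --n-perm 1000 --seed 3 --out-prefix scan

rdnakit epistasis --genotype-classes classes.csv --proportions props.csv \
    --variant X1234.A.G --out matrix.tsv
```

All randomness is seeded; a fixed seed reproduces output files exactly.
Filter thresholds default to the published values and can be overridden by
flags or a YAML config (`--config`, section `filters`).

## File formats

- Site counts: TSV with columns `sample source position allele fwd rev`
  (1-based positions; deletions encoded `-`, insertions `ins:<seq>`).
- Variant tables: CSV, one column per variant named `X{pos}.{ref}.{alt}`,
  one row per sample with copy fractions.
- Genotype segments: BED-like TSV (`chrom start end state individual`,
  half-open coordinates in the file only).
- Imputed genotypes: TSV of `chrom position` plus one column per individual
  with states `A`/`H`/`B`.
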