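# popsweep

Population-genetics toolkit for two-population selective-sweep screening and
trait association on diploid biallelic SNP data. It covers the full desk-scale
analysis chain:

- **simdata** — two-population Balding–Nichols simulator (genotypes with
  planted sweep regions and an additive causal SNP, phenotypes, reference
  FASTA, GFF3 gene models, truth file)
- **variants** — VCF input/output and SNP quality control (site quality,
  read support, MAF, missingness; first-failing-rule accounting)
- **annotate** — functional classification of SNPs against gene models
  (exonic with coding consequence, splicing, intronic, strand-aware 1 kb
  flanks, intergenic) and summary tables
- **structure** — genotype p-distance, Saitou–Nei neighbor joining with
  bootstrap support, EIGENSTRAT-style standardization and PCA
- **sweep** — sliding-window Weir–Cockerham Fst and per-bp θπ, Fst binning,
  joint top-quantile selection screen, window→gene annotation
- **gwas** — mixed-linear-model association with a centered kinship matrix
  (REML profile over the variance ratio, per-SNP Wald tests, Bonferroni
  threshold, genomic-control lambda)
- **markers** — per-locus statistics (PIC, homozygosity, heterozygosity,
  effective alleles, HWE chi-square) and one-way genotype–phenotype
  association with LSD / Dunnett-T3 comparisons and letter display
- **rflp** — in-silico PCR-RFLP design (IUPAC motif scanning, fragment
  patterns per genotype, enzyme usability)
- **enrich** — hypergeometric term overrepresentation from GMT flat files
- **pipeline** — end-to-end orchestration from one YAML config with a
  checksummed run manifest

## Test

```sh
python -m pytest -q
```

The suite includes unit tests per module, property-based invariant tests,
independent brute-force oracles for the estimators, and
`tests/test_acceptance.py` with the acceptance criteria (printed-value
reproduction plus recovery/calibration properties).

## Command line

Every stage is a subcommand of `popsweep`:

```sh
popsweep sim --out simdir --seed 1
popsweep filter --vcf simdir/genotypes.vcf --out filtered.vcf
popsweep annotate --vcf filtered.vcf --gff simdir/genes.gff3 \
    --fasta simdir/reference.fa --out anno
popsweep structure --vcf filtered.vcf --out struct --boot 1000 --seed 1
popsweep sweep --vcf filtered.vcf --pops pops.tsv --gff simdir/genes.gff3 \
    --out sweep --quantile 0.95 --pi-mode ratio
popsweep gwas --vcf filtered.vcf --pheno simdir/phenotypes.tsv --out assoc
popsweep markers --calls calls.tsv --pheno simdir/phenotypes.tsv --out mk
popsweep rflp --amplicons amps.fa --enzymes enzymes.tsv --out rflp.tsv
popsweep enrich --genes genes.txt --gmt sets.gmt --out enrich.tsv
popsweep pipeline --config run.yaml
```

A minimal pipeline config:

```yaml
seed: 1
out_dir: run1
sim:
  n_tall: 15
  n_short: 15
structure:
  n_boot: 100
sweep:
  quantile: 0.95
  pi_mode: ratio
```

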