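# grainqtl

Grain-quality trait analysis for inbred rice panels: in-vitro starch
hydrolysis kinetics (resistant starch percent and predicted glycemic
index), mixed-linear-model GWAS with kinship correction and multi-locus
LOD confirmation, favorable-allele effect estimation, and gene-level
haplotype–phenotype (haplo-pheno) analysis with Duncan's multiple range
test. A synthetic-data module generates structured panels with planted
QTLs and full ground truth, so every stage is testable offline.

## Modules

| module               | what it does |
|----------------------|--------------|
| `grainqtl.simulate`  | Structured inbred genotypes (Balding–Nichols subpopulation model), phenotypes with planted QTLs and kinship-structured polygenic background, hydrolysis time-courses, GOPOD read-outs, toy gene models; writes VCF / HapMap TSV / CSV / GFF3 / truth JSON. |
| `grainqtl.kinetics`  | First-order hydrolysis model `C(t) = Cα(1−e^(−kt))`, closed-form AUC, hydrolysis index vs a white-bread reference, `PGI = 39.7 + 0.548·HI`, GI banding, and resistant-starch percent from GOPOD absorbances (glucose × 0.9 conversion). |
| `grainqtl.traits`    | Kernel ratios (LBR = KL/KB, LER = KLAC/KL), gel-consistency bands (soft ≥ 61 mm, medium 41–60, hard < 41), descriptive statistics, pairwise-complete Pearson correlations with significance stars. |
| `grainqtl.genio`     | Genotype IO (VCF via cyvcf2, HapMap-like TSV), GFF3 gene models (gffutils), SNP QC: alt-allele frequency ≥ 0.01 and per-SNP missingness ≤ 0.2. |
| `grainqtl.gwas`      | VanRaden kinship, PC structure covariates, EMMA-style REML null model, per-marker GLS scan with variance components fixed from the null, suggestive MTAs at −log10 p > 5, forward-selection multi-locus LOD (> 3) confirmation, per-allele effects `a_i` with favorable-allele calls, candidate-gene assignment. |
| `grainqtl.haplo`     | Exact-pattern gene haplotype calling from nonsynonymous exonic variants, frequencies, one-way ANOVA + Duncan's multiple range test (harmonic-mean n for unequal groups), superior-haplotype selection per trait direction. |
| `grainqtl.cli`       | `grainqtl simulate | phenotype | gwas | haplopheno | all` with YAML config, overrides and a JSON run manifest. |

## CLI

```sh
# simulate a 150-accession, 8-subpopulation panel with a planted RS QTL
grainqtl simulate --seed 1 --outdir run1 --config config.yaml

# PGI/RS phenotypes from raw hydrolysis curves (reference row flagged)
grainqtl phenotype --curves curves.csv --outdir run1

# MLM scan + LOD confirmation + allele effects
grainqtl gwas --vcf run1/genotypes.vcf --pheno run1/phenotypes.csv \
    --trait RS --outdir run1

# haplotype calling and superior-haplotype summary per candidate gene
grainqtl haplopheno --vcf run1/genotypes.vcf --pheno run1/phenotypes.csv \
    --gff3 run1/genes.gff3 --mta run1/mta.tsv --outdir run1

# or the whole chain on simulated data
grainqtl all --seed 1 --outdir run1
```

Example config (`config.yaml`):

```yaml
simulate:
  n_accessions: 150
  n_subpops: 8
  n_snps: 1000
  divergence: 0.1
  qtls:
    - {snp_index: 40, trait: RS, target_pve: 20, direction: 1}
thresholds:
  neglog10p: 5.0
  lod: 3.0
```

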