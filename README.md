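# evcfkit

Genotype clinically informative sites — including homozygous-reference ones —
from the non-variant block records of a gVCF, and store the result as a
compact **extended VCF (eVCF)**.

## The problem

A standard variant-only VCF records where a genome *differs* from the
reference. For clinical interpretation that is not enough: the reference
genome itself carries minor, rare, pathogenic and GWAS risk alleles at many
positions, so "no variant called here" can mean two very different things —
*homozygous for the reference allele* (an actual genotype, sometimes a
risk-allele genotype) or *no confident call* (insufficient depth or
quality). A gVCF closes the gap by tiling the non-variant genome with block
records carrying confidence summaries (`END`, `GQX`, `MIN_DP`), but gVCFs
are large and unsupported by most annotation platforms.

`evcfkit` resolves an explicit five-way genotype at every site of a clinical
catalog and writes a file that stays ordinary VCF:

* **variant record at the site** → genotype taken from its `GT`
  (`0/0` hom-ref, `0/x` het, `x/x` hom-alt, `x/y` het-alt), FILTER passed
  through unchanged;
* **site fully covered by blocks passing the confidence policy**
  (`FILTER=PASS`, `GQX ≥ 20`, `MIN_DP ≥ 5` by default) → hom-ref, serialized
  with `ALT .` and `GT 0/0`;
* **anything else** → an explicit no-call (`GT ./.`), never silently
  conflated with hom-ref.

The eVCF header records the catalog name/version and the policy; INFO keys
`known`, `gwascat_id`, `odds_ratio`, `clnsig` and `conflict` carry the
clinical annotations.

Supporting analyses from the same workflow are included: genotype
concordance between callsets (truth-referenced sensitivity/specificity,
exact-genotype concordance) with array-allele strand normalization and a
probe-interference filter (polymorphisms 1–10 bp from the probed base),
a reference-allele audit (minor-allele-on-reference MAF bins, risk-allele
zygosity and dosage), and per-base coverage QC (gap detection, region
coverage fractions, GC/AT context windows, binomial coverage thinning).
A deterministic synthetic-data module generates references, catalogs,
Hardy–Weinberg genotypes, gVCFs and array reports with known truth, so the
whole pipeline is testable offline.

## Worked example

```bash
evcfkit simulate --out-dir sim --length 20000 --sites 150 --nocall-frac 0.1 --seed 5
evcfkit build --gvcf sim/sample.gvcf --sites sim/sites.vcf \
    --out sample.evcf.vcf --summary summary.tsv \
    --catalog-name simsites --catalog-version 1
```

prints

```
150 catalog sites: 46 hom-ref, 100 variant, 4 no-call
```

Of the 150 catalog sites, only the 100 het/hom-alt sites would appear in a
variant-only VCF. The block records let 46 more be asserted as confident
homozygous-reference genotypes; the remaining 4 fall in low-confidence
regions (the simulated 10% no-call mask) and are reported as explicit
no-calls rather than assumed to be reference. The eVCF re-parses as
standard VCF, and

```bash
evcfkit export-annovar --evcf sample.evcf.vcf --out sample.annovar.tsv
evcfkit concordance --truth sample.evcf.vcf --test sample.evcf.vcf
```

converts it for annotation tools and cross-tabulates callsets
(self-comparison prints `sensitivity 1.000000`, `specificity 1.000000`,
`concordance 1.000000`).

Coverage QC runs on per-base profile TSVs and FASTA:

```bash
evcfkit qc gaps --profile profile.tsv           # runs > 10 bp below depth/MAPQ/baseQ floors
evcfkit qc fraction --profile profile.tsv --bed exons.bed
evcfkit qc gc --fasta ref.fa                    # normal / high (>=75%) / extreme (>=85%) GC windows
evcfkit qc at-runs --fasta ref.fa               # >= 30 bp alternating AT runs
evcfkit qc thin --profile profile.tsv --target-mean 20 --seed 1 --out thin.tsv
```

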