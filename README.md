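# phshap

Haplotype analysis and diagnostic-marker design for the wheat *Phs-A1*
pre-harvest sprouting locus — and, more generally, for any candidate locus
where a handful of linked biallelic SNPs behave as a low-recombination
haplotype block.

Pre-harvest sprouting (PHS) — germination of mature grain on the ear before
harvest — is controlled in wheat in large part by *Phs-A1* on chromosome arm
4AL, with *TaMKK3-A* carrying the causal C→A polymorphism: the C allele
confers dormancy (PHS resistance), the A allele does not. Breeders working
with this locus need four things this package provides as a single tested
pipeline:

1. **Haplotype definition from VCF genotypes** (`phshap.variant_io`,
   `phshap.haplotypes`). SNPs inside the locus gene intervals are kept when
   their minor-allele frequency (MAF) exceeds 5% and accessions when more
   than 80% of their non-missing calls are homozygous (both strict
   inequalities); fully homozygous allele strings (R = reference allele,
   A = alternate) are grouped into haplotypes H1, H2, … named by descending
   membership. A greedy set-cover picks the small "informative" SNP subset
   (candidate MAF > 30%) that distinguishes all haplotype pairs, and new
   panels are typed against reference haplotypes projected onto that subset
   (projection collisions are reported as compound labels such as `H5/H7`).
2. **Median-joining networks** (`phshap.network`). The ε-relaxed minimum
   spanning network over observed haplotypes — edge (u, v) kept iff
   d(u, v) ≤ bottleneck(u, v) + ε under Hamming distance — is augmented with
   inferred median haplotypes (for biallelic strings the quasi-median of a
   triple is its position-wise majority) whenever they reduce the total
   connection cost.
3. **Germplasm statistics and pedigree diversity** (`phshap.popstats`,
   `phshap.pedigree`). Per-group carrier frequencies with nearest-integer
   percentages; the Pearson χ² (no continuity correction, df = 1) for 2×2
   allele-by-trait tables; and the coefficient of parentage (COP) under the
   inbred-line convention COP(x, x) = 1,
   COP(x, y) = ½·[COP(x, p₁(y)) + COP(x, p₂(y))], with group means over all
   n(n−1)/2 within-group or |a|·|b| between-group pairs.
4. **CAPS and KASP marker design** (`phshap.markers`). In-silico restriction
   digestion over IUPAC motifs on both strands, discovery of enzymes whose
   fragment ladders discriminate an allele pair, and allele-specific primer
   records (two primers differing only at the 3′ SNP base, FAM/HEX dye
   tails, one common primer).

Because the original exome-capture panel is not redistributable, the package
ships a first-class synthetic-data module (`phshap.synthetic`) that plants
founder haplotypes, noise, pedigrees and restriction sites with known truth,
so every stage is testable end to end offline.

## Worked example

Simulate a 58-accession panel planted from 14 founder haplotypes over 39
SNPs with 2% heterozygous and 2% missing calls, then run the haplotype and
network stages:

```bash
phshap simulate --n-founders 14 --n-sites 39 --n-accessions 58 \
    --het-rate 0.02 --missing-rate 0.02 --seed 1 --outdir demo
phshap haplotype --vcf demo/panel.vcf --outdir demo/hap
phshap network --haplotypes demo/hap/haplotypes.tsv --outdir demo/net
```

prints

```
wrote synthetic panel (58 accessions x 39 sites) to demo
14 haplotypes from 58 accessions x 39 sites (33 unassigned)
network: 24 nodes (10 inferred medians), 23 edges
```

All 14 planted haplotypes are recovered (accessions with any heterozygous or
missing call at the 39 sites are listed as unassigned rather than imputed),
and the median-joining network connects them through 10 inferred
intermediate haplotypes. The association between market class and the
dormancy allele, on a metadata table with 11 of 13 bread-making and 10 of 28
feed/biscuit varieties carrying the C allele:

```bash
phshap stats --metadata meta.tsv --outdir demo/stats
```

```
chi2 = 8.497, df = 1, p = 0.003557
bread: 11/13 (85%)
feed: 10/28 (36%)
```

CAPS design on an 887-bp amplicon pair in which the C allele carries an
Hpy166II site (GTNNAC) destroyed by the C→A SNP:

```bash
phshap caps --fasta alleles.fa --snp-position 608 --outdir demo/caps
```

```
1 discriminating assay(s)
  Hpy166II: [605, 282] vs [887]
```

i.e. the C-allele amplicon digests into 605 + 282 bp fragments while the
A-allele amplicon stays intact at 887 bp.

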