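# snppanel

Selection of informative SNP markers for biparental mapping populations.

When two parents of a cross have been resequenced against a draft reference,
only a fraction of the raw variant calls make useful mapping markers: the
site must segregate 1:1 in the progeny (heterozygous in exactly one parent,
homozygous in the other — a pseudo-testcross configuration), the call must
be confident, the locus must be well covered but not collapsed-repeat deep,
and the surrounding sequence must be clean enough to design a genotyping
probe. `snppanel` implements that whole selection path as a tested pipeline:

1. **simulate** (`snppanel.simgenome`) — a seeded synthetic diploid cross:
   reference scaffolds with planted exact repeats and homopolymer runs,
   parental truth genotypes, and per-parent allele-count pileups with
   Poisson depth and a symmetric per-read miscall rate.
2. **call** (`snppanel.genotypes`) — diploid genotype calling per parent
   from allele counts. With `n = ref + alt` informative reads and `k`
   alternate reads, the three genotype likelihoods are binomial,
   `P(k | g) = Binom(k; n, q_g)` with `q_g ∈ {ε, ½, 1−ε}`, combined with a
   flat prior; the phred-like SNP quality is
   `Q = −10·log₁₀ P(hom-ref | data)`.
3. **filter** (`snppanel.snpfilter`) — the selection cascade with an audit
   flag per stage: per-parent coverage bounds (depth in [4, 100]), a 60-bp
   spacing rule against neighbouring SNP candidates and indel evidence,
   the one-het-parent informativeness rule with strict `Q > 100`, a
   ≥ 10-read support floor, and repeat/homopolymer masking (BED intervals
   plus a built-in run scanner).
4. **flanks** (`snppanel.flanks`) — 121-bp assay context (60 bases each
   side), exported as `LEFT[REF/ALT]RIGHT` strings, with a canonical
   k-mer (k = 31, both strands) uniqueness screen against the reference.
5. **report** (`snppanel.report`) — per-scaffold marker density at two
   quality strata (Q > 100, Q > 200), expressed as scaffold length per SNP,
   with genome-level means over the major (chromosome-scale) scaffolds.

## Worked example: density arithmetic of a published peach panel

The package bundles a per-scaffold marker table for the peach genome
(20 scaffolds, counts of panel SNPs above Q 100 and Q 200, scaffold lengths;
the eight chromosome-scale scaffolds are the majors):

```bash
python -c "from snppanel.report import load_example_counts; \
           load_example_counts().to_csv('counts.tsv', sep='\t', index=False)"
snp-panel-select report --counts counts.tsv --out report.tsv
```

prints

```
total SNPs Q>100: 6654  Q>200: 3072  length: 225749601  mean nt/SNP (major): 40176 / 80506
```

and `report.tsv` begins

```
scaffold	n_snps_q1	n_snps_q2	length_nt	length_per_snp_q1	length_per_snp_q2
scaffold_1	1267	716	46877626	36999	65472
scaffold_2	1205	412	26807724	22247	65067
```

Reading: chromosome 1 carries 1,267 markers above Q 100 on 46.9 Mb — one
marker every 36,999 bases. Across the eight major scaffolds the panel of
6,654 markers averages one SNP per 40,176 bases (one per 80,506 at the
stricter Q > 200 stratum), i.e. roughly the "one marker per 40 kb" density
a breeding program needs for QTL work.

## Worked example: a synthetic cross end to end

```bash
snp-panel-select simulate --seed 7 --outdir sim
for p in parent1 parent2 parent3; do
  snp-panel-select call --pileup sim/pileup.$p.tsv --out sim/calls.$p.tsv
done
snp-panel-select filter --calls sim/calls.parent1.tsv --calls sim/calls.parent2.tsv \
    --calls sim/calls.parent3.tsv --repeats sim/repeats.bed \
    --ref sim/reference.fa --out-prefix sim/panel
snp-panel-select flanks --panel sim/panel.vcf --ref sim/reference.fa --out-prefix sim/panel
snp-panel-select report --panel sim/panel.vcf --lengths sim/scaffolds.tsv --out sim/report.tsv
```

On the default eight 50-kb scaffolds (depth 20, 1% miscalls) this run
retains 98 of the raw candidates as informative markers
(`total SNPs Q>100: 98  Q>200: 14  length: 400000`), writes them as PASS
records in `sim/panel.vcf` (failed candidates keep their first failing
filter in the FILTER column), and exports probe-ready flanks such as

```
>scaffold_1:2850:T:C
ATATTTGCTTTATCCTGGTCGCGGATTTGTTGCGTGCGGTACTTCATAAGTGTGCCTGGT[T/C]AGC...
```

The same workflow is available in one call from Python:

```python
from snppanel import SimConfig, run_pipeline
result = run_pipeline(SimConfig(seed=7), outdir="sim")
print(len(result.panel), "markers retained")
```

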