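# Methods

## The problem

A biparental mapping population is most cheaply genotyped on a fixed panel
of SNPs chosen so that every marker (a) segregates 1:1 among the progeny and
(b) can be assayed reliably on an array-style platform. Given per-parent
sequencing evidence aligned to a reference, panel selection is a filtering
problem: call genotypes per parent, keep the sites heterozygous in exactly
one parent, and discard everything an assay probe would stumble over —
shallow or collapsed-repeat coverage, neighbouring variation inside the
probe footprint, repetitive or homopolymeric context.

`snppanel` implements that path end to end, together with a synthetic-data
generator that makes the whole pipeline testable against a known truth set
without any sequence download.

## Genotype model

At one site of one diploid parent, let `n = ref_count + alt_count` be the
reads supporting the two modelled alleles and `k = alt_count`. Under a
symmetric per-read miscall rate `ε`, the probability that a read shows the
alternate allele is `ε` for hom-ref, `½` for het (a coin flip regardless of
miscalls), and `1 − ε` for hom-alt, giving binomial likelihoods

    P(k | g) = C(n, k) · q_g^k · (1 − q_g)^(n−k),   q_g ∈ {ε, ½, 1 − ε}.

Posteriors combine these with a genotype prior (flat by default) and the
MAP genotype is reported; depth 0 yields a no-call. The SNP quality is

    Q = −10 · log₁₀ P(hom-ref | data),

i.e. phred-scaled confidence that the site is variant in that parent.
Hom-ref sites score near 0; a het site with ~10 alternate reads at depth 20
scores well above 100. Q is uncapped (the Q > 200 stratum in reporting is
meaningful); a floating-point floor on the log-posterior keeps it finite.
Reads showing a third base (`other_count`) are excluded from the trials;
sites whose parents disagree on the alternate allele are flagged triallelic
and excluded from selection, since the two-allele model does not cover them.

Properties enforced by tests: exact agreement with a brute-force argmax over
all count splits at depth ≤ 12 and several error rates, allele-swap symmetry
of the likelihoods, monotonicity of Q in the alternate count at fixed depth,
and simulated accuracy at depth 20 / ε = 0.01 within three binomial standard
errors of the analytically summed Bayes accuracy (~99.9%).

## Filter cascade

Default thresholds, with units and boundary semantics:

| stage         | rule                                             | default |
|---------------|--------------------------------------------------|---------|
| coverage      | every parent's depth within [min, max], inclusive| 4, 100 reads |
| spacing       | no raw SNP candidate or indel-evidence site within w bases either side (distance = w violates) | w = 60 bp |
| informative   | exactly one parent het, all others homozygous (either allele), het parent's Q strictly > threshold | Q > 100 |
| depth-support | minimum per-parent depth ≥ threshold, inclusive  | 10 reads |
| repeat-mask   | position outside annotated repeat intervals (BED, 0-based half-open) and outside any homopolymer run ≥ min detected from the reference | run ≥ 6 |

Design choices where the rules were genuinely open:

- **Spacing reference set.** "No neighbouring SNPs" is evaluated against the
  *pre-filter* candidate set plus all gap-evidence sites, and removal is
  symmetric (both members of a close pair fail). Rationale: the filter
  protects the 60-bp probe footprint, and a nearby low-quality SNP corrupts
  a probe regardless of whether it survives its own filters. A consequence
  is that the four post-coverage stages are independent predicates and
  commute; the cascade order only decides which failure the audit reports
  first.
- **Informativeness.** "Only one parent polymorphic" is read as exactly one
  het parent with every other parent homozygous for either allele: het ×
  hom-ref and het × hom-alt both give 1:1 segregation, whereas hom-ref ×
  hom-alt gives none, and shared hets give 3:1/1:2:1 — neither is a usable
  pseudo-testcross marker.
- **Read support** applies to the minimum per-parent depth — the
  conservative reading of a per-site support threshold.
- **Panel quality** of a candidate is the het parent's Q (that is the
  quantity the informativeness filter thresholds); for non-informative audit
  rows it is the maximum variant quality over parents.
- Indels are spacing-filter input only (gap evidence), never genotyped.

The cascade emits an audit table holding every raw candidate, each stage's
pass/fail flag, and the first failing stage in cascade order; the retained
panel provably equals the conjunction of all stage predicates, and the test
suite checks it site-for-site against an independently coded per-site
predicate loop.

## Flanks and uniqueness

Assay context is the reference sequence 60 bases either side of the SNP
(121 bases total, centre base = reference allele), exported in the bracketed
`LEFT[REF/ALT]RIGHT` convention (125 characters: 119 flanking bases plus the
five-character allele block) and as a 121-base consensus with an IUPAC
ambiguity code at the centre. Candidates within 60 bases of a scaffold end
are dropped (`edge`) rather than padded — probes need real context. Flanks
are cut from the reference rather than a per-parent consensus: flanking
bases differing between parent and reference would themselves be SNP or gap
sites, which the spacing filter has already excluded from the footprint.

The uniqueness screen asks whether every k-mer window (default k = 31) of
the 121-base context occurs exactly once in the reference, counting both
strands through canonical k-mers; a context containing N is never unique.
This is a deterministic stand-in for realigning candidate flanks and
discarding those with secondary hits: any exact repeat of length ≥ k
overlapping the context forces a multiplicity ≥ 2. Tests verify exact
agreement with overlap-aware brute-force substring counting on references
up to 50 kb, including reverse-complement copies.

## Density reporting

Per scaffold, the report counts retained SNPs with Q strictly above two
strata (defaults 100 and 200) and reports scaffold length / count, rounded
half-away-from-zero to whole nucleotides; a zero count prints `na`.
Genome-level coverage is the mean of the per-scaffold ratios over the
*major* scaffolds — by default the eight longest, i.e. the chromosome-scale
sequences. The mean-of-ratios convention (rather than total length / total
SNPs) weights each chromosome equally and so exposes uneven coverage;
spread is reported as the sample SD (ddof = 1) of those ratios and
CV = SD/mean as a rounded percentage.

On the bundled peach example table (20 scaffolds, 6,654 markers,
225,749,601 nt) this arithmetic gives one marker per 40,176 bases over the
eight majors (80,506 at Q > 200), SD 22,442, CV 56%. Two caveats of that
printed source table, preserved as data: its Q > 200 column sums to 3,072
although its printed total row says 3,065 (one minor scaffold prints
Q > 100 = 1 against Q > 200 = 8, which is impossible), and its printed CV
rounds to 55 where the ratios themselves give 56; the package always
recomputes totals and spreads from the rows.

## Synthetic data generator

`SimConfig` defaults describe the emulated study conditions: eight 50-kb
scaffolds (a desk-scale stand-in for eight ~28-Mb chromosomes), SNP density
165,000 / 230 Mb ≈ 7.2 × 10⁻⁴ (the genome-wide discovery rate of a deeply
resequenced cross), half of SNP sites informative for the cross split
evenly between the two cross parents (the remainder split between shared-het
and hom-diff configurations — plausible for two cultivars of a selfing
crop, where neither the informative fraction nor its split is estimable
from a printed panel), indel density 10⁻⁴, one planted 200-bp two-copy
repeat plus 7–8-base homopolymer runs per genome, Poisson mean depth 20
(between the per-parent short-read coverages of 12–16× and the quality
criterion conditions), and miscall rate ε = 0.01. Three parents by default:
two cross parents plus a third sequenced parent, matching a two-population
breeding design sharing one parent.

Evidence is simulated at pileup resolution, not read level: depth per
position is Poisson(λ) with zero-depth positions absent (pileup semantics),
alternate counts are binomial with the genotype-dependent probability above,
miscalls at non-variant sites go to `other_count` (no alternate allele is
defined there), and indel carriers emit `gap_count` evidence. Per-purpose
RNG streams derive from `(seed, stream-id, crc32(parent))`, so identical
seeds give byte-identical FASTA/TSV/VCF outputs and adding a parent never
perturbs another parent's data.

What the generator does **not** model — and hence what passing tests do not
show about real data: read-level artefacts (mapping error, strand bias,
base-quality variation), inexact/diverged repeats, structural variation,
reference errors, and non-uniform coverage. The cascade's behaviour under
those failure modes is exactly what the conservative thresholds exist for,
but it is not exercised here.

## Numerical choices and degenerate inputs

- Likelihoods and posteriors are computed in log space (log-sum-exp); the
  log-posterior is floored at log(tiny double) ≈ −708 nats, capping Q around
  3,076 rather than letting it reach infinity.
- MAP ties break toward the first genotype in (hom-ref, het, hom-alt) order,
  matching the brute-force oracle's tie-break.
- Depth 0 → no-call with Q = 0; a site absent from one parent's pileup is
  treated as depth 0 at candidate merge (fails coverage, flagged no-call).
- Ratio rounding is half-away-from-zero; `round_half_away` is asserted on
  fixed fixtures including the 0.5 and negative cases.
- Repeat intervals on unknown scaffolds warn and are ignored; malformed
  BED/TSV lines raise with file and line number.
- Empty inputs flow through: zero candidates produce empty panel, audit,
  and exports.

## Problem sizes

Unit tests run on 2 × 10-kb genomes; the cascade/oracle and determinism
checks use the 8 × 50-kb study condition (about 300 raw candidates, ~100
retained); caller accuracy uses 10⁴ sites at depth 20. The full suite
completes in well under a minute, `scripts/acceptance.py` in ~10 s.

## Known limitations

- The genotype model ignores per-base qualities and mapping quality; ε is a
  single global parameter per run.
- The uniqueness screen is exact-match only: a diverged repeat with no
  shared 31-mer passes, where a local aligner might still find a secondary
  hit.
- Multi-allelic sites are excluded, not resolved.
- The simulator cannot, by construction, validate the pipeline against
  alignment-induced artefacts (see generator caveats above).
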