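# Methods

## Detection model

The screen treats one female and one male resequenced individual mapped to
the same Z-linked reference. Two per-window statistics carry all the
signal:

**Normalized coverage.** Per-site depth is summarized as the arithmetic
mean over covered sites in consecutive non-overlapping 50-kb windows and
divided by the median window depth of a baseline set. The baseline
preference order is: declared autosomal windows, else pseudoautosomal
windows, else all windows of the chromosome; the choice is recorded in the
output metadata. On this scale a two-copy region sits at 1.0 in either sex,
the hemizygous Z at 0.5 in the female, and a Z-linked duplication at ≥1.5
in the male. Windows are tumbling, not sliding: the upstream workflow this
mirrors computes one value per fixed 50-kb span, and the 30-kb absolute
coverage floor presumes full windows (the trailing partial window is
dropped). Sites deeper than three times the genome-wide mean are removed
first (strictly greater; equality retains), and windows with fewer than
60% of their span covered are excluded (strictly below; 30,000/50,000
retains).

**SNP density.** Retained heterozygous SNPs per 50-kb window, per sex. A
variant is retained if it passes the hard filters (below) and its alternate
allele fraction lies in [0.3, 0.7], inclusive — the expectation for a
heterozygous site in one diploid individual is 0.5, and the window allows
for binomial sampling around it. Density elevation is judged against the
per-sex background λ_bg, estimated as the median window density over the
baseline windows (a median so that candidate regions cannot drag their own
background up). The elevation rule, density ≥ max(k·λ_bg, λ_bg + 3√λ_bg)
with k = 3, combines a fold threshold with a Poisson three-sigma band so
that it stays meaningful when λ_bg is small.

Window labels follow from the joint signature (coverage interval defaults:
two-copy [0.8, 1.25], hemizygous [0.35, 0.65], duplication male floor 1.5):

| label | female cov | male cov | female density | male density |
|---|---|---|---|---|
| ZTR | full | full | elevated | not elevated |
| PAR | full | full | not elevated | not elevated |
| Z_DUP | — | ≥ 1.5 | elevated | elevated |
| HEMIZYGOUS_Z | hemizygous | full | not elevated | — |

None of these numeric thresholds is dictated by the underlying biology
beyond placing the expected signatures at interval centers; all are
config-exposed. PAR is classified by signature only — terminal position on
the chromosome is never used as evidence. AUTOSOME_LIKE is reserved for
declared baseline chromosomes; anything else is UNCLASSIFIED.

**Merging.** Maximal runs of one label become region calls. A single
interior excluded or unclassified window between two runs of the same
label is bridged (long calls should not fragment on one noisy window).
Hemizygous runs flanked by ZTR on both sides are absorbed into a single
ZTR envelope and recorded as candidate W-deletions — exactly the pattern a
secondary deletion on the W produces, since the female falls back to one
copy there. Runs shorter than `min_run` (default 2 windows) are demoted to
UNCLASSIFIED. Candidate deletions shorter than `min_run` windows are
likewise ignored by the deletion caller; deletions are therefore
window-resolution calls and their retained-length accounting
(envelope = deleted + retained) is exact by construction.

**Rank-sum test.** Female ZTR window densities are compared against the
rest of the chromosome (and against male densities inside the ZTR) with a
Mann–Whitney test; candidate-deletion windows are excluded from the
contrast because the W-derived signal is genuinely absent there. For
min(n, m) ≤ 8 (and a tractable number of assignments, ≤ 2·10⁵) the p-value
is computed by exact enumeration over all group assignments of the pooled
values, which handles ties without approximation. Otherwise a normal
approximation is used with tie-corrected variance, continuity correction,
and an Edgeworth kurtosis term (the null U distribution is platykurtic,
excess kurtosis −(6/5)(n²+m²+nm+n+m)/(nm(N+1)) without ties); the term
reduces the worst-case disagreement with exact enumeration at n = m = 8
from ~0.011 to ~5·10⁻⁴ on tie-free data. The corrected CDF is clamped to
(0, 1) so extreme tails cannot produce p ≤ 0.

## Hard filters

A record fails when FS > 10.0, QD < 2.0, MQ < 50.0, SOR > 1.5,
MQRankSum < −1.5 or ReadPosRankSum < −8.0 (strict inequalities; missing
annotations leave a criterion unapplied, following variant-caller
convention). Any SNP within 10 bp of another SNP fails with reason
`cluster` — the cluster-of-2-in-10-bp rule — which also removes genuinely
adjacent divergence sites; that loss is accepted as part of the filter
definition. Indels share the numeric criteria but are exempt from the
cluster rule and never counted in SNP density; they are retained for
pseudo-sequence construction. All applicable fail reasons are recorded, so
|PASS| + |failed| = |input| and filtering is idempotent.

## W pseudo-sequence and gene fates

All retained female heterozygous variants inside the ZTR envelope are
treated as Z-W divergence and their alternate alleles assigned to the W
haplotype (unphased). This is the young-ZTR assumption: with divergence
d ≈ 2·10⁻³/bp far above polymorphism π ≈ 10⁻⁴/bp, polymorphism
contamination of the pseudo-sequence is a few percent and is not modelled.
Variants are applied left to right; a variant whose REF span intersects an
already-applied span is skipped (leftmost wins — deterministic and
consistent with left-normalized VCF conventions) and counted. The
coordinate map stores cumulative indel offsets at each breakpoint; interval
liftover shrinks or shifts across indels and is flagged `partial`/`deleted`
only against coverage-defined W-deletions.

Gene fate: a gene wholly inside a W-deletion is `deleted`; any overlap is
`partial_deletion` even if the residual ORF could be intact (matching how
partially deleted transposed genes are labelled in practice); otherwise the
CDS is lifted, reverse-complemented per strand, translated with the
standard code, and called `pseudogene` on a net indel length ≢ 0 (mod 3)
(frameshift) and/or an in-frame stop strictly before the annotated terminal
codon (premature stop), else `intact`. Coordinate liftover plus translation
replaces homology-based gene prediction; at young-ZTR divergence the exon
structure is unchanged, which is what makes the substitution safe. The Z
CDS of each input model is sanity-checked to translate without internal
stops.

## Branch dN/dS

Nei–Gojobori (1986) counting: per-codon synonymous site fractions (changes
to stop codons count as nonsynonymous, so S + N = 3 × codons exactly);
substitutions between differing codons averaged over all minimal mutational
pathways, excluding pathways through stop codons unless no stop-free
pathway exists (then all pathways are used so the difference count is
conserved); proportions corrected with Jukes–Cantor,
d = −(3/4)·ln(1 − (4/3)p), flagged saturated at p ≥ 3/4. ω with dS = 0 is
reported as undefined alongside dN, never as infinity — zero observed
substitutions can make the ratio degenerate in either direction.

Branch assignment on a (Z, W, outgroup) triplet is by parsimony: at each
Z/W-differing codon the copy matching the outgroup is ancestral and the
substitutions go to the other copy's branch; codons where all three differ
are reported separately as unpolarized (a warning fires above 20%). The
conservation identity sd_Z + sd_W + sd_unpolarized = pairwise sd(Z, W)
holds exactly, and likewise for nd. This counting estimator stands in for
a maximum-likelihood branch model; at the low divergence of young
transposed regions the two agree well, and the counting route is fully
auditable. Parsimony has one intrinsic failure mode worth knowing:
if the outgroup independently realizes the same change as the Z branch
(homoplasy), the substitution is mis-assigned to the W branch. The
demonstration that a fully constrained W copy yields nd_W = 0 therefore
simulates the outgroup under the same purifying ω as W, which removes the
nonsynonymous homoplasy route; with a permissive outgroup an occasional
spurious nd_W > 0 is a property of parsimony polarization, not an
implementation error.

## Synthetic data: what it emulates, and what it does not

Per-site depth is Poisson(c·D) with copy numbers c as in the detection
table (ZTR female c = 2 because W reads co-map; inside a W-deletion c = 1;
Z_DUP male c = 4). The model is Poisson rather than negative binomial
because the inference uses only window means; a gamma overdispersion knob
exists (default 0). Sites drawing depth 0 are absent from the table, as in
a coverage-only depth report — at D = 15 essentially every site is
covered, so the 60%-coverage exclusion is exercised by constructed
fixtures, not by the default simulation. No separate W contig is emitted:
ZTR reads are represented purely as a copy-number and heterozygosity
signal on the Z, matching the perfect co-mapping assumption.

Heterozygous sites arise as independent Poisson processes: background π in
both sexes everywhere, divergence d in the female only inside ZTRs (minus
deletions), paralogous variants in both sexes inside duplications, and
W-copy indels inside ZTRs. Allele fractions are Beta(50,50)-binomial at
site depth, keeping most sites inside the [0.3, 0.7] acceptance window at
D ≥ 15. Annotation fields draw from distributions that pass every hard
filter except a planted `fail_fraction` (default 5%) of records that each
violate exactly one criterion, so filter-reason bookkeeping is testable
record by record. Divergence SNPs landing in the CDS of a gene whose
planted fate is not a pseudogene are made synonymous (or dropped when the
codon admits no synonymous change), and indels avoid CDS entirely except
the single 1-bp deletion planted into each designated frameshift
pseudogene — this is what makes planted gene fates exact truth rather than
high-probability truth. Defaults (D = 15, d = 0.002, π = 10⁻⁴,
dup_psv_rate = 0.002) are the study conditions the pipeline is screened
under; the haploid depth of the emulated datasets is not published, so
15× is a choice of a typical resequencing depth, not a reproduction.

Codon alignments evolve on the fixed rooted tree ((Z, W), outgroup) with
per-branch (length, ω): per-site mutation attempts are Poisson(length),
proposals creating stops are rejected, synonymous proposals always accepted
and nonsynonymous ones with probability ω, so realized dN/dS equals ω. By
default at most one substitution is realized per codon per branch — the
young-divergence regime — which makes realized truth counts identical to
minimal-path counts. Branch length is therefore in units of neutral
mutation attempts per site, not substitutions.

Everything is deterministic under the configured seed; each generator
draws from its own seed stream, so adding one output never perturbs
another.

What the generator does *not* model — and hence what passing tests do not
establish about real data: read-level artifacts (mapping bias, duplicates,
reference bias against the W allele), GC- or mappability-structured
coverage, linked polymorphism or any coalescent structure, recombination,
sequencing error in allele fractions beyond binomial sampling, shared
polymorphism between the sexes, and TE or repeat content. Recovery rates
on this generator measure the pipeline's statistical logic under its own
assumptions, not robustness to alignment pathology.

## Numerical and boundary choices

* All internal coordinates are 0-based half-open; depth tables, VCF and
  GFF3 use their native 1-based conventions at I/O.
* Boundary semantics are strict where the rules say "higher/less than":
  3× mean depth retains equality, the 60% rule excludes strictly below,
  hard-filter thresholds fail strictly beyond, the allele-fraction window
  is inclusive.
* The genome-wide (not per-chromosome) mean is used in the 3× depth rule.
* Window means are over present sites only (no zero-filling), mirroring
  interval-map semantics over reported positions.
* Variant re-derivation (the round-trip check) aligns Z against W with
  affine gap costs (substitution 1, gap open 2, extend 0.5) so that a
  substitution is cheaper than an insertion-deletion pair and consolidated
  gaps are strictly preferred; both applied and derived indels are
  left-normalized before comparison. Plain edit-distance alignment is not
  sufficient: it may split a multi-base indel around a coincidentally
  matching base at equal cost.
* Exact rank-sum enumeration is additionally capped at 2·10⁵ assignments;
  beyond that the asymptotic branch is used regardless of min(n, m).

## Problem sizes used in the shipped checks

The default synthetic study is one 10 Mb focal chromosome (200 windows)
plus a 1 Mb baseline; the acceptance script runs five seeded replicates of
it, a 20 × 600-codon constraint check, and a 20-seed ω-recovery experiment
at 1,000 codons. The module test suite uses a 2 Mb focal chromosome for
everything that does not specifically exercise the default study. These
sizes give per-window coverage standard errors of ~1% and expected ZTR
window densities of ~90 against a background of ~5, i.e. the planted
effects are far from threshold and recovery failures would indicate logic
errors rather than bad luck.

## Known limitations

* W-deletions are window-resolution (50 kb) coverage calls; deletions
  below `min_run` windows are invisible by design, and no split-read or
  alignment-level refinement is attempted.
* The alternate allele is assigned to the W haplotype without phasing; at
  appreciable polymorphism levels the pseudo-sequence absorbs some
  within-Z variation.
* Parsimony polarization cannot resolve codons where all three sequences
  differ, and mis-polarizes under outgroup homoplasy (see above); the
  triplet interface accepts a single outgroup by design.
* The gonad-bias fold threshold (2×) and the classification thresholds are
  operational defaults, not estimated quantities; all are config-exposed.
* Detection requires the transposition to be young enough for W reads to
  co-map to the Z; ancient transpositions fall outside the method's
  assumptions entirely.
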