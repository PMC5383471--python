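# Methods

This note documents the statistical models and procedural choices
behind the package, the defaults and why they were chosen, and what the
synthetic cohorts do and do not establish about real data.

## Two-lineage divergence model

Nuclear SNPs are simulated under a Balding–Nichols parameterisation.
Each site has an ancestral allele frequency p ~ Uniform(0.05, 0.95)
(bounds keep the Beta parameters non-degenerate), and each lineage
independently draws its frequency from

Beta(α, β),  α = p(1−F)/F,  β = (1−p)(1−F)/F,

which has mean p and variance F·p(1−p). F ∈ [0, 1) is the divergence
parameter; the expected Hudson-type F_ST across many sites equals F,
which gives the simulator a closed-form truth for estimator tests. At
F = 0 both lineages inherit p exactly (no degenerate Beta is drawn).
The large-n expectation of the Weir–Cockerham ratio-of-sums also equals
F under this model: E[s²] = F·p(1−p) and E[p̄(1−p̄) + s²/2] = p(1−p),
so the estimator is checked against the parameter it is supposed to
recover, not against itself.

Defaults: `fst=0.062` (the allopatric divergence level the analysis
targets), 20,000 sites, four groups of 10 diploid samples. Sites are
unlinked; no recombination map, mutation process, or read-level error
is modelled. Consequently the block jackknife is exercised on exchangeable
blocks — the simulations validate its arithmetic, not its robustness to
linkage, which is the reason block resampling is used on real data.

## Admixture

Admixture is modelled at the allele level: a bird with ancestry
fraction q draws each of its two allele copies from lineage A with
probability q, independently across copies and sites. Backcross
generations map onto q (BC1 into tristis ⇒ q = 0.25); genotype
fractions at fixed sites follow the binomial expectations
(q², 2q(1−q), (1−q)²). A true F1 is not this process — it carries one
chromosome from each parent and is heterozygous at *every* fixed
difference — so `SampleSpec(cross="f1")` forces one copy per lineage.
Pedigree structure beyond F1 (linkage blocks in backcrosses) is not
modelled; every statistic computed here depends only on per-site
genotype distributions, for which the allele-level model is sufficient.

Default sympatric cohorts were fixed once to emulate the observed
introgression gradient: northern ancestry fractions
(0.9, 0.5, 0.25, 0.25, 0.1, 0.1, 0.05, 0.05, 0.25, 0) with mean
q ≈ 0.25 (strong bias toward tristis) and southern fractions
(1, 0.9, 0.75, 0.5, 0.4, 0.25, 0.1, 0.05, 0.05, 0) with mean q ≈ 0.40,
each mixing near-pure birds, intermediates and backcrosses. A
morphotype label is derived from q (≥ 0.7 abietinus-like, ≤ 0.3
tristis-like, else intermediate) so that phenotype-based groupings of
sympatric birds can be reproduced.

## SNP filtering

High stringency keeps a site when it has a called genotype in at least
9 of the 10 individuals of **every** group; low stringency requires
at least 6 called individuals in **each allopatric reference group**
only. Thresholds are inclusive ("at least"). "Present in N
individuals" is read as "genotype called in N individuals"; the
alternative reading ("carries the alternate allele") is available via
`StringencyFilter(presence="alt_carrier")` but is not the default,
since the low-stringency rule parallels the high-stringency one, which
is unambiguously about call availability. Quality gates mask calls
with GQ < 30 or DP < 5 by default and drop sites left with no calls.
Multiallelic VCF records are dropped at load (logged): the analysis is
defined on biallelic SNPs.

## Polymorphism classes and percentages

For a pair of groups, a site with at least one called genotype in each
is fixed / shared / private-A / private-B / invariant based on the
allele sets observed per group. Percentages are reported over the four
polymorphism-relevant classes; same-allele invariant sites are counted
separately rather than folded into a denominator, because summary
tables of this kind conventionally total ≈ 100% over the four classes.
All reported percentages use exact rational division and half-up
rounding to one decimal, so printed-count arithmetic reproduces
bit-for-bit.

## F_ST

Weir & Cockerham (1984) per-site variance components a (between
populations), b (between individuals within populations) and c (within
individuals), computed from genotype counts — observed heterozygosity
enters through h̄, and unequal/per-site sample sizes through n_c. The
point estimate is the ratio of sums Σa / Σ(a+b+c) over used sites
(≥ 2 called genotypes per group). The standard error is a
delete-one-block jackknife over consecutive, non-overlapping 50-SNP
windows in genome order: contiguous blocks are chosen (rather than
random sets) because on real data they absorb local linkage
correlation. W&C is the field-default estimator; monomorphic-everywhere
input raises rather than returning 0/0.

## Hybrid index and admixture EM

The diagnostic panel is exactly the set of fixed sites between the
reference groups, ordered by coordinate. Scoring uses called panel
sites only (missing calls are excluded from the denominator and
reported alongside), so the fraction triplet sums to 1 exactly on
counts. Note the panel is *sample*-fixed: with only 10 reference birds
per lineage some panel sites are not truly fixed in the population, so
pure sympatric birds can legitimately show a small fraction of
opposite-lineage or heterozygous calls — the simulations reproduce
this behaviour.

The unsupervised estimator is a two-source binomial EM: genotype
g_ij ~ Binomial(2, q_i f_Aj + (1−q_i) f_Bj), with per-allele-copy
source responsibilities in the E-step. The log-likelihood is monotone
non-decreasing; convergence is declared when it changes by less than
`tol=1e-5` (absolute), with `max_iter=1000`. Source frequencies are
initialised from the declared reference groups when given (with a 0.5
pseudocount), else uniformly at random from the seed; label switching
is resolved by anchoring source A to the declared lineage-A group.
This is a deliberately minimal assignment model — no admixture prior,
no MCMC, K fixed at 2 — adequate for cross-checking the supervised
hybrid index, not a substitute for full model-based clustering.

## mtDNA RFLP

Digestion is linear (the assayed template is an amplicon, not the
circular mitogenome). Cut coordinates are 0-based between-base
positions internally, with the Hinf I cut one base into the GANTC
motif (G^ANTC). GANTC is its own reverse complement, so a
single-strand scan finds every recognition site; note that the
*fragment boundaries* read from the opposite strand shift by the
3-base overhang — patterns are compared per strand, as a gel lane
would be scored. Haplotype calling is exact matching on the
fragment-length multiset with no gel-resolution tolerance; a template/
enzyme combination in which two haplotypes share a multiset is a
configuration error raised at load.

The synthetic 389-bp template places the five diagnostic substitutions
at coordinates (60, 135, 200, 270, 330), with the assayed three at
(60, 200, 330) each toggling a planted GANTC context (abietinus cuts
at 60 and 330, tristis at 200, tristis-2 at 200 and 330). The real
amplicon's diagnostic coordinates are not published; the template is
synthetic by construction and verified at build time (no unplanned
motif in any haplotype, pairwise-distinct digests).

## Song classification

The three criteria (ascending elements, note rate, frequency range)
each vote abietinus / tristis / mixed against closed intervals; the
published ranges are descriptive summaries, so endpoints are treated
as inside. The combination rule is unanimity-for-pure: any
disagreement yields a mixed call, consistent with mixed song being
defined as a combination of both note types with intermediate rate and
frequency. The ascending-element threshold for a tristis-like verdict
(mean > 90%) is configurable; the sources state presence/absence
rather than a cutoff. The simulator draws pure songs uniformly inside
the lineage ranges and mixed songs inside the inter-range gap, which
makes label recovery exact by construction — the round-trip validates
the rule wiring, not the discriminability of real field recordings.

## Reporting

Summary tables carry per-character denominators (only individuals
scored for that character), and every emitted percentage is recomputed
from its count and denominator at write time as an integrity check.
Concordance tables are plain cross-tabulations over individuals scored
for both characters of a pair; an empty overlap omits the table.

## Problem sizes used in checks

The automated checks run on cohorts of 18,000 SNPs × 40 samples for
F_ST recovery (360 jackknife blocks), 11,000–12,000 SNPs at high
divergence for panel construction (≈ 3,800 sample-fixed sites, of
which the first 3,555 form the scoring panel), 100 random small
fixtures for each brute-force oracle comparison, and 60–90 draws per
round-trip. These sizes put Monte-Carlo noise well inside the stated
tolerances (e.g. binomial SD of q̂ on a 3,555-site panel is ≈ 0.006
against a ±0.03 band).

## Known limitations

* No linkage, recombination, or coalescent realism in the simulator;
  jackknife robustness to linkage is untested by construction.
* The diagnostic panel inherits ascertainment noise from finite
  reference samples (see above).
* The EM reports convergence by log-likelihood movement only; it does
  not quantify uncertainty in q̂.
* Song and plumage inputs are taken as extracted features/labels;
  nothing here touches audio or images.
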