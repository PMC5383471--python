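# chiffchaff

Analysis toolkit for a songbird hybrid zone: quantifying genetic
admixture between the European chiffchaff (*Phylloscopus collybita
abietinus*) and the Siberian chiffchaff (*P. c. tristis*) where their
breeding ranges overlap along the Ural mountains, and relating it to
plumage, song, and mitochondrial haplotype.

The package is aimed at population geneticists and ornithologists who
have multi-sample SNP genotypes (VCF), per-bird phenotype records, and
a short mtDNA amplicon, and want to score every individual's genomic
composition against the two parental lineages.

## What it computes

Given two *allopatric* reference groups (pure representatives of each
lineage) and *sympatric* cohorts of unknown composition:

* **SNP filtering** — the two retention rules used throughout:
  *high stringency* (genotype called in ≥ 9 of 10 individuals in every
  group; used for F_ST and PCA) and *low stringency* (called in ≥ 6
  individuals in each allopatric group; used for polymorphism
  classification and ancestry), plus optional per-genotype GQ/DP gates.
* **Polymorphism classes** — each site is *fixed* (groups monomorphic
  for different alleles), *shared* (polymorphic in both), *private* to
  one group, or *invariant*; reported as counts and half-up one-decimal
  percentages.
* **F_ST** — Weir & Cockerham (1984) variance components per site,
  combined as θ̂ = Σa / Σ(a+b+c), with a delete-one-block jackknife
  standard error over consecutive 50-SNP windows.
* **Hybrid index** — a *diagnostic panel* of sites fixed between the
  references; each bird's called panel genotypes give fractions
  (hom-A, hom-B, het) and q̂ = (2·n_homA + n_het)/(2·n_called), the
  fraction of its allele copies of lineage-A origin (F1 = 0.5, first
  backcrosses 0.25/0.75). An unsupervised check is provided by a K=2
  binomial-likelihood admixture EM (`AdmixtureModel(...).fit()`).
* **mtDNA haplotyping** — in-silico Hinf I (GANTC, cut G^ANTC)
  digestion of the 389-bp CytB amplicon; fragment-length patterns call
  each bird's haplotype (abietinus / tristis / tristis-2).
* **Song classification** — note rate (abietinus 2.8–3.3 vs tristis
  4.7–7.2 notes/s), note frequency band (3.7–4.6 vs 2.9–3.7 kHz) and
  ascending-element percentage; a male is called a pure type only when
  all three criteria agree, otherwise a *mixed singer*.
* **Reporting** — per-region summary tables with per-character
  denominators, pairwise concordance cross-tabs (e.g. morphotype vs
  mtDNA), and a 2×2 Yates-corrected χ² for frequency contrasts.

A fully parameterised simulator (Balding–Nichols divergence with known
F_ST, allele-level admixture with known q, the synthetic amplicon and
song models) generates complete test cohorts, so every stage is
verifiable against known truth without any external data.

## Worked example

```python
from chiffchaff import (AdmixtureScenario, DivergenceModel,
                        draw_lineage_frequencies, simulate_genotypes,
                        fst, build_panel, score_cohort, aggregate_by_region)

# two allopatric reference groups + two admixed sympatric regions
model = DivergenceModel(n_sites=18_000, fst=0.062, seed=1)
scenario = AdmixtureScenario.default_cohort(10)
freqs = draw_lineage_frequencies(model)
matrix = simulate_genotypes(freqs, scenario, model)

est = fst(matrix, "allopatric_abietinus", "allopatric_tristis")
print(f"allopatric F_ST = {est.fst:.3f} +/- {est.se:.3f}")

strong = DivergenceModel(n_sites=12_000, fst=0.9, seed=1)
m2 = simulate_genotypes(draw_lineage_frequencies(strong), scenario, strong)
panel = build_panel(m2, "allopatric_abietinus", "allopatric_tristis")
profiles = score_cohort(panel, m2)
print(aggregate_by_region(profiles).round(3).to_string(index=False))
```

prints

```
allopatric F_ST = 0.061 +/- 0.001
        region  n  hom_a  hom_b   het  q_hat
allopatry_east 10  0.000  1.000 0.000  0.000
allopatry_west 10  1.000  0.000 0.000  1.000
         north 10  0.126  0.634 0.240  0.246
         south 10  0.283  0.488 0.229  0.397
         total 40  0.352  0.530 0.117  0.411
```

The F_ST estimate recovers the simulated divergence (0.062) within its
jackknife error. The ancestry table is the per-region average genomic
composition: allopatric birds are pure (q̂ of exactly 1 and 0), while
the northern sympatric cohort is strongly biased toward tristis
(q̂ ≈ 0.25, i.e. three quarters of its allele copies are of Siberian
origin) and the southern cohort carries more European ancestry
(q̂ ≈ 0.40), with substantial heterozygosity in both — the signature of
ongoing hybridisation and backcrossing.

A command-line interface mirrors the library
(`chiffchaff simulate|filter|classify|fst|pca|panel|score|admix|haplotype|song|report|run-all`);
`chiffchaff run-all -o outdir` runs the whole pipeline on one simulated
cohort.

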