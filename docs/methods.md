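# Methods

`duoburden` implements a germline rare-variant burden analysis for
mother–infant exome *duos*: pairs in which the mother and her child — here,
an infant leukemia patient — are sequenced, but no father is available.
The pipeline takes called, annotated variants (alignment, calling and
functional annotation are upstream and out of scope), reduces them to each
individual's rare, non-synonymous, predicted-deleterious set, and asks
three questions: is the patients' surviving variation enriched in
leukemia-associated candidate genes; which of an infant's variants are
maternal; and which genes behave as compound heterozygotes under a
presence-based rule.

## Variant identity and normalization

All matching — annotation joins and maternal attribution — uses the key
`(chrom, pos, ref, alt)` after normalization: a leading `chr` prefix is
stripped and alleles are trimmed (shared suffix first, then shared prefix
with the position advanced). Trimming makes parsimony-equivalent indel
spellings collide; full left-alignment against the reference genome is not
attempted because the package never sees the reference sequence, so two
callers writing the *same* indel at different anchor points in a repeat
tract would not match. In practice both members of a duo are processed by
one caller, which keeps representations consistent. Genotype (het/hom) is
deliberately ignored throughout: buccal-derived DNA at a ≥5-read-per-allele
floor does not support confident zygosity, and every downstream rule is
presence-based.

Multi-allelic VCF records are decomposed into one row per alt allele
carried in the genotype. A variant annotated to more than one gene is
duplicated, one row per gene, since genes are the unit of every statistic.
When FORMAT/AD is missing the per-allele depth is unknown and recorded as
0, so the variant fails the per-allele floor — a conservative default.

## The filter cascade

Two passes, each stage recorded so the cascade can be audited:

| stage | rule | default |
|---|---|---|
| allele depth | reads supporting the alt allele | ≥ 5 |
| position depth | total reads at the site | ≥ 10 |
| genotype quality | phred-scaled GQ | ≥ 10 |
| mapping quality | caller RMS MQ | ≥ 60 |
| consequence | non-synonymous, stop gain/loss, frameshift and in-frame indel, splice site | — |
| rarity | allele frequency strictly < `max_maf` in reference panels | 1% |
| deleteriousness | in-silico prediction votes | any_vote |

All quality floors are inclusive. Rarity defaults to `all_panels`: every
panel that reports the variant must show < 1% (absence from all panels
counts as rare, as novel variants should); `any_panel` — rare in at least
one reporting panel — is selectable, since "rare in either database" admits
both readings for a two-panel reduction. A variant at exactly 1% is not
rare. `deleterious_rule` combines prediction votes as `any_vote` (≥ 1 of
the algorithms that produced a prediction), the most sensitive reading and
the common practice for multi-algorithm annotation reductions;
`majority_vote` and `all_votes` are available. A variant with no
predictions at all passes — the filter removes evidence of benignity, not
absence of evidence.

## Enrichment testing

For a sample group, the *variant gene universe* is the set of distinct
genes carrying ≥ 1 surviving variant aggregated across the group's samples,
and the observed statistic is its overlap with a candidate gene list. Two
routes assess significance:

* **Exact tail.** `hypergeometric_upper_tail(k, K, n, N)` returns
  P[X ≥ k] for X ~ Hypergeometric(N, K, n) — N exome genes, K candidates,
  n variant genes — summed in log space (`gammaln` + `logsumexp`) so exome-
  scale binomial coefficients never overflow. Verified against exhaustive
  integer-combinatorics enumeration for every urn with N ≤ 25 to 1e−12.
* **Permutation null.** Either draw `n` genes uniformly without replacement
  from the exome universe and record candidate overlap
  (`resample_variant_genes`), or draw candidate-list-sized random gene
  lists and record their overlap with the variant genes
  (`random_gene_lists`). Default 100 000 iterations; the empirical p uses
  the add-one convention (r+1)/(n+1), so "never exceeded" is reported as
  p ≤ 1/(n+1) rather than 0. Both schemes sample gene *sets*, hence without
  replacement. Significance is declared at the stringent α = 0.005.

The exome gene universe — the sampling frame — is an explicit input (the
gene-model table), because a permutation test is only as meaningful as its
frame; it is recorded in every run manifest. Fixed seeds make the null
distribution and all summaries bit-reproducible. "More extreme" means ≥
observed only: enrichment, not depletion, is the hypothesis.

`enrichment_rate_ratio(a, b, c, d) = (a/b)/(c/d)` compares candidate-variant
rates between groups. Note the estimand depends on the denominators: with
*total*-variant denominators and candidate length-share `c`, a true
multiplier `f` appears as `f/(f·c + 1 − c) < f`; the package's recovery
studies therefore feed candidate and **non-candidate** counts, for which the
ratio equals `f` in expectation. Applied to the study-style printed
per-exome averages (candidate vs total variants, AML infants 163.4/2549.9
against controls 27.5/582.8) the formula gives 1.358, which rounds to the
reported 1.4; the analogous ALL computation (12/1264.4 vs 2/582.8) gives
≈ 2.8, not the reported 2.0 — that figure evidently came from a different
derivation that the printed averages alone cannot reconstruct, so it is
documented here rather than asserted anywhere.

## Duo analysis

An infant variant is **maternal** iff its normalized key occurs among the
mother's *filtered* variants, otherwise **non-maternal** — a class that
deliberately conflates paternal inheritance and de novo mutation, which are
indistinguishable without a paternal sample. A gene is called a
**compound heterozygote** when the infant carries ≥ 2 variants at distinct
sites in it with ≥ 1 maternal and ≥ 1 non-maternal. Phase is unknown (no
trios), so this is a presence-based surrogate for trans-configuration, not
a phased call; the same site observed twice never counts as two variants.
Recurrence tables report, per gene, the fraction of a cohort's infants
carrying a call.

## Ranking and the gene-size check

The variability matrix counts surviving variants per candidate gene per
individual, columns ordered by the sample table so infant and mother panels
align by duo. Top genes are ranked breadth-first — individuals affected,
then total variants, then symbol — a deterministic total order; the
breadth-first choice reflects that recurrence across patients, not depth in
one patient, is what makes a gene interesting here. The gene-size check is
the R² of an OLS fit of per-gene variant totals on coding length (equal to
the squared Pearson correlation); zero-variance counts define R² = 0. It
guards against the trivial explanation that big genes simply collect more
variants.

## The synthetic cohort generator

Defaults are the study conditions: 12 ALL and 11 AML mother–infant duos
(23 pairs) plus 12 unaffected controls; 2 000 genes with lognormal coding
lengths (log-mean 7.2, log-sd 0.6 — median ≈ 1.3 kb, a realistic coding
length scale); 5% of genes flagged as candidates; a baseline of 0.5 raw
variants per coding kb per exome, which after decoy attrition yields
roughly 500–1500 surviving variants per sample, matching the study's
per-exome range; infant enrichment multiplier 2.0 on candidate genes with
mothers at 1.5 (enriched "to a lesser degree"); transmission probability
0.5; and two planted compound-het genes, one in every infant and one in
half of them, echoing the recurrence pattern the duo design exists to
detect.

Each gene owns a catalog of variant *sites* (≈ 1 per 20 coding bases) on a
single synthetic chromosome, one million-base block per gene; coordinates
are synthetic because downstream logic only ever uses identity keys.
Site-level properties — consequence class, panel frequencies,
prediction votes — are drawn once and shared by all carriers, as real
polymorphisms are. A sample carries each site independently with
probability `λ_gene / n_sites`, making per-gene counts Binomial ≈
Poisson(λ) with λ = length_kb × rate × multiplier while guaranteeing
distinct sites within a sample. Transmitted infant variants appear verbatim
in the mother's table; the mother additionally draws her own background
variants, excluding her infant's non-maternal sites so transmission truth
is never aliased by coincidence. Quality metrics of a transmitted variant
are drawn once per duo and shared by both copies — the idealization that
makes ground-truth origin and filtered-profile attribution coincide
exactly; real duos can disagree (a site can fail QC in just one member),
which is precisely why the pipeline attributes against the mother's
*filtered* profile rather than assuming symmetric visibility.

Decoys: 15% of observations fail exactly one randomly chosen quality floor;
15% of sites are synonymous; 30% carry a panel frequency ≥ 1%; 10% are
unanimously benign; 5% have no prediction (and pass). Passing observations
draw total depth ~ Poisson(43) (the study-like average coverage), alt depth
binomial around half, GQ ~ Poisson(60) clipped to [10, 99], MQ 60.

What the generator does **not** emulate: linkage and haplotype structure,
caller-specific artifacts, population stratification, gene-class-dependent
mutation-rate variation, overlapping gene annotations, or reference-genome
context for indel left-alignment. Passing tests therefore demonstrate that
the statistics and rules are implemented correctly and are calibrated under
the stated generative model — not that the model captures every property of
real exomes.

## Validation studies and problem sizes

The `studies` module fixes the designs used by the test suite and the
reproduction script:

* **Exact-tail oracle**: every (k, K, n, N) with N ≤ 25 against integer
  enumeration, tolerance 1e−12.
* **Permutation convergence**: 200 000 `random_gene_lists` draws on a
  20-gene exome (5 candidates, 8 variant genes) against the closed-form
  Hypergeometric(20, 5, 8) pmf (±0.005 per support point) and tail (3
  Monte-Carlo SE).
* **Type-I calibration**: 2 000 null cohorts (multipliers 1.0), 1 000
  permutation iterations each — scaled down from the production 100 000 —
  rejecting at α = 0.005. The null design (1 600 genes, 320 candidates, two
  infants) was chosen by computing the exact expected rejection rate
  E_k P[Binom(1000, s_k) ≤ 4]: the empirical p of a discrete overlap
  statistic is super-uniform, and a coarse overlap grid would make the test
  visibly conservative at this α; at this design the exact rate is 0.0042.
* **Multiplier recovery**: cohorts of 12 infants and 12 controls over 400
  genes with dense site catalogs; the bootstrap (resampling individuals
  within groups) supplies the standard error of the log rate ratio, and the
  95% interval is log-symmetric with a Student-t(22) reference and the
  √(n/(n−1)) finite-sample inflation — plain percentile, BCa and
  quantile bootstrap-t intervals all measurably undercover (~92%) at a
  dozen samples per group, while this construction achieves 94–95%
  coverage; 200 replicates per multiplier.
* **Compound-het exactness**: 100 planted cohorts; pipeline calls compared
  both with the ground-truth origins and with an independent three-clause
  re-check per gene.

These sizes keep the full suite and the reproduction script in the
minutes range on a single CPU.

## Numerical and degenerate-input choices

* Hypergeometric tails clip to [0, 1]; the minimum-possible-overlap region
  returns exactly 1.0 and k above the support returns 0.0.
* Permutation sampling materializes uniform subsets via `argpartition` of
  random keys, chunked to bound memory near 160 MB at exome scale;
  identical seeds give identical draws regardless of chunking.
* Empty inputs: an empty VCF yields an empty list; an empty filter input
  yields a profile with all stage counts 0; an empty gene list, an empty
  cohort for recurrence, and fewer than 3 genes (or < 2 distinct lengths)
  for the size correlation are errors.
* Result tables are TSV with a JSON manifest (config, seed, SHA-256 of
  inputs and outputs); re-verification raises on any checksum mismatch.

## Known limitations

* Non-maternal ≠ paternal: de novo mutations are included by construction.
* The compound-het rule is unphased; two variants on the same haplotype can
  satisfy it.
* The rarity filter trusts panel frequencies as annotated; panel versions
  are carried only as `pop_afs` keys, not pinned.
* The permutation schemes weight all genes equally; a gene-length-weighted
  null is a possible extension, not implemented.
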