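# Methods

This note documents the models and procedures implemented in panelcc,
the assumptions behind them, the defaults and why they were chosen,
what the synthetic cohort does and does not emulate, and the package's
known limitations.

## Study design being modeled

A case–control burden comparison at the gene level: women with
familial breast cancer (a proband with breast cancer plus a family
history of breast/ovarian cancer), already negative for BRCA1/2,
sequenced over a 26-gene panel, compared against summed allele counts
from a large population reference (ExAC non-Finnish Europeans,
TCGA-excluded). Cases contribute per-sample variant calls; controls
contribute only per-variant AC/AN summaries. That asymmetry shapes the
whole pipeline: case-side filters (allelic ratio, call rate, kinship)
have no control-side counterpart, and control carriers are alleles,
never genotypes.

## Sample QC

Exclusion cascade, fixed precedence, one primary reason per sample:
low reads (<1,000,000) → low mean bait coverage (<20×) →
heterozygosity outlier (beyond ±3 SD of the cohort mean) → inferred
male → duplicate (kinship > 0.354) / first-degree (kinship > 0.177,
one member of each pair removed) → prior BRCA1/2-positive. The
precedence order is a package decision (the filters themselves are
standard); it is deterministic and fully logged, and the heterozygosity
mean/SD are computed on the full cohort before any removals.

*Sex inference.* Autosomal heterozygosity alone cannot prove a sample
is male, so the "male" label requires both a low-het outlier position
(> 3 SD below the mean) and ≥99% homozygosity at X-linked markers when
the panel provides them; without X markers the sample is excluded as a
heterozygosity outlier instead. This deliberately under-calls sex
rather than over-claiming it.

*Kinship.* The KING-robust identity-by-state estimator
φ = (N_het,het − 2·N_opp-hom) / (N_het(a) + N_het(b)), computed over
the pair's shared called sites. Duplicates sit near 0.5, parent–child
near 0.25, unrelated near 0. Pairs with fewer than 50 shared informative
sites are flagged unreliable and never auto-excluded. Within a flagged
pair the member with lower mean bait coverage is removed (ties broken
lexicographically by sample id) — deterministic, and it keeps the
better-sequenced sample.

*Site filters.* Alternate allelic ratio must lie in the inclusive
window [0.20, 0.80]; sites with call rate <50% are dropped. Records
with a *missing* allelic ratio are retained and flagged, never
silently dropped. The window is configurable; a narrower 30–70%
display convention exists in some summaries of this kind of data, but
the analysis window here is 20–80%.

## Variant classification

A deterministic rule composition producing a five-tier label plus two
bookkeeping buckets, each call carrying an ordered rule trace:

1. **Named low-risk alleles** (CHEK2 p.I157T, p.S428F) → LOW_RISK,
   absorbing.
2. **AF gate.** Any population source (ExAC, ESP6500, 1000G) above 3%
   → EXCLUDED, absorbing. Any source above 0.3% caps the label at
   VUS/LB/B. Named exception variants bypass both gates; the default
   exception is CHEK2 c.1100delC (population AF ≈ 0.4–0.5%), a
   well-established pathogenic founder allele that the 0.3% ceiling
   would otherwise wrongly demote — the exception must cover both
   gates for the truncating-CHEK2 burden arithmetic to be internally
   consistent. Absent sources count as frequency zero: a variant seen
   in no reference population is eligible by rarity.
3. **Loss of function** → LP: nonsense, frameshift, whole-gene
   deletion, splice at offsets ±1/±2 (canonical dinucleotide, offsets
   measured from the nearest exon boundary) — unless positioned beyond
   a configured per-gene benign-truncation boundary.
4. **ClinVar concordance** → LP for missense, deeper splice (|offset|
   ≥ 3), intronic or synonymous variants asserted P/LP by ≥2 trusted
   submitters (Ambry, Sharing Clinical Reports Project, InVitae,
   GeneDX, Emory, InSiGHT; one submitter one vote). TP53 requires only
   one trusted submitter — its pathogenic missense alleles are too
   rare to accumulate multiple assertions.
5. **Benign concordance** (symmetric package decision, since no
   explicit B/LB criterion exists in this style of pipeline): ≥2
   trusted submitters asserting B/LB with zero P/LP assertions → LB,
   or B when every such assertion is B.
6. Otherwise **VUS**; a missing consequence annotation yields VUS with
   the review flag raised.

ClinVar assertions are *inputs* (submitter, assertion pairs) — the
package never queries ClinVar, so runs are reproducible offline and
pinned to whatever snapshot produced the annotations. The second
classification methodology (a commercial ACMG-style engine) is likewise
an input column: `resolve_consensus` accepts concordant calls as final
and queues discordant ones (primary label kept, review flag raised)
rather than adjudicating. The engine emits LP for rule-derived calls;
P and LP are counted identically everywhere downstream.

Invariants enforced by tests: order independence; monotonicity
(removing pathogenic evidence or raising any population AF never
upgrades a label toward P); every P/LP call is ≤0.3% in all sources or
a named exception; LOW_RISK and EXCLUDED are absorbing.

## CNV handling

Case CNVs must be called by both read-depth algorithms (same sample,
gene and type, ≥1 shared exon); the consensus span is the
intersection. The wet-lab era's visual read-depth review is replaced
by a boolean confirm flag carried on each call. Deletions are LP when
frame-disrupting — decided from a per-gene exon-length table (summed
deleted exon lengths mod 3) — or whole-gene; whole-gene duplications
and single-exon in-frame deletions are VUS (a duplication's transcript
effect is not resolvable from depth alone). Control-population CNVs
are kept only when single-gene, ≥2 exons, and outside
repetitive/pseudogene regions, mirroring what is assessable in the
case data. No control CNV odds ratios are computed: the reference
dataset's CNV-assessable denominator is not defined.

## Carrier and allele bookkeeping

Carriers are modeled heterozygous (the analyzed variants are
heterozygous calls); each carrier contributes one alternate allele.
An apparently homozygous call (allelic ratio > 0.95) triggers a
warning rather than silent double-counting. Per-gene rules:

* `n_carriers(g)` counts distinct samples with ≥1 P/LP event in g;
  double carriers (P/LP in two different genes) appear in both genes'
  counts but once in the overall total.
* `case_AC(g) = n_carriers(g) − |CNV carriers(g) ∪ double carriers(g)|`
  — CNV events are not allele-countable against an SNV/indel control
  table, and double carriers are excluded from the allele-based
  comparison.
* `case_AN = 2·N_cohort − excluded alleles`. The exclusion count is an
  explicit parameter; the default removes one allele per CNV-carrying
  case, the only reading consistent with the arithmetic this pipeline
  is built to reproduce (2·2134 − 14 = 4254).
* The truncating subset of a gene (used for CHEK2, whose missense
  burden is not comparable) counts indel/nonsense + splicing events
  only, minus its own double carriers.
* Group rates are sums of member-gene carrier counts over cohort size
  (so a within-group double carrier contributes to two member genes) —
  matching how such spectrum tables are conventionally printed.
* Monoallelic MUTYH and the named low-risk alleles are tallied apart
  from the breast-cancer-gene totals.

## Case–control statistics

*Fisher test.* Two-sided minimum-likelihood form: with margins fixed,
p = Σ P(X=k) over every table in the hypergeometric support whose
probability is ≤ the observed table's, with a 1e-7 relative tolerance
absorbing floating-point ties; when the rule includes the entire
support, p is snapped to exactly 1. Degenerate margins give p = 1.
The implementation sums `scipy.stats.hypergeom` pmf values over the
(always small) support; tests verify exact equality against an
independent integer-arithmetic enumeration oracle for all tables with
grand total ≤ 24 plus thousands of sampled tables up to total 60, and
cross-check `scipy.stats.fisher_exact` at study-scale margins.

*Odds ratio.* Default point estimate is the unconditional
cross-product ad/bc — the estimator that reproduces published
gene-panel ORs at printed precision. The conditional MLE (maximizer of
the noncentral hypergeometric likelihood, via
`scipy.stats.contingency.odds_ratio`) is available and verified
against a golden-section oracle. A zero control AC yields an open
upper bound (∞); two zero ACs yield an undefined OR, flagged.

*Confidence interval.* Default is the exact conditional (Cornfield)
interval, inverting noncentral hypergeometric tails at 2.5% per side;
Woolf's log-OR ± 1.96·√(Σ 1/cell) is the alternative (Haldane 0.5
correction when a cell is zero so the finite side stays computable).
Printed CIs in the literature rarely name their method, so agreement
is asserted as containment/overlap, not equality.

*ExAC allele numbers.* The control AN for a gene is the arithmetic
mean (nearest integer) of per-variant allele numbers over its counted
mutation sites; dividing by two gives the carrier-scale control
denominator (≈26,375 individuals at AN ≈ 52,750).

*Multiple testing.* Significance is reported at both the corrected
threshold p < 0.002 (≈ 0.05/26 genes) and nominal 0.05.

*Power.* Monte-Carlo, at the person level ("carrier rate" semantics):
per replicate, case carriers ~ Binomial(n_case, RR·p0) and control
carriers ~ Binomial(n_control, p0), the same Fisher test applied to
each 2×2, power = rejection fraction ± binomial MC error. Simulation
is used rather than a closed form because the claim concerns the exact
test itself. At RR = 1 the attained level is *below* α (~0.02–0.03 at
rare margins): Fisher's exact test is conservative on discrete
supports, so validity (level ≤ α), not equality to α, is the property
asserted.

## The synthetic cohort

The generator exists because no patient-level data of this kind can be
deposited; it emulates the *statistical structure* of the study:

* 2266 enrolled samples; planted QC failures (15 low-read, 10
  low-coverage, 6 inbred-like low-het, 4 contamination-like high-het,
  8 males, 6 duplicate pairs, 6 first-degree pairs = 55 removals,
  61 failure flags counting both members of kinship pairs) leaving
  2211, then 77 planted BRCA-positive samples, leaving 2134.
* QC genotypes at 1000 polymorphic sites (700 autosomal + 300
  X-linked, allele frequencies U(0.2, 0.5), 1% missingness). The site
  count and X fraction are chosen so every planted outlier class
  separates from the null by construction (males sit ≈8 base-SDs below
  the mean, ≈3.7 SDs after outlier-inflated variance) while natural
  samples essentially never cross the ±3 SD cut; first-degree kinship
  at these sites resolves ≈5 SDs above the 0.177 threshold.
* A per-gene mutation spectrum planted exactly (carrier counts and
  type breakdown per gene, six double carriers with fixed gene pairs,
  14 CNV events of which 12 are pathogenic), embedded in a corpus of
  2859 unique variants of which 114 (4.0%) satisfy the P/LP rules —
  recurrence pools (CHEK2 c.1100delC carried by 12 samples;
  founder-style recurrent alleles in ATM, PALB2, MUTYH) map the 169
  SNV/indel mutation events onto 114 unique variants.
* An ExAC-style control table whose per-gene pathogenic AC and AN
  match the planted study conditions exactly (AN jitter is symmetric
  within each mutation-type group so every subset average is exact),
  plus ~9,300 VUS/benign background rows; control rows are labeled by
  running the same rule engine on their annotations.
* Planted artifacts: calls with allelic ratios outside 20–80% and
  low-call-rate sites, which the site filters must remove.
* Carrier allelic ratios are Beta(60,60) clipped to [0.25, 0.75] — a
  tight heterozygous cloud that cannot collide with the filter window,
  so planted counts survive filtering exactly.

Determinism: one master seed; each component draws from
`numpy.random.default_rng([seed, stream])` with fixed stream offsets,
so outputs are byte-identical under (config, seed) and components stay
independent. A `binomial` composition mode draws carrier counts
binomially from (OR, control frequency) pairs instead of planting
exact counts; it backs the parameter-recovery harness.

What the generator does **not** emulate — and therefore what passing
tests do not show about real data: linkage and haplotype structure
(variants are assigned independently), sequencing error processes
(artifacts are planted, not emergent), population stratification and
ancestry mismatch between cases and controls, variant-calling biases
shared between arms, and pedigree structure beyond single
duplicate/parent–child pairs. Reproducing the planted arithmetic
validates the bookkeeping and inference machinery, not the biology.

## Numerical choices and degenerate inputs

* Fisher tie tolerance 1e-7 (relative); whole-support inclusion snaps
  to p = 1; p capped at 1.
* Exact-CI inversion via scipy's conditional odds-ratio machinery;
  recovery harness caches per-table results (binomial draws collide
  heavily at rare counts).
* Mean AN rounding: nearest integer (banker's rounding at exact .5,
  which cannot occur with the symmetric jitter used).
* Empty genotype vectors → metrics marked unknown, never zero.
* Empty control table / missing gene → control AC 0 with a warning and
  the table-wide average AN, flagged in the result.
* derive_case_AN rejects negative allele numbers; tally rejects
  duplicate (sample, variant) keys outright.

## Calibration findings

Measured by the recovery harness at study-scale margins (2134 vs
26,375 persons): at a 0.1% control carrier rate the expected case
carrier count under the null is ≈2, and *any* exact interval
over-covers by construction (exact conditional ≈0.99, mid-p ≈0.98) —
discreteness, not miscalibration. At the panel's moderate-frequency
genes (carrier rates 0.67–1.5%, as for truncating CHEK2, FANCM,
MUTYH) exact-conditional coverage is nominal (0.94–0.97 at 500
replicates), which is where the coverage calibration is asserted. At
OR = 4 and 0.1% control frequency the median unconditional OR estimate
is ≈4.0, Haldane-corrected log-OR bias ≈−0.01, and detection rate
≈0.83 — consistent with the design's >80% power claim (85.4% at 2000
replicates).

## Limitations

* Exact conditional CIs are conservative for ultra-rare genes (see
  above); reported intervals there are wide and their coverage exceeds
  95%.
* The age-at-diagnosis contrast uses Welch's t by choice; with ~11
  carriers its power at the 1% level is only ≈0.6 even for a 9-year
  shift, so non-significant age contrasts in small carrier groups are
  weak evidence of absence.
* The allele-based 2×2 treats control carriers as independent alleles;
  with maximum per-gene control AF ≈0.8% the distinction from a
  person-level model is negligible but not zero.
* Consequence annotation, transcript choice and ClinVar snapshot are
  upstream inputs; the package classifies what it is given.
* No covariate adjustment, ancestry matching, or aggregated burden
  testing beyond per-gene carrier counts.
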