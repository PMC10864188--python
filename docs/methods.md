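# Methods

This note documents the models, rules and numerical choices behind
`pamlcat`, and what the synthetic-data tests do and do not demonstrate.

## Screening rules and boundary semantics

The tumor-only somatic screen keeps a variant only if **all** of the
following hold: the gene is on the screening panel; the pathogenicity
annotation is pathogenic or likely pathogenic; population allele
frequency ≤ 0.001; the exact allele (chrom, pos, ref, alt) occurs in
≤ 5% of cohort cases; supporting reads > 5; VAF > 5%. Boundary semantics
are deliberate and asymmetric: the read-support and VAF rules filter
*inclusively* ("≤ 5 reads", "≤ 5%" are removed), whereas the UBTF
detector's "≥ 3 supporting reads", the soft-clip "≥ 10 bases", germline
coverage "≥ 20/≥ 15", the germline SNV VAF window [0.2, 0.8] and the
fingerprint "≥ 90%" all keep inclusively. Every removed record carries
the identifiers of all rules that fired, so decisions are auditable and
re-orderable.

The cohort-recurrence rule is applied to putatively pathogenic
candidates keyed by exact allele, with the cohort size as denominator.
When a subset of calls is re-screened, the caller should pass the
original cohort size (`n_cases=`) so recurrence keeps its meaning; under
a fixed denominator the filter is idempotent, and tightening any
threshold can only shrink the kept set (property-tested).

The UBTF tandem-duplication detector approximates "exon 13 or adjacent
introns" by a configurable ±500 bp window around the GRCh37 hotspot
chr17:42,288,162–42,288,192, because exact exon coordinates depend on
the annotation build. A positive call combines two independently
reported evidence channels — a retained caller candidate (reads ≥ 3,
score < 10, interval overlapping the window) **or** at least three reads
soft-clipped by ≥ 10 bases inside the hotspot — since either alone is
diagnostic in practice and both are reported separately for review.

## Allele-specific expression

With paired WGS, markers heterozygous in the genome (0.2 ≤ VAF ≤ 0.8)
and covered ≥ 10× in RNA are tested with an exact two-sided binomial
test at success probability 0.5; two-sidedness follows the
minimum-likelihood convention (sum of all outcome probabilities no
larger than the observed outcome's), which is symmetric at p = 0.5 and
matches mainstream exact-test implementations. The locus verdict is the
median of the per-marker p-values; the positivity cut (median p < 0.05)
is a package choice — the underlying procedure only prescribes the
median summary — and is exposed as `alpha`. In RNA-only mode a locus is
*supported* when every marker with ≥ 10× coverage has RNA VAF ≤ 0.2 or
≥ 0.8; `min_imbalanced_fraction` relaxes the "every" to a fraction. An
empty eligible-marker set yields `indeterminate`, which downstream code
treats as absence of evidence, not as a negative.

## Expression processing

Counts are filtered (cpm ≥ 10 in ≥ 5 samples) and transformed to
log2(cpm) with values below zero floored at zero; zero counts map to
exactly zero, so the transformed matrix is non-negative. Variable genes
are ranked by plain log2-cpm variance with a lexicographic tie-break —
a deliberate simplification of variance-stabilizing selection, which
changes at most the tail of the ranking. Signature scores are means of
per-gene z-scores (population SD across samples; zero-variance genes
contribute 0). Differential expression uses a per-gene Welch t-test on
log2-cpm with BH adjustment rather than a moderated linear model; the
significance thresholds (|fold change| > 2 on the cpm scale, FDR < 0.05)
are unchanged, and for the well-separated two-group comparisons this
package targets the two approaches agree.

HOX superfamily assignment replaces embedding-based clustering with
transparent signature thresholds: HOXA group = HOXA-signature score
≥ 0.5 and HOXB-signature score ≤ 0; HOXB group = both scores ≥ 0.5
(biologically, HOXB-group leukemias express both HOX clusters). The
shipped signatures are HOXA9/HOXA10/MEIS1 and HOXB2–HOXB5. For users
who wish to reproduce the original embedding externally, the reference
parameters were: top 315 variable genes, 100 principal components, UMAP
n_neighbors = 12, min_dist = 0.2, Louvain resolution 3.5.

## The category registry

The shipped registry defines 23 mutually exclusive categories — 11
WHO-defined (APL, RUNX1::RUNX1T1, CBFB::MYH11, DEK::NUP214,
RBM15::MRTFA, BCR::ABL1, KMT2Ar, MECOM, NUP98r, NPM1, CEBPA) and 12
others (UBTF, GLISr, FET::ETS, BCL11B, PICALM::MLLT10, KAT6Ar, MNX1,
RUNX1::RUNX1T1-like, CBFB-GDXY, GATA1, HOXr, KMT2A-PTD) — with
`Unclassified` as fallback. Rules are evaluated in (tier, registry
order); the first match labels the case and all later matches become
notes, making mutual exclusivity structural rather than statistical.

Decisions embedded in the registry:

* NPM1 fusions and NPM1 indels (C-terminal or not) all map to the NPM1
  category; TBL1XR1::RARB maps to APL. Both reflect expression
  similarity of these rare variants to the canonical entities.
* CEBPA accepts any pathogenic CEBPA mutation; restricting to bZIP
  in-frame variants is a registry edit away (the shipped rule matches
  the broader definition).
* Family patterns are configuration, not code: NUP98r and KMT2Ar accept
  any partner; GLIS = {GLIS2, GLIS3}; FET::ETS = {FUS, EWSR1} ×
  {ERG, FEV, FLI1}; RUNX1::RUNX1T1-like = RUNX1 × {CBFA2T2, CBFA2T3};
  HOXr matches any HOX-cluster gene by symbol prefix.
* Tier-3 categories (MECOM, BCL11B, MNX1) require *both* an SV at the
  locus and expression corroboration (ASE positive or outlier z ≥ 3),
  because the SV alone does not establish enhancer hijacking.
* Tier-4 categories pass an expression-consistency gate: KMT2A-PTD
  requires the HOXB signature (≥ 0.5), HOXr either HOX signature, GATA1
  a megakaryocytic marker signature (PF4/ITGA2B/GP9). The gate stands
  in for cluster-proximity checks that cannot be reproduced from text.
* Myelodysplasia-related mutations (ASXL1, BCOR, EZH2, SF3B1, SRSF2,
  STAG2, U2AF1, ZRSR2) and complex karyotype/monosomy 7 never classify;
  they are annotated onto results because they do not drive consistent
  expression patterns in pAML.
* Two defining fusions in one case resolve by registry order with a
  mandatory conflict note; such co-occurrence is rare and a reviewer
  should see it.

The registry round-trips through YAML (`registry_to_yaml` /
`registry_from_yaml`) for site-specific editing, and `registry_lint`
checks label uniqueness, tier sanity and pattern syntax.

## Co-occurrence statistics

Two-sided Fisher's exact tests use the minimum-likelihood rule (the
convention of mainstream statistical software). BH adjustment is applied
across the full category × alteration grid by default; `family=
"per_alteration"` switches to per-column families, since the appropriate
family is a judgment call. Degenerate margins give p = 1.

## Survival framework

Kaplan–Meier uses the product-limit estimator with the standard
events-before-censoring tie convention and Greenwood variance. The
k-sample log-rank test uses the hypergeometric (tie-corrected) variance
and a chi-square reference with k−1 degrees of freedom.

Risk partitioning is a greedy instantiation of recursive partitioning
for censored data: categories are ordered by Nelson–Aalen cumulative
hazard evaluated at the pooled median follow-up time (ties broken by
name, making the fit deterministic and order-independent); candidate
binary splits respect that order; each step takes the split maximizing
the two-sample log-rank statistic subject to a minimum node size (20)
and a complexity threshold (statistic ≥ 6.63, i.e. chi-square(1) at
p ≈ 0.01), until three leaves exist. Leaves are ranked by exponential
hazard into low/intermediate/high. The original analysis used an
rpart-style exponential-scaling CART; both procedures produce
hazard-ordered groupings on well-separated data, which is the regime the
category-level problem lives in. A configured default risk map is also
shipped (low: RUNX1::RUNX1T1, CBFB::MYH11, CEBPA, DEK::NUP214, MNX1,
RUNX1::RUNX1T1-like, CBFB-GDXY; high: GLISr, MECOM, PICALM::MLLT10,
KAT6Ar, UBTF; all others, including Unclassified, intermediate) with
provenance marked `configured`, since the fitted leaf membership is
cohort-dependent.

The six risk strata cross {low, intermediate, high} with MRD status;
cases lacking MRD are excluded and reported, mirroring analyses
restricted to patients with available MRD. EFS events are relapse, death
in remission and nonresponse, the last encoded at time zero. Harrell's C
treats a pair as usable when the shorter observed time is an event, with
tied scores counting one half; bootstrap intervals resample patients
with replacement (default 1,000 replicates) and use the 2.5/97.5
percentiles, for C values and for pairwise differences between systems.
Cox modelling is out of scope; C is computed directly from ordinal risk
scores.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with every draw from one seeded NumPy generator (fixed seed ⇒ identical
output, byte-for-byte through the writers).

* **Categories** are drawn from a configurable frequency table whose
  defaults approximate the published cohort makeup (KMT2Ar 20.3%,
  RUNX1::RUNX1T1 12.4%, NPM1 7.6%, CEBPA 5.5%, …, Unclassified 9.2%).
* **Defining evidence** is emitted per category — fusion records,
  pathogenic mutations, tandem-duplication candidates above the
  detector thresholds, or a DNA SV plus skewed ASE markers (allele
  fraction 0.9) and a 32-fold marker-gene expression shift. Hotspot
  mutation alleles are spread over 20 nearby positions so that no exact
  allele recurs in > 5% of cases, mirroring real hotspot allele
  diversity; otherwise the recurrence filter would correctly remove the
  planted truth. A generator invariant, enforced by tests: planted
  defining evidence always passes the corresponding screens.
* **Cooperating mutations** follow category-conditional probabilities:
  FLT3-ITD 0.60 in NUP98r/NPM1/UBTF/KMT2A-PTD/BCL11B vs 0.05 baseline;
  WT1 0.40 in NUP98r/UBTF/BCL11B vs 0.03; KRAS 0.30 in
  KMT2Ar/KAT6Ar/HOXr vs 0.04; NRAS 0.18 broadly.
* **Expression** is negative-binomial (dispersion 10) over ~165 genes:
  HOXA/HOXB signature blocks, the MECOM/BCL11B/MNX1 markers, a
  megakaryocytic block, 150 filler genes with log-normal baselines and
  five near-zero genes to exercise the expressed-gene filter. Signature
  baselines use mean 20 so that zero counts are rare — with a low
  baseline the log2-cpm zero-floor makes the baseline bimodal and a
  planted shift stops being a z ≥ 3 outlier. Library sizes vary
  log-normally (σ = 0.2).
* **Survival** is exponential per stratum with uniform censoring over
  10 years. The default hazard ladder (low/MRD− 0.03, low/MRD+ 0.08,
  int/MRD− 0.15, int/MRD+ 0.28, high/MRD− 0.50, high/MRD+ 0.90 per
  year) is deliberately well separated so the six strata are ordered by
  construction; survival checks run at n = 2,000 so that the smallest
  stratum (low/MRD+) carries enough events for the ordering to be
  stable, and use the event-rate (exponential MLE) summary, which is the
  sufficient statistic under this model. MRD positivity is 0.15/0.30/
  0.45 by risk group and missing in 5% of cases.
* **The ambiguity injector** adds a lower-tier alteration (NPM1 indel,
  CEBPA mutation or KMT2A-PTD) to a random subset of tier-1
  fusion-defined cases; the expected resolution is always the original
  defining alteration. HOXr cases are not injection targets because
  their own rule is conditional (tier 4) and would legitimately lose to
  injected tier-2 evidence.

**What passing tests show — and do not.** The generator's separations
are chosen for testability: defining evidence is noise-free above
threshold, signature shifts are large, and hazards are well spaced.
Recovery rates near 100% therefore validate the *correctness of the
rules and statistics*, not their sensitivity on real data, where
evidence is noisier, categories blur at cluster boundaries, and batch
effects (not simulated — the synthetic data is batch-free) matter.
Per-category enrichment power is a real constraint the simulation makes
visible: categories at 1–2% frequency cannot individually reach q < 0.05
against a cohort-wide baseline at n = 500, which is why planted
enrichment recovery is asserted at the HOX-superfamily level plus every
adequately powered per-category cell (expected ≥ 12 carriers).

## Numerical choices

* Percentages round half-up to one decimal (`percent`), matching the
  reporting convention of the source counts.
* Hypergeometric and binomial tail computations are delegated to SciPy
  (log-space internals, overflow-safe); package-level enumeration
  oracles in the test suite verify them to 1e-7 relative (Fisher, all
  2×2 tables with total ≤ 40) and 1e-12 absolute (binomial, coverage
  ≤ 25).
* Kaplan–Meier agrees with an independent survival library to 1e-10 on
  random fixtures; log-rank and Harrell's C agree to machine precision.
* Degenerate inputs: zero-margin Fisher tables give p = 1; zero-variance
  genes give z = 0 (signature) or a warned `False` (outlier flag);
  all-censored KM is identically 1; an empty eligible ASE marker set is
  `indeterminate`; the partition warns and returns fewer groups when no
  split beats the complexity threshold or there are fewer categories
  than leaves.

## Known limitations

* Pathogenicity, consequence annotation, alignment, and raw fusion/SV
  calling are consumed as inputs, never computed.
* The variable-gene and DE methods are simplified relative to
  variance-stabilizing selection and moderated linear models; the HOX
  grouping is threshold-based rather than cluster-based.
* The shipped gene panels are editable defaults, not the full curated
  panels, and the configured risk map is figure-informed rather than
  fitted to trial data.
* Batch correction, embedding methods, gene-set and network analyses,
  stemness/hierarchy scores, ancestry inference and multivariate Cox
  modelling are out of scope.
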