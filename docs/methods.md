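# Methods

## The discrepancy score

HLA genes are typed as unordered diploid allele pairs. Every known allele of
a gene has a cDNA sequence in the IPD-IMGT/HLA catalogue, so a candidate pair
(HLA₁, HLA₂) determines, at each biallelic exonic SNP marker, an expected
genotype: both alleles carry the marker's alleleA nucleotide (HOM_A), both
carry alleleB (HOM_B), or one each (HET). Sequences are projected onto the
chip strand (reverse-strand genes are complemented) before this comparison,
so the expected genotype is directly comparable with chip or imputation
output.

Given an individual's genotype posteriors (p_AA, p_AB, p_BB) at a marker, the
per-marker discrepancy of a pair is the posterior mass inconsistent with it:

    s = 1 − p(expected genotype),   s ∈ [0, 1].

Two degenerate cases complete the definition:

* **Impossible** — a known base outside {alleleA, alleleB} (the database
  allele carries a third nucleotide at the chip marker). No mass can match:
  s = 1. This is meaningful, not an error.
* **Undefined** — either allele's base unknown at the marker (many catalogue
  alleles are sequenced only over exons 2–3). The marker is excluded for that
  pair and does not count toward the markers used.

The pair's score is the plain sum over usable markers,

    D(genome, HLA₁, HLA₂) = Σ_rs s(rs),        0 ≤ D ≤ n_used,

and the quantity reported for an attributed pair is the gap to the best
achievable pair over the *entire* database,

    ΔD = D(attributed) − min over all n(n+1)/2 pairs of D.

ΔD = 0 means no pair fits the genotype better than the attributed one. The
sum is used rather than the product-of-probabilities combiner Σ log(1 − s):
a single badly imputed marker drives log(1 − s) to −∞ and dominates the
score, whereas the sum caps any one marker's influence at 1.

Posterior triplets may sum to less than 1 (imputation output permits this);
the missing mass simply counts as disagreement. We do not renormalize, and
we do not normalize D by n_used when different pairs are scored over
different marker subsets — the score is a bare sum by definition.

## Exhaustive search

All unordered pairs, homozygous included, are enumerated; this is required
semantics, and the vectorized implementation is asserted equal to a naive
double loop in the test suite (exact minimum and the full argmin set, ties
at |D − D_min| ≤ 1e−9). Even the most polymorphic real gene (~100 alleles →
~5,000 pairs × ~120 markers) is a desk-scale computation, well under a
second per individual.

Alleles whose base is known at fewer than half the markers are excluded from
the search by default (`min_coverage = 0.5`): a pair scored over a small
marker subset wins spurious ties against fully characterized pairs. The
attributed pair itself is always scored, whatever its coverage.

## Cutoff calibration

Flagging uses a normal model: fit μ and σ (sample mean and SD, ddof = 1) to
a sample of ΔD values and flag individuals with ΔD strictly greater than
μ + 2σ — the ~2.28% upper tail if the sample really is normal. Two choices
of sample are implemented:

* **cohort** (default): the ΔD values of the cohort's own attributed
  assignments. This is an outlier rule on the observed distribution; on a
  mostly-correct cohort μ sits near 0, wrong assignments inflate σ, and the
  cutoff lands a little above the correct cluster. This mode reproduces the
  regime in which per-gene cutoffs round to small integers (2 for HLA-A and
  HLA-C, 7 for the more polymorphic HLA-B against ~118 exonic markers) and a
  few percent of a cohort is removed, part of it correctly typed — which is
  what published filtering tallies look like.
* **shuffled**: ΔD of assignments permuted uniformly between individuals
  (pairs kept intact; the genotypes untouched), pooled over `n_shuffles`
  permutations (default 10) with a recorded seed. This null describes how
  *random* pairs score and is the right diagnostic for showing real and
  shuffled assignments separate (the histogram-overlay comparison). As a
  cutoff source it is deliberately conservative: it can only flag
  individuals scoring worse than random pairs typically do, so a cutoff at
  its μ + 2σ catches almost none of the assignments that are merely wrong
  rather than extreme. It is provided, but not the default, for exactly that
  reason.

Cutoff rounding to the nearest integer is available behind a flag and off by
default. Calibration requires at least two distinct pairs in the cohort; a
cohort typed with one pair throughout carries no signal and raises.

An assignment that cannot be scored at all — an attributed allele absent
from the database, or no usable marker — is flagged, not crashed on:
unverifiability is itself implausibility. ΔD exactly at the cutoff is kept
(strict inequality).

## Accuracy evaluation

Imputed alleles arrive as binary presence/absence markers with posterior
dosages in [0, 2]. An allele is called with one copy for dosage in
(0.5, 1.5] and two copies above 1.5; an individual is *called* only when
exactly two copies result. Accuracy is counted per allele, not per
individual: each called individual contributes its two called alleles,
matched against the two true alleles as multisets after truncating names to
the requested resolution (one or two fields), so a wrong homozygous call
cannot double-count a single true allele. Uncalled individuals leave the
denominator; individuals without truth are excluded with a warning.

The filtering evaluation reports accuracy on all called individuals, the
number removed by the cutoff with the fraction of removed alleles that were
actually correct, and accuracy on the kept subset — the
base / removed / sub-population layout.

Typed (gold-standard) cohorts can be pre-filtered with the same machinery
before they are used as imputation truth, reported as a removed/total tally
per gene.

## The synthetic generator

No public cohort couples SNP posteriors with gold-standard HLA typing, so
the contracts are exercised on generated data with known ground truth:

* **Allele table** — each of `n_markers` markers gets two distinct
  nucleotides; each of `n_alleles` alleles carries one of them, masked to
  unknown with probability `unknown_rate`. Tables are rejection-sampled
  until every allele pair differs at ≥ 1 mutually known marker (bounded
  retries, then an explicit error), so the search problem is identifiable.
* **Cohort** — true pairs are Hardy–Weinberg draws (two independent alleles)
  from the frequency spectrum; by default a geometric decay with ratio 0.7,
  since a handful of common alleles dominates each real HLA gene. At each
  marker the posterior puts mass 1 − e on the implied genotype and e/2 on
  each other genotype; a marker where the (masked) table leaves the true
  genotype undefined is omitted for that individual rather than invented.
* **Corruption** — a Bernoulli(`corrupt_frac`) subset of individuals has its
  recorded pair replaced by a uniform draw from the pairs at
  ≥ `corrupt_min_distance` markers from the truth (distance = markers with
  differing, defined implied genotypes). The corrupted id set is returned as
  ground truth for sensitivity/specificity measurement.

Defaults are fixed study conditions, not tuning knobs: 300 individuals, 10
alleles × 20 markers, unknown_rate 0, noise e = 0.1, 5% corrupted at
distance ≥ 3, seed 0. Under these conditions a clean individual's ΔD is
exactly 0 (the true pair stays the unique argmin for e < 0.5 with all bases
known) while a corrupted pair gains roughly (1 − 3e/2) per differing marker,
so the cohort-calibrated cutoff separates the two groups cleanly.

What the generator does **not** emulate: linkage-disequilibrium structure in
the imputation error (noise is symmetric and independent across markers),
population structure, real allele-sequence similarity (bases are
independent coin flips, so synthetic alleles are farther apart than real
ones), and missing markers. Passing tests therefore demonstrate the
contracts — scoring, search, calibration, bookkeeping — not field accuracy
on any particular panel.

## Numerical and design choices

* Per-marker s clamped to [0, 1]; D symmetric in pair order and additive
  over disjoint marker sets (both property-tested).
* Indel columns in the cDNA alignment: columns where the *reference* has the
  indel placeholder leave the coordinate frame entirely (alleles' inserted
  bases are discarded); an allele's placeholder at a kept reference position
  is a deletion and becomes unknown. The method is defined only over SNP
  markers, so indels carry no signal here.
* cDNA coordinates are 1-based in the gapless reference frame after indel
  columns are removed; the marker file is the single source of truth for
  which positions are used (exon-2/3 subsetting is a property of the marker
  panel, not of the parser).
* Name collapsing to one/two fields takes, within each truncated-name group,
  the member with the lexicographically smallest full name as representative
  (conventionally the ":01" allele that defines the group's protein). The
  reconciliation of four-field catalogue names with two-field panel typings
  is a genuine open choice; this one is deterministic and conventional.
* Missing markers for an individual are skipped for *all* pairs, keeping the
  pair comparison on a common marker set per individual.
* A zero-usable-marker pair scores NaN with an explicit status, never a
  silent 0.
* The estimator (`HlaCheck`) follows the scikit-learn outlier-detection
  convention: `score_samples` returns −ΔD (lower = more anomalous),
  `decision_function` subtracts the offset −cutoff, `predict` returns
  +1/−1. A sample is one (genotypes, attributed pair) tuple.

## Known limitations

* Unphased, single-gene scoring only; no joint multi-gene model and no
  allele *calling* from D itself.
* Genes with few exonic markers or heavy paralogy (the DRB1 situation) give
  overlapping real/null ΔD distributions; the score cannot help there, and
  the shuffled-null diagnostic is how you detect that regime.
* Because different pairs may be scored over different marker subsets when
  the catalogue is incomplete, D values are comparable within an individual
  but only approximately across pairs with very different coverage; the
  min-coverage filter bounds, but does not eliminate, this effect.
* The GEN triplet dialect is the only posterior input format (no BGEN, no
  VCF GP field); converters are out of scope.
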