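# Methods

## Imputation Quality Score

The IQS of a set of imputed genotypes against hard truth calls is Cohen's
kappa on a 3×3 truth × imputed table. Two readings of "concordance with the
posterior probabilities" are possible: score only the best-guess genotype,
or credit the full posterior trio. The default here is the posterior-
weighted reading — cell *(j, k)* accumulates the trio probability of
genotype *k* over genotypes whose truth call is *j*, so row sums equal the
truth genotype counts exactly while columns are fractional — because it
uses all of the information the imputation emits and penalises
overconfident wrong calls continuously. A hard-call mode
(`hard_calls=True`, trios collapsed to point masses on the argmax with ties
broken toward the smaller genotype code) is provided for cross-checks; the
two agree exactly on point-mass inputs.

From the table, `P_o` is the diagonal mass over *N* and
`P_c = Σ_j row_j · col_j / N²`; `IQS = (P_o − P_c)/(1 − P_c)`. When
`1 − P_c < 1e-12` (e.g. a monomorphic stratum predicted constantly) the
score is returned as a *flagged undefined* value, never 0 or 1:
substituting a number would bias per-region summaries. Downstream
consumers either drop undefined strata (default) or carry them as missing.
Pooling strata is exact: the table of a pooled stratum is the cell-wise
sum of the member tables (kappa itself is not linear, and no claim is made
that pooled IQS lies between per-stratum scores).

Missing genotypes — a missing trio, or a missing truth call — are excluded
from the table rather than imputed as uniform, keeping denominators honest.
MAF used for rare/common binning (threshold 0.01) is always computed from
the truth calls, never from imputed dosages. Region scoring assigns a
variant to *every* region containing its position; overlapping regions
therefore double-count genotypes by design.

## Hybrid merging

Two runs are merged per genotype: retain trio A iff
`p_max(A) > p_max(B) + δ` (strict), else the priority trio B; δ defaults
to 0.05 and priority to the B (server) run. The margin exists because
different imputation programs systematically inflate maxima relative to
one another by ~1e-2, where switching gains nothing; both δ and the
priority side are configurable since the margin is an empirical choice.
Selection is per genotype, not per variant — two individuals at one
variant may draw from different runs. The retained trio is copied
verbatim, never blended; dosage (`p1 + 2·p2`) and the hard call are
recomputed from it. Variants imputed by a single run pass through
unconditionally, so the merged set is the union of the two variant sets.

Concordance labels: Accord iff both argmax genotypes agree (ties toward
the smaller code), Discord otherwise, n/a if either trio is missing. The
per-individual report gives the Accord fraction, the correct-call fraction
within each set for each source and for the merge, and IQS restricted to
each set.

Variant identity is the exact tuple (chrom, pos, ref, alt). Ref/alt-swap
reconciliation (matching A's `(ref, alt)` to B's `(alt, ref)` and
reversing B's trio to `(p2, p1, p0)`) is opt-in; strand flips are never
attempted because they are ambiguous for A/T and C/G variants.

## Consensus switch-error rate

K phasings of identical genotypes from K random seeds are compared on the
relative phase of *adjacent* heterozygous site pairs — the standard
switch-error convention, which counts a long-range switch once at its
boundary. The orientation held by the majority of replicates is taken as
correct; each replicate's SER is its disagreement fraction against that
consensus, and the per-individual estimate is the mean over replicates.
K must be odd (≥ 3) so the majority among full votes is strict; ties can
only arise when replicate-level exclusions (unphased genotypes) leave an
even vote count, and such pairs are dropped and counted. Replicates that
disagree on genotype *content* are a hard error — phasing must not change
genotypes. A truth-based SER over known haplotypes is included as the
validation oracle: for per-pair flip rates s < 0.5 and K = 21 the
consensus recovers the truth orientation for ≥ 99.9% of pairs, so the
consensus SER is an almost unbiased estimate of s; at s ≥ 0.5 the
consensus breaks down, and the simulator refuses such rates.

## IBD aggregation

Totals and coverage follow different contracts. For sharing matrices,
per target individual and reference cluster the genetic lengths of all
segments to cluster members are *summed* (each segment once; overlaps are
not deduplicated — total sharing, not coverage), split at 3 cM
(`> 3` long, `≤ 3` short, so `all = long + short` cell-wise by
construction); the matrix cell is the mean of these totals over the target
group's individuals, with segment-free individuals contributing zeros —
omitting them would inflate group means toward active sharers. For dosage
stratification, an individual's long segments to a chosen reference set
are *merged* by physical overlap into per-chromosome intervals (coverage
semantics) and used as the genotype-level inside/outside mask. Haplotype
indices in segment files are carried for provenance but ignored by both
aggregations: segments are treated as person-pair events. Segment files
must carry the genetic length column; no genetic map is interpolated.

## Simulation model

Truth genotypes are i.i.d. Hardy–Weinberg draws per variant:
`P(0,1,2) = ((1−f)², 2f(1−f), f²)` with `f` from a configurable spectrum —
default 40% rare variants (MAF uniform on [0.002, 0.01)) and 60% common
(uniform on [0.01, 0.5]), 3,000 variants × 120 individuals in two groups
of 60. Variants are independent (no LD): every contract exercised by the
toolkit is marginal per genotype or per adjacent het pair, so LD would add
cost without adding test coverage.

Imputed posteriors: per genotype, with probability *a* — looked up by
strategy, MAF bin and sample group — the argmax is the true genotype;
otherwise it is drawn among the other two genotypes proportional to their
HWE priors. The miscall distribution matters: drawing wrong calls from the
HWE priors makes the imputed margin match the truth margin, which pins the
IQS of an accuracy-free run at exactly zero in expectation. That identity
(`P_o = P_c`) holds at a *fixed* allele frequency; pooling chance-level
genotypes across a frequency spectrum correlates the margins through `f`
and yields a positive pooled kappa, so the chance-level control is run at
a point-mass MAF. Trios put `p_top` on the argmax and split the remainder
over the other two genotypes proportional to their priors. With the
calibration switch on (default), `p_top = a` exactly, so confidence equals
realized correctness — the regime in which most-confident voting is
near-optimal; calibrated accuracies must exceed 0.5 so the nominal argmax
is genuinely the trio maximum. Uncalibrated trios use a fixed
concentration (default 0.9) regardless of *a*, for probing the rule's
behaviour under miscalibration.

Default accuracy table ("the benchmark scenario"): the `ssp` strategy
(local panel covering the `west` group) scores 0.97/0.96 (rare/common) for
`west` and 0.80/0.90 for `east`; the `server` strategy scores 0.85/0.97
everywhere. The local panel's allele-count cutoff (minor allele count ≥ 5)
is emulated against a notional sequenced panel of 850 individuals: each
variant's panel minor-allele count is drawn Binomial(1700, f) and the
variant is dropped from the `ssp` run when it falls below the cutoff.
Filtering on the 120-sample target cohort's realized MAC instead would
remove essentially every rare variant (MAC ≥ 5 at 240 alleles means
MAF ≥ 0.021) and destroy the scenario's rare-variant structure; the filter
belongs to the panel, not the cohort. The server run covers all variants,
hence a strict superset.

Seed phasings: all individuals are heterozygous at all sites; truth
orientations are uniform per pair, and each replicate flips each
orientation independently with the configured switch rate (default 0.02,
K = 21, 2,000 pairs). IBD segments: per (target, reference) pair the
count is Poisson with the group-pair rate (default 0.08 for
(`west`, `c1`), 0.02 otherwise, 30 reference individuals per cluster);
lengths are 1 cM (a detector-limit floor) plus an exponential with mean
3 cM (total mean 4 cM), placed uniformly on a 250 Mb chromosome at
~1 Mb/cM.

All draws go through `numpy.random.default_rng` seeded from the
configuration (separate streams per stage, strategy streams keyed by a
CRC of the strategy name), so every output is bit-reproducible.

## Evaluation conventions

Per-individual IQS comparisons between two runs (and the merge) are made
on the *intersection* of their variant sets — scores over different
variant sets are not comparable, since the set composition moves `P_c`.
The merged run is additionally evaluated over its union when coverage
itself is the question. Problem sizes in the shipped benchmark (3,000
variants × 120 individuals; 200 × 2,000 × 21 for switch-error recovery)
were chosen so that the expected effects exceed their Monte-Carlo standard
errors by an order of magnitude while the whole suite runs in seconds.

## VCF handling

Reading is cyvcf2-backed (plain or gzip/bgzip). Only biallelic SNV/indel
records are loaded; multiallelic and symbolic-allele records are excluded
and counted in the QC summary. Posterior trios whose sum is within 1e-2
of 1 are renormalised to sum exactly 1 (guaranteeing `p_max ≥ 1/3`);
larger deviations are counted and the genotype treated as missing — a
malformed trio is evidence, not data. A probability field absent from
every record is a configuration error (the field name is configurable
because pipelines emit different dialects); absent on some records, those
genotypes are missing. Truth VCFs must be diploid; half-missing genotypes
map to missing, and haploid or polyploid calls are record-level errors.
Written VCFs carry GT (argmax), GP, DS (`p1 + 2·p2`) and optionally the
merge provenance as a per-genotype string field, and round-trip through
the reader within 1e-4 per probability (float32 FORMAT storage).
Coordinates are 1-based inclusive everywhere; BED input is converted from
0-based half-open at the parsing boundary. BCF and genome-build liftover
are out of scope.

## Known limitations

* The simulator has no LD, no genotyping error in the truth set, and no
  relatedness; passing tests demonstrate the correctness of the scoring,
  merging and aggregation machinery, not the realism of any imputation
  accuracy level.
* Posterior calibration in real imputation output is imperfect; the
  merge's near-optimality degrades gracefully but is only guaranteed under
  calibration (the uncalibrated switch exists to explore this).
* Merging is pairwise only; combining more than two runs means chaining
  merges, whose result can depend on the order.
* Undefined IQS strata are dropped from averages by default; with many
  monomorphic strata (tiny regions, rare-variant bins in small samples)
  the remaining average can be unrepresentative — the `defined` flag and
  counts are always reported so consumers can decide.
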