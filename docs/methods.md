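# Methods

This note documents the models, default parameters, and design choices
behind `axiomcurate`, and what the synthetic-data validation does and
does not demonstrate about real array data.

## Data model

A dataset is a marker × sample matrix of genotype calls (AA/AB/BB/
NoCall, stored as the numeric export convention 2/1/0/−1) with aligned
Contrast and Size signal matrices and a per-SNP metrics table.
Contrast is the transformed allele-signal ratio: homozygotes sit near
±1 (AA positive), heterozygotes near 0. Missing signals and missing
metrics are NaN throughout — absence is never coded as 0, because 0 is
a meaningful value for both signals and metrics.

## Ploidy inference

For each sample the Contrast values over all usable SNPs (at least
500; at most 50 000, subsampled with a fixed seed — the distribution
shape converges far below full-array size) are histogrammed into 88
bins spanning [−2.2, 2.2]. Modes are detected with multi-scale
continuous-wavelet-transform peak finding (`scipy.signal.
find_peaks_cwt`) over smoothing widths from 1% to 10% of the bin
count, then filtered two ways: a prominence gate (peak density ≥ 5% of
the maximum density) that suppresses shoulder peaks on heavy-tailed
data, and a merge of peaks closer than 0.2 Contrast units, which
collapses ridge duplicates of a single mode — genuine genotype modes
are at least ~⅔ of a Contrast unit apart (the triploid spacing), so
the merge cannot join two real modes. The label is a pure function of
the peak count: 3 → diploid, 4 → triploid, otherwise *other*. Samples
labeled *other* are flagged, never auto-excluded: ploidy is a review
decision in a semi-automatic pipeline. Detection parameters were tuned
once on the synthetic fixtures and are exposed in configuration.

## SNP classes

`filterm` evaluates, per SNP, the called genotype clusters among
analysis samples (not excluded, not flagged non-diploid — polyploid
samples generate exactly the intermediate clusters these filters
target):

* **MonoHighResolution**: exactly one genotype class present.
* **HomHomCluster**: exactly {AA, BB} present (a null-allele-like
  pattern where heterozygotes are mis-called homozygous).
* **UnexpectedDistribution**: any homozygote cluster's Contrast
  midpoint at least 1.5 from 0. The midpoint is the arithmetic mean of
  member contrasts (robust at typical cluster sizes and consistent
  with how cluster variance is defined; the midrange is not). The
  bound is inclusive, and one displaced cluster suffices.
* **MetricsThreshold**: per failed metric test, with the metric and
  value recorded in the label detail. Defaults follow the published
  Axiom Best Practices values: FLD ≥ 3.6; HomFLD ≥ 6.5 (tested only
  when no AB cluster exists, which is the regime HomFLD describes);
  HetSO ≥ −0.1; HomRO ≥ 0.6/0.3/−0.9 for 1/2/3 genotype clusters
  present; cluster-variance z-score within ±2 of the dataset-wide
  mean (mean and sd of all per-cluster variances, computed once per
  run). Minima fail on strict `<`, maxima on strict `>`; any unset
  threshold disables its test; a missing metric skips its test. A SNP
  with zero called samples gets `MetricsThreshold(no-calls)` — the
  class list does not otherwise cover the all-NoCall case.

## Sub-cluster detection

`filterc` analyzes each called genotype cluster independently in one
dimension, the Contrast axis (cluster splitting manifests along
Contrast; Size mostly carries intensity, and 1-D keeps the test cheap
and well-calibrated at array scale). The cluster is described either
by one Gaussian or by a two-component Gaussian mixture fitted by EM
with a deterministic initialisation (split the sorted points at the
median), so the command is reproducible without a seed. The
two-component description wins only if its BIC (5 parameters) beats
the single Gaussian's (2 parameters). A winning split must then pass
acceptance gates: each subcluster ≥ 5 points and ≥ 5% of the cluster,
and center separation ≥ 0.3 Contrast units (≈ 3 cluster standard
deviations at typical noise). Clusters smaller than 10 points are
never split. Component variances are floored at 10⁻⁶ to prevent
likelihood collapse onto single points; the size gates catch any
degenerate split that survives. The gates are what keep the
false-split rate near zero over the ~15 000 clusters of an array-scale
run without per-SNP tuning; measured on pure Gaussian clusters (n=50,
sd 0.08) the false-split rate is 0/500.

## Relationship scanning

All scans use only Pass SNPs and non-excluded samples; reference
genotypes, when provided, join the comparison pool but are never
excluded or labeled.

* **Duplicates**: call concordance over mutually called SNPs ≥ 0.98.
  The member with the lower call rate is excluded (ties keep the
  lexicographically smaller id — deterministic and defensible).
* **Parent–offspring**: the opposing-homozygote rate (AA vs BB) among
  jointly homozygous SNPs ≤ 0.01, evaluated among non-duplicate pairs.
  Genotypes cannot orient the pair; direction comes from a reference
  pedigree when available.
* **Trios**: candidates pair up each sample's PO partners (plus
  reference-pedigree entries with two known parents); a candidate is
  confirmed at Mendelian-error rate ≤ 0.02. Wrong candidates formed by
  two offspring "parenting" their true parent carry error rates of
  several percent under random mating and are rejected by the same
  threshold. Scoring is symmetric in the parents.

Any pair or trio with fewer than 500 comparable (or informative)
SNPs is indeterminate and skipped with a warning rather than scored.
These thresholds are this package's own defaults — chosen so that,
at ≥ 5000 SNPs and ≤ 0.5% call error, true relationships sit orders of
magnitude inside the bounds (a true duplicate's concordance is
≈ 1 − 2·error ≈ 0.996; a true PO pair's opposing rate is ≈ the error
rate times the homozygote mis-call fraction) while unrelated pairs
concentrate near concordance ≈ 0.4 and opposing rate ≈ 0.5. All are
configuration-exposed.

Mendelian consistency itself is the exact biallelic transmission rule
(the child must receive one allele from each parent; any NoCall makes
the position vacuously consistent and untested), implemented as a
64-entry lookup table and verified in the tests against exhaustive
enumeration. `filterp` labels SNPs with errors in ≥ 2 confirmed trios.

## Ledger semantics

The ledger is one JSON document (replacing a server database with an
embedded store removes a deployment dependency while keeping the
persistence contract; a load/save seam admits other backends).
Automatic labels are sticky: re-running a filter — even with looser
thresholds — never removes a label; only the explicit Manual* labels
override (ManualInclude re-admits a SNP past automatic labels,
ManualExclude wins over everything), and only a ledger reset clears
history. This preserves the audit trail the review workflow implies.
Re-running any command with identical inputs leaves the curation state
unchanged; the run log records every command and its parameters.

## The synthetic generator

The generator is the package's study condition, not a demo: founders
are independent Hardy–Weinberg draws from per-SNP allele frequencies
(uniform on [0.2, 0.8]); offspring receive one allele from each
assigned parent; duplicates copy a founder's genotypes with fresh
signal noise; triploid founders draw dosage from Binomial(3, p) and
their signals from the four-mode geometry at ±1 and ±⅓. Signal noise
is Gaussian (sd 0.10 by default) around the class centers. Injected
defect classes (2% of SNPs each by default) override the geometry:
monomorphic SNPs are fixed for one allele (so transmission stays
consistent); hom-hom SNPs re-call their heterozygotes to a random
homozygote *and redraw those signals at the new center* — the
null-allele phenotype — so they do not double as split clusters;
displaced SNPs move both homozygote centers to a magnitude drawn from
[1.6, 1.9]; split SNPs divide the AB cluster at 0.6 Contrast units
(sd 0.08); bad-metrics SNPs sit half a unit below the FLD and HetSO
thresholds so strict-versus-inclusive comparison semantics are
directly testable. Clean-SNP metrics are drawn from bounded uniform
ranges clear of every threshold — bounded support matters because the
variance z-score test is a tail test, and a defect-free dataset must
genuinely contain no tail. Planted call errors (0.2% default) and
no-calls (0.5%) are applied last and only to clean SNPs, so each
injected class keeps its defining pattern exactly; every error
position is recorded in the truth labels.

What passing against this generator shows: the detectors implement
their definitions exactly, with calibrated error rates under Gaussian
noise and the stated geometry. What it does not show: robustness to
the heavier-tailed signal noise, plate effects, and metric
correlations of real arrays — on real data the review step and the
configurable thresholds carry that weight. A tail-inflation stress
option is a natural extension.

Problem sizes throughout (5000 SNPs, 56 samples, two 8-offspring
families, 200-replicate detector simulations) are the package's
standard validation conditions; distributional behaviour of every
statistic has converged well below these sizes.

## Known limitations

* Sub-clustering is 1-D; a split purely in Size would be missed.
* Tetraploids and aneuploids are not modeled; they surface as *other*
  ploidy labels for review.
* PO pairs are undirected without a reference pedigree.
* The ledger is single-writer, last-save-wins; no concurrent use.
* Metrics are consumed, never recomputed from raw signals — SNPs whose
  export omits a metric simply skip that test.
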