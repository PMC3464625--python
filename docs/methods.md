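# Methods

## Overview

`cnvpop` infers copy-number variants (CNVs) for a whole cohort from
SNP-array intensity data and condenses the per-probe calls into a
population-level catalog of consensus regions. The pipeline has five
stages: CN-ratio computation, genomic smoothing, population-wise mixture
calling, consensus merging, and frequency classification; two evaluation
engines score the resulting catalog.

## Copy-number ratios

For a subject with allele intensities S_A, S_B at a SNP and reference-panel
mean intensities R_A, R_B, two ratio variants are available:

* total:   CNR = log2((S_A + S_B) / (R_A + R_B))
* allelic: CNR = log2(S_A / R_A) + log2(S_B / R_B)

The total variant sums intensities before the log and is robust; the
allelic variant sums in log space and is more sensitive but noisier. When
no external reference panel exists, `batch_median_ratio` uses the median
intensity of each subject's processing batch as the reference, which also
removes additive batch effects by construction. All three require strictly
positive intensities; missing cells must be imputed upstream.

## Loess smoothing

Raw ratios are smoothed along each chromosome with a locally weighted
linear regression over a 41-probe window (roughly 100 kb on a 500K array).
Design choices, where the procedure is underdetermined:

* the window is selected by *rank* along the chromosome (the 41 nearest
  probes), not by basepair distance, so it always holds 41 probes;
* tricube weights are computed from basepair distances within the window;
* degree-1 local fits (exact on linear trends), 0 robustifying iterations
  by default (configurable bisquare iterations are available);
* windows shrink to the chromosome when a chromosome has fewer probes, and
  become asymmetric at chromosome ends rather than padding with invented
  data.

Smoothing is strictly chromosome-local and commutes with per-subject
constant shifts. Its cost is the spatial smearing of short CNVs: a CNV
spanning w probes is attenuated by roughly w/41 when w < 41, so events
much shorter than the window lose amplitude and apparent extent.

## Constrained Gaussian-mixture dosage calling

At each probe, the smoothed ratios of all subjects are modelled as a
four-component Gaussian mixture, one component per copy-number state
k in {1, 2, 3, 4} (hemizygous deletion, copy-neutral, one and two extra
copies; no homozygous-deletion component by default, though the state set
is configurable). Component means are pinned to

    mu_k = c + log2(k / 2)

with a single free shift c in [-0.5, 0.5]: the relative spacing of states
on the log2 scale is fixed by arithmetic, while c absorbs a population
whose average copy number is not exactly two. Weights (floored at 1e-4)
and per-component standard deviations (floored at 0.01 log2 units) are
free; a tied-variance option exists.

The penalized negative log-likelihood is minimised with the Nelder-Mead
simplex (derivative-free), with weights softmax-reparameterized and
standard deviations as `floor + exp(theta)` so the constraints hold by
construction; the shift bound is a quadratic penalty. Convergence uses an
absolute log-likelihood tolerance of 1e-8 with a 2000-iteration cap.
Initialization is a moment estimate: c0 = median of the values (the cohort
is diploid-dominant), initial weights from assigning each value to its
nearest pinned mean (blended with a diploid-dominant prior), initial
spreads from within-assignment standard deviations. During a chromosome
scan, each probe's fit is additionally warm-started from the previous
probe's solution with a tight initial simplex whenever that start scores
better — adjacent probes have strongly correlated smoothed data, and this
roughly halves the optimisation cost without changing the model.

Each subject's call is the Bayes posterior over the four states; the
reported *dosage* is the probability-weighted copy number sum_k k p_k, a
continuous value in [1, 4] that carries calling uncertainty forward (state
probabilities of 1%, 9%, 85%, 5% give dosage 2.94). Probes whose fit fails
are set to dosage 2 and listed in a QC report. A caveat: with unequal
component variances the dosage is not globally monotone in the ratio (the
widest component dominates both tails); with tied variances monotonicity
holds exactly.

## Segment classification

Externally produced segments (e.g. from circular binary segmentation)
carry only mean log2 ratios. Gain/loss thresholds are derived from the
population of segment means by the Tukey rule (Q1 - 1.5 IQR, Q3 + 1.5 IQR),
genome-wide; on typical array data this lands near the canonical +/-0.25
cut-offs, which can also be set explicitly. Classification is strict
(mean > upper -> CN 3, mean < lower -> CN 1, ties are copy-neutral), and
classified segments expand to a probe-level integer CN matrix with
uncovered probes set to CN 2.

## Consensus merging

**Simple merge** groups maximal runs of adjacent probes whose integer CN
columns are identical across all subjects (dosages are rounded half-up
first), splitting any non-copy-neutral run whose consecutive probes lie
more than 500 kb apart. It is exact but brittle at CNV boundaries: one
subject with a one-probe breakpoint shift breaks the run, so real cohorts
fragment each CNV edge into many single-probe regions.

**PCA merge** repairs this in four steps per chromosome: (1) partition the
chromosome into blocks bounded by stretches of >= 1 Mb at which every
subject's dosage rounds to 2; (2) winsorize each probe's dosages across
subjects at the (1st, 99th) percentiles — outlier cells are almost always
single-probe noise; (3) PCA the centered block (covariance, no scaling —
dosages share one unit) and keep the m leading components reaching 90%
cumulative variance, giving each probe an m-dimensional eigen-profile of
loadings scaled by singular values; (4) cluster eigen-profiles with a 2-D
batch self-organizing map and merge strictly adjacent same-cluster probes
into regions. Boundary stretches become copy-neutral regions directly, so
both mergers partition the probe set exactly.

SOM details (the choices were open): square grid of side
k = max(2, ceil(p^(1/4)) - 1) for a p-probe block, rectangular topology,
Gaussian neighbourhood shrinking linearly from k/2 to 0.5 over 200 batch
epochs, codebooks initialized uniformly in the per-dimension data range
under the configured seed, best-matching-unit ties resolved to the lowest
unit index (deterministic), and numerically identical profiles short-cut
to a single cluster. The small grid capacity is deliberate: a block
bounded by all-diploid stretches typically contains one CNV event plus its
fragmented shoulders, and benchmark runs showed that surplus units
quantize the shoulder loading gradient into spurious adjacent labels,
re-fragmenting exactly the boundaries the method exists to repair. With
four units per typical block, the PCA merge produced fewer regions than
the simple merge on 20/20 jitter-fragmented benchmark cohorts while
recovering planted CNVs at reciprocal Jaccard >= 0.5.

## Frequency classification

A subject is a carrier of a region when its rounded mean dosage over the
region's probes differs from 2 (a modal integer-CN rule is selectable;
the mean rule is robust to single-probe noise inside a region). Regions
with fewer than 5 carriers are excluded; carrier frequency > 1% makes a
CNP; the rest (roughly 0.1-1%) are CNVRs. The carrier-count filter takes
precedence over the frequency floor, since 5 carriers only "roughly"
correspond to 0.1% at a given cohort size. Catalog summaries count regions
by class, size stratum and chromosome, and genome coverage divides summed
region lengths per class by total genome length.

## Evaluation engines

**Overlap with a reference catalog.** Each predicted region is scored by
its best Jaccard coefficient (basepair intersection over union) against
any reference entry, and scores are histogrammed into a dedicated zero bin
plus ten equal-width bins of (0, 1]. Raw counts are calibrated against a
permutation null that relocates every predicted region uniformly at random
within its own chromosome, preserving length and chromosome composition
(the two properties the control must hold fixed); per-bin one-sided
enrichment/depletion p-values come from the empirical permutation
distribution with a +1 pseudo-count, not a normal approximation.

**Relatedness prediction.** First-degree relatives share CNVs far more
often than random pairs, so the Euclidean distance between two subjects'
per-region dosage profiles discriminates related from unrelated pairs.
Pairs are scored by negative distance; the precision-recall curve is
computed over all thresholds and its area taken by the trapezoid rule over
recall (tied-recall points are integrated in threshold order). Robustness
comes from redrawing the unrelated pairs (default 100 replicates); an ROC
AUC is reported as a secondary statistic. Profiles use continuous dosages
by default; integer CN profiles work identically.

## Synthetic cohorts

The generator plants CNVs into a probe map of evenly spaced probes: each
CNV has a chromosome, probe span, copy-number state and population
frequency; carriers are independent Bernoulli draws. Carrier ratios at CNV
probes are centered at log2(cn/2), non-carriers at 0, with i.i.d. Gaussian
noise on the log2 scale (default sd 0.1, comparable to post-normalization
SNP-array noise). Optional realism: per-batch offset/scale effects,
per-carrier breakpoint jitter in probes (the feature that fragments simple
merge), related pairs whose second member copies each of the first
member's carrier CNVs with a configurable sharing probability (and
otherwise redraws at the population frequency), and a two-allele intensity
split with lognormal noise to exercise the intensity-level entry points.

What the generator does not emulate — and hence what passing tests do not
establish about real arrays: genotype calls and linkage disequilibrium,
allele-specific (B-allele-frequency) signal, GC-content waves and other
structured spatial noise beyond what Loess smoothing induces, probe-level
quality heterogeneity, and homozygous deletions. Real-data performance
additionally depends on upstream normalization quality, which is out of
scope here.

## Problem sizes used by the benchmark suite

The bundled end-to-end benchmarks run 20 cohorts of 300 subjects with two
140-probe chromosomes (50 kb probe spacing, one 50-probe deletion and one
50-probe duplication at 10% frequency, +/-2-probe breakpoint jitter),
chosen so that clean diploid flanks exceed the 1 Mb partition span after
smoothing smear and CNVs comfortably exceed the smoothing window. Mixture
recovery is benchmarked on 50 replicates of 1000 subjects; the permutation
engine on 80-entry references with 1000 permutations (300 for the
uniformity sweep); the relatedness benchmark on 50 related pairs at 90%
sharing over 24 planted CNVs with 100 unrelated-pair redraws.

## Known limitations

* No HMM along the chromosome and no allelic-ratio modelling: probes are
  modelled independently given the smoothing, which under-uses spatial
  information for very short or very rare events.
* Dosage monotonicity in the input ratio is guaranteed only under tied
  component variances.
* The simple merge requires integer calls; continuous dosages must be
  rounded, losing the uncertainty the GMM preserves (the PCA merge keeps
  it).
* Winsorization at the (1st, 99th) percentiles can flatten variants rarer
  than 1/n of the cohort within the PCA step when a block's only signal is
  such a variant; the partition step still isolates the block, which then
  merges as a single region.
* The permutation null relocates regions independently and uniformly,
  ignoring probe-density and accessibility structure a real genome has.
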