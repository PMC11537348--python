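# Methods

## Matching statistics as the filtration primitive

The scoring layer consumes one number per read position: the length of the
longest suffix of the read prefix ending there that occurs exactly in the
reference collection. `hostguard.pml` computes this *matching statistics*
vector exactly, with a suffix automaton built over the concatenation of the
forward and reverse-complement strands of every reference record, separated
by sentinel characters so matches can never span records or strands. `N` is
mapped to a sentinel on the reference side and has no automaton transition
on the query side, so it matches nothing — including another `N`. This is a
conservative policy: ambiguous bases can never contribute to a host call.

Production indexing tools report *pseudo-matching lengths* (PMLs), cheap
approximations that reset on mismatch during backward search and therefore
sit at or below the true matching statistics. We compute the exact quantity
instead because it is deterministic, independent of any index
implementation, and verifiable against a brute-force oracle (every suffix of
every prefix, scanned directly against every strand); the test suite asserts
exact equality on over a thousand random cases plus the matching-statistics
ramp invariant `values[i] ≤ values[i−1]+1`. Build and query are linear; the
pure-Python automaton is intended for desk-scale references (kilobases to a
few megabases), not human pangenomes.

### Consequence of exactness for score specificity

For a random query against a reference of `G` indexed bases, per-position
matching statistics concentrate near `log₄ G`. Already at `G ≈ 20 kb` that
is ≈ 7, so chance runs longer than `w = 5` occur in essentially every read,
and the `custom` and `average` scores of *unrelated* reads exceed the
default thresholds. The defaults were derived for approximate PMLs, which
suppress chance matches; under the exact surrogate they are maximally
conservative — they remove virtually all reads that share ≥ 6-bp chance
matches with the index, microbial reads included. All host-side guarantees
(no host read survives a complete index) are unaffected, and the
`maximum` metric retains its intended specificity at any scale, because a
chance exact 31-mer is vanishingly unlikely (`G/4³¹`). Benchmarks of
microbial *retention* in this package therefore use the `maximum` metric or
the seed-based alignment stage; benchmarks of host *removal* use any metric.

## Scores, runs and thresholds

A *run* is a maximal ramp segment of the distribution (`values[i] =
values[i−1]+1` within the segment); its length is the peak value in the
segment, i.e. the length of the underlying exact match. Segments whose peak
is 0 yield no run. This definition makes the theoretical threshold read —
length 150, one contiguous matching stretch of 31 bases, zeros elsewhere —
contain exactly one run of length 31, and reproduces all three default
thresholds simultaneously:

* maximum: `31`
* average: `(31·32/2)/150 = 3.30666…` → quoted truncated as `3.306`
* custom (w = 5, natural log): `(31 + 31·ln 2)/300 = 0.174958…` → quoted
  rounded as `0.175`

The natural logarithm is forced by threshold reproduction (no other base
gives 0.175 from this read), as is reading the prefactor as `1/(2L)`. Run
inclusion is strict (`len(r) > w`). Host calls use `score ≥ threshold`
with the score rounded to the threshold's stored precision (3 decimals for
the defaults), so the threshold-defining read itself classifies as host;
full-precision comparison would put it infinitesimally below.

## Pipeline topologies

All methods share a 45-bp inclusive minimum-length pre-filter (adapter and
quality trimming are external-tool territory and not modelled). Methods 1
and 2 precede the index stage with per-reference *alignment-surrogate*
stages: a read "maps" when its longest exact match to that single reference
reaches the seed length `S = 31`. This replaces a seed-chain-align aligner
with its seeding criterion alone — deterministic, and sharing the aligner's
essential property that reads from regions absent from the reference do not
map. Method 1 uses exactly two such stages, Method 2 any number (one per
reference, sequentially), Method 3 none. The final stage always scores
reads against one aggregated index of all index references. In paired-end
mode every removal stage is followed by pair re-synchronization: a pair
survives only if both mates survive; single survivors are dropped as
orphans and counted. Stage reports reconcile exactly
(`input = removed + surviving` at every stage).

## Read simulator

Genomes are i.i.d. uniform over {A,C,G,T} (minimum 300 bp); reads are drawn
uniformly over start positions and strands, with independent per-base
substitutions to a uniformly chosen different base and a constant Q37
quality string. No indels and no empirical quality profiles: the scoring
layer consumes sequence only, so substitution-only errors exercise every
in-scope computation. Paired mode emits inward-facing mates from a fixed
fragment length without size jitter. Mixtures use exact class counts
(default 50 % host) and a deterministic shuffle. Uniform random genomes
lack the repeat structure, GC skew and homology of real genomes — chance
matches between simulated host and microbe genomes are rarer than between a
real human and real microbes — so passing benchmarks here demonstrate the
pipeline's bookkeeping and the two planted mechanisms, not real-data
sensitivity/specificity rates.

The two failure-mechanism fixtures are constructive: `holdout_region`
deletes an interval from the filtering copy of the host genome (reads
simulated inside it leak past any stage using that copy and are removed by
any stage holding the full genome); `inject_shared_segment` splices an
identical segment — typically low-complexity, e.g. `ACACAC…` — into a host
and a microbe genome, after which leaked host reads from the segment
seed-match the microbe reference.

## Benchmark statistics

Wilcoxon signed-rank comparisons are two-sided, with zero differences
dropped before ranking (the common convention) and the statistic reported
as `W = min(W⁺, W⁻)`. P-values are exact for up to 25 non-zero pairs — the
full null distribution of the signed rank sum computed by convolution over
doubled midranks, so ties are handled exactly — and use a normal
approximation with continuity and tie correction beyond. Ten paired
observations with all differences of one sign give `W = 0`,
`p = 2/2¹⁰ = 0.001953` (prints as 0.0020). The grid search sweeps the
custom metric over thresholds 0.145–0.200 in steps of 0.005 and
`w = 2…12` (132 cells), reporting host recall (the positive class is
truth-host), host precision (defined as 1 when nothing is flagged) and the
fraction of microbial reads retained. Coverage summaries reduce alignment
intervals to mean depth (`Σ lengths / genome length`) and breadth
(`|union| / genome length`); depth ≥ breadth always, and a high
depth-to-breadth ratio is the signature of reads piling on one shared
segment rather than covering a genome.

## Re-identification model

The site likelihood, likelihood score, Hardy–Weinberg background and its
expectation/variance are implemented exactly as stated in the README, in
log space throughout (natural log; the standardization is base-invariant
but consistency matters). Useful identities used as test oracles: for a
heterozygote `L(1,n,k) = 2⁻ⁿ` independent of `k` and ε; for `p = 0` the
population is degenerate and the variance vanishes. ε defaults to 10⁻⁶.

Design choices where the procedure was genuinely open:

* **Test side.** The standardized score is converted to an *upper-tail*
  P-value: a donor's genotype makes the observed reads more likely than a
  random population genotype, so evidence of identity is large positive z.
* **LD pruning.** A greedy deterministic pass: slide a 100-site window in
  steps of 30 over the covered-site list; within a window, scan kept pairs
  in index order and drop the later site of any pair with r² > 0.1 on
  genotype dosages. Monomorphic sites and sites with degenerate allele
  frequency (p ∈ {0,1}) are excluded up front to avoid zero-variance
  pathologies. Pruning runs per metagenome on its covered sites.
* **Missing genotypes** skip their sites in LS, with E and V restricted to
  the same sites so the standardization remains aligned.
* **Insufficient metagenomes** (no usable covered site after pruning) are
  excluded from the result table but still count toward the Bonferroni
  denominators, mirroring how a fixed study design sets its thresholds.

Bonferroni thresholds: pairwise `α/(M_meta·M_geno)` and per-metagenome
`α/M_meta`; at α = 0.05 with 343 + 343 samples these are 4.25 × 10⁻⁷ and
1.46 × 10⁻⁴.

### Synthetic cohort

One metagenome per donor. Alternative allele frequencies are uniform on
[0.05, 0.95] (common SNPs, as a genotyping panel would contain); genotypes
are HWE draws independent across sites; per-site depth is Poisson with mean
0.1 by default — sparse coverage emulating the scarcity of leaked host
reads in fecal data, where most panel sites receive no read; conditional on
donor dosage g, the reference-supporting count is Binomial(n, q) with
q = 1−ε, ½, ε for g = 0, 1, 2 — the exact generative counterpart of the
site likelihood. Because E(LS_pop) is the expectation of LS over a random
HWE genotype *conditional on the observed pileup*, non-donor standardized
scores have mean 0 and variance 1 by construction; the test suite checks
this calibration empirically. The attrition operator thins every read
independently with a retention probability, modelling host filtration;
sweeping retention from 1 to 0 moves the cohort from fully re-identifiable
to fully anonymous. Real cohorts differ in ways the generator ignores:
linkage disequilibrium between sites (here absent, so pruning removes only
chance correlations), imputation error in the panel, non-uniform coverage,
and contaminating non-donor human reads.

## Problem sizes and numerics

Default experiment sizes — 8-kb genomes, 1000-read mixtures, 50-donor ×
5000-site cohorts — were chosen so every property in the test suite is
decided well away from its noise floor while the whole suite runs in
seconds; they are study-design choices of this package, and all scale
linearly if enlarged. Likelihoods are computed in log space and
exponentiated only on demand (a naive probability-scale product underflows
beyond a few dozen covered sites). Thresholds and tolerances are stated at
the precision they are derived; no tolerance is tuned to data.

## Known limitations

* Exact matching statistics upper-bound approximate PMLs; see the
  specificity note above. Plugging a real aligner or compressed index in
  behind the alignment/index stage interfaces would recover
  production-scale behavior.
* The pure-Python suffix automaton holds ~50 automaton states per reference
  base in memory; megabase references are the practical ceiling.
* The simulator's uniform genomes and substitution-only errors understate
  real-data difficulty (repeats, indels, quality-dependent errors).
* The re-identification pipeline starts from pileup tables; producing them
  from alignments (mapping/base quality filtering) is out of scope.
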