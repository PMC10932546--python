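# Methods

This note documents the models, statistical procedures, parameter choices
and numerical conventions implemented in `pcdhgamma`, and what the
synthetic-data generators do and do not emulate.

## Expression matrices and binarization

The quantitative unit is the deduplicated UMI count per (cell barcode,
isoform): `build_count_matrix` counts *distinct* UMI sequences per
(barcode, isoform), so PCR duplicates collapse and re-feeding the same
records is idempotent. The default registry is the mouse Pcdhg locus —
12 γA isoforms (Pcdhga1–a12), 7 γB isoforms (Pcdhgb1, b2, b4–b8; b3 does
not exist in mouse), and the C-types Pcdhgc3/c4/c5 — and is configurable
for other naming schemes.

Filtering and binarization use strict ("greater than") thresholds:

- a cell is retained iff its total UMI count over all 22 isoforms
  (variable **and** C-type) is > 10, i.e. ≥ 11;
- an isoform is called expressed iff its own count is > 1, i.e. ≥ 2.

An empty post-filter matrix is a valid result. An optional barcode
whitelist models the intersection of a gene-expression library with an
enrichment library; by default no whitelist is applied.

## Similarity metrics

The similarity level of two cells is the Jaccard index of their binarized
**variable**-isoform sets; C-type isoforms are near-ubiquitous, carry no
combinatorial information, and are rejected outright if passed in. The
statistic is undefined at 0/0, so pairs in which both cells express no
variable isoform are excluded from distributions (and counted), not scored
as 0.

Euclidean distance operates on the 19-entry variable-isoform UMI vectors.
In normalized mode each vector is first scaled to unit sum, which bounds
the distance by √2 (attained exactly by disjoint single-isoform profiles);
an all-zero vector cannot be normalized and is an error. Distribution
binning uses a dedicated exact-zero bin plus ten right-closed bins
(0, 0.1], …, (0.9, 1.0]: Jaccard values are small-denominator rationals
and the zero mass dominates real data, so conflating 0 with (0, 0.1]
would hide the dominant feature.

## Co-occurrence test

Let k_c be the number of isoform types expressed by cell c (default
subset: variable + C-type; configurable). If isoforms express
independently with frequencies p_i, then Var(k) = Σ p_i (1 − p_i). All
variances are population variances (divide by N) so the observed statistic
is commensurate with that sum — indeed, for binary columns the observed
population variance decomposes exactly into Σ p̂_i(1 − p̂_i) plus the sum of
cross-isoform sample covariances, so the test isolates the covariance
term.

The null ensemble permutes each isoform column independently across cells
(100 shuffles by default), preserving every p̂_i exactly while destroying
cross-isoform dependence. The Z statistic is

    z = (Var_obs − Σ p̂_i (1 − p̂_i)) / SD(shuffled variances),

with the shuffled-ensemble SD taken with ddof = 1. Both the two-sided and
the upper-tail normal p-values are reported; the *co-occurrence call* is
directional — it requires Var_obs above expectation and tests in the upper
tail at level α (default 0.05), which keeps the call's type-I error at the
nominal level (a two-sided gate would halve it). Because the report emits
both `variance_excess_over_expected` and `variance_excess_over_shuffled`,
either reference can be plotted. A degenerate ensemble (zero SD, e.g. a
single-isoform matrix) is an explicit error.

## Uptake model

For a plasmid mixture with green molar fraction q (q = 5/6 for the
six-plasmid equimolar design: five green-tagged species, one red), a cell
receiving exactly n plasmids shows

    R_GFP-only = q^n,  R_RFP-only = (1 − q)^n,
    R_co = 1 − q^n − (1 − q)^n,  R_RedInTotal = 1 − q^n.

One published form of the cell-averaged R_RFP-only reads as an average of
1 − (1/6)^n, which is inconsistent with the fixed-n expression
R_RFP-only = (1/6)^n; this package averages (1/6)^n (through q), keeping
the identity R_RedInTotal = R_co + R_RFP-only exact in every mode.

The per-cell plasmid count n is Normal(μ, σ²), rounded to the nearest
integer and truncated below at 1 (n is a count of physical plasmids; a
rejection-sampling alternative is exposed but clipping is the default).
`simulate_uptake` draws n per cell and then n species draws with
replacement, with probabilities proportional to molar weights; a cell
expresses every species it drew at least once. At (μ, σ) = (18, 6) and
10,000 cells the mean number of distinct species per cell is ≈ 5.6 of 6.

`fit_mu_sigma` grid-searches integer (μ, σ), minimizing the squared error
on (R_RFP-only, R_RedInTotal). The model prediction at every grid point
reuses **one** vector of standard-normal draws derived from the seed
(common random numbers). This matters: the two observables only weakly
identify σ, so independent Monte-Carlo noise at each grid point can move
the argmin one cell off the truth; with a shared draw vector the objective
surface is smooth and observations produced by `normal_n_fractions` with
the same seed and k are recovered exactly. Ties break toward smaller μ,
then smaller σ.

## EPSC detection

Sign convention: at a holding potential of −70 mV an excitatory synaptic
current is inward, so detection is one-sided on negative-going deflections
(and therefore invariant to any constant holding-current offset).

Per sweep set (one ordered pre → post pair, ≥ 10 trials, 20 kHz default):

1. baseline mean and SD per trial over the 1 s before the stimulus; the
   working SD is the mean of per-trial SDs (pooled SD available);
2. on the trial-averaged trace, the onset is the first sample in the 3 ms
   post-stimulus window whose inward deviation from baseline exceeds
   3 × SD for at least 2 consecutive samples (the 2-sample persistence
   requirement rejects single-sample noise spikes which would otherwise
   register spurious early onsets and inflate the jitter estimate);
3. per-trial onsets are measured the same way; the call requires an
   average-trace crossing, individual crossings in ≥ 50% of trials
   (artifact guard, configurable), and onset jitter — SD of per-trial
   latencies by default, max−min optionally — below 0.2 ms.

Rejections carry a reason code (`no_average_crossing`,
`too_few_trial_crossings`, `jitter_too_large`). Whether the original
3 × SD rule was applied per trial or on the average trace is not
documented in the source protocol; the average trace is the default here
because averaged traces are what such recordings conventionally display
and measure, and the per-trial crossing quota covers the other reading.

Session assembly (`build_adjacency`) accepts at most 6 simultaneously
patched cells, one sweep set per ordered pair at most, and marks missing
ordered pairs as untested so they never enter downstream denominators.

## Connectivity statistics

Counting modes: `pair` (default) scores an unordered pair connected if
either direction responds, matching the "15 possible pairings among 6
cells" framing; `directed` scores ordered pairs. Published denominators
cannot always be unambiguously attributed to one mode, so both are
first-class and labeled. Pair-mode probability is always ≥ directed-mode
probability on the same table.

Group comparisons are Pearson chi-square on 2×2 tables without Yates
correction (standard at these sample sizes; the correction is a flag),
with Benjamini–Hochberg adjustment across an explicitly declared family —
families are never pooled implicitly, mirroring per-panel correction.
Bootstrap uncertainty resamples pair outcomes with replacement (default
nboot = 100) and reports the mean and SD of the resampled probabilities.

The similarity-vs-connectivity relationship is summarized by an ordinary
least-squares line of probability on similarity level (the underlying
relationship is reported as a monotone negative correlation; the family is
pluggable in principle but linear is the implemented default). The 95%
band refits after binomially resampling each point's connected count at
its fixed tested count and takes 2.5/97.5 percentiles of the fitted lines
at the input similarity levels.

## Synthetic-data generators

`gen_expression_matrix` emulates the structure the analyses assume:
C-type frequencies ≈ 0.9, variable-isoform frequencies spread over
[0.05, 0.4], and co-occurrence induced by a per-cell lognormal propensity
a_c with E[a] = 1 and Var(a) = ρ that scales all expression probabilities
to min(1, a_c p_i). A shared propensity is the simplest mechanism that
inflates the variance of per-cell isoform counts — exactly the statistic
the co-occurrence test measures; copula-style dependence structures are
out of scope. The default coupling ρ = 0.1 was chosen once as a "subtle
but clearly detectable" effect: it roughly doubles the count variance at
the default frequencies, detected with power ≈ 1 at 2000 cells, while
ρ = 0 yields exactly independent columns for calibration. Expressed
entries draw 2 + Poisson(depth − 2) UMIs (default depth 8), so they always
survive the > 1 UMI cutoff; unexpressed entries are 0, or 1 with
probability 0.02 (sub-threshold ambient counts). What this generator does
*not* emulate: amplification bias, barcode collisions/doublets, cell-type
structure, or realistic full-transcriptome backgrounds — so passing tests
demonstrate correctness of the computations, not robustness to every
artifact of real libraries.

`gen_session` plants difference-of-exponentials EPSCs (rise 0.5 ms, decay
5 ms, unit-normalized peak) at a configurable latency (default 1.5 ms)
with Gaussian per-trial jitter (default 0.05 ms) on top of white Gaussian
noise (default 5 pA; default amplitude 50 pA = 10× noise SD). Real
recordings have colored (Bessel-filtered) noise, stimulus artifacts and
series-resistance dynamics; the generator's white noise makes the
false-positive analysis conservative in the sense of testing the bare
criterion arithmetic.

`gen_pair_table` draws Bernoulli outcomes at stated group probabilities;
`exact_count_pair_table` encodes exact (connected, tested) tallies so that
published percentages can be reproduced verbatim.

All generators are deterministic given their seed.

## Problem sizes and numerical conventions

Default analysis sizes were chosen to give stable Monte-Carlo estimates:
10,000 cells for the uptake headline (SE of the mean type count
≈ 0.006), 50,000 cells for uptake fitting, 100 shuffles for the
co-occurrence null, 200 replicates of 2000 cells for type-I calibration,
100 ordered pairs / 1000 noise sweep sets for detector validation, and
nboot = 100 for connectivity bootstraps. Seeds are explicit everywhere;
derived generators use independent `numpy` `default_rng` streams.

Known limitations: the co-occurrence Z-test relies on a normal
approximation to the permutation distribution (adequate at thousands of
cells, unverified below ~100); the uptake fit assumes the design's molar
ratios are exact; EPSC detection assumes a single monosynaptic component
(polysynaptic cascades within the 3 ms window would be called connected);
and the linear connectivity fit is a summary of monotonicity, not a
mechanistic dose-response model.
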