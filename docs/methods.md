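# Methods

This note documents the models and procedures implemented in
`assemblyreaders`, the choices made where the design was genuinely open,
and what the synthetic-data studies do and do not establish.

## Candidate assembly detection

Spike trains restricted to the analysis epochs (e.g., slow-wave sleep) are
binned into 15-ms bins and z-scored per unit; epochs are binned
independently, so no bin straddles a gap. Principal components of the
correlation matrix with eigenvalues above the upper Marchenko–Pastur bound
`(1 + sqrt(n_units/n_bins))^2` mark significant co-activation structure; a
fixed-point ICA (scikit-learn's FastICA, logcosh contrast, tolerance 1e-4,
deterministic initialization from the run seed) on the projection onto that
subspace yields one weight vector per significant dimension. Weight vectors
are scaled to unit norm and signed so the largest absolute weight is
positive. Members are the high-|weight| group under Otsu's threshold
(exhaustive maximization of inter-class variance; effectiveness =
inter-class / total variance). Assemblies whose members carry both signs
are discarded: they reflect ICA limitations rather than coincident firing,
and their activation strength is high in scenarios other than member
coactivity. Because ICA is rotation-ambiguous and can duplicate sources,
components with |cosine| > 0.95 are de-duplicated, keeping the higher
effectiveness one. Units firing below 0.05 Hz in the epochs are excluded
from detection (their rows cannot be z-scored stably); the threshold is a
parameter.

Validation utilities: spike-identity shuffling (unit labels permuted across
spikes, preserving spike times, per-unit counts and the pooled population
rate), split-half cross-validation on balanced random 10-s interval sets
with greedy |cosine| matching (threshold 0.7) against a weight-permutation
null, peer-prediction gain, and z-scored member-pair cross-correlograms.

## Activation strength and events

For an assembly with unit-norm weights C, the instantaneous activation
strength is the quadratic form `A(t) = z(t)' P z(t)` with `P = C C'` and a
zeroed diagonal, computed over members only: z(t) is the member spike count
in a sliding 15-ms window advanced by 1 ms, standardized with the mean/sd
of the fixed 15-ms bins so the trace is commensurate with detection-time
statistics (re-standardizing the sliding trace itself is the documented
alternative). The member-only restriction keeps the trace specific to
member coactivity; the all-units variant is implemented for comparison and
systematically attributes events to moments with fewer coactive members.

The baseline is the median of A(t) (a point mass corresponding to empty
windows); "values above baseline" is the strict set {A > median}, and the
activation threshold is its 95th percentile. Events are maximal contiguous
supra-threshold runs (never bridging epoch gaps); the event peak is the run
midpoint, and recruited members are those with a spike within half a
window of the peak (the attribution window is a parameter).

A consequence worth noting: the threshold rule caps the detected event rate
at roughly 5% of the above-baseline time fraction divided by the typical
run length. Under this package's synthetic conditions that is ~0.3–0.5 Hz
per assembly, and the detected events are biased toward activations
recruiting many members. Real recordings with more members and denser
firing sit higher.

## Reader detection

For each assembly–reader pair, reader spikes are collected in ±1 s windows
(10-ms bins, q = 200) around activation peaks into a trials × bins matrix;
PETHs with fewer than 30 spikes are not testable. The null permutes the
time bins independently within each trial row (200 repeats), preserving
per-trial counts while destroying alignment; this is implemented exactly
and in O(nonzeros) per repeat by drawing, per trial, a uniform ordered
subset of distinct bins for the nonzero counts (partial Fisher–Yates,
numba-compiled). A pair is significant when (a) the summed PETH exceeds
the per-bin 95th-percentile band in at least one bin of the 10–30 ms
response window, (b) its maximum exceeds the 95th percentile of per-repeat
maxima (the global band, controlling for the 200 bins), and (c) the PETH
mode is a unique positive-delay bin. The joint criterion is deliberately
conservative: on simulated uncoupled pairs the per-bin exceedance sits near
5% (slightly below, from count discreteness) while the full pair-level
false-positive rate is far below 5%.

The response score is `(m - mean_null)/sd_null` per bin; stability is
assessed by splitting the peaks into two balanced random interval sets and
correlating the two score curves. Member-count response curves, per-member
influence (response to a member's out-of-event spikes) and leave-k-out
responses follow directly from the event table.

## Collective coding

The linear benchmark is a least-squares readout with identity link — the
prediction is the matrix product of weights with the member count vector,
so a Gaussian/identity fit is the faithful model — trained on member
spikes emitted outside activation runs: per delay on a 5-ms grid over
±1 s, reader counts in a 15-ms bin at that delay are regressed on the
member spike-count vector (plus intercept) around each out-of-assembly
trigger. All delays share one design matrix, giving a single multi-RHS
solve; rank deficiency falls back to the minimum-norm solution. Applied to
in-assembly triggers this yields the linear response eta, and

    S(dt) = (mean R_in(dt) - mean eta(dt)) / mean eta(20 ms).

Trigger sets above 4000 are subsampled (seeded) for tractability.

Two surrogates bracket the measurement: a perfect reader spiking 20 ms
after each activation recruiting at least half the members (with n = the
largest observed coactive subset when smaller than the assembly), and an
independent reader copying every member spike with a +20 ms shift. At desk
scale the planted sigmoid-response readers themselves can show S <= 0:
only the strongest co-activations cross the activation threshold, so the
"outside activations" training set still contains abundant collective
responses and the linear fit partially absorbs them. The dissociation
studies therefore use the two surrogates, which are immune to this leakage
by construction.

In the timescale scan, assemblies are re-detected at each bin width,
tracked across scales by |cosine| >= 0.7, and activation runs overlapping
any briefer-scale run of the same assembly are excluded, so each scale's
statistic reflects structure specific to it; in-triggers come from the
surviving runs and out-triggers exclude runs at every scale. Because R_in
and eta are on count scales that vary across bin widths, the scan
statistic z-scores the two curves jointly (concatenated) and reports their
difference at 20 ms.

AB/AA analysis: for an ordered member pair (A, B), AB events are
consecutive A-then-B (or B-then-A) spikes within the timescale with no
intervening A/B spike; AA events are two consecutive A spikes under the
same rule; the reference is the midpoint, and reader PETHs around AB and
AA references are z-scored conjointly. The comparison's premise is a
constant total number of assembly spikes. With planted ensembles, most AB
pairs fall inside collective activations where other members also fire,
which inflates AB responses for any member-driven reader; callers can
therefore pass the pooled other-member spikes, and pairs with any
other-member spike within half a timescale of either defining spike are
rejected, enforcing the constant-count premise exactly. The dissociation
study uses this strict form.

## Pattern completion and separation

Completion uses member co-activation events enumerated directly from the
spike trains (maximal timescale-wide groups of member spikes): unlike
supra-threshold events, these include partial and single-member
activations, which the zero-diagonal strength can never detect. Responses
per distinct recruited subset (>= 20 events each; each event counts toward
exactly one subset) are expressed relative to the reader's baseline rate,
normalized by the complete-assembly response, and fit with a bounded
sigmoid `1/(1 + exp(-k (x - x0)))` (k in (0, 100], x0 in [0, 1],
multistart least squares) against the parameter-free proportional model
F(x) = x; both R² values use the same residual/total sum-of-squares form,
which is only meaningful because normalization puts both models on the
same output scale. The boost r − x is summarized in tertiles of x.

Separation: the Hoyer sparsity
`H = (sqrt(n) - sum(r)/sqrt(sum(r^2))) / (sqrt(n) - 1)` of a neuron's
response vector across simultaneously recorded assemblies, referenced to
1,000 identity shuffles of the pooled activations
(`increase = (H - H0)/H0`); and the discrimination index
`d = (r1 - r2)/(r1 + r2)` between a paired and an overlapping assembly
(shared members >= 25% of each, both with > 2 members, >= 20 activations
each), tested against 1,000 pooled-label shuffles at the 95th percentile.
Responses entering H and d are baseline-subtracted and floored at zero,
keeping both statistics in their documented ranges. ICA cannot separate
planted assemblies sharing half their members (the sources are dependent),
so the pipeline-level separation study uses 3-of-8-member overlap, which
separates reliably; the discrimination statistic itself is additionally
exercised at 50% overlap on planted event times.

## Plasticity

Assemblies are detected once on the concatenated pre+post epochs (so the
"same" assembly is compared by construction) and their events extracted
per epoch. The change statistic is the post-minus-pre difference in mean
10–30 ms response; its null permutes epoch labels over the pooled
activations (1,000 repeats), the minimal exchangeability null for a
pre/post difference; a pair changes when the observed delta leaves the
central 95% of the null. Condition contrasts use a 2×2 chi-squared test
without continuity correction, with Fisher's exact test when an expected
count drops below 5. On sparse count data the permutation test is
conservative (achievable level below nominal); with responses present it
rejects at ~4–5% under the null.

## Hierarchical bootstrap

Resampling with replacement follows the hierarchy animal → session →
observation, drawing at each level as many items as observed; the
statistic (mean or median) is computed per repeat (1,000 default) and the
CI is percentile-based. A vectorized fast path covers balanced designs.
Coverage on nested Gaussian data with the cohort generator's shape
(4 animals × 5 sessions × 20 observations, random-effect sd 0.2 against
unit observation noise) is ~94–96%. A known property, not a bug: with few
top-level clusters and dominant cluster effects, percentile intervals
under-cover (~85–90% at 4 animals with cluster sd equal to the
observation sd); interpret CIs accordingly when one animal dominates.

## The synthetic generator

The generator emulates two reciprocally connected structures recorded
during sleep. Background spikes are inhomogeneous Poisson with per-unit
log-normal rates (median 1 Hz, sd 0.5 log units — sparse SWS-like firing)
and a shared sinusoidal modulation (amplitude 0.1 of the rate, 1 Hz). The
amplitude is deliberately modest: the spike-identity shuffle preserves any
coherent population-rate modulation, and a modulation strong enough to
push the global eigenvalue above the Marchenko–Pastur bound would be
detected as a (same-sign) assembly in shuffled data, contrary to what the
shuffle control is meant to show. Even so, the planted activations
themselves create population-rate bursts that survive the shuffle, so
shuffled sessions typically retain one global component — the shuffle
tests assert "at most a global component, never a planted member set"
rather than literally zero.

Assemblies (default five, eight members each, disjoint unless configured
otherwise) activate as Poisson events at 1.8 Hz; each member is recruited
with probability 0.7 and emits one spike uniformly jittered within the
15-ms timescale. Eight members is the default size: activation events are
plentiful (~500–800 per 30-min session under the threshold rule) while
remaining realistic for PCA-ICA assemblies. Readers live in the opposite
structure and come in three kinds: "collective" readers respond to
observed member co-activation groups with probability sigmoidal in the
fraction of distinct coactive members (midpoint 0.4, steepness 10 — a
completion-capable coincidence detector), "independent" readers fire
after every member spike with a fixed probability (the rate-driven
control), and "coincidence" readers fire whenever two distinct members
spike within the timescale, wherever that occurs. Reader spikes are added
to the reader's own background train, with delay 20 ± 3 ms. Cohorts add
per-animal log-normal rate offsets (sd 0.2) with per-(animal, session)
seeds; pre/post pairs re-run the same process with selected couplings'
response probabilities scaled in the post epoch (clipped at 1 with a
warning — the plasticity studies use fixed-probability couplings at 0.3
precisely so a ×2.5 multiplier has headroom).

What the generator does not emulate: bursting and refractoriness, UP/DOWN
state alternation, non-stationary rates across a session, spike-sorting
errors, and realistic assembly overlap statistics. Passing the studies
therefore shows the pipeline's statistics are calibrated and powerful
under Poisson-like conditions with planted ground truth, not that every
effect size transfers to real recordings.

## Problem sizes and numerical choices

The validation studies use: 20 sessions (60+20 units, 30 min) for
recovery; 500 simulated pairs for each null calibration; 8 sessions for
the supralinearity and AB/AA dissociations; 2 sessions for the timescale
scan; 6 sessions for completion and separation; 3 conditions × 4 pre/post
sessions (15 min per epoch) for plasticity; and 500 nested experiments ×
1,000 repeats for bootstrap coverage. Median peer-prediction gain is
degenerate (exactly zero) in sparse regimes where the empty-bin point mass
covers the median of absolute errors; its test uses a denser regime
(10-member assembly, ~6 Hz units). Ties and degenerate inputs: Otsu
requires at least two distinct |weights|; constant strength traces yield
zero events with a warning; all-zero response vectors make sparsity and
discrimination "not testable" rather than raising.
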