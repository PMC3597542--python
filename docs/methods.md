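# Methods

## Codewords and data model

Population activity is discretized into bins of width Δτ (default 20 ms,
configurable): a neuron is assigned σᵢ = 1 in a bin if it fired one *or
more* spikes there, 0 otherwise. Bins are half-open [bΔτ, (b+1)Δτ) with
0-based indices, so a spike exactly on a boundary belongs to the later bin.
The bin width is chosen so that most pairwise spike–spike interactions fall
*within* one bin, making successive codewords approximately independent —
all information-theoretic rates below assume that independence and ignore
residual temporal correlation between bins (a known limitation, not an
implementation detail).

Rasters carry a (repeat × time bin × neuron) binary tensor plus optional
2-D neuron positions for distance analyses. Train/test splitting assigns
odd-numbered repeats (1-based) to training and even to testing, so slow
non-stationarity is shared between the halves; a per-neuron drift statistic
(regression slope of per-repeat rate on repeat index, times the repeat
count, over the mean rate) quantifies that non-stationarity.

## Empirical statistics

Total covariance and correlation are pooled over all (time bin, repeat)
samples. Significance of pairwise correlations is judged against a null in
which each neuron's spike train is independently permuted in time within
each repeat; the default cutoff is null mean + 2·null std, with a
95th-percentile alternative (`rule="p95"`). Signal correlations are the
correlations of a surrogate raster whose repeat indices are permuted
independently per neuron and time bin (averaged over `n_perms = 20`
permutations); noise correlation is total − signal, elementwise, which makes
the decomposition an identity by construction. A conditionally independent
population has zero noise correlation up to sampling noise.

## Linear–nonlinear front end

Filters are spike-triggered averages over D = 40 stimulus taps
(most-recent-first, the spike bin included), mean-subtracted and unit-norm:
any LN model is invariant to filter rescaling, so all scale lives in the
nonlinearity. The stimulus is held onto the Δτ grid by zero-order hold.
Generator-signal bins: stage 1 places K equal-occupancy (quantile) edges
(K default 10; performance saturates with K); stage 2 makes binning denser
where rates are high — bins above the spike-weighted median of x holding
more than twice the stage-1 average spike count are split at their internal
median, merging the least-spiking adjacent low-x pair to keep K constant.
The exact high-x refinement rule is a design choice of this package.
Nonlinearities are Bayes inversions: f(bin) equals the mean spike rate of
samples in the bin, which makes training-data rate prediction exact per bin
and conserves the mean rate. Empty bins (possible only when edges come from
elsewhere) get 0.5 pseudo-spikes over the average bin occupancy and are
flagged.

## The model grid and its conventions

Energy convention: E(σ; t) = −Σᵢ hᵢ(t)σᵢ − Σᵢ<ⱼ Jᵢⱼσᵢσⱼ with
P = e^(−E)/Z, so probable codewords are minima of the landscape. Fields are
static (vocabulary models), per-time-bin (T models) or functions of the
binned generator signal (S models); couplings are always static and
symmetric with zero diagonal. Codewords are encoded as integers with neuron
0 the least significant bit. Enumeration is exact up to N = 20 (2²⁰
states, blocked matrix algebra); all larger-N expectations use the sampler.

The Metropolis sampler flips single random sites and records one pattern
per `spacing` flip attempts (default 100, 5000 samples per context when
estimating codeword distributions); chains burn in for 10·spacing flips.
Correctness is validated against enumeration by total-variation distance.

T1 is closed-form: λᵢ(t) = ln(p/(1−p)) with p = rᵢ(t)Δτ, p clipped to
[ε, 1−ε], ε = 1/(2·samples) when the sample count is known.

## Inference

Fitting is maximum likelihood = moment matching, and the problem is convex
with a unique solution. Parameters are initialized at the independent
closed form (J = 0), so order-1 models converge immediately. Each
iteration compares data statistics with exact (N ≤ 20) or Monte-Carlo model
expectations and steps each parameter by a diagonal-Newton rule — the
constraint residual divided by the statistic's model variance (floored at
10⁻⁴) — scaled by a per-block rate (1.0 for fields, 0.4 for couplings) that
is halved when the combined error clearly oscillates (>20% worsening) and
regrown gently. Steps are clipped to ±0.5 (trust region): unclipped Newton
oscillates when fields and couplings are strongly cross-coupled, e.g. for
near-degenerate pairs. Plain fixed-rate gradient steps in probability units
were rejected: their convergence time scales like 1/(lr·p) iterations at
per-bin probabilities p ≈ 0.05.

Convergence is declared when the mean relative error on rate constraints
drops below 1% and on coincidence constraints below 5% (both configurable);
relative errors are floored at half a count of the relevant sample size so
that empty bins cannot dominate. Parameters are capped at |θ| ≤ 15;
touching the cap flags the fit as degenerate (e.g. a perfectly coupled pair,
whose coupling diverges logarithmically). Non-convergence returns the best
model with a flag and the full error trace.

For N > 20 the model expectations come from per-context Metropolis sample
pools that are importance-reweighted across parameter updates
(w ∝ exp(ΔlogP̃)) and redrawn for any context whose effective sample size
falls below 50%. This path is exercised against enumeration on small
populations; the acceptance-scale analyses all run in the exact regime.

## Entropy and information

Exact entropies are −ΣP log₂P by enumeration. Above the cap, entropy comes
from heat-capacity integration: with P_T ∝ e^(−E/T),
S(1) = N ln2 − ∫₁^Tmax C(T)/T dT − Var_∞[E]/(2Tmax²) in nats, where
C(T) = Var_T[E]/T². The grid is 60 log-spaced temperatures on [1, 100],
integrated by the trapezoidal rule from the hot side (S(∞) = N ln2 is
exact, and the hot anchor avoids ground-state degeneracy issues); chains
anneal downward, each temperature reusing the previous final state; the
tail term uses the uniform-distribution energy variance (estimated from
i.i.d. fair-coin codewords). At N = 10 with 4000 samples per temperature
the estimator agrees with enumeration to well under 1%. log Z is available
by the analogous thermodynamic integration over inverse temperature.

Information accounting: the vocabulary model (static) provides P(σ); the
codebook model provides P(σ|t). Mutual information per codeword is
S[vocabulary] − mean_t S[P(σ|t)]; rates divide by Δτ. The surprise trace is
Ŝ_x(t) = −⟨log₂ P_vocab(σ)⟩_{P(σ|t)}/Δτ and instantaneous information
i(t) = Ŝ_x(t) − S[P(σ|t)]/Δτ, non-negative whenever the vocabulary is the
codebook's marginal (Gibbs' inequality); its time average is the
information rate. Because a converged static pairwise fit matches exactly
the moments that appear in its own log-probability, the time-averaged
surprise under any marginal-consistent codebook equals the vocabulary
entropy rate up to fit tolerance. The vocabulary may also be an explicit
probability vector (an empirical vocabulary); codewords it never saw then
produce infinite surprise and a warning. The stimulus source entropy rate
is the entropy of the Gaussian luminance distribution quantized to the
8-bit display grid (rounding, end levels absorbing the tails) times the
update rate.

Two orderings deserve care, because only their *averaged* forms are
mathematically guaranteed: (i) adding the pooled pairwise constraint lowers
the context-averaged conditional entropy (S2 ≤ S1), but individual contexts
can go either way, since the pairwise constraint couples contexts; (ii) a
pooled (vocabulary) model's per-codeword negative log-likelihood is bounded
below by the pooled plug-in test entropy, while a stimulus-conditional
model is bounded by the mean per-context plug-in entropy — a conditional
model on well-sampled data can legitimately beat the pooled bound.

## Evaluation

Per-codeword negative log₂ likelihoods (bits/codeword, lower is better)
are computed on test repeats only. The time-dependent independent model is
evaluated with a rate regularizer p → (p+ε)/(1+2ε), ε grid-searched over 10
log-spaced values in [10⁻⁴, 10⁻¹] to maximize *test* likelihood (maximally
favoring that baseline); the empirical-train baseline is mixture-regularized
with the uniform distribution, its weight grid-searched the same way; the
empirical-test baseline is the plug-in entropy lower bound. The vocabulary
scatter compares empirical test codeword probabilities with Monte-Carlo
model frequencies (5000 samples per time bin pooled; exact per-context
categorical sampling when enumerable), restricted to codewords present in
both; the all-silent codeword is reported separately. GoF is the standard
deviation over plotted non-silent codewords of
z_w = (log₂p̂_w − log₂q_w)/δ_w with δ_w = √((1−p̂_w)/(Mp̂_w))/ln2 the
delta-method multinomial error at M test samples — a model sampled from
the test distribution itself gives GoF ≈ 1. Top-K overlap counts the
intersection of the K most frequent test codewords and the K most frequent
model samples (ties broken by integer encoding). Noise-correlation
prediction simulates a raster from the model with the test repeat/time
structure and regresses predicted on measured noise correlations over
significantly correlated pairs.

## Energy-landscape clustering

Every observed codeword is assigned to a metastable state by greedy
steepest descent: repeatedly apply the single-bit flip with the largest
energy decrease (ties broken by lowest neuron index) until no flip lowers
the energy. Descent is deterministic and idempotent, energy strictly
decreases along the path, and for generic real-valued parameters ties never
occur; the reached attractors coincide with exhaustively verified local
minima. The census keeps, per time bin, attractors visited more than
`min_visits` times (default 30) with their energies; train/test overlap of
the attractor sets and visit-frequency correlation measure how well the
partition generalizes across disjoint repeats.

## Synthetic ground truth

The generator emulates a frozen-noise retinal experiment. Stimulus:
i.i.d. Gaussian luminance, mean 147 and std 33 luminance units, quantized
to 256 levels (8 bits) at 30 Hz (60 Hz frames shown twice). Population:
biphasic OFF-type temporal kernels (40 taps, unit norm, small shape
jitter), logistic nonlinearity in the generator signal — fields linear in
x keep the truth exactly inside the coupled model class, so parameter
recovery is well-posed — and symmetric couplings with positive mean
decaying exponentially with distance on a √N×√N grid at 100 µm pitch
(scale 0.5, length 150 µm, 50% relative jitter; zero scale gives exactly
J = 0). Offsets set a ~3 Hz uncoupled baseline rate and gains give ~1.5
field units per generator-signal standard deviation; with the default
positive couplings the realized mean rate is ~10 Hz. Each (time bin,
repeat) codeword is drawn independently from the conditional distribution
— exactly by enumeration for N ≤ 20. All outputs are bit-reproducible
given (seed, config).

What the generator does *not* emulate: spike-history dependence and
refractoriness, adaptation and slow drift, spatially structured stimuli,
within-bin temporal structure, spike-sorting errors. A green test on this
world therefore validates the estimators and inference machinery, not the
biological adequacy of the model class.

## Known limitations

- Entropy/information rates assume codeword independence across bins.
- The S-class model inherits the single-filter assumption: stimulus
  dependence enters only through one linear projection per neuron, so some
  stimulus correlation can masquerade as noise correlation (visible as a
  noise-correlation regression slope below 1 even for self-simulation of a
  fitted model).
- The MC fitting path refreshes per-context sample pools independently; for
  very long stimuli a pooled-context refresh schedule would be cheaper.
- Greedy descent explores single-bit moves only; basin volumes and saddle
  structure are out of scope.
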