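# Methods

## The covered-codend selectivity model

A covered-codend experiment observes, for each haul *j* and 1-cm length
class *l*, the count retained in the codend (nRⱼₗ) and the count that
escaped into the fine-mesh cover (nEⱼₗ).  Conditional on the fish that
entered, retention is Bernoulli per fish with probability r(l), so the
class counts are binomial.  Large catches are subsampled on deck; each
compartment's subsampling ratio q ∈ (0, 1] applies at the haul ×
compartment level, and counts enter the likelihood raised by 1/q.  Hauls
are pooled — the fitted curve is the length-dependent retention averaged
over hauls — and parameters maximise

  −Σⱼ Σₗ { nRⱼₗ/qRⱼ · ln r(l) + nEⱼₗ/qEⱼ · ln(1 − r(l)) }.

Binomial coefficients are omitted: they are parameter-free within a
dataset, so likelihood ratios, AIC differences and rankings are
unaffected, while absolute AIC values carry an arbitrary offset.  Raised
counts may be non-integer; the saturated likelihood for the deviance uses
the raised per-class proportions.

Assumptions: fish enter the codend independently; retention depends on
length only (pooled over hauls); the cover itself is non-selective and
does not mask the codend; subsampling is random within compartment.

## Curve families

Each classical family is a location-scale sigmoid F((l − a)/b).  The
public parameters are L50 (cm) and SR = L75 − L25 (cm); (a, b) follow
from the family's standard quantile function X(p):
b = SR / (X(0.75) − X(0.25)), a = L50 − b·X(0.5).  Concretely the Logit
rate is 2·ln 3 / SR and the Probit scale SR / (2·Φ⁻¹(0.75)).  The Richard
family is the exponentiated logistic F(z) = expit(z)^(1/δ) with
X(p) = ln(p^δ / (1 − p^δ)) — the standard form in the selectivity
literature; at 1/δ = 1 it reduces to the Logit curve exactly.  Published
Richard parameterisations differ in where 1/δ acts (on the whole curve,
as here, or inside the logistic argument); absolute AIC comparisons with
other software depend on that choice, rankings among the families fitted
here do not.

Contact variants mix a retained-outright component into the base curve:
r(l) = 1 − C + C·base(l).  The mechanism: only a fraction C of entering
fish contact the meshes in a way that gives them a length-dependent
escape chance; a fish without such contact cannot escape, so it is
retained regardless of length, producing the floor 1 − C.  For contact
models the reported "overall" L50/SR are quantiles of the mixture curve;
they exist only when the floor lies below 0.5 (0.25) and are otherwise
reported as not reached.

## Optimisation

The optimiser works on unconstrained transforms — L50 free, log SR,
log 1/δ, logit C — to keep the search off the natural-scale boundaries,
with wide box bounds as a safety net (C's upper bound sits at 1 − 1e−8 so
the classical limit C → 1 is effectively reachable and nested-model
comparisons are clean).  Mixture likelihoods are multimodal, so fits run
a deterministic multi-start grid: L50 at the 10/30/50/70/90% weighted
percentiles of the raised length distribution, SR ∈ {2, 4, 8} cm,
C ∈ {0.3, 0.6, 0.9}, 1/δ ∈ {0.5, 1, 2}; the best optimum over all starts
is kept.  L-BFGS-B converges at ftol 1e−9 on the objective.  Retention is
clipped to [1e−12, 1 − 1e−12] inside every logarithm and empty cells
contribute exactly zero (0·ln 0 = 0).  A solution within 1e−4 of a
transform bound is flagged `at_boundary` (e.g. every fish in the cover
drives retention to the floor).  Deviance degrees of freedom count
occupied classes (positive raised total) minus the number of parameters;
non-positive dof is reported as "not assessable" rather than a p-value.
Overdispersion (deviance/dof) is reported but not corrected.

## Double bootstrap and delta curves

Each replicate resamples the m hauls with replacement (between-haul
variation), then within each selected haul copy resamples its measured
fish with replacement (within-haul variation), then refits.  The fish
list of a haul is the joint (length class, compartment) sample, so the
inner stage is one multinomial draw over those cells; resampling jointly
rather than within each compartment regenerates the binomial
codend/cover split noise that the inner stage exists to capture.
Subsampling ratios stay fixed and resampled counts are raised by 1/q, so
raising noise propagates.  Replicates that fail to converge are redrawn
up to 10 times, then logged and kept, so the population size is exactly
n_boot; more than 5% persistent failures raises a warning.  Refits
warm-start from the point estimate plus a few coarse starts.  A master
seed drives per-replicate substreams, so populations are bit-reproducible.

Confidence intervals are Efron percentiles (2.5/97.5) of the replicate
population, per parameter and per point of a 0.1-cm length grid spanning
the observed range padded by 2 cm.  For two gears bootstrapped
independently with equal n_boot, the difference population pairs
replicate i with replicate i; the delta curve's CI therefore can never
exceed the two marginal CIs combined, which is what gives the paired
comparison its power.  Significant ranges are maximal runs of consecutive
grid points whose interval excludes zero.

Calibration: the coverage experiment in the test suite shows the known
small-m behaviour of percentile intervals.  With 10 hauls and no
between-haul heterogeneity the outer stage adds variance the data do not
have and the intervals over-cover; with strong between-haul L50 jitter
(SD 0.5 cm) they undercover by several points, because the m-out-of-m
outer bootstrap shrinks the between-haul standard deviation by about
√((m−1)/m) and percentile intervals apply a normal rather than a
t-quantile to what is effectively a 9-degree-of-freedom variance
estimate.  This is a property of the interval method at small haul
counts, not of the implementation (the resampling scheme reproduces the
sampling variance of fit-free statistics to within 1%); conclusions
drawn from few hauls should treat 95% intervals as approximate.

## Motion analysis

Depth peaks and valleys come from prominence-based peak detection run on
the trace and its negation, with plateaus of equal extreme readings
resolved to the plateau's midpoint time.  Alternation is then enforced:
between two peaks only the most extreme valley survives and vice versa.
Defaults: minimum prominence 0.02 m (the depth logger's resolution
scale) and minimum separation 2 s (shortest credible oscillation at 1 Hz
sampling); both are exposed because no standard values exist.
Peak-to-peak amplitude is the excursion between adjacent alternating
extrema; the amplitude ratio divides it by the side-panel length
(default 99.6 cm); periods are successive peak-to-peak gaps
(valley-to-valley would differ by at most one sampling interval on the
traces considered here).

At sea the seabed depth changes continually, which masks the codend's
own oscillation, so statistics are computed on stable segments: maximal
greedy left-to-right windows whose depth range stays within 0.5 m,
lasting at least 30 s (long enough for two oscillations at the longest
period observed at sea, ~20.7 s; records oscillating more slowly than
that would need a longer minimum).  Sea records are trimmed by 60 s at
each end (setting and haul-back); flume records by 300 s at the start
(flow stabilisation).  Trend-on-velocity fits are ordinary least squares.

## The synthetic generators

`simulate_catch` draws fish lengths from a normal(22.7, 3.5) truncated
to 13–40 cm and binned at 1 cm — the observed redfish population's mean,
spread and range — with per-haul totals Poisson around 2000 (negative
binomial if a dispersion is set).  Retention is simulated mechanistically:
under a contact model each fish first contacts the meshes with
probability C and then escapes with the length-dependent probability,
so the 1 − C floor emerges from the mechanism rather than being imposed.
Between-haul variation enters as normal jitter on each haul's L50
(default SD 0, exposed as `haul_l50_sd`); compartment subsampling thins
measured counts binomially with q fixed or uniform on a range.  Ten
hauls of ~2000 fish mirrors the larger of the two sea-trial gears; the
4-haul configurations used in some tests mirror the smaller one.

What the generator does *not* emulate: fish-behavioural correlation
within hauls (schooling makes real fish non-independent, inflating
overdispersion), haul-to-haul variation in SR or C, length-dependent
contact, cover masking, and measurement error in length.  Passing
recovery and coverage tests therefore demonstrate correctness of the
estimation machinery under the stated model, not robustness to those
real-data effects.

`simulate_depth` produces base + drift·t + A·sin(2πt/period) + noise at
1 Hz.  Defaults (A = 0.055 m, period 9.2 s) match the at-sea oscillation
regime; flume-style traces use A ≈ 0.13 m and periods of 7–14 s.  Tests
that require exact amplitude recovery use period 8 s so the sampling
lattice hits the sine extremes.

## Sizes used by the test and acceptance runs

Simulation-based checks run at: 100 datasets for recovery bias, 200
outer replicates × 200 bootstrap replicates for coverage, 20 null and 50
alternative replicates (200 bootstrap replicates each) for the delta
curve's error rate and power, 200 replicates for the goodness-of-fit
p-value uniformity check.  Bootstrap replicate counts are scaled down
from the 1000 a full analysis would use; percentile endpoints are
correspondingly noisier but unbiased.

## Known limitations

- Pooling hauls ignores between-haul random effects; with few hauls the
  deviance test then rejects well-fitting curves through overdispersion
  (reported, not corrected).
- Percentile double-bootstrap intervals are approximate at small haul
  counts (see calibration note above).
- Absolute AIC values are offset by the omitted binomial coefficients
  and by the Richard parameterisation choice; only differences within a
  run are meaningful.
- The bundled sea-trial haul log records per-haul totals only (no length
  frequencies), so it supports bookkeeping and metadata summaries, not
  selectivity fitting.
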