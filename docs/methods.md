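# Methods

## Model

A sorted cluster is modelled as the superposition of spikes from one
intended ("true positive", TP) neuron and from N contaminant neurons whose
spikes were misassigned to it ("false positives", FP). All neurons fire as
Poisson processes; the only biophysical structure retained is the absolute
refractory period τ, which forbids two spikes of the *same* neuron closer
than τ and therefore makes every inter-spike interval (ISI) shorter than τ
evidence of contamination.

### Homogeneous firing

With constant assignment rates R_TP and R_FP (Hz), each TP spike opens a
double-sided window of width 2τₑ in which an FP produces an ISI violation,
where τₑ = τ − τ_c is the effective refractory period after removing the
sorter's censor period τ_c (spikes detected within τ_c of another are
discarded before counting). FPs also violate with FPs from *other*
contaminants; with the FP rate split evenly over N contaminants a fraction
(N−1)/N of the pool is available, and a factor ½ avoids double counting:

    R_v = 2τₑ R_FP R_TP + ½ (N−1)/N · 2τₑ R_FP²             (violations/s)

Substituting R_t = R_TP + R_FP, f = FDR = R_FP/R_t and ISIv = R_v/R_t:

    ISIv = 2 τₑ R_t ( f − (N+1)/(2N) · f² )

which is inverted in closed form. Two conventions matter:

* **Root choice.** The quadratic has two roots; the smaller is kept. This
  encodes the labelling convention that the majority contributor of spikes
  is the TP neuron — the larger root describes the same cluster with the
  labels swapped.
* **Capping.** The parabola peaks at f = N/(N+1) (=FDR_max; ½ for N=1, 1 in
  the N→∞ limit). An observed ISIv above the peak makes the discriminant
  negative; the estimate is then returned as FDR_max with `capped=True`,
  never as an exception, because finite-duration ISIv estimates routinely
  overshoot their expectation.

### Time-varying firing

Real firing is non-stationary, so rates become length-n binned profiles
(PSTHs). A time-resolved FDR(t) would be both noisy and pointless; the
target is the time-averaged FDR. The mean violation rate depends on the
expected element-wise product of the profiles, E[a⃗·b⃗] = (a⃗·b⃗)/n.
Writing the FP profile as a magnitude M times a unit profile R̂_FP, and
D = R̂_t·R̂_FP for the overlap of the total-rate and FP unit profiles,

    R̄_v = 2τₑ ( M·D·|R⃗_t| − (N+1)/(2N)·M² ) / n,

and setting R̄_v = ISIv · R̄_t (mean total rate) gives the smaller root

    M = N/(N+1) · [ D|R⃗_t| − sqrt( D²|R⃗_t|² − (N+1)/N · n · R̄_t · ISIv / τₑ ) ].

The FDR is then mean(M·R̂_FP)/R̄_t. For constant profiles this reduces
*exactly* to the homogeneous closed form (unit-tested to 1e−10), which also
fixes the form of the term under the radical: dimensional analysis requires
the mean total rate there, not the vector magnitude. Positive TP–FP
covariance inflates violation production at fixed FDR, so ignoring it
(using the homogeneous inverse) overestimates FDR, and vice versa; the
vector model absorbs this through D.

### Estimation with unknown N and R̂_FP

Applied to a recorded session, R⃗_t and ISIv are measured per cluster; τ is
prior knowledge (default 2.5 ms, appropriate for mouse cortex and adjusted
for other preparations); τ_c is user-supplied after inspecting the
aggregated ISI histograms (a CSV export supports this; auto-detection is
deliberately not attempted). N and R̂_FP are unknowable, so the pipeline
computes two bracketing solutions and averages them:

* **N = 1 branch** — the cluster is inverted against every other cluster's
  unit PSTH; each per-pair estimate is capped at 0.5 and the per-pair
  values are averaged (unweighted). Capping before averaging is a
  convention choice; the alternative (cap after) is ill-defined when a
  pair's root is imaginary.
* **N = ∞ branch** — a single inversion against the pooled PSTH of all
  other clusters (sum of their rate profiles, i.e. spike-count weighted),
  unit-normalised.

The final estimate is the mean of the branches, capped at (½+1)/2 = 0.75.
Sessions without trial events fall back to the homogeneous inverse on the
session-mean rate (whole-session binned rates proved too sensitive to bin
size to be worth using). Clusters with fewer than 2 spikes or an empty PSTH
are reported as NaN and excluded from summaries, as FDR is undefined there.

Population summaries (median and mean FDR over clusters, excluding those
labelled `mua`/`multi`) carry standard errors from a seeded nonparametric
bootstrap over clusters (default 1,000 resamples) — distribution-free and
valid for the median, which matters because cluster FDR distributions are
right-skewed.

## Simulator

`compose_cluster` plants a known FDR: the TP neuron fires at (1−f)·R_t and
N contaminants at f·R_t/N each (an even split — the symmetric default,
consistent with the (N−1)/N derivation), each neuron shaped by a PSTH tiled
periodically over the recording (piecewise-constant thinning, exact for
binned profiles) or homogeneous when no shape is given.

Each *finite-indexed* neuron is generated as a Poisson process with dead
time τ: the driving intensity is corrected to λ = r/(1 − rτ) so the
realised rate is exactly r, and spikes within τ of the previous kept spike
are removed. This matters: a memoryless train would violate with *itself*
at rate ≈ τₑ·r², which the N=1 model excludes by construction — single
contaminant clusters would otherwise behave like N≈2. The N = ∞ pool is a
single pure Poisson train, the exact superposition limit of infinitely many
vanishing-rate refractory neurons, and reproduces the ½·2τₑ·R_FP² term.

Violations are counted on consecutive ISIs of the merged train (censored
spikes removed first, then intervals shorter than τ counted, normalised by
the post-censoring spike count) — the field's convention.

Populations draw FDR from a bounded Cauchy distribution (rejection
sampling, which preserves the heavy right tail instead of piling atoms on
the bounds; default bounds (0, 0.5]), total rate from a bounded uniform,
N uniformly from {1, 2, 5, ∞} restricted to counts whose FDR_max
accommodates the drawn FDR, and TP/FP shapes independently from a packaged
library of parametric PSTHs (flat, up/down ramps, early/late transients,
two oscillation phases; all mean 1), which spans TP–FP covariances of both
signs (roughly −0.22 to +0.32 Hz² per unit rate-product, scaled by
R_TP·R_FP — a few tens of Hz² at typical rates). One integer seed expands
deterministically into per-cluster substreams.

### What the simulator does not emulate

Bursting and other non-Poisson firing, rate drift, waveform overlap
censoring at the detection stage, electrode geometry, and false negatives.
Passing validation therefore shows the estimator is correct *under the
generative model it assumes*; on real data from strongly bursting regions
the Poisson overlap statistics, and hence the estimates, degrade.

## Validation experiments and problem sizes

* **Analytic vs simulation** — homogeneous clusters on the grid
  FDR {0.05, 0.2, 0.5} × R_t {1, 10, 20} Hz × N {1, ∞}, 17 h each;
  simulated ISIv is compared to the model within 3 Monte-Carlo SE.
  Known limitation: the model counts violating *pairs*, the simulator (like
  real pipelines) counts *consecutive* ISIs. A pair is missed when a third
  neuron's spike lands inside the violating gap, probability ≈ R_t·τ/2.
  For N = 1 a miss is impossible (three mutually-close spikes require three
  neurons) and agreement is exact to MC noise; for N = ∞ at 20 Hz and
  FDR 0.5 the ≈2% undercount exceeds 3 MC SE at 17-h precision (z ≈ −4),
  and the corresponding check fails at that single extreme grid point. The
  effect on FDR estimates is ≤ ~0.013 even there and negligible elsewhere.
* **Known-parameter recovery** — 100 clusters, 28 h each, R_t ∈ [4, 20] Hz,
  Cauchy(0.2, 0.15) FDRs, all N and shape combinations; inversion with the
  true N, total profile and FP unit profile. RMSE ≈ 0.005–0.02 across
  seeds, dominated by occasional clusters near the N=1 cap where the
  inverse has a square-root singularity.
* **Finite recordings** — 10-minute clusters, R_t ∈ [1, 10] Hz, estimated
  with the realistic averaged-N pipeline on measured PSTHs. Single-cluster
  RMSE ≈ 0.10 with best-fit slope ≈ 1.0–1.1 against truth: noisy ISIv
  passed through the convex inverse (and the per-pair 0.5 caps) produces a
  mild upward bias around true FDR 0.2, visible as slope slightly above 1.
* **Population sweep** — five populations of 1,000 ten-minute clusters,
  R_t ∈ [4, 16] Hz, Cauchy locations 0.01–0.3 (scale tied to the location,
  ≤0.05). Median and mean FDR are recovered with RMSE ≈ 0.03 and ≈ 0.025;
  the median is overestimated at high true medians (> 0.25), consistent
  with the single-cluster bias above.
* **Minimum recording time** — duration at which the estimate's CV reaches
  a target (default 20%), via seeded Monte-Carlo bisection (≥150 replicates
  per duration) around a delta-method closed form
  T = (dFDR/dISIv)²·ISIv/(R_t·(cv·FDR)²); the delta method is also exposed
  directly as a fast approximation. The 8 Hz, 15%-FDR reference cluster
  needs ≈15 min; the requirement is unreachable (∞) for FDR at its cap.

## Numerical conventions

* Unit-vector inputs are validated to |‖u‖−1| ≤ 1e−8; profile
  normalisation itself is exact arithmetic.
* Tiny negative discriminants are treated as capped, not clipped.
* ISIv = 0 returns FDR = 0 without touching the radical.
* `bounded_cauchy(scale=0)` degenerates to a point mass at the location.
* All times in seconds, rates in Hz; the phy writer/reader converts to and
  from integer samples at the stated sampling rate.

## Known limitations

* The "50% FDR at 3 Hz" companion to the 20-Hz/5% reference point is not
  reproduced exactly by any single-N inverse here: at ISIv = 0.5%, R_t = 3 Hz
  the N=∞ inverse gives ≈0.42 and the N=1 inverse is imaginary (capped at
  0.5). The package reports the capped 0.5 under N=1.
* Per-pair N=1 estimates are capped before averaging; with many candidate
  profiles this inflates the N=1 branch for noisy low-rate clusters and is
  the main source of the finite-recording upward bias.
* The pair-vs-consecutive counting approximation above bounds the model's
  intrinsic accuracy at simultaneously high rate, high FDR and large N.
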