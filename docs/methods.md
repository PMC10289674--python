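# Methods

## The question the package answers

Given paired observations of spiking and a continuous motor output —
per-cycle spike times `S` (an N × J_max matrix, NaN-padded) and per-cycle
motor-output PC scores `M` (N × 2) — at what temporal scale does spike
timing stop mattering for the output?  We call that scale the *spike-timing
precision*: the smallest corruption of spike times that measurably destroys
mutual information (MI) between spiking and output.

Two estimation routes are implemented.  The continuous route is the
package's main method; the discrete route is the classical comparator.

## Continuous route: KSG mutual information under noise injection

**MI estimator.** The Kraskov–Stögbauer–Grassberger (KSG) k-nearest-neighbor
estimator, algorithm 1: all variables are standard scored, the distance to
each point's k-th neighbor is measured in the joint space under the max
(Chebyshev) norm, and the numbers of marginal neighbors strictly inside that
distance enter a digamma average,

    I = ψ(k) + ψ(N) − ⟨ψ(n_x + 1) + ψ(n_y + 1)⟩   (nats → bits).

`k = 4` throughout by default; estimates are insensitive to k in 2–7
(checked by test).  Values may be slightly negative near independence and
are reported unclipped.

**Count/timing decomposition.** Spike trains have variable spike counts, so
the total information splits as

    I_total = I(count; M) + Σ_i p(count = i) · I(times | count = i; M).

The count term uses a nearest-neighbor mixed discrete–continuous estimator
(within-class k-th-neighbor radius, full-sample neighbor count), capped at
the label entropy.  Each timing term is a plain KSG run on the n_i × i
matrix of spike times for trials with count i.  Count classes smaller than
max(k + 2, 10) trials are excluded from the timing sum (the weight is still
reported): k + 1 points is the estimator's hard floor and tiny classes
dominate variance.

**Noise protocol.** Every spike time is shifted by an independent draw from
U(0, r_c); the common r_c/2 mean shift is irrelevant to MI.  For each noise
width on a grid (default: 0 plus 60 log-spaced levels from the 0.1 ms
sampling resolution to 32 ms) the decomposed MI is re-estimated many times
(150 by default; reduced in desk-scale runs) and the per-level mean and
standard deviation recorded.  Corruption destroys information carried at
scales finer than r_c, so the curve is flat until r_c reaches the true
precision and decays beyond it, saturating at the count-only term once r_c
far exceeds the spike-time range.

**Zero-noise uncertainty.** The r_c = 0 estimate is deterministic, so its
uncertainty is estimated by data fractioning: for f = 2…5 the trials are
split into f disjoint random subsets, MI estimated on each, the across-subset
standard deviation recorded, and std(n) = A/√n fit by least squares through
the origin and evaluated at the full N.

**Precision selection rules.**

* *STD threshold* (default): the smallest grid value whose mean MI falls
  below (zero-noise MI − zero-noise std).  Chosen as the default for its
  simplicity and because it explicitly accounts for estimation uncertainty.
* *Derivative*: the second finite difference of mean MI, taken on the
  log10(r_c) axis (uniform spacing for the default grid; a linear-axis
  difference would amplify estimator noise at the densely sampled fine
  end), normalized to unit maximum magnitude.  The precision is the highest
  peak of |d²I/du²| passing a minimum amplitude (0.1) and prominence
  (0.05), both configurable.  The curvature magnitude is used because the
  knee of the curve is the curvature extremum irrespective of sign.
* *Two-line*: straight lines are fit to the first and last 30 non-zero
  levels in (log10 r_c, MI) coordinates and the precision read off at their
  intersection; the fit is in log space because that is the axis on which
  the plateau and decay are approximately linear.  Requires ≥ 60 non-zero
  levels; returns "unresolved" for parallel lines or an out-of-range
  intersection.

All three rules agree to within ~1 ms on synthetic recovery runs; the STD
rule is the default.

**Tie handling.** The estimator assumes continuous data, but rounded spike
times (and any data quantized to the acquisition grid) contain exact ties.
A deterministic jitter of amplitude 1e-10 of a (unit) column standard
deviation — seeded from the run seed and a content hash of the variable, so
it is identical regardless of argument order — is added only inside distance
computations.  It sits nine orders of magnitude below the 0.1 ms resolution.
The marginal count radius is additionally shrunk by a relative 1e-12 so the
k-th neighbor, which often lies exactly on a marginal ball boundary, is
excluded deterministically rather than at the mercy of floating-point
rounding in the boundary comparison.

## Discrete route: NSB entropies on spike words

Spikes are binned into b_s equal bins spanning the overall observed
spike-time range (one global window per muscle), giving per-trial "spike
words"; bin size r_d = (t_max − t_min)/b_s.  Motor output is discretized by
splitting each PC score into b_m equal-count groups (default b_m = 3, nine
joint states; ties broken by stable rank).  MI is

    I_d = H(S_d) − Σ_i p(m_i) H(S_d | M_d = m_i)

with every entropy estimated by the Nemenman–Shafee–Bialek (NSB) posterior
mean; uncertainties are posterior standard deviations combined in
quadrature.

**NSB numerics.** The estimator mixes symmetric Dirichlet priors with the
weight that makes the prior over entropy flat, and integrates the closed-form
first and second Dirichlet posterior entropy moments against the evidence.
The integral runs over the concentration parameter on a 300-point log-spaced
grid bracketing essentially the full prior entropy range (brentq on the
prior-entropy map for the endpoints), with unobserved symbols grouped in
closed form so alphabets up to the 1e8 cap cost nothing.  The word-alphabet
size is K = Π_j (1 + max observed count in bin j), capped at 1e8: the true
alphabet is unbounded, NSB needs a finite K, and in the coincidence-dominated
regime the result is insensitive to K well below the cap.

**Shuffling correction and peak rule.** Undersampling bias grows with b_s;
it is estimated by re-computing the conditional entropy with motor states
randomly permuted (n_sh ≥ 10 permutations) and subtracted:
I_d,sh = mean_sh H_sh(S_d | M_d,sh) − H(S_d | M_d).  The precision is the
bin size where I_d,sh peaks.  Ties are broken toward fewer bins (coarser,
conservative), and "tie" includes anything within the propagated uncertainty
of the global maximum — without that, data whose corrected MI plateaus (no
bias growth once bins resolve the structure, as happens for rounded
synthetic data) would have its peak chosen by noise anywhere along the
plateau.

## Synthetic data

* `gaussian_pair`: one "spike time" and two "PC scores" per trial, all
  pairwise correlated at ρ through a common latent factor (so
  corr(score₁, score₂) = ρ²); defaults n = 2500, μ = 0, σ = 2.  The true MI
  has a closed form, making this the primary estimator oracle.
* `moth_like`: per-trial spike counts drawn from a configurable
  distribution over 1–5 (weighted toward 1–3 spikes, as in single flight
  muscles), baseline spike phases spread through a ~45 ms wingbeat window,
  and each spike time coupled to the shared motor drive with correlation
  `timing_rho` (default 0.8) and timing scale 3 ms.  Counts are drawn
  independently of the scores, so information is carried almost entirely in
  timing — the regime the decomposition is designed to isolate.
* `fix_precision`: rounds spike times to multiples of a resolution,
  imposing a known ground-truth precision (idempotent by construction).
* `raw_flight_signal`: 10 kHz traces for the segmentation stage — a
  periodic force with one downward peak per cycle, and a torque whose
  per-cycle variation lives on exactly two latent waveforms.

What the generators do not emulate: temporal dependence across cycles,
non-Gaussian timing jitter, count–output coupling (available by setting the
count distribution, but off by default), recording artifacts, or spike
sorting errors.  Passing recovery tests therefore demonstrates estimator
correctness at known ground truth, not robustness to every property of real
recordings.

## Segmentation

F_z is band-pass filtered (8th-order Butterworth, 5–35 Hz) with zero-phase
forward–backward application — phase lag would shift every cycle's zero
point systematically.  Zero points are the crossings of the Hilbert
analytic phase through a target phase (default π, the waveform minimum =
peak downward force, configurable).  Spikes become within-cycle times in ms
relative to the zero points; per-cycle torque windows truncated to the
shortest cycle length L are reduced by PCA to two scores, with loading signs
fixed so each loading's largest-magnitude element is positive.  Hilbert
phase on finite traces has edge effects of a few samples; the noiseless
fixture is recovered to within 2 ms.

## Numerical and design notes

* MI is reported in bits; all digamma arithmetic is in nats with one
  conversion.
* Neighbor search uses a k-d tree above 200 points and brute-force distance
  matrices below; both agree exactly (tested).  Marginal counting uses a
  JIT-compiled sorted-scan kernel where numba is available, with identical
  results to the tree path.
* The zero-noise MI is computed once per curve (the input is deterministic
  given the tie-break policy); noise repetitions are independent draws, not
  common random numbers across levels.
* Scaled problem sizes: the shipped validation defaults (n = 2500, 30
  corruption repeats, 40-level grid, 4 repeats per condition) keep a full
  recovery experiment around ten minutes on one CPU; 150 repeats remains
  the faithful default in `RunConfig` and reports carry a `scaled_down`
  flag whenever fewer are used.

## Known limitations

* Precision below the 0.1 ms sampling resolution is unobservable by
  construction, and the k-NN operating scale ties the finest detectable
  precision to sample size: with ~2500 trials and strong coupling the STD
  rule can report a value a few percent below a 1 ms ground truth, while at
  truly sub-millisecond ground truths the resolution floor keeps estimates
  conservative (at or above truth).
* The discrete route undersamples quickly as b_s and the motor-state count
  grow; even shuffle-corrected, it is noisier and coarser than the
  continuous route, which is the point of the comparison.
* The mixed discrete–continuous count estimator is one defensible
  construction among several; it is cross-checked against an independent
  implementation and against count-as-continuous encoding in the tests.
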