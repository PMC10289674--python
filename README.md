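# spikeprecision

Estimation of **spike-timing precision**: the temporal scale at which the
precise timing of spikes stops carrying information about a continuous
motor output.

Motor systems such as the hawk moth flight motor program encode control
signals not only in how many spikes a muscle fires per wing stroke but in
*when* those spikes occur, down to the millisecond.  This package
implements an information-theoretic procedure for putting a number on that
scale, for data organized as paired per-cycle observations: an N × J_max
matrix `S` of within-cycle spike times (ms, NaN-padded) and an N × 2
matrix `M` of motor-output principal-component scores.

## Method

The core idea: corrupt every spike time with uniform noise of width r_c,

    S′ = S + U(0, r_c),

and re-estimate the mutual information I(S′; M) with the
Kraskov–Stögbauer–Grassberger (KSG) k-nearest-neighbor estimator (k = 4),
decomposed so that count coding and timing coding are separated:

    I_c = I(S′_count; M) + Σ_i p(count = i) · I(S′_times; M | count = i).

Noise of width r_c destroys information carried at scales finer than r_c,
so the curve of mean MI versus r_c (150 corruption draws per level by
default) stays flat until r_c reaches the code's precision and decays
beyond it.  The reported precision is the noise width where the mean MI
first falls below the zero-noise estimate minus its uncertainty (estimated
by data fractioning); two alternative read-outs — the peak of the second
derivative of the curve, and the intersection of lines fit to its two
log-linear ends — are also provided and agree to ~1 ms.

For comparison the package includes the classical discrete route: spike
trains binned into words of b_s bins, motor output quantile-discretized
into b_m² states, entropies estimated with the Nemenman–Shafee–Bialek
(NSB) Bayesian estimator, residual undersampling bias removed by shuffling
motor states, and the precision read off where the corrected MI peaks as
b_s grows.

Synthetic generators with known ground truth (correlated-Gaussian
time/score pairs; moth-like multi-spike wingbeat data), precision fixing
by rounding, and Hilbert-phase wing-stroke segmentation of raw 10 kHz
force/torque traces round out the pipeline.  See `docs/methods.md` for the
full model description and numerical choices.

## Worked example

Simulate a single-spike dataset whose spike times and motor scores are
correlated Gaussians (ρ = 0.8), fix its precision to exactly 2 ms by
rounding, and estimate that precision back blind:

```sh
spikeprec simulate gaussian-pair --n 400 --rho 0.8 --seed 3 \
    --fix-resolution 2.0 --out ds/
# cfg.json: {"k": 4, "n_noise_reps": 8, "seed": 11,
#            "noise_grid": [0.0, 0.2, 0.3, 0.45, ..., 17.3]}  (12 levels)
spikeprec estimate-continuous --spikes ds/spikes.csv --motor ds/motor.csv \
    --config cfg.json --seed 11 --out out/
# {"std_threshold": 2.278125, "derivative": 2.278125}
spikeprec estimate-discrete --spikes ds/spikes.csv --motor ds/motor.csv \
    --bs-max 30 --nsh 10 --seed 4 --out outd/
# nsb_peak precision: 2.4 ms
```

Both routes recover the imposed 2 ms ground truth from above — estimates
land at the first tested noise width (or bin size) at which information
measurably degrades, here 2.28 ms and 2.4 ms.  `out/noise_curve.csv`
holds the full MI-versus-noise curve (`r_c_ms, mi_mean_bits,
mi_std_bits`) and `outd/discrete_curve.csv` the discrete sweep.

The same from Python:

```python
from spikeprecision import (GaussianPairSpec, gaussian_pair, fix_precision,
                            RunConfig, noise_curve, precision_std)

spikes, motor = gaussian_pair(GaussianPairSpec(n=2500, rho=0.9, seed=1))
spikes = fix_precision(spikes, 2.0)            # impose 2 ms ground truth
curve = noise_curve(spikes, motor, RunConfig(n_noise_reps=30, seed=5))
print(precision_std(curve).value)              # 1.878473504144411 (ms)
```

A full recovery experiment (several ground truths × repeats, with a
report table) is `spikeprec validate`; `spikeprec compare` summarizes the
mean absolute error of each selection rule.

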