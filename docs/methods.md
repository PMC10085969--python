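# Methods

## Signal model

Functional ultrasound power-Doppler imaging reports cerebral blood
volume changes. `fusdeconv` models a set of M region-of-interest (ROI)
time-series `y_m(t)` as a **convolutive mixture** of a few uncorrelated
source signals:

    y_m(t) = sum_{r in T} sum_{l=0}^{L} h_{mr}(l) s_r(t - l)
           + sum_{r in A} a_{mr} s_r(t)

Task sources (set T, e.g. the visual stimulation paradigm) drive each
region through its own hemodynamic response function (HRF) `h_{mr}`;
artifact sources (set A, e.g. motion or instrumentation noise) enter
directly through per-region gains `a_{mr}` — formally a scaled unit
impulse filter. Neither the sources nor the filters are observed: the
problem is blind.

Each task HRF is constrained to a single-gamma shape

    h(t; θ) = θ1 Γ(θ2)^{-1} θ3^{θ2} t^{θ2-1} e^{-θ3 t},

appropriate for CBV-weighted signals, which lack the undershoot of the
canonical BOLD double-gamma. θ1 is the response height, θ2 the delay
(shape) and θ3 the dispersion (rate, 1/s); the curve peaks at
(θ2−1)/θ3 seconds.

## Identification from second-order statistics

Stacking `Lp` lagged copies of each region's series gives a
block-Hankel data matrix `Y` with columns y(n), and the mixture becomes
`Y = H S` with `H` a matrix of banded Toeplitz blocks (Lp × (L+Lp) per
region/source). Because the sources are uncorrelated, the lagged
autocorrelation matrices `R_y(τ) = E{y(n) y(n+τ)ᵀ} = H R_s(τ) Hᵀ` have
block-diagonal core matrices, and stacking τ = 0..K−1 yields a 3-way
tensor admitting a block-term decomposition (BTD)

    T ≈ sum_r C_r ×₁ H_r ×₂ H_r ,

one low-multilinear-rank term per source. Each core `C_r` stacks the
source's lag-shifted Toeplitz autocorrelation slices and is generated
by a single vector `z_r` through the λ operator: slice k has entries
`z_r[|k + i − j|]`. We constrain `z_r` to be symmetric in lag (indexing
by |·|), which is exact for second-order stationary sources and halves
the parameter count relative to an unconstrained generating vector.

The empirical tensor uses the biased estimator with common divisor
`n_valid = (#columns − K)`, keeping slices jointly consistent; slice 0
is symmetric PSD by construction. A second estimator
(`tensor_estimator="stationary"`) assembles the tensor from one
full-record lag-correlation function per region pair, making every
slice exactly Toeplitz-block; it has a markedly lower cost floor on
noiseless data (the direct estimator's per-entry summation windows are
mutually inconsistent, which surfaces as a small systematic latency
distortion), but in benchmark simulations at 0 dB the direct
estimator's full-pipeline latency error was smaller, so direct remains
the default.

## Fitting

The cost

    J = || T − Σ_{r∈T} λ(z_r) ×₁ H_r(θ_r) ×₂ H_r(θ_r)
           − Σ_{r∈A} λ(z_r) ×₁ H_r(a_r) ×₂ H_r(a_r) ||_F²

is minimized by limited-memory BFGS with analytic gradients over the
unconstrained vector [u, a, z]. Positivity of θ is enforced by
θ1 = e^{u1}, θ3 = e^{u3}; for the delay we use θ2 = 1 + e^{u2}. The
strictly-greater-than-one constraint does slightly more than
positivity: it guarantees an interior HRF peak and keeps the lag-0
filter tap finite (the gamma curve diverges at t = 0 for θ2 < 1,
which would make the cost non-finite during line searches). A
hemodynamic response with no interior peak is not physiologically
meaningful, so nothing of scientific interest is excluded.

Scale ambiguity between a core and its mixing column is removed by
pinning `z_r[0] = 1` (unit source variance); response height then
lives in θ1 (or the artifact gains). Sign and common-delay ambiguities
are intrinsic to second-order blind deconvolution: the sign is
resolved downstream (see Source recovery), and the delay is only
weakly anchored by the gamma parametrization — the dominant
contributor to peak-latency error at low SNR.

Per restart, the initial θ2 and θ3 are log-uniform over [1.05, 25] and
[1, 6] (the physiologic corridor of plausible shapes), θ1 = 1, gains
standard normal. The core generators are then set to their exact
least-squares optimum given the initial filters — the cost is
quadratic in z, so this solves a small normal-equation system (~0.1 s)
and spares the quasi-Newton iterations from fitting the cores from
scratch. Stopping: projected-gradient infinity norm ≤ 1e-8, relative
cost change ≤ 1e-14, or `max_iter` iterations (default 500).

Overflow safety: the unconstrained variables are clipped to ±40 before
exponentiation; a restart whose cost turns non-finite is flagged
failed and redrawn (up to a retry budget).

## Stability selection over restarts

The cost is non-convex and restarts land in different local minima.
Following the Icasso rationale, the final estimate is the most
*recurrent* solution rather than the lowest-cost one:

1. Run the decomposition `n_restarts` times (default 20), storing each
   final cost and the M HRFs.
2. Drop high-cost outliers by Otsu's threshold on the costs. The
   criterion is evaluated exactly (exhaustive sweep over inter-point
   midpoints maximizing between-class variance) rather than on a
   histogram: with ~20 values, binning can misplace mode edges.
3. Drop fully collapsed runs in which *every* recovered peak latency
   falls below `pl_floor` (default 0.25 s, the lower edge of the
   physiological latency range): a solution whose task filters all
   peak (near-)instantaneously duplicates the artifact impulse term,
   and such collapsed solutions recur almost identically across
   restarts, forming spuriously tight clusters. Runs with only some
   small latencies are kept — genuinely fast regions exist (screening
   on *any* small latency was tried and discarded: it throws away the
   best run whenever a true latency is small).
4. Cluster the remaining runs on their M-vector of HRF peak latencies:
   agglomerative, complete linkage, Euclidean metric, tree cut at
   `t_cut` seconds.
5. Score each cluster by d_C = (complete diameter) / n_C and pick the
   minimum; singletons (diameter trivially 0) are excluded from
   winning unless nothing recurs at all; remaining ties go to the
   larger cluster, then to lower mean cost.
6. Average the winning cluster's HRF curves pointwise per region (the
   parameter means are reported alongside).

`t_cut` is set so that solutions differing by about one sample of the
simulation grid per region (0.5 s at 2 Hz; √M · 0.5 ≈ 0.87 s in the
M = 3 Euclidean feature space) still count as the same solution;
tighter cuts fragment genuinely recurring solutions into slivers that
lose to accidental near-duplicates.

An optional post-selection *delay polish* (`delay_polish=True`)
resolves the common-delay ambiguity explicitly: every task HRF of each
winning restart is shifted by a candidate offset, the cores — in which
the cost is quadratic — are refit exactly by least squares, and the
offset minimizing the cost is kept before the members are averaged.
The anchor (a time-shifted gamma is not a gamma) is reliable on
low-noise data, where it tightens latency recovery; at 0 dB the noise
overwhelms it and the scan chases spurious minima, so the polish is
off by default.

## Source recovery

With the final HRFs arranged in Toeplitz block columns and the
artifact gains as impulse blocks, the sources are recovered from the
Hankelized data by a truncated-SVD pseudo-inverse of the
**concatenated** mixing matrix `[H_1 ... H_R]`; each source is the
corresponding block of rows of `H⁺ Y`. Inverting the full matrix (as
opposed to one block column at a time) is what separates the sources:
a single block's pseudo-inverse folds every other source into the
estimate. Singular values below `svd_tol · σ_max` (default 0.05) are
discarded; the mixing matrix always carries one structural null
direction (all gamma filters have h(0) = 0), and with noisy data the
truncation also regularizes the deconvolution. The first L Hankel
columns cover samples with incomplete filter history and are excluded
before inversion. The recovered Hankel block is collapsed to a single
series by anti-diagonal averaging (the least-squares projection onto
exactly-Hankel matrices). Sign is canonicalized by positive mean over
the stimulus window when a paradigm is available, else by positive
skewness.

A binary paradigm estimate is produced by peak detection on the task
source (prominence ≥ 0.5 SD, minimum separation default 8 s) and
outward search for the first crossings of half the peak height.

## Synthetic data

The simulator reproduces the block-design visual stimulation protocol:
a binary paradigm of 20 stimuli of 4 s separated by uniform random
10–15 s rests, sampled at 2 Hz; per-region gamma HRFs drawn by
rejection sampling with peak latency in [0.25, 4.5] s, FWHM in
[0.5, 4.5] s and peak amplitude uniform in (0, 1]; and one shared
artifact source — a Gaussian process with piecewise-constant mean
(segment lengths uniform in [20, 60] samples, mean levels N(0,1),
white noise SD 1). The artifact is scaled per region so that
10·log10(var(clean) / var(gain·artifact)) equals the requested SNR;
variance (fluctuation power) rather than raw mean square is used
because the clean signal's DC baseline carries no task information and
is removed when the rows are z-scored, exactly as real ROI series are
normalized before deconvolution.

What the simulator does **not** emulate: trial-to-trial amplitude
variability of real evoked responses, hemodynamic nonlinearity,
pixel-level imaging noise, and spatially structured artifacts. Passing
the simulation benchmarks therefore demonstrates correct recovery
under the stated generative model, not performance on arbitrary in
vivo recordings.

Shape descriptors (peak latency, FWHM) of simulated and estimated
HRFs are measured on a dense 50 ms grid so that sub-sample latencies
are representable; the filter itself lives on the acquisition grid.

## Problem sizes and numerical choices

Defaults follow the first-experiment configuration scaled to the
2 Hz simulation rate: filter support 8 s (L = 16 samples, 17 taps),
Hankel window Lp = 2(L+1) = 34, K = L+1 = 17 lags, one task and one
artifact source, 20 restarts. The Monte-Carlo benchmark in
`scripts/acceptance.py` uses 10 iterations at 0 dB with 20 restarts
and a 500-iteration optimizer cap per restart, and averages the
out-of-family (plateau) experiment over 5 HRF draws with 12 restarts
each — the study design it mirrors used 100 Monte-Carlo iterations,
and the quantities compared (a median and a mean) are stable at the
reduced count up to the Monte-Carlo error of order 0.1 s / 0.05
correlation units. Restart count is the parameter robustness leans
on hardest: halving it mainly hurts the difficult datasets, whose
stable cluster needs several good-basin hits to form.

Degenerate inputs are rejected with typed errors: constant series
(z-scoring, correlation), zero-power clean signals (SNR undefined),
all singular values discarded (truncation), fewer than two restarts
(selection).

## Reproducing the in vivo analyses

The mouse recordings behind the real-data results (SC/LGN/V1 peak
latencies of ≈1/1.75/2 s, Fano factors 0.23/0.42/0.8, paradigm
correlation ≈0.5) are not shipped here. Given the deposited power-
Doppler recordings, the pipeline is: `fusdeconv preprocess` (SVD
clutter filter with the 30 %/1 % cut-offs, per-ensemble power, ROI
averaging over the ICA-derived masks, z-scoring) at the acquisition
rate of 4 Hz, then `fusdeconv deconvolve` with L = K = 32, Lp = 64,
R = 2, 20 restarts, then `fusdeconv sources`/`evaluate` for the
paradigm correlation and `fano_factor` over the stimulus onsets with
the [0, 10] s post-stimulus window. These numbers are documented for
reproducibility but are not part of the desk-scale test suite.

## Known limitations

- The common-delay ambiguity of second-order blind deconvolution is
  resolved only statistically (gamma-family anchoring plus cluster
  averaging); residual peak-latency bias of a fraction of a sample
  remains at low SNR.
- Identifiability degrades when a task HRF approaches an impulse; the
  selection-stage latency floor handles the common collapse mode but
  genuinely sub-0.25 s responses would be screened out with it.
- With multiple task sources the solver does not resolve source
  permutation; downstream matching is the caller's responsibility.
- Truncation level `svd_tol` trades leakage against noise
  amplification; 0.05 suits 0 dB-scale noise, while near-noiseless
  data benefit from ~1e-3.
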