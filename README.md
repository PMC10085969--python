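# fusdeconv

Blind deconvolution of functional ultrasound (fUS) region time-series:
joint recovery of region-specific hemodynamic response functions
(HRFs) and the activity-inducing source signals that drive them, via a
structured block-term decomposition (BTD) of the lagged
autocorrelation tensor.

## The problem

Power-Doppler fUS measures cerebral blood volume changes. The standard
analysis convolves a presumed binary experimental paradigm (EP) with a
fixed HRF — but the HRF varies across brain regions and stimuli, and
the true activity-inducing signal can be richer than the programmed
paradigm. `fusdeconv` treats M region-of-interest series as a
convolutive mixture

    y_m(t) = Σ_{r∈T} Σ_l h_mr(l) s_r(t−l) + Σ_{r∈A} a_mr s_r(t),

with task sources passing through single-gamma HRFs
`h(t;θ) = θ1 Γ(θ2)⁻¹ θ3^θ2 t^(θ2−1) e^(−θ3 t)` and artifact sources
entering as scaled impulses, and estimates *both* the filters and the
sources from second-order statistics alone: Hankelizing the data turns
the mixture into `Y = H S` with Toeplitz-block `H`, and the stacked
lagged autocorrelation matrices form a tensor decomposing as
`T = Σ_r C_r ×₁ H_r ×₂ H_r`. The decomposition cost is minimized by
quasi-Newton descent from many random restarts; an Otsu cost filter
plus agglomerative clustering of HRF peak latencies selects the stable
solution, and sources are recovered by a truncated-SVD pseudo-inverse
of the fitted mixing matrix. See `docs/methods.md` for details.

Intended users: neuroimaging methods researchers working with fUS (or
other hemodynamic) time-series who need region- and stimulus-specific
HRF estimates and data-driven source signals.

## Worked example

```python
import numpy as np
from fusdeconv import BTDDeconvolver, simulate_dataset
from fusdeconv.evaluate import ep_correlation
from fusdeconv.sources import canonicalize_sign

ds = simulate_dataset(M=3, snr_db=0.0, rng=np.random.default_rng(3))
dec = BTDDeconvolver(fs=2.0, n_restarts=20, random_state=3)
dec.fit(ds.Y.T)                       # (n_times, n_regions)

print("estimated PL:", np.round(dec.peak_latencies_[0], 2))
sources = dec.transform(ds.Y.T)       # (n_times, n_sources)
r = ep_correlation(canonicalize_sign(sources[:, 0]), ds.ep.vector, trim=16)
print("paradigm correlation:", round(r, 2))
```

Running exactly this prints

```
estimated PL: [2.25 4.05 1.85]
paradigm correlation: 0.77
```

The three simulated regions' ground-truth peak latencies are
`[1.45, 3.4, 1.3]` seconds: the recovered latencies preserve the
regional ordering (region 2 slowest, region 3 fastest) with a common
residual delay of roughly one sample — the delay ambiguity inherent to
second-order blind deconvolution, discussed in `docs/methods.md`. The
recovered task source (`sources[:, 0]`) correlates 0.77 with the
binary paradigm that generated the data, which is also the mean
correlation across datasets at this 0 dB noise level; `sources[:, 1]`
tracks the artifact.

The same pipeline is scriptable from the shell:

```bash
fusdeconv simulate --snr-db 0 --seed 7 --out sim.csv
fusdeconv deconvolve --input sim.csv --seed 7 --out run/
fusdeconv evaluate --sources run/sources.csv --truth sim.truth.json
```

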