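"""Synthetic multi-ROI hemodynamic datasets.

Emulates a block-design visual stimulation experiment sampled at the
power-Doppler rate: a binary experimental paradigm (EP) drives every
region through a region-specific gamma HRF, and an additive artifact
source (a Gaussian process with piecewise-constant mean, standing in for
motion/instrumentation noise) is mixed in at a controlled per-region
signal-to-noise ratio. Rows of the returned matrix are z-scored, exactly
as real region time-series are normalized before deconvolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .hrf import HRFParameters, evaluate_hrf, sample_random_hrf


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ExperimentalParadigm:
    """Binary stimulus on/off vector with block metadata."""

    vector: np.ndarray
    fs: float
    onsets: np.ndarray   # sample index of each stimulus start
    offsets: np.ndarray  # sample index one past each stimulus end
    n_reps: int

    def __post_init__(self):
        object.__setattr__(self, "vector", np.asarray(self.vector, float))
        object.__setattr__(self, "onsets", np.asarray(self.onsets, int))
        object.__setattr__(self, "offsets", np.asarray(self.offsets, int))

    @property
    def n_samples(self) -> int:
        return self.vector.size


def generate_ep(n_reps: int = 20, stim_dur: float = 4.0,
                rest_range: tuple[float, float] = (10.0, 15.0),
                fs: float = 2.0,
                rng: np.random.Generator | None = None) -> ExperimentalParadigm:
    """Binary paradigm: ``n_reps`` stimulus blocks, each preceded by a rest.

    Rest durations are drawn uniformly from ``rest_range`` seconds and
    rounded to the sample grid; the vector ends at the last stimulus
    offset.
    """
    rng = np.random.default_rng(rng)
    if n_reps < 1:
        raise SimulationError("n_reps must be >= 1")
    if rest_range[0] < 1.0 / fs:
        raise SimulationError("rest_range lower bound shorter than one sample")
    stim_len = stim_dur * fs
    if abs(stim_len - round(stim_len)) > 1e-9:
        stim_len = round(stim_len)
    stim_len = int(round(stim_len))

    pieces, onsets, offsets = [], [], []
    pos = 0
    for _ in range(n_reps):
        rest_len = int(round(rng.uniform(*rest_range) * fs))
        pieces.append(np.zeros(rest_len))
        pos += rest_len
        onsets.append(pos)
        pieces.append(np.ones(stim_len))
        pos += stim_len
        offsets.append(pos)
    vector = np.concatenate(pieces)
    return ExperimentalParadigm(vector=vector, fs=fs, onsets=np.array(onsets),
                                offsets=np.array(offsets), n_reps=n_reps)


def generate_artifact(n: int, segment_len_range: tuple[int, int] = (20, 60),
                      mean_scale: float = 1.0, noise_sd: float = 1.0,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Gaussian process with changing mean.

    Piecewise-constant mean levels ~ N(0, mean_scale^2) on segments of
    random length in ``segment_len_range`` samples, plus white Gaussian
    noise with standard deviation ``noise_sd``.
    """
    rng = np.random.default_rng(rng)
    if n < 1:
        raise SimulationError("n must be >= 1")
    lo, hi = segment_len_range
    mean = np.empty(n)
    pos = 0
    while pos < n:
        seg = int(rng.integers(lo, hi + 1))
        mean[pos:pos + seg] = rng.normal(0.0, mean_scale)
        pos += seg
    return mean + rng.normal(0.0, noise_sd, size=n)


def zscore_rows(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, float)
    mu = Y.mean(axis=1, keepdims=True)
    sd = Y.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise SimulationError("cannot z-score a constant row")
    return (Y - mu) / sd


def causal_convolve(h: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Causal FIR filtering with zero initial history, truncated to len(s)."""
    return np.convolve(s, h)[: s.size]


@dataclass(frozen=True)
class SimulatedDataset:
    """Synthetic region×time dataset with full ground truth attached."""

    Y: np.ndarray                 # M x N, rows z-scored
    Y_raw: np.ndarray             # M x N, pre-normalization
    hrfs: list                    # M HRFParameters (or callables' taps) per region
    hrf_taps: np.ndarray          # M x (L+1) filter taps actually used
    ep: ExperimentalParadigm
    artifact: np.ndarray
    artifact_gains: np.ndarray    # M
    snr_db: np.ndarray            # per-region dB
    fs: float
    L: int
    rng_seed: int | None = field(default=None)

    @property
    def n_regions(self) -> int:
        return self.Y.shape[0]

    def ground_truth_json(self) -> str:
        return json.dumps({
            "fs": self.fs, "L": self.L,
            "snr_db": np.asarray(self.snr_db).tolist(),
            "artifact_gains": self.artifact_gains.tolist(),
            "hrfs": [
                {"theta1": p.theta1, "theta2": p.theta2, "theta3": p.theta3}
                if isinstance(p, HRFParameters) else None
                for p in self.hrfs
            ],
            "ep": self.ep.vector.tolist(),
        })


def _measured_power(x: np.ndarray) -> float:
    # fluctuation power (variance): the DC baseline carries no task
    # information and is removed by the z-scoring anyway, so SNR is
    # calibrated on the informative signal content
    return float(np.var(x))


def simulate_dataset(M: int = 3, snr_db: float | np.ndarray = 0.0,
                     fs: float = 2.0, L: int | None = None,
                     ep_config: dict | None = None,
                     hrf_ranges: dict | None = None,
                     artifact_config: dict | None = None,
                     hrf_taps: np.ndarray | None = None,
                     rng: np.random.Generator | int | None = None) -> SimulatedDataset:
    """Simulate an M-region dataset at a controlled SNR.

    Per region ``m`` the clean signal is the causal convolution of a
    region-specific HRF with the EP; the shared artifact is scaled so
    that ``10 log10(power(clean_m) / power(gain_m * artifact))`` equals
    ``snr_db`` (per region, pre-normalization). ``snr_db = inf`` yields
    an artifact-free dataset. Pass ``hrf_taps`` (M x (L+1)) to override
    the random gamma HRFs, e.g. with an out-of-family plateau shape.
    """
    rng = np.random.default_rng(rng)
    if M < 1:
        raise SimulationError("M must be >= 1")
    if L is None:
        L = int(round(8.0 * fs))
    ep = generate_ep(fs=fs, rng=rng, **(ep_config or {}))
    N = ep.n_samples

    hrfs: list = []
    if hrf_taps is None:
        taps = np.empty((M, L + 1))
        for m in range(M):
            p = sample_random_hrf(rng=rng, **(hrf_ranges or {}))
            hrfs.append(p)
            taps[m] = evaluate_hrf(p, 1.0 / fs, L).values
    else:
        taps = np.asarray(hrf_taps, float)
        if taps.shape != (M, L + 1):
            raise SimulationError(f"hrf_taps must be {(M, L + 1)}, got {taps.shape}")
        hrfs = [None] * M

    clean = np.stack([causal_convolve(taps[m], ep.vector) for m in range(M)])

    snr_db = np.broadcast_to(np.asarray(snr_db, float), (M,)).copy()
    artifact = generate_artifact(N, rng=rng, **(artifact_config or {}))
    p_art = _measured_power(artifact)
    gains = np.zeros(M)
    for m in range(M):
        p_clean = _measured_power(clean[m])
        if p_clean == 0:
            raise SimulationError(f"region {m} has zero-power clean signal; "
                                  "SNR is undefined")
        if np.isfinite(snr_db[m]):
            gains[m] = np.sqrt(p_clean / (p_art * 10.0 ** (snr_db[m] / 10.0)))
    Y_raw = clean + gains[:, None] * artifact
    return SimulatedDataset(Y=zscore_rows(Y_raw), Y_raw=Y_raw, hrfs=hrfs,
                            hrf_taps=taps, ep=ep, artifact=artifact,
                            artifact_gains=gains, snr_db=snr_db, fs=fs, L=L)


def plateau_hrf_taps(fs: float, L: int, peak_latency_s: float = 1.5,
                     plateau_dur_s: float = 2.0, amplitude: float = 1.0,
                     theta2: float = 9.0) -> np.ndarray:
    """A sustained-peak (plateau) HRF outside the single-gamma family.

    Gamma rise to the peak, flat top of ``plateau_dur_s`` seconds, then
    the gamma decay resumed; used to probe robustness to HRF shapes the
    model cannot represent.
    """
    theta3 = (theta2 - 1.0) / peak_latency_s
    base = evaluate_hrf(HRFParameters(1.0, theta2, theta3), 1.0 / fs, L).values
    t = np.arange(L + 1) / fs
    hold = int(round(plateau_dur_s * fs))
    i_peak = int(np.argmax(base))
    out = np.empty(L + 1)
    out[: i_peak + 1] = base[: i_peak + 1]
    out[i_peak + 1: i_peak + 1 + hold] = base[i_peak]
    tail = base[i_peak + 1:]
    n_tail = L + 1 - (i_peak + 1 + hold)
    if n_tail > 0:
        out[i_peak + 1 + hold:] = tail[:n_tail]
    del t
    return amplitude * out / out.max()
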