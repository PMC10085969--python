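"""Single-gamma hemodynamic response functions.

The HRF links an activity-inducing source signal to the measured
hemodynamic (cerebral blood volume) time-series. For CBV-weighted
modalities such as power-Doppler functional ultrasound the undershoot of
the canonical double-gamma BOLD response is absent, so the response is
modelled with a single gamma function

    h(t; theta) = theta1 * Gamma(theta2)^{-1} * theta3^theta2
                  * t^(theta2 - 1) * exp(-theta3 * t)

where ``theta1`` controls the response height, ``theta2`` the delay and
``theta3`` the dispersion. For ``theta2 > 1`` the curve rises from zero
to a unique interior maximum at ``t = (theta2 - 1) / theta3`` and decays
back to zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln


class HRFError(ValueError):
    """Invalid HRF parameters or degenerate curve."""


@dataclass(frozen=True)
class HRFParameters:
    """Parameters of a single-gamma HRF.

    Attributes
    ----------
    theta1 : float
        Response height (dimensionless scale); strictly positive.
    theta2 : float
        Delay (shape) parameter; strictly positive. Values > 1 give an
        interior peak at ``(theta2 - 1) / theta3`` seconds.
    theta3 : float
        Dispersion (rate) parameter in 1/seconds; strictly positive.
    """

    theta1: float
    theta2: float
    theta3: float

    def __post_init__(self) -> None:
        for name in ("theta1", "theta2", "theta3"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise HRFError(f"{name} must be a finite positive real, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.theta3], float)

    def to_json(self, dt: float | None = None, L: int | None = None) -> str:
        rec = {"theta1": self.theta1, "theta2": self.theta2, "theta3": self.theta3}
        if dt is not None:
            rec["dt"] = dt
        if L is not None:
            rec["L"] = L
        return json.dumps(rec)

    @classmethod
    def from_json(cls, s: str) -> "HRFParameters":
        rec = json.loads(s)
        return cls(rec["theta1"], rec["theta2"], rec["theta3"])


@dataclass(frozen=True)
class SampledHRF:
    """A gamma HRF sampled on a uniform grid of ``L + 1`` filter taps."""

    values: np.ndarray
    dt: float
    length_samples: int = field(default=0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, float))
        object.__setattr__(self, "length_samples", self.values.size)
        if self.dt <= 0:
            raise HRFError(f"dt must be positive, got {self.dt}")
        if not np.all(np.isfinite(self.values)):
            raise HRFError("sampled HRF contains non-finite taps")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.length_samples) * self.dt

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.times, self.values]),
                   delimiter=",", header="time,value", comments="")


def gamma_hrf_curve(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Evaluate the single-gamma HRF at times ``t`` (seconds).

    Uses the convention 0**0 = 1 at t = 0 so that theta2 = 1 gives the
    exponential theta1 * theta3 * exp(-theta3 t) exactly.
    """
    t1, t2, t3 = float(theta[0]), float(theta[1]), float(theta[2])
    t = np.asarray(t, float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        vals = t1 * np.exp(-gammaln(t2) + t2 * np.log(t3)) * np.power(t, t2 - 1.0) \
            * np.exp(-t3 * t)
    return vals


def evaluate_hrf(params: HRFParameters, dt: float, L: int) -> SampledHRF:
    """Sample the HRF on ``t = 0, dt, ..., L*dt`` (``L + 1`` taps)."""
    if dt <= 0:
        raise HRFError(f"dt must be positive, got {dt}")
    if L < 1:
        raise HRFError(f"L must be >= 1, got {L}")
    t = np.arange(L + 1) * dt
    values = gamma_hrf_curve(params.as_array(), t)
    return SampledHRF(values=values, dt=dt)


def peak_latency(hrf: SampledHRF) -> float:
    """Time-to-peak in seconds: ``dt * argmax`` (earliest tap on ties)."""
    v = hrf.values
    if np.allclose(v, 0):
        raise HRFError("all-zero curve has no defined peak")
    if np.ptp(v) == 0:
        raise HRFError("constant curve has no defined peak")
    return float(np.argmax(v) * hrf.dt)


def fwhm(hrf: SampledHRF) -> float:
    """Full width at half maximum in seconds.

    The width runs from the first up-crossing to the last down-crossing
    of half the maximum, with linear interpolation between taps. If the
    curve never falls below half-max inside the window a truncated-width
    warning is issued and the window-clipped width returned.
    """
    v = hrf.values
    vmax = v.max()
    if vmax <= 0:
        raise HRFError("curve must have a positive maximum")
    half = vmax / 2.0
    above = v >= half
    if above.all():
        warnings.warn("curve never falls below half-maximum inside the "
                      "filter window; returning window-clipped width",
                      RuntimeWarning, stacklevel=2)
        return float((hrf.length_samples - 1) * hrf.dt)

    idx_above = np.nonzero(above)[0]
    i_first, i_last = idx_above[0], idx_above[-1]
    dt = hrf.dt

    if i_first == 0:
        t_left = 0.0
    else:
        # interpolate between the tap below and the first tap at/above half
        lo, hi = v[i_first - 1], v[i_first]
        t_left = (i_first - 1 + (half - lo) / (hi - lo)) * dt
    if i_last == hrf.length_samples - 1:
        warnings.warn("half-maximum down-crossing beyond the filter window; "
                      "returning window-clipped width", RuntimeWarning,
                      stacklevel=2)
        t_right = i_last * dt
    else:
        hi, lo = v[i_last], v[i_last + 1]
        t_right = (i_last + (hi - half) / (hi - lo)) * dt
    return float(t_right - t_left)


def measure_hrf(params: HRFParameters, dt: float = 0.05,
                duration: float = 24.0) -> tuple[float, float, float]:
    """Measure (peak latency, FWHM, peak amplitude) on a fine grid.

    Shape descriptors of simulated/estimated HRFs are read off a dense
    grid (default 50 ms) rather than the coarse filter grid, so that
    sub-sample latencies such as 0.25 s are representable.
    """
    L = int(round(duration / dt))
    curve = evaluate_hrf(params, dt, L)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        w = fwhm(curve)
    return peak_latency(curve), w, float(curve.values.max())


class HRFSamplingError(RuntimeError):
    """Rejection sampling could not find parameters in the target ranges."""


def sample_random_hrf(pl_range=(0.25, 4.5), fwhm_range=(0.5, 4.5),
                      amp_range=(0.0, 1.0), dt: float = 0.05, L: int = 480,
                      rng: np.random.Generator | None = None,
                      max_tries: int = 10_000) -> HRFParameters:
    """Draw HRF parameters with shape constraints by rejection sampling.

    Proposals are log-uniform over theta2 in [1, 30] and theta3 in
    [0.5, 8]; a draw is accepted when the peak latency and FWHM of the
    sampled curve (grid ``dt``, ``L + 1`` taps) fall in the requested
    ranges. theta1 is then rescaled so the peak amplitude is uniform in
    ``amp_range``. The FWHM of a gamma density has no closed form, hence
    rejection rather than inversion.
    """
    rng = np.random.default_rng(rng)
    (pl_lo, pl_hi), (fw_lo, fw_hi) = pl_range, fwhm_range
    if pl_lo > pl_hi or fw_lo > fw_hi or pl_lo < 0 or fw_lo <= 0:
        raise HRFError("ranges must be positive and ordered")
    for _ in range(max_tries):
        t2 = float(np.exp(rng.uniform(np.log(1.0), np.log(30.0))))
        t3 = float(np.exp(rng.uniform(np.log(0.5), np.log(8.0))))
        if t2 <= 1.0:
            continue  # no interior peak
        params = HRFParameters(1.0, t2, t3)
        pl, w, amp = measure_hrf(params, dt=dt, duration=L * dt)
        # half-dt tolerance at the range edges: the grid quantizes PL
        if not (pl_lo - dt / 2 <= pl <= pl_hi + dt / 2):
            continue
        if not (fw_lo <= w <= fw_hi):
            continue
        target_amp = float(rng.uniform(*amp_range))
        if target_amp <= 0:
            target_amp = np.nextafter(0.0, 1.0)
        return HRFParameters(target_amp / amp, t2, t3)
    raise HRFSamplingError(
        f"no acceptable (theta2, theta3) in {max_tries} proposals for "
        f"PL in {pl_range}, FWHM in {fwhm_range} at dt={dt}")
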