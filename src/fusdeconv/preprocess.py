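"""Power-Doppler preprocessing of compound-frame ensembles.

Ultrafast plane-wave imaging yields compound frames that are grouped
into non-overlapping ensembles (200 frames at 800 Hz by default). Each
ensemble is clutter-filtered by zeroing the largest singular components
(slow, high-energy tissue motion) and the smallest (noise floor); the
power of the filtered signal per pixel gives one power-Doppler image,
so the PDI stream runs at frame_rate / ensemble_length (4 Hz for the
defaults). Region time-series are unweighted means over mask pixels,
z-scored before deconvolution.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .simulate import zscore_rows


class PreprocessingError(ValueError):
    pass


def svd_clutter_filter(ensemble: np.ndarray, low_frac: float = 0.30,
                       high_frac: float = 0.01) -> np.ndarray:
    """Remove tissue clutter and noise subspaces from a pixel x time block.

    The first ``ceil(low_frac * S)`` (largest) and last
    ``ceil(high_frac * S)`` (smallest) of the S singular values are set
    to zero and the ensemble reconstructed from the remainder.
    """
    if low_frac + high_frac >= 1:
        raise PreprocessingError("low_frac + high_frac must be < 1")
    X = np.asarray(ensemble, float)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    S = s.size
    if S < 3:
        raise PreprocessingError("ensemble must have at least 3 singular values")
    n_low = math.ceil(low_frac * S)
    n_high = math.ceil(high_frac * S)
    s = s.copy()
    s[:n_low] = 0.0
    if n_high:
        s[S - n_high:] = 0.0
    return (U * s) @ Vt


def power_doppler(filtered: np.ndarray) -> np.ndarray:
    """Per-pixel mean squared magnitude over the ensemble frames."""
    X = np.asarray(filtered, float)
    if X.size == 0:
        raise PreprocessingError("empty ensemble")
    return np.mean(np.square(X), axis=1)


def ensemble_split(frames: np.ndarray, ensemble_len: int = 200) -> list[np.ndarray]:
    """Partition a pixel x time stack into non-overlapping ensembles.

    A trailing remainder shorter than ``ensemble_len`` is dropped with a
    warning.
    """
    X = np.asarray(frames, float)
    n = X.shape[1] // ensemble_len
    rem = X.shape[1] - n * ensemble_len
    if rem:
        warnings.warn(f"dropping trailing remainder of {rem} frames",
                      RuntimeWarning, stacklevel=2)
    return [X[:, i * ensemble_len:(i + 1) * ensemble_len] for i in range(n)]


def pdi_stream(frames: np.ndarray, ensemble_len: int = 200,
               frame_rate: float = 800.0, low_frac: float = 0.30,
               high_frac: float = 0.01) -> tuple[np.ndarray, float]:
    """Full ensemble -> PDI pipeline; returns (pixels x N stream, fs)."""
    pdis = [power_doppler(svd_clutter_filter(e, low_frac, high_frac))
            for e in ensemble_split(frames, ensemble_len)]
    if not pdis:
        raise PreprocessingError("no complete ensembles in the input")
    return np.stack(pdis, axis=1), frame_rate / ensemble_len


def roi_average(pdi_stream: np.ndarray, masks: np.ndarray,
                region_names: list[str] | None = None) -> np.ndarray:
    """Region time-series: unweighted mean over mask pixels, z-scored rows.

    ``masks`` is (M, n_pixels) boolean; raises naming the region if a
    mask selects no pixels.
    """
    X = np.asarray(pdi_stream, float)
    masks = np.atleast_2d(np.asarray(masks, bool))
    if masks.shape[1] != X.shape[0]:
        raise PreprocessingError("masks and PDI stream disagree on pixel count")
    names = region_names or [f"region_{m}" for m in range(masks.shape[0])]
    rows = []
    for m, mask in enumerate(masks):
        if not mask.any():
            raise PreprocessingError(f"mask for {names[m]} selects no pixels")
        rows.append(X[mask].mean(axis=0))
    return zscore_rows(np.stack(rows))
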