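"""Static and dynamic (sliding-window) functional connectivity.

Static FC is the Pearson correlation of each ROI pair over the whole
150-s analysed period, Fisher z-transformed, giving a 6 x 6 symmetric
matrix with 15 = 6*5/2 unique pairs.  Dynamic FC recomputes the same 15
correlations in 20-s windows advanced in 1-s steps — 131 windows on the
standard 150-s, 10-Hz recording — giving the K x M matrix X (K = 15
pairs, M = 131 windows) that feeds the PCA feature extractor.

Pair ordering is the row-major upper triangle of the fixed ROI order and
is identical for every participant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import ROI_ORDER
from .preprocess import RoiTimeSeries

#: |r| is clipped here before atanh; degenerate perfectly correlated
#: inputs then map to a large finite z instead of infinity.
R_CLIP = 1.0 - 1e-7

WINDOW_S_DEFAULT = 20.0
STEP_S_DEFAULT = 1.0


def pair_labels(roi_order: tuple[str, ...] = ROI_ORDER) -> list[str]:
    """The 15 ROI-pair labels in fixed (upper-triangle, row-major) order."""
    n = len(roi_order)
    return [
        f"{roi_order[i]}~{roi_order[j]}" for i in range(n) for j in range(i + 1, n)
    ]


def pair_indices(n: int = 6) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu


@dataclass
class StaticFcMatrix:
    """6 x 6 Fisher-z matrix plus its fixed-order 15-pair flattening."""

    z: np.ndarray
    roi_order: tuple[str, ...]

    @property
    def pair_vector(self) -> np.ndarray:
        i, j = pair_indices(len(self.roi_order))
        return self.z[i, j]

    @property
    def pair_names(self) -> list[str]:
        return pair_labels(self.roi_order)


@dataclass
class DynamicFcSeries:
    """Window-wise Fisher-z FC: X is K pairs x M windows."""

    X: np.ndarray
    window_s: float
    step_s: float
    window_starts_s: np.ndarray
    roi_order: tuple[str, ...]

    @property
    def n_pairs(self) -> int:
        return self.X.shape[0]

    @property
    def n_windows(self) -> int:
        return self.X.shape[1]

    @property
    def pair_names(self) -> list[str]:
        return pair_labels(self.roi_order)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z-transform atanh(r), with |r| clipped to 1 - 1e-7 first."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) > 1 + 1e-12):
        raise ValueError("correlation outside [-1, 1]")
    z = np.arctanh(np.clip(r_arr, -R_CLIP, R_CLIP))
    return z if isinstance(r, np.ndarray) else float(z)


def _corr_z(block: np.ndarray) -> np.ndarray:
    """Fisher-z pairwise correlation matrix of rows of ``block``."""
    d = block - block.mean(axis=-1, keepdims=True)
    norm = np.sqrt((d * d).sum(axis=-1))
    zero = np.flatnonzero(norm == 0)
    if zero.size:
        raise ValueError(f"constant trace for ROI index {int(zero[0])}")
    c = (d @ d.T) / np.outer(norm, norm)
    z = np.arctanh(np.clip(c, -R_CLIP, R_CLIP))
    np.fill_diagonal(z, 0.0)
    return z


def static_fc(roi_ts: RoiTimeSeries) -> StaticFcMatrix:
    """Time-average FC over the entire analysed period."""
    if roi_ts.traces.shape[1] < 3:
        raise ValueError("need at least 3 samples for a correlation")
    return StaticFcMatrix(z=_corr_z(roi_ts.traces), roi_order=roi_ts.roi_order)


def sliding_windows(
    n_samples: int,
    sampling_rate: float,
    window_s: float = WINDOW_S_DEFAULT,
    step_s: float = STEP_S_DEFAULT,
) -> np.ndarray:
    """Start samples of half-open windows [s, s + window) stepped by step.

    The count is floor((T - window) / step) + 1 in samples; no partial
    final window is emitted.
    """
    w = int(round(window_s * sampling_rate))
    s = int(round(step_s * sampling_rate))
    if w > n_samples:
        raise ValueError(f"window of {w} samples exceeds series length {n_samples}")
    if s < 1:
        raise ValueError("step must be at least one sample")
    return np.arange(0, n_samples - w + 1, s)


def dynamic_fc(
    roi_ts: RoiTimeSeries,
    window_s: float = WINDOW_S_DEFAULT,
    step_s: float = STEP_S_DEFAULT,
) -> DynamicFcSeries:
    """Sliding-window Fisher-z FC; 15 x 131 on the standard recording."""
    traces = roi_ts.traces
    rate = roi_ts.sampling_rate
    starts = sliding_windows(traces.shape[1], rate, window_s, step_s)
    w = int(round(window_s * rate))
    # views: rois x windows x window-samples
    sw = np.lib.stride_tricks.sliding_window_view(traces, w, axis=1)[:, starts, :]
    d = sw - sw.mean(axis=-1, keepdims=True)
    norm = np.sqrt((d * d).sum(axis=-1))  # rois x windows
    if np.any(norm == 0):
        roi_i, win_i = np.argwhere(norm == 0)[0]
        raise ValueError(
            f"constant trace for ROI {roi_ts.roi_order[roi_i]} in window {win_i}"
        )
    cov = np.einsum("iwt,jwt->ijw", d, d)
    corr = cov / (norm[:, None, :] * norm[None, :, :])
    i, j = pair_indices(traces.shape[0])
    X = np.arctanh(np.clip(corr[i, j, :], -R_CLIP, R_CLIP))
    return DynamicFcSeries(
        X=X,
        window_s=window_s,
        step_s=step_s,
        window_starts_s=starts / rate,
        roi_order=roi_ts.roi_order,
    )
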