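"""Cohort feature table: 15 static + 15*N dynamic FC features per participant.

Columns are ordered: the 15 static Fisher-z pair features
(``static|<pair>``), then for each principal-component order n = 1..N the
15 projected dynamic features (``pc<n>|<pair>``).  The same column order
is used everywhere (statistics, classification, file output).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import dynamic_fc, pair_labels, static_fc
from .pca_features import (
    PcaDecomposition,
    pca_decompose,
    project,
    select_n_components,
    shift_nonnegative,
)
from .preprocess import RoiTimeSeries


def static_label(pair: str) -> str:
    return f"static|{pair}"


def pc_label(order: int, pair: str) -> str:
    return f"pc{order}|{pair}"


def feature_columns(n_components: int, roi_order=None) -> list[str]:
    pairs = pair_labels(roi_order) if roi_order else pair_labels()
    cols = [static_label(p) for p in pairs]
    for n in range(1, n_components + 1):
        cols += [pc_label(n, p) for p in pairs]
    return cols


@dataclass
class FeatureExtraction:
    """Feature table plus the cohort-level extraction metadata."""

    table: pd.DataFrame  # index: participant_id; columns: features
    n_components: int
    shift_constant: float
    mean_ccr_curve: np.ndarray
    window_s: float
    step_s: float
    #: per-participant unshifted D matrices, needed to re-fit the shift
    #: constant on training folds inside cross-validation
    raw_d: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def static_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("static|")]

    def pc_columns(self, order: int) -> list[str]:
        return [c for c in self.table.columns if c.startswith(f"pc{order}|")]


def extract_features(
    roi_series: Sequence[RoiTimeSeries],
    window_s: float = 20.0,
    step_s: float = 1.0,
    ccr_lo: float = 90.0,
    ccr_hi: float = 95.0,
    n_components: int | None = None,
) -> FeatureExtraction:
    """Static + PCA-reduced dynamic FC features for a cohort.

    N is chosen on the cohort-mean CCR curve unless ``n_components`` is
    forced.  The non-negativity shift constant is the cohort-global
    minimum of the concatenated D matrices.
    """
    if not roi_series:
        raise ValueError("empty cohort")
    ids = [
        ts.participant_id if ts.participant_id is not None else f"sub-{i:03d}"
        for i, ts in enumerate(roi_series)
    ]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate participant ids")
    pairs = pair_labels(roi_series[0].roi_order)

    statics: list[np.ndarray] = []
    dyns = []
    decomps: list[PcaDecomposition] = []
    for ts in roi_series:
        statics.append(static_fc(ts).pair_vector)
        dyn = dynamic_fc(ts, window_s=window_s, step_s=step_s)
        dyns.append(dyn)
        decomps.append(pca_decompose(dyn))

    if n_components is None:
        n, mean_curve = select_n_components(decomps, lo=ccr_lo, hi=ccr_hi)
    else:
        n = int(n_components)
        mean_curve = np.stack([d.ccr_curve for d in decomps]).mean(axis=0)
    d_raw = [project(dyn, dec, n) for dyn, dec in zip(dyns, decomps)]
    d_shifted, shift = shift_nonnegative(d_raw)

    cols = [static_label(p) for p in pairs]
    for order in range(1, n + 1):
        cols += [pc_label(order, p) for p in pairs]
    rows = [
        np.concatenate([sv, d.T.ravel()])  # D.T.ravel(): pc-major, pair-minor
        for sv, d in zip(statics, d_shifted)
    ]
    table = pd.DataFrame(rows, index=pd.Index(ids, name="participant_id"), columns=cols)
    return FeatureExtraction(
        table=table,
        n_components=n,
        shift_constant=shift,
        mean_ccr_curve=mean_curve,
        window_s=window_s,
        step_s=step_s,
        raw_d={pid: d for pid, d in zip(ids, d_raw)},
    )
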