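"""Channel-level signal-to-noise quality control.

Each recording starts with a 10-second task-free baseline segment.  A
channel's quality at wavelength lambda is summarised as

    SNR (dB) = 20 * log10(mu / sigma)

where mu and sigma are the mean and (n-1) standard deviation of the
baseline signal.  A channel is retained only if it reaches the threshold
(default 40 dB) at *both* wavelengths — i.e. it is excluded as soon as it
fails at one wavelength.

QC exclusions are cohort-wide by default: a channel failing in any
participant is dropped for everyone, so all participants share a montage.
A per-participant mode is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

from .montage import Montage

DEFAULT_SNR_THRESHOLD_DB = 40.0


class UndefinedSnrError(ValueError):
    """Baseline mean is zero or negative; SNR in dB is undefined."""


@dataclass
class BaselineSegment:
    """10-second baseline intensities, one array per wavelength.

    ``samples`` maps wavelength (nm) to a channels x time array of raw
    intensities; rows follow ``channel_ids``.
    """

    samples: dict[int, np.ndarray]
    channel_ids: list[int]
    sampling_rate: float

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.samples.values()}
        if len(shapes) != 1:
            raise ValueError("wavelength arrays differ in shape")
        (shape,) = shapes
        if shape[0] != len(self.channel_ids):
            raise ValueError("channel_ids does not match sample rows")
        for lam, arr in self.samples.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite baseline values at {lam} nm")
        if shape[1] < 2:
            raise ValueError("need at least 2 baseline samples per channel")

    @property
    def wavelengths(self) -> list[int]:
        return sorted(self.samples)

    @property
    def duration_s(self) -> float:
        n = next(iter(self.samples.values())).shape[1]
        return n / self.sampling_rate


@dataclass
class QcReport:
    """SNR per channel and wavelength, plus the retention decision."""

    snr_db: dict[int, dict[int, float]]  # channel -> wavelength -> dB
    threshold_db: float
    excluded_channels: set[int] = field(init=False)
    retained_channels: list[int] = field(init=False)

    def __post_init__(self) -> None:
        self.retained_channels = [
            ch
            for ch, per_wl in self.snr_db.items()
            if min(per_wl.values()) >= self.threshold_db
        ]
        self.excluded_channels = set(self.snr_db) - set(self.retained_channels)

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "channel": ch,
                "wavelength_nm": lam,
                "snr_db": snr,
                "pass": snr >= self.threshold_db,
            }
            for ch, per_wl in self.snr_db.items()
            for lam, snr in per_wl.items()
        ]
        return pd.DataFrame(rows)


def snr_db(values: np.ndarray) -> float:
    """SNR in dB of one baseline channel: 20*log10(mean/sd), sd with n-1.

    A zero sd gives +inf (a perfectly steady channel passes any
    threshold); a non-positive mean raises :class:`UndefinedSnrError`.
    """
    values = np.asarray(values, dtype=float)
    mu = values.mean()
    if mu <= 0:
        raise UndefinedSnrError(f"baseline mean {mu:g} <= 0; SNR undefined")
    sigma = values.std(ddof=1)
    if sigma == 0:
        return math.inf
    return 20.0 * math.log10(mu / sigma)


def compute_snr(
    baseline: BaselineSegment, threshold_db: float = DEFAULT_SNR_THRESHOLD_DB
) -> QcReport:
    """QC report for one participant's baseline segment.

    Channels with an undefined SNR (non-positive baseline mean) are
    flagged by assigning -inf at the offending wavelength, never silently
    dropped: they fail the threshold and appear in ``excluded_channels``.
    """
    snr: dict[int, dict[int, float]] = {}
    for i, ch in enumerate(baseline.channel_ids):
        snr[ch] = {}
        for lam in baseline.wavelengths:
            try:
                snr[ch][lam] = snr_db(baseline.samples[lam][i])
            except UndefinedSnrError:
                snr[ch][lam] = -math.inf
    return QcReport(snr, threshold_db)


def apply_channel_filter(report: QcReport, montage: Montage) -> Montage:
    """Restrict ``montage`` to channels passing QC at both wavelengths."""
    missing = set(montage.channel_ids) - set(report.snr_db)
    if missing:
        raise ValueError(f"QC report does not cover channels {sorted(missing)}")
    keep = [ch for ch in montage.channel_ids if ch in set(report.retained_channels)]
    return montage.restrict(keep)


def cohort_qc(
    baselines: Iterable[BaselineSegment],
    montage: Montage,
    threshold_db: float = DEFAULT_SNR_THRESHOLD_DB,
    mode: Literal["cohort", "per-participant"] = "cohort",
) -> tuple[Montage | list[Montage], list[QcReport]]:
    """QC across a cohort.

    In ``cohort`` mode (default) a channel failing for *any* participant
    is excluded for all, returning one shared montage.  In
    ``per-participant`` mode each participant gets their own montage.
    """
    reports = [compute_snr(b, threshold_db) for b in baselines]
    if not reports:
        raise ValueError("empty cohort")
    if mode == "per-participant":
        return [apply_channel_filter(r, montage) for r in reports], reports
    failed: set[int] = set()
    for r in reports:
        failed |= r.excluded_channels
    keep = [ch for ch in montage.channel_ids if ch not in failed]
    return montage.restrict(keep), reports
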