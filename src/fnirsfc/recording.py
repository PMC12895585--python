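"""Raw recording container shared by the simulator, QC and preprocessing."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .qc import BaselineSegment

WAVELENGTHS_NM = (695, 830)


@dataclass
class TaskTimeline:
    """Block timeline of the verbal fluency task, in seconds."""

    pre_s: float = 30.0
    task_s: float = 60.0
    post_s: float = 60.0
    baseline_s: float = 10.0

    @property
    def analysis_s(self) -> float:
        """Length of the analysed period (pre + task + post)."""
        return self.pre_s + self.task_s + self.post_s


@dataclass
class RawRecording:
    """Dual-wavelength raw intensities for one participant.

    ``intensity`` maps wavelength (nm) to a channels x time array covering
    the 10-s task-free baseline (first ``baseline_samples`` columns)
    followed by the analysed task period.
    """

    participant_id: str
    intensity: dict[int, np.ndarray]
    channel_ids: list[int]
    sampling_rate: float
    baseline_samples: int
    timeline: TaskTimeline = field(default_factory=TaskTimeline)
    group: str | None = None
    #: free-form event log, e.g. injected artifact onsets in the simulator
    log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.intensity.values()}
        if len(shapes) != 1:
            raise ValueError("wavelength arrays differ in shape")
        (shape,) = shapes
        if shape[0] != len(self.channel_ids):
            raise ValueError("channel_ids does not match intensity rows")

    @property
    def wavelengths(self) -> list[int]:
        return sorted(self.intensity)

    @property
    def n_task_samples(self) -> int:
        return next(iter(self.intensity.values())).shape[1] - self.baseline_samples

    def baseline_segment(self) -> BaselineSegment:
        return BaselineSegment(
            samples={
                lam: arr[:, : self.baseline_samples]
                for lam, arr in self.intensity.items()
            },
            channel_ids=list(self.channel_ids),
            sampling_rate=self.sampling_rate,
        )

    def task_intensity(self) -> dict[int, np.ndarray]:
        return {
            lam: arr[:, self.baseline_samples :] for lam, arr in self.intensity.items()
        }

    def restrict_channels(self, keep_ids) -> "RawRecording":
        keep = [i for i, ch in enumerate(self.channel_ids) if ch in set(keep_ids)]
        return RawRecording(
            participant_id=self.participant_id,
            intensity={lam: arr[keep] for lam, arr in self.intensity.items()},
            channel_ids=[self.channel_ids[i] for i in keep],
            sampling_rate=self.sampling_rate,
            baseline_samples=self.baseline_samples,
            timeline=self.timeline,
            group=self.group,
            log=list(self.log),
        )
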