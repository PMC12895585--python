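"""Optode montage for the 52-channel frontotemporal fNIRS layout.

The standard cap places 33 optodes (17 sources, 16 detectors) on a 3 x 11
grid with 3 cm spacing, sources and detectors alternating.  Every adjacent
source-detector pair is a measurement channel: 10 horizontal pairs in each
of the 3 optode rows plus 11 vertical pairs between each pair of adjacent
rows, i.e. 3*10 + 2*11 = 52 channels.

Channels are numbered row-major: 1-10 (top row, horizontal), 11-21
(top-middle vertical), 22-31 (middle row, horizontal), 32-42
(middle-bottom vertical), 43-52 (bottom row, horizontal).  The cap is
described from a frontal view with the participant's right on low column
indices.

The channel -> ROI assignment (six regions: bilateral DLPFC, mPFC and
temporal lobe) is configuration, not code: it ships as an editable JSON
file (``data/roi_map_52.json``) generated from the grid geometry, and any
mapping covering the montage can be substituted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

#: Fixed ROI order used for ROI time series, FC matrices and feature names.
ROI_ORDER: tuple[str, ...] = (
    "DLPFC(R)", "DLPFC(L)", "mPFC(R)", "mPFC(L)", "TL(R)", "TL(L)",
)

N_GRID_ROWS = 3
N_GRID_COLS = 11


@dataclass(frozen=True)
class Channel:
    """One source-detector measurement channel."""

    id: int
    source_id: int
    detector_id: int
    #: grid position of the channel midpoint, (column, row); columns run
    #: 1..11 from the participant's right, rows 1..3 from the top.
    position: tuple[float, float]


@dataclass
class Montage:
    """Channel list plus the channel -> ROI map.

    Parameters
    ----------
    channels
        Measurement channels, ordered by id.
    roi_map
        Mapping from channel id to ROI label; every channel must map to
        exactly one of the six ROI labels in :data:`ROI_ORDER`.
    interoptode_distance_cm
        Source-detector separation in cm (3.0 for the standard cap).
    """

    channels: list[Channel]
    roi_map: dict[int, str]
    interoptode_distance_cm: float = 3.0
    roi_order: tuple[str, ...] = field(default=ROI_ORDER)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate channel ids in montage")
        missing = [i for i in ids if i not in self.roi_map]
        if missing:
            raise ValueError(f"channels without ROI assignment: {missing}")
        bad = sorted({r for r in self.roi_map.values()} - set(self.roi_order))
        if bad:
            raise ValueError(f"unknown ROI labels in roi_map: {bad}")

    @property
    def channel_ids(self) -> list[int]:
        return [c.id for c in self.channels]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_sources(self) -> int:
        return len({c.source_id for c in self.channels})

    @property
    def n_detectors(self) -> int:
        return len({c.detector_id for c in self.channels})

    def roi_channels(self, roi: str) -> list[int]:
        return [c.id for c in self.channels if self.roi_map[c.id] == roi]

    def restrict(self, keep_ids: Sequence[int]) -> "Montage":
        """Montage restricted to ``keep_ids`` (order preserved).

        Raises
        ------
        ValueError
            If the restriction would leave any ROI without channels, which
            makes downstream ROI aggregation impossible.
        """
        keep = set(keep_ids)
        channels = [c for c in self.channels if c.id in keep]
        roi_map = {c.id: self.roi_map[c.id] for c in channels}
        empty = [r for r in self.roi_order if r not in roi_map.values()]
        if empty:
            raise ValueError(
                f"channel restriction empties ROI(s) {empty}; cannot aggregate"
            )
        return Montage(channels, roi_map, self.interoptode_distance_cm, self.roi_order)

    # ---- serialisation -------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "interoptode_distance_cm": self.interoptode_distance_cm,
                "roi_order": list(self.roi_order),
                "channels": [
                    {
                        "id": c.id,
                        "source_id": c.source_id,
                        "detector_id": c.detector_id,
                        "position": list(c.position),
                        "roi": self.roi_map[c.id],
                    }
                    for c in self.channels
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "Montage":
        obj = json.loads(text)
        channels = [
            Channel(d["id"], d["source_id"], d["detector_id"], tuple(d["position"]))
            for d in obj["channels"]
        ]
        roi_map = {d["id"]: d["roi"] for d in obj["channels"]}
        return cls(
            channels,
            roi_map,
            obj.get("interoptode_distance_cm", 3.0),
            tuple(obj.get("roi_order", ROI_ORDER)),
        )


def grid_optodes() -> dict[tuple[int, int], tuple[str, int]]:
    """Optode kind and index at each (row, col) of the 3 x 11 grid.

    Sources and detectors alternate row-major starting with a source, so
    odd grid indices (1-based) are sources: 17 sources, 16 detectors.
    """
    optodes: dict[tuple[int, int], tuple[str, int]] = {}
    n_src = n_det = 0
    for r in range(1, N_GRID_ROWS + 1):
        for c in range(1, N_GRID_COLS + 1):
            i = (r - 1) * N_GRID_COLS + c
            if i % 2 == 1:
                n_src += 1
                optodes[(r, c)] = ("S", n_src)
            else:
                n_det += 1
                optodes[(r, c)] = ("D", n_det)
    return optodes


def _default_roi(position: tuple[float, float]) -> str:
    """Geometric ROI rule for the default map (see module docstring)."""
    x, y = position
    if x <= 2.5:
        return "TL(R)"
    if x >= 9.5:
        return "TL(L)"
    if x < 5.25:
        return "DLPFC(R)"
    if x > 6.75:
        return "DLPFC(L)"
    if x < 6:
        return "mPFC(R)"
    if x > 6:
        return "mPFC(L)"
    # midline vertical channels: alternate by inter-row to balance sides
    return "mPFC(R)" if y < 2 else "mPFC(L)"


def build_standard_montage(roi_map: Mapping[int, str] | None = None) -> Montage:
    """Build the 52-channel montage from the 3 x 11 alternating grid.

    With the default geometry-derived ROI map each of the six ROIs covers
    8-10 channels.  Pass ``roi_map`` to override the assignment.
    """
    optodes = grid_optodes()
    channels: list[Channel] = []
    ch = 0

    def add(a: tuple[int, int], b: tuple[int, int], pos: tuple[float, float]) -> None:
        nonlocal ch
        ch += 1
        (ka, ia), (kb, ib) = optodes[a], optodes[b]
        if ka == kb:
            raise ValueError("adjacent optodes of the same kind; not a channel")
        src = ia if ka == "S" else ib
        det = ib if kb == "D" else ia
        channels.append(Channel(ch, src, det, pos))

    for r in range(1, N_GRID_ROWS + 1):
        for c in range(1, N_GRID_COLS):  # horizontal pairs in row r
            add((r, c), (r, c + 1), (c + 0.5, float(r)))
        if r < N_GRID_ROWS:  # vertical pairs between rows r and r+1
            for c in range(1, N_GRID_COLS + 1):
                add((r, c), (r + 1, c), (float(c), r + 0.5))

    mapping = (
        dict(roi_map)
        if roi_map is not None
        else {c.id: _default_roi(c.position) for c in channels}
    )
    return Montage(channels, mapping)


def load_default_montage() -> Montage:
    """Montage with the ROI map shipped in ``data/roi_map_52.json``."""
    text = resources.files("fnirsfc.data").joinpath("roi_map_52.json").read_text()
    obj = json.loads(text)
    return build_standard_montage(roi_map={int(k): v for k, v in obj["roi_map"].items()})
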