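"""CSV/TSV/JSON interchange helpers with strict dialect guards.

Plain CSV is the canonical interchange format (vendor-native binary
formats are out of scope).  Time is stored in seconds; the baseline
segment of a recording carries negative time stamps (-10 s .. 0 s) and
the analysed task period runs from 0 s.  Numeric round-trips are stable
to better than 1e-12 (17 significant digits).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import RawRecording, TaskTimeline

FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    pass


def _guard_csv_dialect(path: Path) -> None:
    head = path.open("r", encoding="utf-8").readline()
    if ";" in head:
        raise ParseError(
            f"{path}: semicolon-delimited file (locale decimal-comma dialect?); "
            "expected comma-separated values with '.' decimals"
        )


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a CSV/TSV with a header row, rejecting non-numeric surprises."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing input file: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    if sep == ",":
        _guard_csv_dialect(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as e:
        raise ParseError(f"{path}: {e}") from e
    return df


def require_numeric(df: pd.DataFrame, columns, path) -> None:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"{path}: non-numeric cell at row {row + 2}, column {col!r}"
            )


# ---------------------------------------------------------------------------
# recordings


def write_recording_csv(rec: RawRecording, path: str | Path) -> None:
    """One CSV per participant: time_s then ch<id>_<lambda>nm columns.

    Baseline samples carry negative time; the task period starts at 0 s.
    """
    path = Path(path)
    n_total = next(iter(rec.intensity.values())).shape[1]
    t = (np.arange(n_total) - rec.baseline_samples) / rec.sampling_rate
    data = {"time_s": t}
    for lam in rec.wavelengths:
        for i, ch in enumerate(rec.channel_ids):
            data[f"ch{ch:02d}_{lam}nm"] = rec.intensity[lam][i]
    pd.DataFrame(data).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_recording_csv(
    path: str | Path,
    participant_id: str,
    group: str | None = None,
    timeline: TaskTimeline | None = None,
) -> RawRecording:
    df = read_table(path)
    if "time_s" not in df.columns:
        raise ParseError(f"{path}: missing required first column 'time_s'")
    require_numeric(df, df.columns, path)
    chan_cols = [c for c in df.columns if c.startswith("ch")]
    lams = sorted({int(c.split("_")[1][:-2]) for c in chan_cols})
    channel_ids = sorted({int(c.split("_")[0][2:]) for c in chan_cols})
    for lam in lams:
        for ch in channel_ids:
            if f"ch{ch:02d}_{lam}nm" not in df.columns:
                raise ParseError(f"{path}: missing channel column ch{ch:02d}_{lam}nm")
    t = df["time_s"].to_numpy(float)
    baseline_samples = int(np.sum(t < 0))
    rate = 1.0 / float(np.median(np.diff(t)))
    intensity = {
        lam: np.stack([df[f"ch{ch:02d}_{lam}nm"].to_numpy(float) for ch in channel_ids])
        for lam in lams
    }
    return RawRecording(
        participant_id=participant_id,
        intensity=intensity,
        channel_ids=channel_ids,
        sampling_rate=rate,
        baseline_samples=baseline_samples,
        timeline=timeline or TaskTimeline(),
        group=group,
    )


# ---------------------------------------------------------------------------
# labelled matrices


def write_matrix(
    matrix: np.ndarray, row_labels, col_labels, path: str | Path, index_name="row"
) -> None:
    df = pd.DataFrame(matrix, index=row_labels, columns=col_labels)
    df.index.name = index_name
    df.to_csv(path, float_format=FLOAT_FMT)


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    return df.set_index(df.columns[0])


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serialisable: {type(o)}")


def read_json(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing input file: {path}")
    return json.loads(path.read_text())


def write_provenance(path: str | Path, stage: str, parameters: dict, seed=None) -> None:
    from . import __version__

    write_json(
        {
            "stage": stage,
            "parameters": parameters,
            "seed": seed,
            "software": f"fnirsfc {__version__}",
        },
        path,
    )
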