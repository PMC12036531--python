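"""File formats: WAV audio, Praat TextGrid interval tiers, CSV tables.

TextGrid support is a minimal reader/writer for the long text format with
interval tiers, sufficient for exchanging speech/pause annotations with
Praat; it is not a general TextGrid implementation.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .segments import PAUSE, SPEECH, SegmentSequence
from .vad import PauseRecord


class FormatError(ValueError):
    """Raised for malformed or unexpected file contents."""


# ---------------------------------------------------------------------------
# WAV
# ---------------------------------------------------------------------------

def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a WAV file as a float waveform in [-1, 1]; stereo is downmixed."""
    rate, data = wavfile.read(path)
    x = np.asarray(data)
    if np.issubdtype(x.dtype, np.integer):
        x = x.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        x = x.astype(float)
    if x.ndim == 2:
        x = x.mean(axis=1)
    return x, int(rate)


def write_wav(path, waveform: np.ndarray, sample_rate: int) -> None:
    wavfile.write(path, int(sample_rate), np.asarray(waveform, dtype=np.float32))


# ---------------------------------------------------------------------------
# TextGrid
# ---------------------------------------------------------------------------

def write_textgrid(path, segments: SegmentSequence, tier_name: str = "speech") -> None:
    """Write one interval tier with labels "speech"/"pause"."""
    ivs = segments.intervals
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {segments.duration:.6f}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        f'        name = "{tier_name}"',
        "        xmin = 0",
        f"        xmax = {segments.duration:.6f}",
        f"        intervals: size = {len(ivs)}",
    ]
    for i, iv in enumerate(ivs, 1):
        lines += [
            f"        intervals [{i}]:",
            f"            xmin = {iv.start:.6f}",
            f"            xmax = {iv.end:.6f}",
            f'            text = "{iv.label}"',
        ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_KV = re.compile(r'^\s*(\w[\w ?]*\w|\w)\s*=\s*(.*?)\s*$')


def read_textgrid(
    path, tier_name: str = "speech", label_map: dict | None = None
) -> SegmentSequence:
    """Read an interval tier as a SegmentSequence.

    Labels are mapped through ``label_map`` (default: "speech" stays speech,
    anything else becomes pause); gaps between intervals are emitted as
    pause intervals.
    """
    text = Path(path).read_text(encoding="utf-8")
    # split into tiers
    tiers: list[dict] = []
    current: dict | None = None
    intervals: list[dict] | None = None
    pending: dict | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("item [") and line != "item []:":
            current = {"name": None, "class": None, "intervals": []}
            tiers.append(current)
            intervals = current["intervals"]
            pending = None
            continue
        m = _KV.match(line)
        if not m or current is None:
            if line.startswith("intervals [") and current is not None:
                pending = {}
                intervals.append(pending)
            continue
        key, val = m.group(1), m.group(2).strip('"')
        if key == "class":
            current["class"] = val
        elif key == "name":
            current["name"] = val
        elif key in ("xmin", "xmax", "text") and pending is not None:
            pending[key] = val
    names = [t["name"] for t in tiers]
    match = [t for t in tiers if t["name"] == tier_name]
    if not match:
        raise FormatError(f"tier {tier_name!r} not found; tiers present: {names}")
    tier = match[0]
    if tier["class"] != "IntervalTier":
        raise FormatError(f"tier {tier_name!r} is not an IntervalTier")
    if label_map is None:
        label_map = {}
    ivs = []
    t_prev = 0.0
    for rec in tier["intervals"]:
        a, b = float(rec["xmin"]), float(rec["xmax"])
        if a < t_prev - 1e-6:
            raise FormatError(f"overlapping intervals at t={a:.4f}")
        if a > t_prev + 1e-6:  # unlabeled gap -> pause
            ivs.append((t_prev, a, PAUSE))
        raw_label = rec.get("text", "")
        label = label_map.get(raw_label, SPEECH if raw_label == SPEECH else PAUSE)
        ivs.append((a, b, label))
        t_prev = b
    if not ivs:
        raise FormatError(f"tier {tier_name!r} has no intervals")
    return SegmentSequence(ivs)


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

_PAUSE_COLUMNS = ["speaker_id", "group", "moment", "fragment_id", "duration_ms"]


def write_pause_table(records, path) -> None:
    """Write pause records as CSV with a deterministic row order."""
    if isinstance(records, pd.DataFrame):
        frame = records[_PAUSE_COLUMNS].copy()
    else:
        frame = pd.DataFrame(
            [{c: getattr(r, c) for c in _PAUSE_COLUMNS} for r in records],
            columns=_PAUSE_COLUMNS,
        )
    frame = frame.sort_values(
        ["speaker_id", "moment", "fragment_id", "duration_ms"], kind="stable"
    ).reset_index(drop=True)
    frame.to_csv(path, index=False, encoding="utf-8")


def read_pause_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(_PAUSE_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"pause table missing columns {sorted(missing)}")
    return frame


def write_interval_table(frame: pd.DataFrame, path) -> None:
    cols = ["speaker_id", "group", "moment", "fragment_id", "start_s", "end_s", "label"]
    frame[cols].to_csv(path, index=False, encoding="utf-8")


def read_interval_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    needed = {"speaker_id", "group", "moment", "fragment_id", "start_s", "end_s", "label"}
    missing = needed - set(frame.columns)
    if missing:
        raise FormatError(f"interval table missing columns {sorted(missing)}")
    return frame


def sequences_from_interval_table(frame: pd.DataFrame):
    """Yield ((speaker_id, group, moment, fragment_id), SegmentSequence)."""
    keys = ["speaker_id", "group", "moment", "fragment_id"]
    for key, sub in frame.groupby(keys, sort=True):
        sub = sub.sort_values("start_s")
        seq = SegmentSequence(sub[["start_s", "end_s", "label"]].itertuples(index=False, name=None))
        yield key, seq
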