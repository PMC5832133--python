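"""File round-trips: event tables, recordings (EDF and raw binary), models.

Events travel as a tab-separated table with one row per stimulus event.
Recordings are written either as 16-bit EDF (physical units microvolts) or
as a raw little-endian float64 matrix next to a JSON sidecar; both readers
return the same Recording container.  Models persist as JSON with the
weight vector stored sparsely.
"""

from __future__ import annotations

import json
import math
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from p300screen.classifier import LassoLdaModel
from p300screen.errors import DataFormatError
from p300screen.recording import Recording
from p300screen.sequencer import EVENT_TYPES, SessionSchedule, StimulusEvent, TimingConfig

EVENT_COLUMNS = (
    "onset_s",
    "duration_s",
    "marker_id",
    "event_type",
    "block",
    "repetition",
    "trial",
    "is_target",
)


# ---------------------------------------------------------------------------
# Event tables (TSV)

def events_to_frame(events: list[StimulusEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_s": [round(e.onset, 6) for e in events],
            "duration_s": [round(e.duration, 6) for e in events],
            "marker_id": [e.marker_id for e in events],
            "event_type": [e.event_type for e in events],
            "block": [e.block for e in events],
            "repetition": [e.repetition for e in events],
            "trial": [e.trial for e in events],
            "is_target": [int(e.is_target) for e in events],
        }
    )


def write_events(events: list[StimulusEvent] | SessionSchedule, path: str | Path) -> None:
    if isinstance(events, SessionSchedule):
        events = events.events
    events_to_frame(events).to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> list[StimulusEvent]:
    frame = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(frame.columns)
    if missing:
        raise DataFormatError(f"event table {path} lacks columns {sorted(missing)}")
    bad = set(frame["event_type"]) - set(EVENT_TYPES)
    if bad:
        raise DataFormatError(f"unknown event_type values {sorted(bad)} in {path}")
    return [
        StimulusEvent(
            onset=float(r.onset_s),
            duration=float(r.duration_s),
            marker_id=int(r.marker_id),
            event_type=str(r.event_type),
            block=int(r.block),
            repetition=int(r.repetition),
            trial=int(r.trial),
            is_target=bool(r.is_target),
        )
        for r in frame.itertuples(index=False)
    ]


def schedule_from_events(
    events: list[StimulusEvent], timing: TimingConfig | None = None
) -> SessionSchedule:
    """Rebuild a SessionSchedule from a persisted event table.

    total_duration is recovered from the final event's offset; targets from
    the target-cue events in repetition order.
    """
    if not events:
        raise DataFormatError("empty event list")
    timing = timing if timing is not None else TimingConfig()
    cues = sorted(
        (e for e in events if e.event_type == "target_cue"), key=lambda e: e.repetition
    )
    last = max(events, key=lambda e: e.onset + e.duration)
    return SessionSchedule(
        events=sorted(events, key=lambda e: e.onset),
        timing=timing,
        targets=[e.marker_id for e in cues],
        total_duration=last.onset + last.duration,
    )


# ---------------------------------------------------------------------------
# Recordings: raw float64 matrix + JSON sidecar

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_recording_binary(recording: Recording, path: str | Path) -> None:
    """Raw little-endian float64, channel-major; lossless round trip."""
    path = Path(path)
    data = np.ascontiguousarray(recording.samples, dtype="<f8")
    path.write_bytes(data.tobytes())
    sidecar = {
        "format": "raw-float64-le",
        "sample_rate": recording.sample_rate,
        "channel_names": list(recording.channel_names),
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
        "units": "uV",
        "start_offset_s": 0.0,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def _read_recording_binary(path: Path) -> Recording:
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise DataFormatError(f"missing sidecar {sidecar_file}")
    meta = json.loads(sidecar_file.read_text())
    for key in ("sample_rate", "channel_names", "n_channels", "n_samples"):
        if key not in meta:
            raise DataFormatError(f"sidecar {sidecar_file} lacks field {key!r}")
    expected = meta["n_channels"] * meta["n_samples"] * 8
    blob = path.read_bytes()
    if len(blob) != expected:
        raise DataFormatError(
            f"{path}: expected {expected} bytes, found {len(blob)} "
            f"(truncated at byte {len(blob)})"
        )
    samples = np.frombuffer(blob, dtype="<f8").reshape(
        meta["n_channels"], meta["n_samples"]
    )
    return Recording(
        samples=samples.copy(),
        sample_rate=float(meta["sample_rate"]),
        channel_names=tuple(meta["channel_names"]),
    )


# ---------------------------------------------------------------------------
# Recordings: minimal 16-bit EDF
#
# Fixed-width ASCII header of 256 + 256 * ns bytes, then data records of
# int16 little-endian samples, one second per record, zero-padded at the end.

def _ascii(value, width: int) -> bytes:
    text = f"{value}"[:width]
    return text.ljust(width).encode("ascii")


def write_recording_edf(recording: Recording, path: str | Path) -> None:
    if abs(recording.sample_rate - round(recording.sample_rate)) > 1e-9:
        raise DataFormatError("EDF writer requires an integer sample rate")
    spr = int(round(recording.sample_rate))
    ns = recording.n_channels
    n_records = int(math.ceil(recording.n_samples / spr))
    pmax = np.maximum(np.abs(recording.samples).max(axis=1), 1.0)
    dig = 32767
    scale = pmax / dig

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii("Startdate 01-JAN-2000 synthetic", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(256 * (ns + 1), 8),
            _ascii("", 44),
            _ascii(n_records, 8),
            _ascii("1", 8),
            _ascii(ns, 4),
        ]
    )
    fields = [
        b"".join(_ascii(name, 16) for name in recording.channel_names),
        b"".join(_ascii("synthetic", 80) for _ in range(ns)),
        b"".join(_ascii("uV", 8) for _ in range(ns)),
        b"".join(_ascii(f"{-p:.6g}"[:8], 8) for p in pmax),
        b"".join(_ascii(f"{p:.6g}"[:8], 8) for p in pmax),
        b"".join(_ascii(-dig, 8) for _ in range(ns)),
        b"".join(_ascii(dig, 8) for _ in range(ns)),
        b"".join(_ascii("", 80) for _ in range(ns)),
        b"".join(_ascii(spr, 8) for _ in range(ns)),
        b"".join(_ascii("", 32) for _ in range(ns)),
    ]
    padded = np.zeros((ns, n_records * spr))
    padded[:, : recording.n_samples] = recording.samples
    digital = np.clip(np.round(padded / scale[:, None]), -dig, dig).astype("<i2")
    # records are interleaved: all samples of channel 0 for second 0, then
    # channel 1, ... then the next second
    records = digital.reshape(ns, n_records, spr).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.writelines(fields)
        fh.write(records.tobytes())


def _read_recording_edf(path: Path) -> Recording:
    blob = path.read_bytes()
    if len(blob) < 256:
        raise DataFormatError(f"{path}: EDF header truncated at byte {len(blob)}")
    n_records = int(blob[236:244])
    ns = int(blob[252:256])
    header_bytes = 256 * (ns + 1)
    if len(blob) < header_bytes:
        raise DataFormatError(f"{path}: EDF signal header truncated at byte {len(blob)}")

    # signal header block: per-field widths in bytes per signal —
    # label 16, transducer 80, dim 8, physmin 8, physmax 8, digmin 8,
    # digmax 8, prefilter 80, samples-per-record 8, reserved 32
    base = 256
    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]

    def block(index: int) -> list[str]:
        off = base + sum(w * ns for w in widths[:index])
        w = widths[index]
        return [
            blob[off + i * w : off + (i + 1) * w].decode("ascii").strip()
            for i in range(ns)
        ]

    labels = block(0)
    pmin = np.array([float(v) for v in block(3)])
    pmax = np.array([float(v) for v in block(4)])
    dmin = np.array([float(v) for v in block(5)])
    dmax = np.array([float(v) for v in block(6)])
    spr = [int(v) for v in block(8)]
    if len(set(spr)) != 1:
        raise DataFormatError("mixed samples-per-record not supported")
    spr = spr[0]
    expected = header_bytes + n_records * ns * spr * 2
    if len(blob) < expected:
        raise DataFormatError(
            f"{path}: expected {expected} bytes, truncated at byte {len(blob)}"
        )
    raw = np.frombuffer(blob, dtype="<i2", offset=header_bytes, count=n_records * ns * spr)
    digital = raw.reshape(n_records, ns, spr).transpose(1, 0, 2).reshape(ns, -1)
    scale = (pmax - pmin) / (dmax - dmin)
    physical = (digital - dmin[:, None]) * scale[:, None] + pmin[:, None]
    # one-second records imply the sample rate equals samples per record
    return Recording(
        samples=physical, sample_rate=float(spr), channel_names=tuple(labels)
    )


def write_recording(recording: Recording, path: str | Path) -> None:
    """Dispatch on extension: .edf for EDF, anything else raw binary."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        write_recording_edf(recording, path)
    else:
        write_recording_binary(recording, path)


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"no such recording {path}")
    if path.suffix.lower() == ".edf":
        return _read_recording_edf(path)
    return _read_recording_binary(path)


# ---------------------------------------------------------------------------
# Feature matrices: dense float64 matrix + JSON sidecar with row metadata

def write_features(features: list, path: str | Path) -> None:
    """Persist feature vectors row-major (little-endian float64); the sidecar
    carries (repetition, trial, marker_id, label) per row, in row order."""
    path = Path(path)
    X = np.stack([np.asarray(f.values, dtype="<f8") for f in features])
    path.write_bytes(np.ascontiguousarray(X).tobytes())
    sidecar = {
        "format": "features-float64-le",
        "n_rows": X.shape[0],
        "d": X.shape[1],
        "rows": [
            {
                "repetition": int(f.repetition),
                "trial": int(f.trial),
                "marker_id": int(f.marker_id),
                "label": int(f.label),
            }
            for f in features
        ],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))


def read_features(path: str | Path) -> list:
    from p300screen.preprocessing import FeatureVector

    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise DataFormatError(f"missing sidecar {sidecar_file}")
    meta = json.loads(sidecar_file.read_text())
    if meta.get("format") != "features-float64-le":
        raise DataFormatError(f"{path} is not a persisted feature matrix")
    expected = meta["n_rows"] * meta["d"] * 8
    blob = path.read_bytes()
    if len(blob) != expected:
        raise DataFormatError(
            f"{path}: expected {expected} bytes, found {len(blob)} "
            f"(truncated at byte {len(blob)})"
        )
    X = np.frombuffer(blob, dtype="<f8").reshape(meta["n_rows"], meta["d"])
    return [
        FeatureVector(
            values=X[i].copy(),
            marker_id=row["marker_id"],
            trial=row["trial"],
            repetition=row["repetition"],
            label=row["label"],
        )
        for i, row in enumerate(meta["rows"])
    ]


# ---------------------------------------------------------------------------
# Models and tables

def save_model(model: LassoLdaModel, path: str | Path, extra: dict | None = None) -> None:
    support = model.support
    payload = {
        "format": "lasso-lda-v1",
        "d": model.d,
        "lambda": model.lam,
        "b": model.b,
        "cv_folds": model.cv_folds,
        "support_indices": [int(i) for i in support],
        "support_values": [float(v) for v in model.w[support]],
    }
    if extra:
        payload["extra"] = extra
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> LassoLdaModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "lasso-lda-v1":
        raise DataFormatError(f"{path} is not a persisted LASSO-LDA model")
    w = np.zeros(int(payload["d"]))
    w[np.asarray(payload["support_indices"], dtype=int)] = payload["support_values"]
    return LassoLdaModel(
        w=w,
        b=float(payload["b"]),
        lam=float(payload["lambda"]),
        cv_folds=int(payload["cv_folds"]),
    )


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
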