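"""Readers and writers for wireless-headstage LFP text dialects and session tables.

The head-mounted recording module streams one channel per animal at 1024 Hz
and saves each 30-minute chunk as a separate space-delimited text file of
fixed-width hexadecimal tokens (two's-complement ADC counts).  This module
decodes that dialect, concatenates chunk files into continuous traces, and
reads/writes the per-second behavioural annotation table and the session
manifest that ties subjects, conditions and files together.

Samples are kept as unitless signed integers throughout; no voltage
calibration is applied anywhere in the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LfpTrace",
    "SessionManifest",
    "AnnotationTable",
    "LOCOMOTIVE_STATES",
    "read_cbrain_hex",
    "write_cbrain_hex",
    "read_plain_text",
    "write_plain_text",
    "read_trace",
    "write_trace",
    "concatenate_segments",
    "read_annotations",
    "write_annotations",
    "read_manifest",
    "write_manifest",
]

#: Closed vocabulary of per-second locomotive states.
LOCOMOTIVE_STATES = ("inactive", "active_still", "active")

CONDITIONS = ("group", "single")


class FormatError(ValueError):
    """Malformed on-disk data (bad hex token, missing annotation second...)."""


@dataclass
class LfpTrace:
    """One animal's continuous single-channel LFP recording.

    Parameters
    ----------
    subject_id, cohort_id : str
        Animal and cohort identifiers from the session manifest.
    condition : {"group", "single"}
        Social context the session was recorded in.
    fs : float
        Sampling rate in Hz (1024 for the wireless headstage).
    samples : ndarray of int
        Signed ADC counts, unitless.
    t0 : float
        Session-relative start time of the first sample, in seconds.
    bit_width : int
        ADC word size; samples must fit in a signed integer of this width.
    """

    subject_id: str
    cohort_id: str
    condition: str
    fs: float
    samples: np.ndarray
    t0: float = 0.0
    bit_width: int = 16

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        self.samples = np.asarray(self.samples)
        if self.samples.size == 0:
            raise ValueError("trace must contain at least one sample")
        if not np.issubdtype(self.samples.dtype, np.integer):
            if not np.all(self.samples == np.round(self.samples)):
                raise ValueError("samples must be integers (unitless ADC counts)")
            self.samples = self.samples.astype(np.int64)
        lo, hi = _signed_range(self.bit_width)
        if self.samples.min() < lo or self.samples.max() > hi:
            raise ValueError(
                f"samples exceed the declared {self.bit_width}-bit signed range [{lo}, {hi}]"
            )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def astype_float(self) -> np.ndarray:
        return self.samples.astype(np.float64)


@dataclass
class SessionManifest:
    """Cohort/condition/file bookkeeping for one recording session."""

    cohort_id: str
    condition: str
    subjects: list[str]
    files: dict[str, list[str]] = field(default_factory=dict)
    duration_s: float | None = None
    fs: float = 1024.0
    bit_width: int = 16
    max_subjects: int = 4

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if not 1 <= len(self.subjects) <= self.max_subjects:
            raise ValueError(
                f"expected 1..{self.max_subjects} subjects, got {len(self.subjects)}"
            )
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("duplicate subject IDs in manifest")
        for sid, paths in self.files.items():
            if sid not in self.subjects:
                raise ValueError(f"file map references unknown subject {sid!r}")
            if not paths:
                raise ValueError(f"empty segment list for subject {sid!r}")


@dataclass
class AnnotationTable:
    """Per-second behavioural annotation for every subject in a session.

    Wraps a long-format DataFrame with columns ``subject_id``, ``second``,
    ``locomotive_state``, ``huddle_group_id`` (pandas NA when the animal is
    not huddled) and optionally ``sleep`` (bool, added by
    :func:`mblfp.behavior.label_sleep`).
    """

    df: pd.DataFrame
    condition: str

    def __post_init__(self) -> None:
        required = {"subject_id", "second", "locomotive_state"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if "huddle_group_id" not in self.df.columns:
            self.df = self.df.assign(huddle_group_id=pd.array([pd.NA] * len(self.df)))
        bad = set(self.df["locomotive_state"]) - set(LOCOMOTIVE_STATES)
        if bad:
            raise FormatError(
                f"unknown locomotive state(s) {sorted(bad)}; allowed: {LOCOMOTIVE_STATES}"
            )
        if self.condition == "single" and self.df["huddle_group_id"].notna().any():
            raise ValueError("huddle labels are not allowed in single condition")

    @property
    def subjects(self) -> list[str]:
        return sorted(self.df["subject_id"].unique())

    @property
    def n_seconds(self) -> int:
        return int(self.df["second"].max()) + 1 if len(self.df) else 0

    def for_subject(self, subject_id: str) -> pd.DataFrame:
        sub = self.df[self.df["subject_id"] == subject_id]
        return sub.sort_values("second").reset_index(drop=True)

    def states(self, subject_id: str) -> np.ndarray:
        """Locomotive state per second for one subject, as an object array."""
        return self.for_subject(subject_id)["locomotive_state"].to_numpy()

    def huddled_flags(self, subject_id: str) -> np.ndarray:
        """Boolean per-second 'participates in a huddle' flag for one subject."""
        return self.for_subject(subject_id)["huddle_group_id"].notna().to_numpy()


def _signed_range(bit_width: int) -> tuple[int, int]:
    return -(1 << (bit_width - 1)), (1 << (bit_width - 1)) - 1


# ---------------------------------------------------------------------------
# hexadecimal LFP dialect
# ---------------------------------------------------------------------------

def read_cbrain_hex(
    path: str | Path,
    fs: float = 1024.0,
    bit_width: int = 16,
    *,
    subject_id: str = "",
    cohort_id: str = "",
    condition: str = "single",
    t0: float = 0.0,
) -> LfpTrace:
    """Decode a space-delimited fixed-width hexadecimal LFP text file.

    Tokens are interpreted as two's-complement signed integers of
    ``bit_width`` bits; any whitespace (including newlines) separates tokens.
    """
    path = Path(path)
    text = path.read_text()
    tokens = text.split()
    if not tokens:
        raise FormatError(f"{path}: empty LFP file")
    width = bit_width // 4
    values = np.empty(len(tokens), dtype=np.int64)
    for i, tok in enumerate(tokens):
        if len(tok) != width:
            raise FormatError(
                f"{path}: token {i} ({tok!r}) is not a {width}-character hex word"
            )
        try:
            v = int(tok, 16)
        except ValueError:
            raise FormatError(f"{path}: token {i} ({tok!r}) is not valid hexadecimal") from None
        if v >= 1 << (bit_width - 1):  # two's complement
            v -= 1 << bit_width
        values[i] = v
    return LfpTrace(
        subject_id=subject_id,
        cohort_id=cohort_id,
        condition=condition,
        fs=fs,
        samples=values,
        t0=t0,
        bit_width=bit_width,
    )


def write_cbrain_hex(trace: LfpTrace, path: str | Path, per_line: int = 16) -> Path:
    """Write a trace in the hexadecimal dialect; re-readable bit-exactly."""
    path = Path(path)
    lo, hi = _signed_range(trace.bit_width)
    samples = np.asarray(trace.samples, dtype=np.int64)
    if samples.min() < lo or samples.max() > hi:
        raise ValueError(f"sample out of representable {trace.bit_width}-bit range")
    width = trace.bit_width // 4
    mask = (1 << trace.bit_width) - 1
    unsigned = samples & mask
    toks = [format(int(v), f"0{width}X") for v in unsigned]
    lines = [
        " ".join(toks[i : i + per_line]) for i in range(0, len(toks), per_line)
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# plain-text fallback dialect
# ---------------------------------------------------------------------------

def read_plain_text(path: str | Path, fs: float = 1024.0, **meta) -> LfpTrace:
    """Read a one-column signed-decimal-integer text trace."""
    path = Path(path)
    try:
        values = np.loadtxt(path, dtype=np.int64, ndmin=1)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None
    if values.size == 0:
        raise FormatError(f"{path}: empty LFP file")
    meta.setdefault("condition", "single")
    return LfpTrace(
        subject_id=meta.pop("subject_id", ""),
        cohort_id=meta.pop("cohort_id", ""),
        fs=fs,
        samples=values,
        **meta,
    )


def write_plain_text(trace: LfpTrace, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, np.asarray(trace.samples, dtype=np.int64), fmt="%d")
    return path


def read_binary_int16(path: str | Path, fs: float = 1024.0, **meta) -> LfpTrace:
    """Read a little-endian int16 binary trace."""
    path = Path(path)
    values = np.fromfile(path, dtype="<i2").astype(np.int64)
    if values.size == 0:
        raise FormatError(f"{path}: empty LFP file")
    meta.setdefault("condition", "single")
    return LfpTrace(
        subject_id=meta.pop("subject_id", ""),
        cohort_id=meta.pop("cohort_id", ""),
        fs=fs,
        samples=values,
        **meta,
    )


def write_binary_int16(trace: LfpTrace, path: str | Path) -> Path:
    path = Path(path)
    np.asarray(trace.samples, dtype="<i2").tofile(path)
    return path


def read_trace(path: str | Path, fs: float = 1024.0, bit_width: int = 16, **meta) -> LfpTrace:
    """Dispatch on extension: ``.hex`` hexadecimal, ``.bin`` int16, else plain text."""
    path = Path(path)
    if path.suffix.lower() == ".hex":
        return read_cbrain_hex(path, fs=fs, bit_width=bit_width, **meta)
    if path.suffix.lower() == ".bin":
        return read_binary_int16(path, fs=fs, **meta)
    return read_plain_text(path, fs=fs, **meta)


def write_trace(trace: LfpTrace, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() == ".hex":
        return write_cbrain_hex(trace, path)
    if path.suffix.lower() == ".bin":
        return write_binary_int16(trace, path)
    return write_plain_text(trace, path)


def concatenate_segments(
    paths: Sequence[str | Path],
    fs: float = 1024.0,
    bit_width: int = 16,
    **meta,
) -> LfpTrace:
    """Concatenate ordered 30-min chunk files into one continuous trace."""
    if not paths:
        raise ValueError("need at least one segment file")
    traces = [read_trace(p, fs=fs, bit_width=bit_width, **meta) for p in paths]
    samples = np.concatenate([t.samples for t in traces])
    return replace(traces[0], samples=samples)


# ---------------------------------------------------------------------------
# annotation table and manifest
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path, manifest: SessionManifest) -> AnnotationTable:
    """Read the per-second annotation CSV and validate it against a manifest.

    The table must contain one row per (subject, second) for every subject in
    the manifest and every second ``0..duration_s-1``; gaps and unknown
    subjects or states are reported as errors.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "huddle_group_id": "string"})
    required = {"subject_id", "second", "locomotive_state"}
    if missing := required - set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    unknown_subjects = set(df["subject_id"]) - set(manifest.subjects)
    if unknown_subjects:
        raise FormatError(f"{path}: unknown subject(s) {sorted(unknown_subjects)}")
    bad_states = set(df["locomotive_state"]) - set(LOCOMOTIVE_STATES)
    if bad_states:
        raise FormatError(
            f"{path}: unknown locomotive state(s) {sorted(bad_states)}; "
            f"allowed: {LOCOMOTIVE_STATES}"
        )
    n_seconds = int(manifest.duration_s) if manifest.duration_s else int(df["second"].max()) + 1
    expected = set(range(n_seconds))
    gaps: list[tuple[str, int]] = []
    for sid in manifest.subjects:
        have = set(df.loc[df["subject_id"] == sid, "second"].astype(int))
        gaps.extend((sid, s) for s in sorted(expected - have))
    if gaps:
        shown = ", ".join(f"({sid}, {s})" for sid, s in gaps[:10])
        raise FormatError(
            f"{path}: {len(gaps)} missing (subject, second) entries, e.g. {shown}"
        )
    df = df[df["second"] < n_seconds]
    if "huddle_group_id" not in df.columns:
        df["huddle_group_id"] = pd.array([pd.NA] * len(df), dtype="string")
    return AnnotationTable(df=df.reset_index(drop=True), condition=manifest.condition)


def write_annotations(table: AnnotationTable, path: str | Path) -> Path:
    path = Path(path)
    cols = ["subject_id", "second", "locomotive_state", "huddle_group_id"]
    if "sleep" in table.df.columns:
        cols.append("sleep")
    table.df[cols].to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> SessionManifest:
    """Read a YAML or JSON session manifest."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return SessionManifest(
        cohort_id=str(data["cohort_id"]),
        condition=data["condition"],
        subjects=[str(s) for s in data["subjects"]],
        files={str(k): list(v) for k, v in data.get("files", {}).items()},
        duration_s=data.get("duration_s"),
        fs=float(data.get("fs", 1024.0)),
        bit_width=int(data.get("bit_width", 16)),
    )


def write_manifest(manifest: SessionManifest, path: str | Path) -> Path:
    path = Path(path)
    data = {
        "cohort_id": manifest.cohort_id,
        "condition": manifest.condition,
        "subjects": list(manifest.subjects),
        "files": {k: list(v) for k, v in manifest.files.items()},
        "duration_s": manifest.duration_s,
        "fs": manifest.fs,
        "bit_width": manifest.bit_width,
    }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path
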