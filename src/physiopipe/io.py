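"""Session I/O: XDF / CSV-dialect loading, marker trimming, output writing.

A session is a set of synchronously recorded physiological streams (ECG,
EDA, EMG, respiration) plus experiment markers.  The native container is
XDF as produced by a Lab-Streaming-Layer recorder; a plain-text CSV
dialect (one file per channel, a ``markers.csv`` sidecar and an optional
``session.json`` with participant metadata) is supported so that fixtures
stay diffable and loading is testable without binary files.

CSV dialect
-----------
Each channel file starts with a header line ``# modality=ECG,fs=250.0,units=mV``
followed by a two-column table ``time_s,value``.  Markers live in
``markers.csv`` (columns ``label,time_s``).  Timestamps are authoritative;
``fs`` is the nominal rate used for filtering and resampling.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MODALITIES = ("ECG", "EDA", "EMG", "RESP")

#: default substring patterns used to match stream names/labels to modalities
DEFAULT_STREAM_SPEC: dict[str, str] = {m: m.lower() for m in MODALITIES}

EXPERIENCE_START = "experience_start"
EXPERIENCE_END = "experience_end"


class LoadError(RuntimeError):
    """Raised when a session container cannot be read."""


class AmbiguousStreamError(LoadError):
    """Raised when one modality pattern matches more than one stream."""


class TrimError(RuntimeError):
    """Raised when an experience marker required for trimming is missing."""


@dataclass
class Channel:
    """One uniformly sampled physiological stream.

    ``samples`` are in device units (mV for ECG/EMG, microsiemens for EDA,
    arbitrary impedance units for respiration).  ``t0`` is the time of the
    first sample in seconds on the session clock.
    """

    modality: str
    samples: np.ndarray
    fs: float
    t0: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return max(self.samples.size - 1, 0) / self.fs


@dataclass
class SessionRecording:
    """All channels and markers for one participant's session."""

    participant_id: str
    channels: dict[str, Channel] = field(default_factory=dict)
    markers: list[tuple[str, float]] = field(default_factory=list)
    group_labels: dict[str, str] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def marker_time(self, label: str) -> float | None:
        for lab, t in self.markers:
            if lab == label:
                return t
        return None

    def has(self, modality: str) -> bool:
        return modality in self.channels


# ---------------------------------------------------------------------------
# loading


def _match_modalities(
    names: Sequence[tuple[str, str]], stream_spec: Mapping[str, str]
) -> dict[str, int]:
    """Map modality -> stream index by case-insensitive substring match.

    ``names`` is a list of (name, label) per stream.  Matching more than one
    stream for a modality is an error; matching none records the modality as
    absent.
    """
    out: dict[str, int] = {}
    for modality, pattern in stream_spec.items():
        pat = pattern.lower()
        hits = [
            i
            for i, (name, label) in enumerate(names)
            if pat in name.lower() or pat in label.lower()
        ]
        if len(hits) > 1:
            matched = ", ".join(repr(names[i][0]) for i in hits)
            raise AmbiguousStreamError(
                f"pattern {pattern!r} for modality {modality} matches "
                f"multiple streams: {matched}"
            )
        if hits:
            out[modality] = hits[0]
    return out


def load_session(
    path: str | Path,
    stream_spec: Mapping[str, str] | None = None,
    participant_id: str | None = None,
) -> SessionRecording:
    """Load a session from an XDF file or a CSV-dialect directory.

    Streams are selected per modality by case-insensitive substring match of
    ``stream_spec`` patterns against stream names and labels.  Unmatched
    modalities are recorded as absent, not an error.  All timestamps are
    re-expressed relative to the earliest sample in the recording.
    """
    path = Path(path)
    spec = dict(stream_spec or DEFAULT_STREAM_SPEC)
    if path.is_dir():
        return _load_csv_session(path, spec, participant_id)
    if path.suffix.lower() == ".xdf":
        return _load_xdf_session(path, spec, participant_id)
    raise LoadError(f"cannot load session from {path}: not a directory or .xdf file")


_HEADER_RE = re.compile(r"#\s*modality=([^,]+),\s*fs=([^,]+),\s*units=(.*)")


def _load_csv_session(
    path: Path, spec: Mapping[str, str], participant_id: str | None
) -> SessionRecording:
    files = sorted(
        f
        for f in path.glob("*.csv")
        if f.name not in ("markers.csv",)
    )
    headers: list[tuple[str, str]] = []  # (name, label) per candidate file
    parsed: list[tuple[Path, str, float, str]] = []
    for f in files:
        with open(f) as fh:
            first = fh.readline()
        m = _HEADER_RE.match(first.strip())
        if not m:
            raise LoadError(f"{f}: missing channel header line")
        modality, fs_s, units = m.group(1).strip(), m.group(2).strip(), m.group(3).strip()
        try:
            fs = float(fs_s)
        except ValueError as e:
            raise LoadError(f"{f}: bad fs {fs_s!r}") from e
        parsed.append((f, modality, fs, units))
        headers.append((f.stem, modality))

    chosen = _match_modalities(headers, spec)
    channels: dict[str, Channel] = {}
    t_starts: list[float] = []
    for modality, idx in chosen.items():
        f, declared, fs, units = parsed[idx]
        tab = pd.read_csv(f, comment="#")
        if not {"time_s", "value"} <= set(tab.columns):
            raise LoadError(f"{f}: expected columns time_s,value")
        t = tab["time_s"].to_numpy(dtype=float)
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise LoadError(f"{f}: timestamps are not strictly increasing")
        channels[modality] = Channel(
            modality=modality,
            samples=tab["value"].to_numpy(dtype=float),
            fs=fs,
            t0=float(t[0]) if t.size else 0.0,
            units=units,
        )
        if t.size:
            t_starts.append(float(t[0]))

    markers: list[tuple[str, float]] = []
    mfile = path / "markers.csv"
    if mfile.exists():
        mtab = pd.read_csv(mfile)
        markers = [(str(r.label), float(r.time_s)) for r in mtab.itertuples()]

    meta = {}
    jfile = path / "session.json"
    if jfile.exists():
        meta = json.loads(jfile.read_text())

    rec = SessionRecording(
        participant_id=participant_id or meta.get("participant_id", path.name),
        channels=channels,
        markers=markers,
        group_labels={k: meta[k] for k in ("tech", "stim") if k in meta},
    )
    return _rebase_times(rec)


def _load_xdf_session(
    path: Path, spec: Mapping[str, str], participant_id: str | None
) -> SessionRecording:
    try:
        import pyxdf  # type: ignore[import-not-found]
    except ImportError as e:  # pragma: no cover - environment dependent
        raise LoadError(
            "reading .xdf requires the optional pyxdf dependency "
            "(pip install physiopipe[xdf]); alternatively convert the session "
            "to the CSV dialect"
        ) from e

    try:
        streams, _ = pyxdf.load_xdf(str(path))
    except Exception as e:  # pragma: no cover
        raise LoadError(f"failed to parse XDF file {path}: {e}") from e

    def _info(stream, key):
        v = stream["info"].get(key, [""])
        return str(v[0]) if v else ""

    names = [(_info(s, "name"), _info(s, "type")) for s in streams]
    chosen = _match_modalities(names, spec)
    channels: dict[str, Channel] = {}
    for modality, idx in chosen.items():
        s = streams[idx]
        ts = np.asarray(s["time_stamps"], dtype=float)
        vals = np.asarray(s["time_series"], dtype=float)
        if vals.ndim > 1:
            vals = vals[:, 0]
        fs = float(_info(s, "nominal_srate") or 0) or (
            (ts.size - 1) / (ts[-1] - ts[0]) if ts.size > 1 else 1.0
        )
        channels[modality] = Channel(
            modality=modality, samples=vals, fs=fs, t0=float(ts[0]) if ts.size else 0.0
        )

    markers: list[tuple[str, float]] = []
    for s in streams:
        if _info(s, "type").lower() == "markers" or _info(s, "name").lower().startswith(
            "marker"
        ):
            for lab, t in zip(s["time_series"], s["time_stamps"]):
                lab0 = lab[0] if isinstance(lab, (list, tuple, np.ndarray)) else lab
                markers.append((str(lab0), float(t)))

    rec = SessionRecording(
        participant_id=participant_id or path.stem,
        channels=channels,
        markers=markers,
    )
    return _rebase_times(rec)


def _rebase_times(rec: SessionRecording) -> SessionRecording:
    """Shift all times so the earliest sample of any channel is t=0."""
    starts = [ch.t0 for ch in rec.channels.values()]
    if not starts:
        return rec
    t_ref = min(starts)
    for ch in rec.channels.values():
        ch.t0 -= t_ref
    rec.markers = [(lab, t - t_ref) for lab, t in rec.markers]
    return rec


# ---------------------------------------------------------------------------
# trimming


def trim_to_experience(
    rec: SessionRecording,
    start_label: str = EXPERIENCE_START,
    end_label: str = EXPERIENCE_END,
) -> SessionRecording:
    """Restrict every channel to the experience-marker window.

    All times are re-expressed relative to the start marker so that
    downstream windowing ("first 2 min", "last 5 min") begins at t=0.
    Channels falling entirely outside the window are dropped with a note.
    Idempotent: trimming a trimmed recording is a no-op.
    """
    t_start = rec.marker_time(start_label)
    t_end = rec.marker_time(end_label)
    if t_start is None:
        raise TrimError(f"missing marker {start_label!r}")
    if t_end is None:
        raise TrimError(f"missing marker {end_label!r}")
    if t_end <= t_start:
        raise TrimError(
            f"marker {end_label!r} ({t_end}) not after {start_label!r} ({t_start})"
        )

    channels: dict[str, Channel] = {}
    notes = list(rec.notes)
    for modality, ch in rec.channels.items():
        t = ch.times
        keep = (t >= t_start) & (t <= t_end)
        if not keep.any():
            notes.append(f"{modality}: no samples within experience window, dropped")
            continue
        idx = np.flatnonzero(keep)
        channels[modality] = replace(
            ch,
            samples=ch.samples[idx[0] : idx[-1] + 1].copy(),
            t0=float(t[idx[0]] - t_start),
        )
    markers = [(lab, t - t_start) for lab, t in rec.markers]
    return SessionRecording(
        participant_id=rec.participant_id,
        channels=channels,
        markers=markers,
        group_labels=dict(rec.group_labels),
        notes=notes,
    )


# ---------------------------------------------------------------------------
# writing


def write_session(rec: SessionRecording, out_dir: str | Path, overwrite: bool = False) -> Path:
    """Write a session in the CSV dialect (one file per channel + sidecars)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for modality, ch in rec.channels.items():
        f = out / f"{modality.lower()}.csv"
        if f.exists() and not overwrite:
            raise FileExistsError(f"{f} exists; pass overwrite=True")
        with open(f, "w") as fh:
            fh.write(f"# modality={ch.modality},fs={float(ch.fs)!r},units={ch.units}\n")
            fh.write("time_s,value\n")
            for t, v in zip(ch.times, ch.samples):
                fh.write(f"{float(t)!r},{float(v)!r}\n")
    mfile = out / "markers.csv"
    if mfile.exists() and not overwrite:
        raise FileExistsError(f"{mfile} exists; pass overwrite=True")
    with open(mfile, "w") as fh:
        fh.write("label,time_s\n")
        for lab, t in rec.markers:
            fh.write(f"{lab},{float(t)!r}\n")
    meta = {"participant_id": rec.participant_id, **rec.group_labels}
    (out / "session.json").write_text(json.dumps(meta, indent=1))
    return out


def write_outputs(
    features: pd.DataFrame,
    qc: Iterable[Mapping],
    out_dir: str | Path,
    overwrite: bool = False,
) -> tuple[Path, Path]:
    """Write the feature table (TSV) and QC report (JSON).

    Missing feature values are written as empty cells, never 0.  Refuses to
    clobber existing files unless ``overwrite`` is set.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    f_feat = out / "features.tsv"
    f_qc = out / "qc_report.json"
    for f in (f_feat, f_qc):
        if f.exists() and not overwrite:
            raise FileExistsError(f"{f} exists; pass overwrite=True")
    features.to_csv(f_feat, sep="\t", index=False, float_format="%.10g", na_rep="")
    f_qc.write_text(json.dumps(list(qc), indent=1, default=_jsonable))
    return f_feat, f_qc


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_outputs`."""
    return pd.read_csv(path, sep="\t")
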