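"""On-disk formats: CSV sessions with JSON event sidecars, JSON networks.

A session is stored as a plain CSV of samples × channels (header = channel
labels, µV) next to a ``<stem>.events.json`` sidecar carrying the sampling
rate, subject metadata, the turn events, and run metadata (seed, config
fingerprint, package version).  Networks serialize to JSON as
``{n, W (row-major), T, stored: [{label, bits}]}``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .hopfield import HopfieldNetwork
from .report import PerformanceReport
from .selection import BipolarPattern
from .synth import EEGSession, TurnEvent


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".events.json")


def config_fingerprint(obj: Any) -> str:
    """Stable short hash of any JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode("utf8")
    return hashlib.sha256(blob).hexdigest()[:12]


def write_session(
    session: EEGSession,
    path: str | Path,
    metadata: dict[str, Any] | None = None,
    float_fmt: str = "%.6f",
) -> Path:
    """Write samples × channels CSV plus the JSON event sidecar; returns the CSV path."""
    path = Path(path).with_suffix(".csv")
    df = pd.DataFrame(session.data.T, columns=list(session.channel_labels))
    df.to_csv(path, index=False, float_format=float_fmt)
    sidecar = {
        "fs": session.fs,
        "subject_id": session.subject_id,
        "group": session.group,
        "n_samples": session.n_samples,
        "channel_labels": list(session.channel_labels),
        "events": [asdict(ev) for ev in session.events],
        "meta": {"package_version": __version__, **(metadata or {})},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_session(path: str | Path) -> EEGSession:
    """Read a CSV session and its sidecar back into an :class:`EEGSession`."""
    path = Path(path).with_suffix(".csv")
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(f"missing event sidecar {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    df = pd.read_csv(path)
    expected = sidecar.get("channel_labels")
    if expected:
        missing = [c for c in expected if c not in df.columns]
        if missing:
            raise ValueError(f"CSV is missing channel column(s): {missing}")
        df = df[expected]
    events = [TurnEvent(**ev) for ev in sidecar["events"]]
    return EEGSession(
        df.to_numpy(dtype=float).T,
        fs=float(sidecar["fs"]),
        channel_labels=tuple(df.columns),
        events=events,
        subject_id=sidecar.get("subject_id", ""),
        group=sidecar.get("group"),
    )


def network_to_json(net: HopfieldNetwork, path: str | Path | None = None) -> dict:
    doc = {
        "n": net.n,
        "W": net.W.astype(int).ravel().tolist(),
        "T": net.T.tolist(),
        "stored": [
            {"label": p.label, "bits": p.bits.tolist(),
             "feature_ids": list(p.feature_ids)}
            for p in net.stored
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=1))
    return doc


def network_from_json(source: str | Path | dict) -> HopfieldNetwork:
    doc = source if isinstance(source, dict) else json.loads(Path(source).read_text())
    n = int(doc["n"])
    stored = [
        BipolarPattern(np.array(p["bits"]), label=p.get("label"),
                       feature_ids=list(p.get("feature_ids", [])))
        for p in doc.get("stored", [])
    ]
    return HopfieldNetwork(np.array(doc["W"]).reshape(n, n),
                           np.array(doc["T"], dtype=float), stored=stored)


def write_report(report: PerformanceReport, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=1, default=str))
    return path
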