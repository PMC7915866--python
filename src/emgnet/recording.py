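"""Core container for multichannel surface-EMG recordings.

A recording is a dense ``(n_samples, n_channels)`` float matrix sampled at a
fixed rate, with display channel labels (``V1`` ... ``V33`` by convention),
a movement-condition label, and a list of phase spans marking where each
repetition's movement phases (lift / hold / lower) sit in the sample axis.

Recordings round-trip through a plain-text pair: a CSV matrix (header row =
channel labels, one sample per row) and a JSON sidecar carrying the rate,
condition, phase spans and any generator metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["PhaseSpan", "EMGRecording", "write_recording", "read_recording"]

#: canonical phase names in temporal order within one repetition
PHASES = ("lift", "hold", "lower")


@dataclass(frozen=True)
class PhaseSpan:
    """Half-open sample range ``[start, stop)`` of one phase of one repetition."""

    repetition: int
    phase: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError(f"empty phase span: {self}")


@dataclass
class EMGRecording:
    """Samples-by-channels EMG matrix with phase annotations.

    Parameters
    ----------
    data
        Array of shape ``(n_samples, n_channels)``.
    rate
        Sampling rate in Hz.
    labels
        Channel display labels, one per column.
    condition
        Movement-condition label (e.g. ``"appropriate"``), or ``None``.
    spans
        Phase spans covering the annotated parts of the recording.
    meta
        Free-form metadata (seed, generator parameters, truth record, ...).
    """

    data: np.ndarray
    rate: float
    labels: Sequence[str]
    condition: str | None = None
    spans: Sequence[PhaseSpan] = field(default_factory=tuple)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (samples x channels)")
        if len(self.labels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[1]} channels"
            )
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        for sp in self.spans:
            if sp.stop > self.data.shape[0]:
                raise ValueError(f"phase span {sp} exceeds record length")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        try:
            j = list(self.labels).index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None
        return self.data[:, j]

    @property
    def repetitions(self) -> list[int]:
        return sorted({sp.repetition for sp in self.spans})

    def phase_spans(self, phase: str) -> list[PhaseSpan]:
        return sorted(
            (sp for sp in self.spans if sp.phase == phase),
            key=lambda sp: sp.repetition,
        )


def default_labels(n_channels: int) -> list[str]:
    """1-based display labels ``V1`` ... ``Vn``."""
    return [f"V{i + 1}" for i in range(n_channels)]


def write_recording(rec: EMGRecording, csv_path: str | Path) -> Path:
    """Write ``rec`` as CSV plus a JSON sidecar next to it.

    Returns the sidecar path (``<stem>.json``).
    """
    csv_path = Path(csv_path)
    pd.DataFrame(rec.data, columns=list(rec.labels)).to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    payload = {
        "rate": rec.rate,
        "condition": rec.condition,
        "spans": [asdict(sp) for sp in rec.spans],
        "meta": _jsonable(rec.meta),
    }
    sidecar.write_text(json.dumps(payload, indent=1))
    return sidecar


def read_recording(csv_path: str | Path) -> EMGRecording:
    """Read a recording written by :func:`write_recording`."""
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path)
    sidecar = csv_path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    payload = json.loads(sidecar.read_text())
    spans = tuple(PhaseSpan(**sp) for sp in payload.get("spans", ()))
    return EMGRecording(
        data=frame.to_numpy(dtype=float),
        rate=float(payload["rate"]),
        labels=list(frame.columns),
        condition=payload.get("condition"),
        spans=spans,
        meta=payload.get("meta", {}),
    )


def _jsonable(obj: Any) -> Any:
    """Best-effort conversion of metadata values to JSON-encodable types."""
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
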