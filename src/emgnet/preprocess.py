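"""Filtering and phase segmentation of EMG recordings.

The raw signal is band-pass filtered (zero-phase Butterworth, default
20-450 Hz, order 4) and mean-subtracted per channel to remove zero drift.
Zero-phase (forward-backward) filtering is used so that envelope timing —
which the causality stage depends on — is not shifted by the filter's group
delay.  Analysis then proceeds on per-repetition windows of a single
movement phase, conventionally the lift phase where the prosthesis load
falls on the stump.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as _signal

from .recording import EMGRecording, PhaseSpan, PHASES

__all__ = ["Segment", "preprocess_recording", "segment_phase"]


@dataclass
class Segment:
    """One phase window of one repetition, all channels."""

    data: np.ndarray  # (samples, channels)
    rate: float
    labels: Sequence[str]
    condition: str | None
    repetition: int
    phase: str

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]


def preprocess_recording(
    rec: EMGRecording,
    low: float = 20.0,
    high: float = 450.0,
    order: int = 4,
    trim: float = 0.0,
) -> EMGRecording:
    """Zero-phase Butterworth band-pass plus per-channel mean removal.

    Parameters
    ----------
    low, high
        Pass-band edges in Hz; must satisfy ``0 < low < high < rate / 2``.
    order
        Filter order (applied once in each direction).
    trim
        Seconds to drop from each end of every repetition's phase spans to
        discard filter edge transients (default: keep everything).
    """
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= rec.rate / 2:
        raise ValueError(f"band edge {high} Hz is not below Nyquist {rec.rate / 2} Hz")
    bad = ~np.isfinite(rec.data).all(axis=0)
    if bad.any():
        names = [lab for lab, b in zip(rec.labels, bad) if b]
        raise ValueError(f"non-finite samples in channel(s) {names}")

    sos = _signal.butter(order, (low, high), btype="band", fs=rec.rate, output="sos")
    filtered = _signal.sosfiltfilt(sos, rec.data, axis=0)
    filtered = filtered - filtered.mean(axis=0, keepdims=True)

    spans = rec.spans
    if trim > 0:
        cut = int(round(trim * rec.rate))
        trimmed = []
        for sp in spans:
            if sp.stop - sp.start > 2 * cut:
                trimmed.append(PhaseSpan(sp.repetition, sp.phase, sp.start + cut, sp.stop - cut))
        spans = tuple(trimmed)

    return EMGRecording(
        data=filtered,
        rate=rec.rate,
        labels=list(rec.labels),
        condition=rec.condition,
        spans=spans,
        meta={**rec.meta, "preprocess": {"low": low, "high": high, "order": order, "trim": trim}},
    )


def segment_phase(rec: EMGRecording, phase: str = "lift") -> list[Segment]:
    """Extract one :class:`Segment` per repetition for the requested phase.

    Segments are ordered by repetition index.  An empty recording (no spans)
    yields an empty list.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
    out: list[Segment] = []
    for sp in rec.phase_spans(phase):
        if sp.stop > rec.n_samples:
            raise ValueError(f"span {sp} exceeds record length {rec.n_samples}")
        out.append(
            Segment(
                data=rec.data[sp.start : sp.stop],
                rate=rec.rate,
                labels=list(rec.labels),
                condition=rec.condition,
                repetition=sp.repetition,
                phase=phase,
            )
        )
    return out
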