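"""Filtering and segmentation of raw ECoG traces.

Preprocessing is deliberately minimal: zero-phase 50 Hz notch (Q = 30) and a
zero-phase first-order 0.1 Hz Butterworth high-pass, then segmentation into
per-concentration blocks (discarding the transient head of each protocol
segment) and non-overlapping fixed-length analysis windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synthetic_data import Recording

__all__ = [
    "Block",
    "Window",
    "notch_filter",
    "highpass_filter",
    "preprocess_recording",
    "segment_blocks",
    "window_block",
    "window_blocks",
]


def notch_filter(
    x: np.ndarray, sample_rate: float, center_hz: float = 50.0, quality: float = 30.0
) -> np.ndarray:
    """Zero-phase (forward-backward) IIR notch at ``center_hz``."""
    if center_hz >= sample_rate / 2.0:
        raise ValueError("notch center must be below Nyquist")
    b, a = signal.iirnotch(center_hz, quality, fs=sample_rate)
    return signal.filtfilt(b, a, np.asarray(x, dtype=float))


def highpass_filter(
    x: np.ndarray, sample_rate: float, cutoff_hz: float = 0.1, order: int = 1
) -> np.ndarray:
    """Zero-phase Butterworth high-pass; removes DC and slow drift."""
    if cutoff_hz >= sample_rate / 2.0:
        raise ValueError("cutoff must be below Nyquist")
    x = np.asarray(x, dtype=float)
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=sample_rate, output="sos")
    # scipy's default pad (a few samples) is far shorter than this filter's
    # ~1/(2*pi*cutoff) time constant; pad to ~3 time constants
    padlen = min(x.size - 1, int(3 * sample_rate / cutoff_hz / (2 * np.pi)) * 3)
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def preprocess_recording(
    rec: Recording,
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
    highpass_hz: float = 0.1,
) -> Recording:
    """Apply notch then high-pass to both channels (both zero-phase, so the
    order is immaterial); returns a new Recording."""
    if not rec.input_referred:
        raise ValueError("recording must be input-referred (amplifier gain removed)")
    return Recording(
        channel_contra=highpass_filter(
            notch_filter(rec.channel_contra, rec.sample_rate, notch_hz, notch_q),
            rec.sample_rate,
            highpass_hz,
        ),
        channel_ipsi=highpass_filter(
            notch_filter(rec.channel_ipsi, rec.sample_rate, notch_hz, notch_q),
            rec.sample_rate,
            highpass_hz,
        ),
        sample_rate=rec.sample_rate,
        stim_onsets=rec.stim_onsets,
        protocol=rec.protocol,
        animal_id=rec.animal_id,
        ground_truth_depth=rec.ground_truth_depth,
    )


@dataclass
class Block:
    """One per-concentration analysis block (post-discard part of a segment)."""

    animal_id: str
    segment_index: int
    concentration: float
    start_s: float
    end_s: float
    sample_rate: float
    channel_contra: np.ndarray
    channel_ipsi: np.ndarray

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def channels(self) -> dict[str, np.ndarray]:
        return {"contra": self.channel_contra, "ipsi": self.channel_ipsi}


@dataclass
class Window:
    """One fixed-length, non-overlapping analysis window within a block."""

    animal_id: str
    segment_index: int
    concentration: float
    window_index: int
    t_start_s: float
    sample_rate: float
    channel_contra: np.ndarray
    channel_ipsi: np.ndarray

    def channels(self) -> dict[str, np.ndarray]:
        return {"contra": self.channel_contra, "ipsi": self.channel_ipsi}


def segment_blocks(rec: Recording, discard_minutes: float = 5.0) -> list[Block]:
    """Cut the recording into per-segment blocks, dropping the first
    ``discard_minutes`` of every protocol segment (anesthetic transient)."""
    edges = rec.protocol.boundaries_s()
    discard_s = discard_minutes * 60.0
    blocks = []
    for k, (conc, _dur) in enumerate(rec.protocol.segments):
        start = edges[k] + discard_s
        end = min(edges[k + 1], rec.duration_s)
        if start >= end:
            raise ValueError(
                f"segment {k} ({end - edges[k]:.0f} s) shorter than discard interval"
            )
        i0 = int(round(start * rec.sample_rate))
        i1 = int(round(end * rec.sample_rate))
        blocks.append(
            Block(
                animal_id=rec.animal_id,
                segment_index=k,
                concentration=conc,
                start_s=start,
                end_s=end,
                sample_rate=rec.sample_rate,
                channel_contra=rec.channel_contra[i0:i1],
                channel_ipsi=rec.channel_ipsi[i0:i1],
            )
        )
    return blocks


def window_block(block: Block, window_seconds: float = 10.0) -> list[Window]:
    """Split a block into consecutive non-overlapping windows; any trailing
    remainder shorter than ``window_seconds`` is dropped."""
    n_win = int(window_seconds * block.sample_rate)
    if block.channel_contra.size < n_win:
        raise ValueError("block shorter than one window")
    count = block.channel_contra.size // n_win
    wins = []
    for w in range(count):
        i0 = w * n_win
        wins.append(
            Window(
                animal_id=block.animal_id,
                segment_index=block.segment_index,
                concentration=block.concentration,
                window_index=w,
                t_start_s=block.start_s + i0 / block.sample_rate,
                sample_rate=block.sample_rate,
                channel_contra=block.channel_contra[i0 : i0 + n_win],
                channel_ipsi=block.channel_ipsi[i0 : i0 + n_win],
            )
        )
    return wins


def window_blocks(blocks: list[Block], window_seconds: float = 10.0) -> list[Window]:
    out: list[Window] = []
    for b in blocks:
        out.extend(window_block(b, window_seconds))
    return out
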