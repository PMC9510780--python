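"""Stimulus-locked evoked responses and the evoked-response-attenuation (ERA)
target.

ERA is a unit-less proxy of anesthetic depth: a trailing moving average of the
per-stimulus maximum evoked-response amplitude (contralateral channel), divided
by the animal's mean amplitude during its 1.0 % isoflurane blocks. By
construction ERA averages to ~1 inside 1.0 % blocks and is invariant to global
rescaling of the recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import Block
from .synthetic_data import Recording

__all__ = [
    "EvokedTrial",
    "ERASeries",
    "extract_trials",
    "trial_max_amplitude",
    "era_series",
    "attach_era",
]

TRIAL_WINDOW_S = (-0.2, 0.5)


@dataclass(frozen=True)
class EvokedTrial:
    """Baseline-corrected peri-stimulus snippet over [-0.2, +0.5] s."""

    onset_s: float
    samples: np.ndarray  # baseline already subtracted
    baseline_uv: float
    sample_rate: float


@dataclass(frozen=True)
class ERASeries:
    """ERA evaluated at stimulus times, plus the 1.0 % reference level (uV)."""

    times_s: np.ndarray
    values: np.ndarray
    reference_uv: float


def extract_trials(
    x: np.ndarray,
    stim_onsets: np.ndarray,
    sample_rate: float,
    window_s: tuple[float, float] = TRIAL_WINDOW_S,
) -> tuple[list[EvokedTrial], int]:
    """Cut peri-stimulus trials, zero-aligned by the pre-stimulus baseline mean.

    Onsets too close to the edges for a full window are skipped; the skipped
    count is returned alongside the trials.
    """
    x = np.asarray(x, dtype=float)
    pre = int(round(-window_s[0] * sample_rate))
    post = int(round(window_s[1] * sample_rate))
    trials = []
    skipped = 0
    for onset in np.asarray(stim_onsets, dtype=float):
        i0 = int(round(onset * sample_rate))
        if i0 - pre < 0 or i0 + post >= x.size:
            skipped += 1
            continue
        snippet = x[i0 - pre : i0 + post + 1]
        baseline = float(snippet[:pre].mean()) if pre > 0 else 0.0
        trials.append(
            EvokedTrial(
                onset_s=float(onset),
                samples=snippet - baseline,
                baseline_uv=baseline,
                sample_rate=sample_rate,
            )
        )
    return trials, skipped


def trial_max_amplitude(trial: EvokedTrial, window_s: tuple[float, float] = TRIAL_WINDOW_S) -> float:
    """Maximum absolute post-stimulus deflection (uV) of a baseline-corrected trial."""
    pre = int(round(-window_s[0] * trial.sample_rate))
    post = trial.samples[pre + 1 :]
    return float(np.abs(post).max()) if post.size else 0.0


def era_series(
    amplitudes: np.ndarray,
    times_s: np.ndarray,
    reference_mask: np.ndarray,
    window_stimuli: int = 10,
) -> ERASeries:
    """Trailing moving average of per-stimulus amplitudes, normalized by the
    mean amplitude over the reference (1.0 % isoflurane) stimuli.

    ``reference_mask`` flags the stimuli lying inside reference blocks.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if not reference_mask.any():
        raise ValueError("no stimuli in a reference (1.0 %) block; cannot normalize")
    reference = float(amplitudes[reference_mask].mean())
    if reference <= 0:
        raise ValueError("reference amplitude must be positive")
    smoothed = np.empty_like(amplitudes)
    for i in range(amplitudes.size):
        smoothed[i] = amplitudes[max(0, i - window_stimuli + 1) : i + 1].mean()
    return ERASeries(times_s=times_s, values=smoothed / reference, reference_uv=reference)


def _stimulus_amplitudes(
    rec: Recording, blocks: list[Block], reference_concentration: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-stimulus max amplitudes for stimuli inside analysis blocks.

    Stimuli in the discarded head of each segment are excluded, so they also
    do not contribute to the 1.0 % reference.
    """
    trials, _ = extract_trials(rec.channel_contra, rec.stim_onsets, rec.sample_rate)
    times, amps, in_ref = [], [], []
    spans = [(b.start_s, b.end_s, b.concentration) for b in blocks]
    for trial in trials:
        for start, end, conc in spans:
            if start <= trial.onset_s < end:
                times.append(trial.onset_s)
                amps.append(trial_max_amplitude(trial))
                in_ref.append(np.isclose(conc, reference_concentration))
                break
    return np.array(times), np.array(amps), np.array(in_ref, dtype=bool)


def attach_era(
    feature_table: pd.DataFrame,
    rec: Recording,
    blocks: list[Block],
    window_stimuli: int = 10,
    reference_concentration: float = 1.0,
    window_s: float = 10.0,
) -> pd.DataFrame:
    """Append an ``era`` column: the latest available ERA value at or before
    the end of each feature window (NaN before the first stimulus)."""
    times, amps, ref_mask = _stimulus_amplitudes(rec, blocks, reference_concentration)
    series = era_series(amps, times, ref_mask, window_stimuli)
    table = feature_table[feature_table["animal_id"] == rec.animal_id].copy()
    win_end = table["t_start_s"].to_numpy() + window_s
    idx = np.searchsorted(series.times_s, win_end, side="right") - 1
    era = np.where(idx >= 0, series.values[np.clip(idx, 0, None)], np.nan)
    table["era"] = era
    return table
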