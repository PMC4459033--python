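"""Theta-gamma cross-frequency coupling and between-channel synchrony.

The coupling statistic is the composite-signal modulation index: the
modulus of the time-mean of ``amplitude * exp(i * phase)``, where phase
comes from the slow band (default 7-8 Hz) and amplitude from the fast
band (default 40-50 Hz).  Raw values carry the amplitude's microvolt
scale, so comparisons use a surrogate z-score: the amplitude series is
circularly time-shifted by random offsets, which preserves both marginals
while destroying the phase-amplitude relationship.

Between-channel synchrony is the phase-locking value: the across-epoch
modulus of the mean phase-difference vector per time-frequency point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CFCResult:
    """Modulation index for one participant/channel/condition."""

    participant_id: str
    channel: str
    condition: str
    phase_band: tuple[float, float]
    amp_band: tuple[float, float]
    mi_raw: float            # microvolts
    mi_z: float              # surrogate-normalised, unitless
    n_surrogates: int
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.mi_raw < 0:
            raise ValueError("mi_raw must be >= 0")
        if self.n_surrogates < 100:
            raise ValueError("need at least 100 surrogates")


@dataclass
class SynchronyMap:
    """Phase-locking value map between two channels."""

    channel_pair: tuple[str, str]
    condition: str
    freqs: np.ndarray
    times: np.ndarray
    plv: np.ndarray          # (F, T) in [0, 1]
    n_epochs: int

    def __post_init__(self) -> None:
        if np.any(self.plv < 0) or np.any(self.plv > 1 + 1e-6):
            raise ValueError("plv must lie in [0, 1]")


def modulation_index(phase_series: np.ndarray, amp_series: np.ndarray) -> float:
    """|mean over samples of amp * e^{i phase}|."""
    phase = np.asarray(phase_series, dtype=float)
    amp = np.asarray(amp_series, dtype=float)
    if phase.shape != amp.shape:
        raise ValueError(f"shape mismatch: {phase.shape} vs {amp.shape}")
    if phase.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.mean(amp * np.exp(1j * phase))))


def _shift_composite_means(phase: np.ndarray, amp: np.ndarray) -> np.ndarray:
    """Composite mean amp((t+s) mod n) * e^{i phase(t)} at every circular
    shift s, along the last axis, via one FFT cross-correlation."""
    n = phase.shape[-1]
    z = np.exp(1j * phase)
    cross = np.fft.ifft(np.fft.fft(amp, axis=-1)
                        * np.conj(np.fft.fft(np.conj(z), axis=-1)), axis=-1)
    return cross / n


def surrogate_mi_zscore(phase_series: np.ndarray, amp_series: np.ndarray,
                        n_surrogates: int = 200, min_shift: float = 0.5,
                        sfreq: float = 500.0, seed=None) -> float:
    """Surrogate-normalised modulation index.

    The amplitude is circularly time-shifted by ``n_surrogates`` random
    offsets of at least ``min_shift`` seconds (in either direction); the
    z-score is (observed - surrogate mean) / surrogate SD.  Deterministic
    given ``seed``.

    A 1-D input is treated as a single continuous series and shifted
    whole.  A 2-D (trials x time) input is shifted independently within
    each trial, which keeps surrogates free of the stimulus-locked
    repetition structure a trial-concatenated series carries when phases
    are aligned across trials; the observed index is then computed over
    all trials' samples pooled.
    """
    phase = np.asarray(phase_series, dtype=float)
    amp = np.asarray(amp_series, dtype=float)
    if phase.shape != amp.shape:
        raise ValueError(f"shape mismatch: {phase.shape} vs {amp.shape}")
    if phase.ndim not in (1, 2):
        raise ValueError("phase/amp must be 1-D or 2-D (trials x time)")
    n = phase.shape[-1]
    k_min = int(round(min_shift * sfreq))
    if not 0 < k_min < n - k_min:
        raise ValueError("min_shift must be below half the series duration")
    rng = np.random.default_rng(seed)
    observed = modulation_index(phase.ravel(), amp.ravel())
    comp = _shift_composite_means(phase, amp)
    if phase.ndim == 1:
        shifts = rng.integers(k_min, n - k_min, size=n_surrogates)
        sur = np.abs(comp[shifts])
    else:
        k_trials = phase.shape[0]
        shifts = rng.integers(k_min, n - k_min, size=(n_surrogates, k_trials))
        sur = np.abs(comp[np.arange(k_trials)[None, :], shifts].mean(axis=1))
    sd = float(sur.std(ddof=1))
    if sd <= 1e-12 * max(1.0, abs(observed), float(sur.mean())):
        raise ValueError("degenerate surrogate distribution (zero spread)")
    return float((observed - sur.mean()) / sd)


def phase_locking_value(phases_a: np.ndarray, phases_b: np.ndarray) -> np.ndarray:
    """PLV per time-frequency point: |mean over epochs of e^{i(a-b)}|.

    Inputs are (K, F, T) phase arrays from the two channels' decompositions
    of the same epochs.
    """
    a = np.asarray(phases_a, dtype=float)
    b = np.asarray(phases_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 epochs")
    plv = np.abs(np.exp(1j * (a - b)).mean(axis=0))
    return np.minimum(plv, 1.0)
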