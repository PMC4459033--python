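"""Event-related potentials and their relation to phase alignment.

ERPs follow the conventional recipe: each trial is band-pass filtered
(default 1-8 Hz, zero-phase), its prestimulus baseline mean (default the
200 ms before stimulus onset) is subtracted, and trials are averaged.

The filter is a symmetric (linear-phase) Hamming-window FIR applied with
centred convolution, which is exactly zero-phase; trials are reflect-padded
so the epoch edges stay usable.  The design targets a 1 Hz transition
width, giving ~53 dB stop-band attenuation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import firwin, fftconvolve

from .alignment import PAIMap
from .io import EpochSet


@dataclass
class ERPWave:
    """Trial-averaged, baseline-corrected evoked waveform."""

    participant_id: str
    channel: str
    condition: str
    times: np.ndarray
    values: np.ndarray          # microvolts
    filter_band: tuple[float, float] = (1.0, 8.0)
    baseline_window: tuple[float, float] = (-0.2, 0.0)

    def __post_init__(self) -> None:
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must align")


@lru_cache(maxsize=8)
def _bandpass_fir(sfreq: float, lo: float, hi: float) -> np.ndarray:
    trans = min(lo, 1.0)             # Hz, narrowest transition (low edge)
    numtaps = int(np.ceil(3.3 * sfreq / trans))
    numtaps += 1 - numtaps % 2       # odd -> exactly symmetric
    return firwin(numtaps, [lo, hi], pass_zero=False, fs=sfreq)


def bandpass_zero_phase(data: np.ndarray, sfreq: float,
                        band: tuple[float, float]) -> np.ndarray:
    """Zero-phase FIR band-pass along the last axis, reflect-padded."""
    h = _bandpass_fir(float(sfreq), float(band[0]), float(band[1]))
    pad = len(h) // 2
    data = np.atleast_2d(np.asarray(data, dtype=float))
    padded = np.concatenate(
        [data[..., 1:pad + 1][..., ::-1], data, data[..., -pad - 1:-1][..., ::-1]],
        axis=-1)
    out = fftconvolve(padded, h[None, :], mode="same", axes=-1)
    return out[..., pad:pad + data.shape[-1]]


def compute_erp(epochs: EpochSet, channel: str, condition: str,
                filter_band: tuple[float, float] = (1.0, 8.0),
                baseline_window: tuple[float, float] = (-0.2, 0.0)) -> ERPWave:
    """Filter each trial, subtract its baseline mean, average over trials."""
    mask = epochs.condition_mask(condition)
    if not mask.any():
        raise ValueError(f"no epochs in condition {condition}")
    b_lo, b_hi = baseline_window
    bmask = (epochs.times >= b_lo) & (epochs.times <= b_hi)
    if not bmask.any():
        raise ValueError("baseline window lies outside the epoch")
    ci = epochs.channel_index(channel)
    trials = epochs.data[mask, ci, :]
    filtered = bandpass_zero_phase(trials, epochs.sampling_rate, filter_band)
    baselined = filtered - filtered[:, bmask].mean(axis=1, keepdims=True)
    return ERPWave(
        participant_id=epochs.participant_id, channel=channel,
        condition=condition, times=epochs.times,
        values=baselined.mean(axis=0),
        filter_band=filter_band, baseline_window=baseline_window,
    )


def erp_peak(erp: ERPWave, window: tuple[float, float]) -> tuple[float, float]:
    """Signed amplitude and latency of the largest |deflection| in a window.

    Ties are broken in favour of the earliest latency.
    """
    lo, hi = window
    mask = (erp.times >= lo) & (erp.times <= hi)
    if not mask.any():
        raise ValueError("window selects no samples")
    vals = erp.values[mask]
    ts = erp.times[mask]
    k = int(np.argmax(np.abs(vals)))   # argmax returns the first maximum
    return float(vals[k]), float(ts[k])


def erp_alignment_correlation(erps, pai_maps, window: tuple[float, float] = (0.0, 0.5),
                              band: tuple[float, float] = (4.0, 20.0)):
    """Pearson correlation of |ERP| with band-mean PAI over window times.

    ``erps`` and ``pai_maps`` are matched sequences (or single objects)
    for the participants of one condition; pairs (|ERP(t)|, PAI(t)) at the
    PAI map's grid times inside the window are pooled across participants.
    """
    from .stats import pearson_r

    if isinstance(erps, ERPWave):
        erps = [erps]
    if isinstance(pai_maps, PAIMap):
        pai_maps = [pai_maps]
    if len(erps) != len(pai_maps):
        raise ValueError("need one PAI map per ERP")
    xs, ys = [], []
    for erp, pm in zip(erps, pai_maps):
        lo, hi = window
        tmask = (pm.times >= lo) & (pm.times <= hi)
        fmask = (pm.freqs >= band[0]) & (pm.freqs <= band[1])
        if not tmask.any() or not fmask.any():
            raise ValueError("window/band outside the PAI map axes")
        pai_t = pm.pai[fmask][:, tmask].mean(axis=0)
        # PAI times are a subset of the epoch grid; index the ERP there
        pos = np.searchsorted(erp.times, pm.times[tmask])
        pos = np.clip(pos, 0, erp.times.size - 1)
        if not np.allclose(erp.times[pos], pm.times[tmask], atol=1e-9):
            raise ValueError("PAI map times are not aligned with the ERP grid")
        xs.append(np.abs(erp.values[pos]))
        ys.append(pai_t)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size < 3:
        raise ValueError("fewer than 3 paired points")
    return pearson_r(x, y, label=f"|ERP| vs PAI {band[0]:g}-{band[1]:g} Hz, "
                                 f"{window[0]:g}-{window[1]:g} s")
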