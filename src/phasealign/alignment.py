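"""Phase alignment index (phase-locking factor) over time-frequency maps.

At each time-frequency point the phase alignment index across K epochs is

    PAI = | sum_k exp(i phi_k) | / K

which is 0 for phases spread uniformly around the circle and 1 when all
epochs share the same phase.  Trial counts are balanced between conditions
by seeded random subsampling before the index is computed, so that the two
conditions' indices share a common positive bias floor (~1/sqrt(K)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CONDITIONS, EpochSet
from .tfr import TFAtlas


@dataclass
class PAIMap:
    """Phase alignment index map for one participant/channel/condition."""

    participant_id: str
    channel: str
    condition: str
    freqs: np.ndarray
    times: np.ndarray
    pai: np.ndarray        # (F, T), values in [0, 1]
    n_epochs: int

    def __post_init__(self) -> None:
        if self.pai.shape != (self.freqs.size, self.times.size):
            raise ValueError("pai shape does not match axes")
        if np.any(self.pai < 0) or np.any(self.pai > 1 + 1e-6):
            raise ValueError("pai values must lie in [0, 1]")


def phase_alignment_index(phases: np.ndarray) -> np.ndarray:
    """PAI over the first (epoch) axis of a (K, ...) phase array."""
    phases = np.asarray(phases)
    if phases.ndim < 1 or phases.shape[0] < 2:
        raise ValueError("need at least 2 epochs to compute a phase alignment index")
    res = np.abs(np.exp(1j * phases.astype(np.float64)).mean(axis=0))
    return np.minimum(res, 1.0)


def balance_trials(epochs: EpochSet, seed=None) -> EpochSet:
    """Equalise SE/UE trial counts by random subsampling of the larger set.

    The subsample is drawn without replacement; the surviving epochs keep
    their original order.  Already-balanced sets are returned unchanged.
    """
    masks = {c: epochs.condition_mask(c) for c in CONDITIONS}
    counts = {c: int(m.sum()) for c, m in masks.items()}
    for c, k in counts.items():
        if k == 0:
            raise ValueError(f"cannot balance: no epochs in condition {c}")
    if counts["SE"] == counts["UE"]:
        return epochs
    small = min(counts.values())
    rng = np.random.default_rng(seed)
    keep = np.zeros(epochs.n_epochs, dtype=bool)
    for c, m in masks.items():
        idx = np.flatnonzero(m)
        if idx.size > small:
            idx = np.sort(rng.choice(idx, size=small, replace=False))
        keep[idx] = True
    return epochs.select_epochs(np.flatnonzero(keep))


def pai_map_from_tf(tf: TFAtlas, participant_id: str, channel: str,
                    condition: str, epoch_mask: np.ndarray) -> PAIMap:
    """PAIMap for the epochs selected by ``epoch_mask`` of a TFAtlas."""
    phases = tf.phase[epoch_mask]
    return PAIMap(
        participant_id=participant_id, channel=channel, condition=condition,
        freqs=tf.freqs, times=tf.times,
        pai=phase_alignment_index(phases),
        n_epochs=int(np.sum(epoch_mask)),
    )


def window_mean_pai(pai_map: PAIMap, time_window: tuple[float, float],
                    freq_band: tuple[float, float]) -> float:
    """Mean PAI over grid points in a closed time window x frequency band."""
    t_lo, t_hi = time_window
    f_lo, f_hi = freq_band
    tm = (pai_map.times >= t_lo) & (pai_map.times <= t_hi)
    fm = (pai_map.freqs >= f_lo) & (pai_map.freqs <= f_hi)
    if not tm.any() or not fm.any():
        raise ValueError("window/band selects no grid points")
    return float(pai_map.pai[np.ix_(fm, tm)].mean())
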