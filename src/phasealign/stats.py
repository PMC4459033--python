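"""Group statistics: cluster-size permutation tests and the correlation
battery (Pearson, Benjamini-Hochberg FDR, Fisher z comparison).

The condition contrast on phase-alignment maps uses paired two-sided
t-tests across participants at every time-frequency point, followed by a
cluster-size permutation test: connected components (4-adjacency, positive
and negative t clustered separately) of points with p below the cluster-
forming threshold are measured by their point count, and compared against
the permutation null distribution of the largest such cluster obtained by
randomly swapping each participant's condition labels (equivalently,
sign-flipping the paired differences).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("phasealign")

#: 4-connectivity structure for time-frequency grids (no diagonals)
_ADJACENCY = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class Cluster:
    """One suprathreshold cluster of adjacent time-frequency points."""

    points: np.ndarray          # (size, 2) array of (freq_idx, time_idx)
    size: int                   # number of member points
    sign: int                   # +1 for positive t, -1 for negative
    p_value: float = np.nan


@dataclass
class ClusterTestResult:
    t_map: np.ndarray
    p_map: np.ndarray
    clusters: list
    null_max_sizes: np.ndarray  # (n_permutations,)
    alpha: float
    n_permutations: int

    @property
    def cluster_p(self) -> np.ndarray:
        return np.array([c.p_value for c in self.clusters])


@dataclass
class CorrelationResult:
    r: float
    n: int
    t_stat: float
    p: float
    label: str = ""
    p_fdr: float | None = None


@dataclass
class FisherComparison:
    z: float
    p: float
    r1: float
    n1: int
    r2: float
    n2: int


def pointwise_t_map(pai_se: np.ndarray, pai_ue: np.ndarray):
    """Paired two-sided t-test across participants at every map point.

    Inputs are (participants, freqs, times) stacks.  Points with zero
    variance of the paired differences get t = 0, p = 1 with a warning.
    """
    a = np.asarray(pai_se, dtype=float)
    b = np.asarray(pai_ue, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 participants for a paired t-test")
    d = a - b
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("%d time-frequency points have zero paired-difference "
                       "variance; setting p = 1 there", int(degenerate.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(degenerate, 0.0, t)
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    p = np.where(degenerate, 1.0, p)
    return t, p


def _label_clusters(mask: np.ndarray, sign: int) -> list[Cluster]:
    labels, n = ndimage.label(mask, structure=_ADJACENCY)
    out = []
    for k in range(1, n + 1):
        pts = np.argwhere(labels == k)
        out.append(Cluster(points=pts, size=pts.shape[0], sign=sign))
    return out


def _max_cluster_size(sig_pos: np.ndarray, sig_neg: np.ndarray) -> int:
    best = 0
    for mask in (sig_pos, sig_neg):
        if mask.any():
            labels, n = ndimage.label(mask, structure=_ADJACENCY)
            if n:
                best = max(best, int(np.bincount(labels.ravel())[1:].max()))
    return best


def cluster_size_permutation(pai_se: np.ndarray, pai_ue: np.ndarray,
                             n_permutations: int = 1000, alpha: float = 0.05,
                             seed=None) -> ClusterTestResult:
    """Cluster-size permutation test of the SE-vs-UE map contrast.

    The null swaps condition labels within participant (a sign flip of the
    paired differences); each permutation records its largest cluster size
    over both signs.  Cluster p-values use the add-one estimator
    ``(1 + #{null >= observed}) / (1 + n_permutations)``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_permutations < 100:
        logger.warning("n_permutations = %d is very low; p-value resolution "
                       "will be poor", n_permutations)
    t, p = pointwise_t_map(pai_se, pai_ue)
    clusters = (_label_clusters((p < alpha) & (t > 0), +1)
                + _label_clusters((p < alpha) & (t < 0), -1))

    d = (np.asarray(pai_se, float) - np.asarray(pai_ue, float))
    n_part = d.shape[0]
    flat = d.reshape(n_part, -1)
    ssq = np.sum(flat**2, axis=0)
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df=n_part - 1)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n_part))
    null_sizes = np.empty(n_permutations, dtype=int)
    shape = d.shape[1:]
    for i in range(n_permutations):
        m = signs[i] @ flat / n_part
        var = (ssq - n_part * m**2) / (n_part - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tn = m / np.sqrt(var / n_part)
        tn = np.nan_to_num(tn, nan=0.0, posinf=0.0, neginf=0.0)
        tn = tn.reshape(shape)
        null_sizes[i] = _max_cluster_size(tn > t_crit, tn < -t_crit)

    for c in clusters:
        c.p_value = (1.0 + np.sum(null_sizes >= c.size)) / (1.0 + n_permutations)
    return ClusterTestResult(t_map=t, p_map=p, clusters=clusters,
                             null_max_sizes=null_sizes, alpha=alpha,
                             n_permutations=n_permutations)


def pearson_p_from_r(r: float, n: int) -> tuple[float, float]:
    """(t statistic, two-sided p) for a Pearson r at sample size n."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return float(np.sign(r) * np.inf), 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(t), float(2.0 * sps.t.sf(abs(t), df=n - 2))


def pearson_r(x, y, label: str = "") -> CorrelationResult:
    """Sample Pearson correlation with its Student-t two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    t, p = pearson_p_from_r(r, n)
    return CorrelationResult(r=r, n=n, t_stat=t, p=p, label=label)


def bh_fdr(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values, rejection flags at level q).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> FisherComparison:
    """Compare two independent correlations via the Fisher z-transform.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), referred to the
    unit normal (two-sided).
    """
    if abs(r1) >= 1.0 or abs(r2) >= 1.0:
        raise ValueError("|r| = 1 has an infinite Fisher transform")
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 in both samples")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = float(2.0 * sps.norm.sf(abs(z)))
    return FisherComparison(z=float(z), p=p, r1=float(r1), n1=int(n1),
                            r2=float(r2), n2=int(n2))
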