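"""Calibration and power studies on synthetic cohorts.

These functions repeat the core pipeline over many independently seeded
cohorts to measure operating characteristics: the false-positive rate of
the cluster-size permutation test under a null generator, its detection
rate under a strong injected theta reset difference, the monotonicity of
the surrogate-normalised coupling score in the injected coupling depth,
and the recovery of a known across-participant correlation between reset
strength and coupling gain.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from .pipeline import RunConfig, cfc_scores, pai_cfc_correlation, \
    ratn_cluster_test
from .synth import SynthConfig, generate_cohort

#: reduced time-frequency map for permutation-scale studies (~20 freqs)
STUDY_FREQS = np.arange(2.0, 22.0)
STUDY_DECIM = 5


def _child_seeds(seed, n):
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def null_cluster_rate(n_cohorts: int = 200, kappa: float = 0.8,
                      n_permutations: int = 1000, alpha: float = 0.05,
                      seed: int = 0) -> float:
    """Fraction of null cohorts (kappa_SE = kappa_UE) in which the RATN
    SE-vs-UE contrast yields any significant cluster.

    A calibrated test keeps this near ``alpha``.
    """
    seeds = _child_seeds(seed, 2 * n_cohorts)
    hits = 0
    for i in range(n_cohorts):
        cfg = SynthConfig(kappa_SE=kappa, kappa_UE=kappa, kappa_cv=0.0,
                          seed=seeds[2 * i])
        res, _, _ = ratn_cluster_test(cfg, freqs=STUDY_FREQS,
                                      decim=STUDY_DECIM,
                                      n_permutations=n_permutations,
                                      alpha=alpha, perm_seed=seeds[2 * i + 1])
        if any(c.p_value < alpha for c in res.clusters):
            hits += 1
    return hits / n_cohorts


def detection_rate(n_cohorts: int = 20, kappa_se: float = 1.5,
                   kappa_ue: float = 0.0, window=(0.9, 1.1), band=(4.0, 8.0),
                   n_permutations: int = 1000, alpha: float = 0.05,
                   seed: int = 0) -> float:
    """Fraction of effect cohorts in which a significant cluster overlaps
    the expected late theta region (``window`` x ``band``)."""
    seeds = _child_seeds(seed, 2 * n_cohorts)
    hits = 0
    for i in range(n_cohorts):
        cfg = SynthConfig(kappa_SE=kappa_se, kappa_UE=kappa_ue, kappa_cv=0.0,
                          seed=seeds[2 * i])
        res, freqs, times = ratn_cluster_test(
            cfg, freqs=STUDY_FREQS, decim=STUDY_DECIM,
            n_permutations=n_permutations, alpha=alpha,
            perm_seed=seeds[2 * i + 1])
        for c in res.clusters:
            if c.p_value >= alpha:
                continue
            f = freqs[c.points[:, 0]]
            t = times[c.points[:, 1]]
            in_region = ((f >= band[0]) & (f <= band[1])
                         & (t >= window[0]) & (t <= window[1]))
            if in_region.any():
                hits += 1
                break
    return hits / n_cohorts


def coupling_depth_monotonicity(n_levels: int = 10, n_reps: int = 20,
                                seed: int = 0):
    """Monotonicity of the measured mi_z in the injected coupling depth,
    on single-participant generator output.

    Each of ``n_levels`` depths is replicated ``n_reps`` times; the
    returned Spearman coefficient correlates depth with the per-level
    mean z-score (replication averages out single-run estimation noise,
    so the statistic reflects the response curve, not the noise floor).
    Returns ``(rho, levels, mean_z_per_level)``.
    """
    levels = np.linspace(0.05, 0.9, n_levels)
    seeds = _child_seeds(seed, n_levels * n_reps)
    mean_z = []
    k = 0
    for gain in levels:
        zs = []
        for _ in range(n_reps):
            cfg = SynthConfig(n_participants=1, pac_gain_mean=float(gain),
                              pac_gain_sd=0.0, seed=seeds[k])
            cohort, _ = generate_cohort(cfg)
            res = cfc_scores(cohort[0], RunConfig(synth=cfg), seeds[k] + 1)
            zs.append(res["SE"].mi_z)
            k += 1
        mean_z.append(np.mean(zs))
    rho, _ = spearmanr(levels, mean_z)
    return float(rho), levels, np.array(mean_z)


def recovery_correlations(rho: float, n_cohorts: int = 100,
                          seed: int = 0) -> np.ndarray:
    """Sample correlations (one per cohort) between measured late-window
    RATN phase alignment and mi_z across participants, for cohorts
    generated with ``participant_effect_rho = rho``."""
    seeds = _child_seeds(seed, 2 * n_cohorts)
    rs = []
    for i in range(n_cohorts):
        cfg = SynthConfig(participant_effect_rho=rho, seed=seeds[2 * i])
        corr, _, _ = pai_cfc_correlation(cfg, surrogate_seed=seeds[2 * i + 1])
        rs.append(corr.r)
    return np.array(rs)
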