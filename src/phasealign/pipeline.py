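"""End-to-end analysis: generate/load -> decompose -> align -> couple ->
contrast -> correlate, as one reproducible run.

A :class:`RunConfig` fixes every band, window, and seed; the run produces
per-participant phase-alignment maps and window summaries, SE-vs-UE
cluster-size permutation tests per channel, theta-gamma coupling scores,
frontal-thalamic synchrony, the correlation battery with BH-FDR and
Fisher z condition comparisons, ERPs and ERP-alignment correlations, and
a machine-readable JSON summary in which every statistic carries its
window, band, sample size, and seed provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alignment import balance_trials, pai_map_from_tf, window_mean_pai
from .coupling import CFCResult, SynchronyMap, modulation_index, \
    phase_locking_value, surrogate_mi_zscore
from .erp import compute_erp, erp_alignment_correlation, erp_peak
from .io import CONDITIONS, EpochSet, read_epoch_container, write_epoch_container
from .stats import bh_fdr, cluster_size_permutation, fisher_z_compare, pearson_r
from .synth import PAC_CHANNEL, SynthConfig, generate_cohort, write_truth_table
from .tfr import band_complex_mean, morlet_decompose

logger = logging.getLogger("phasealign")

FRONTAL = "frontal"
RATN = PAC_CHANNEL  # "R-ATN"


@dataclass
class RunConfig:
    """Everything one analysis run depends on."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    container_path: str | None = None      # read epochs here instead of generating

    # time-frequency decomposition
    freq_range: tuple[float, float, float] = (2.0, 100.0, 1.0)  # lo, hi, step
    n_cycles: float = 5.0
    decim: int = 5

    # analysis bands (Hz) and windows (s)
    theta_band: tuple[float, float] = (4.0, 8.0)
    theta_alpha_band: tuple[float, float] = (7.0, 12.0)
    broadband: tuple[float, float] = (4.0, 20.0)
    cfc_phase_band: tuple[float, float] = (7.0, 8.0)
    cfc_amp_band: tuple[float, float] = (40.0, 50.0)
    cfc_window: tuple[float, float] = (0.5, 1.5)
    early_window: tuple[float, float] = (0.0, 0.5)
    late_window: tuple[float, float] = (0.9, 1.1)

    # statistics
    n_permutations: int = 1000
    alpha: float = 0.05
    fdr_q: float = 0.05
    n_surrogates: int = 200
    min_shift: float = 0.1   # s, within-trial circular-shift minimum

    # named stage seeds (generation comes from synth.seed)
    seed_balancing: int = 101
    seed_permutation: int = 202
    seed_surrogates: int = 303

    # which channels get the full PAI/cluster treatment
    cluster_channels: tuple[str, ...] | None = None   # None -> all

    output_dir: str | None = None

    @property
    def freqs(self) -> np.ndarray:
        lo, hi, step = self.freq_range
        return np.arange(lo, hi + step / 2, step)

    def validate(self) -> None:
        nyq = self.synth.sampling_rate / 2.0
        if self.freqs[-1] >= nyq:
            raise ValueError("analysis frequencies must stay below Nyquist")
        start, end = self.synth.epoch_window
        for name in ("early_window", "late_window", "cfc_window"):
            lo, hi = getattr(self, name)
            if not (start <= lo < hi <= end):
                raise ValueError(f"{name} must lie inside the epoch window")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        synth = d.pop("synth", {})
        if isinstance(synth, dict):
            synth = {k: tuple(v) if isinstance(v, list) else v
                     for k, v in synth.items()}
            synth = SynthConfig(**synth)
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(synth=synth, **d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))

    def to_file(self, path) -> None:
        obj = json.loads(json.dumps(self.to_dict()))
        Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


# ---------------------------------------------------------------------------
# stage helpers

def _load_cohort(config: RunConfig):
    if config.container_path is not None:
        cohort = read_epoch_container(config.container_path)
        params = None
        logger.info("read %d participants from %s", len(cohort),
                    config.container_path)
    else:
        cohort, params = generate_cohort(config.synth)
        logger.info("generated %d synthetic participants (seed %d)",
                    len(cohort), config.synth.seed)
    roles_needed = {FRONTAL, RATN}
    for es in cohort:
        missing = roles_needed - set(es.channels)
        if missing:
            raise ValueError(f"participant {es.participant_id} lacks channels "
                             f"{sorted(missing)}")
        for c in CONDITIONS:
            if not es.condition_mask(c).any():
                raise ValueError(f"participant {es.participant_id} has no "
                                 f"{c} epochs")
    return cohort, params


def participant_pai_maps(es: EpochSet, channel: str, freqs, n_cycles: float,
                         decim: int):
    """Balanced SE/UE PAI maps for one participant's channel."""
    tf = morlet_decompose(es, freqs, n_cycles, channel=channel, decim=decim)
    maps = {}
    for cond in CONDITIONS:
        mask = es.condition_mask(cond)
        maps[cond] = pai_map_from_tf(tf, es.participant_id, channel, cond, mask)
    return maps, tf


def cfc_scores(es: EpochSet, config: RunConfig, seed) -> dict:
    """Theta-gamma modulation index (raw and surrogate z) per condition.

    Band series are concatenated across the condition's epochs inside the
    analysis window before the index is computed.
    """
    phase_grid = np.arange(config.cfc_phase_band[0],
                           config.cfc_phase_band[1] + 0.5, 1.0)
    amp_grid = np.arange(config.cfc_amp_band[0],
                         config.cfc_amp_band[1] + 0.5, 2.0)
    tf_p = morlet_decompose(es, phase_grid, config.n_cycles, channel=RATN)
    tf_a = morlet_decompose(es, amp_grid, config.n_cycles, channel=RATN)
    tmask_p = tf_p.time_mask(config.cfc_window)
    tmask_a = tf_a.time_mask(config.cfc_window)
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = ss.spawn(len(CONDITIONS))
    out = {}
    for cond, child in zip(CONDITIONS, children):
        emask = es.condition_mask(cond)
        zp = band_complex_mean(tf_p, config.cfc_phase_band)[emask][:, tmask_p]
        za = band_complex_mean(tf_a, config.cfc_amp_band)[emask][:, tmask_a]
        # amp-band times are a superset of the phase-band times (shorter
        # wavelets trim less); align on the phase-band grid
        ta = tf_a.times[tmask_a]
        tp = tf_p.times[tmask_p]
        pos = np.searchsorted(ta, tp)
        za = za[:, pos]
        phase = np.angle(zp)      # (trials, time): per-trial surrogate shifts
        amp = np.abs(za)
        mi = modulation_index(phase.ravel(), amp.ravel())
        z = surrogate_mi_zscore(phase, amp, config.n_surrogates,
                                config.min_shift, es.sampling_rate, child)
        out[cond] = CFCResult(
            participant_id=es.participant_id, channel=RATN, condition=cond,
            phase_band=config.cfc_phase_band, amp_band=config.cfc_amp_band,
            mi_raw=mi, mi_z=z, n_surrogates=config.n_surrogates,
            window=config.cfc_window)
    return out


def synchrony_scores(es: EpochSet, config: RunConfig) -> dict:
    """Frontal-RATN phase-locking value summaries per condition."""
    grid = np.arange(min(config.theta_band[0], config.theta_alpha_band[0]),
                     max(config.theta_band[1], config.theta_alpha_band[1]) + 0.5,
                     1.0)
    tf_f = morlet_decompose(es, grid, config.n_cycles, channel=FRONTAL,
                            decim=config.decim)
    tf_r = morlet_decompose(es, grid, config.n_cycles, channel=RATN,
                            decim=config.decim)
    out = {}
    for cond in CONDITIONS:
        emask = es.condition_mask(cond)
        plv = phase_locking_value(tf_f.phase[emask], tf_r.phase[emask])
        smap = SynchronyMap(channel_pair=(FRONTAL, RATN), condition=cond,
                            freqs=tf_f.freqs, times=tf_f.times, plv=plv,
                            n_epochs=int(emask.sum()))
        fm_late = (grid >= config.theta_band[0]) & (grid <= config.theta_band[1])
        fm_early = (grid >= config.theta_alpha_band[0]) & (grid <= config.theta_alpha_band[1])
        tm_late = tf_f.time_mask(config.late_window)
        tm_early = tf_f.time_mask(config.early_window)
        out[cond] = {
            "map": smap,
            "late_theta": float(plv[np.ix_(fm_late, tm_late)].mean()),
            "early_theta_alpha": float(plv[np.ix_(fm_early, tm_early)].mean()),
        }
    return out


# ---------------------------------------------------------------------------

def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole pipeline; returns the report dict (also written to
    ``config.output_dir`` as TSV tables + JSON summary when set)."""
    config.validate()
    t_start = time.time()
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(outdir / "run.log", mode="w")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(fh)
    try:
        return _run(config, outdir, t_start)
    finally:
        if outdir:
            logger.removeHandler(fh)
            fh.close()


def _run(config: RunConfig, outdir, t_start) -> dict:
    cohort, truth = _load_cohort(config)
    bal_ss = np.random.SeedSequence(entropy=config.seed_balancing)
    cohort = [balance_trials(es, child)
              for es, child in zip(cohort, bal_ss.spawn(len(cohort)))]
    pids = [es.participant_id for es in cohort]
    n_part = len(cohort)
    freqs = config.freqs

    channels = config.cluster_channels or cohort[0].channels
    logger.info("PAI maps on %d freqs for channels %s", freqs.size, channels)

    # --- PAI maps + cluster tests per channel -----------------------------
    perm_ss = np.random.SeedSequence(entropy=config.seed_permutation)
    perm_children = perm_ss.spawn(len(channels))
    window_defs = {
        "early_frontal_theta_alpha": (FRONTAL, config.early_window, config.theta_alpha_band),
        "early_ratn_broadband": (RATN, config.early_window, config.broadband),
        "late_frontal_theta": (FRONTAL, config.late_window, config.theta_band),
        "late_ratn_theta": (RATN, config.late_window, config.theta_band),
    }
    window_pai = {k: {c: np.zeros(n_part) for c in CONDITIONS}
                  for k in window_defs}
    cluster_reports = {}
    pai_maps_store = {}   # (channel) -> per-condition stacks for TSV/ERP use
    for ch, pseed in zip(channels, perm_children):
        stacks = {c: [] for c in CONDITIONS}
        per_part_maps = {c: [] for c in CONDITIONS}
        for es in cohort:
            maps, _ = participant_pai_maps(es, ch, freqs, config.n_cycles,
                                           config.decim)
            for c in CONDITIONS:
                stacks[c].append(maps[c].pai)
                per_part_maps[c].append(maps[c])
        pai_maps_store[ch] = per_part_maps
        for key, (role, window, band) in window_defs.items():
            if role != ch:
                continue
            for c in CONDITIONS:
                window_pai[key][c] = np.array(
                    [window_mean_pai(m, window, band) for m in per_part_maps[c]])
        res = cluster_size_permutation(
            np.stack(stacks["SE"]), np.stack(stacks["UE"]),
            n_permutations=config.n_permutations, alpha=config.alpha,
            seed=pseed)
        any_map = per_part_maps["SE"][0]
        sig = [c for c in res.clusters if c.p_value < config.alpha]
        logger.info("channel %s: %d clusters, %d significant", ch,
                    len(res.clusters), len(sig))
        cluster_reports[ch] = _cluster_report(res, any_map.freqs, any_map.times,
                                              config)

    # --- CFC and synchrony -------------------------------------------------
    sur_ss = np.random.SeedSequence(entropy=config.seed_surrogates)
    cfc = [cfc_scores(es, config, child)
           for es, child in zip(cohort, sur_ss.spawn(n_part))]
    mi_z = {c: np.array([r[c].mi_z for r in cfc]) for c in CONDITIONS}
    sync = [synchrony_scores(es, config) for es in cohort]
    plv_late = {c: np.array([s[c]["late_theta"] for s in sync]) for c in CONDITIONS}
    plv_early = {c: np.array([s[c]["early_theta_alpha"] for s in sync])
                 for c in CONDITIONS}

    # --- correlation battery ----------------------------------------------
    battery = []
    for key in window_defs:
        for c in CONDITIONS:
            battery.append(pearson_r(window_pai[key][c], mi_z[c],
                                     label=f"{key}_pai_vs_cfc_{c}"))
    battery.append(pearson_r(window_pai["late_frontal_theta"]["SE"],
                             plv_late["SE"], label="late_frontal_pai_vs_late_plv_SE"))
    battery.append(pearson_r(window_pai["late_ratn_theta"]["SE"],
                             plv_late["SE"], label="late_ratn_pai_vs_late_plv_SE"))
    pooled_front = np.concatenate([window_pai["early_frontal_theta_alpha"][c]
                                   for c in CONDITIONS])
    pooled_ratn = np.concatenate([window_pai["early_ratn_broadband"][c]
                                  for c in CONDITIONS])
    pooled_plv = np.concatenate([plv_early[c] for c in CONDITIONS])
    battery.append(pearson_r(pooled_front, pooled_plv,
                             label="early_frontal_pai_vs_early_plv_pooled"))
    battery.append(pearson_r(pooled_ratn, pooled_plv,
                             label="early_ratn_pai_vs_early_plv_pooled"))
    adjusted, reject = bh_fdr([c.p for c in battery], q=config.fdr_q)
    for c, p_adj in zip(battery, adjusted):
        c.p_fdr = float(p_adj)

    fisher = {}
    if n_part >= 4:
        for key in window_defs:
            r_se = next(c for c in battery if c.label == f"{key}_pai_vs_cfc_SE")
            r_ue = next(c for c in battery if c.label == f"{key}_pai_vs_cfc_UE")
            fisher[key] = fisher_z_compare(r_se.r, r_se.n, r_ue.r, r_ue.n)
    else:
        logger.warning("fewer than 4 participants; skipping Fisher z comparisons")

    # --- ERPs ---------------------------------------------------------------
    erp_rows, erp_corr = [], {}
    erp_store = {}
    for ch in (FRONTAL, RATN):
        for cond in CONDITIONS:
            waves = [compute_erp(es, ch, cond) for es in cohort]
            erp_store[(ch, cond)] = waves
            for w in waves:
                amp, lat = erp_peak(w, config.early_window)
                erp_rows.append({"participant_id": w.participant_id,
                                 "channel": ch, "condition": cond,
                                 "peak_uV": amp, "peak_latency_s": lat})
    for cond in CONDITIONS:
        if RATN in pai_maps_store:
            erp_corr[f"ratn_{cond}"] = erp_alignment_correlation(
                erp_store[(RATN, cond)], pai_maps_store[RATN][cond],
                window=config.early_window, band=config.broadband)
        if FRONTAL in pai_maps_store:
            erp_corr[f"frontal_{cond}"] = erp_alignment_correlation(
                erp_store[(FRONTAL, cond)], pai_maps_store[FRONTAL][cond],
                window=config.early_window, band=config.theta_alpha_band)

    # --- report -------------------------------------------------------------
    report = {
        "participants": pids,
        "n_participants": n_part,
        "seeds": {"generation": config.synth.seed,
                  "balancing": config.seed_balancing,
                  "permutation": config.seed_permutation,
                  "surrogates": config.seed_surrogates},
        "window_pai": {
            key: {c: [float(v) for v in window_pai[key][c]] for c in CONDITIONS}
            for key in window_defs},
        "window_defs": {key: {"channel": v[0], "window_s": list(v[1]),
                              "band_hz": list(v[2]), "n": n_part}
                        for key, v in window_defs.items()},
        "cluster_tests": cluster_reports,
        "cfc": {c: {"mi_z": [float(v) for v in mi_z[c]],
                    "phase_band_hz": list(config.cfc_phase_band),
                    "amp_band_hz": list(config.cfc_amp_band),
                    "window_s": list(config.cfc_window),
                    "n_surrogates": config.n_surrogates} for c in CONDITIONS},
        "plv": {"late_theta": {c: [float(v) for v in plv_late[c]]
                               for c in CONDITIONS},
                "early_theta_alpha": {c: [float(v) for v in plv_early[c]]
                                      for c in CONDITIONS}},
        "correlations": [{
            "label": c.label, "r": c.r, "n": c.n, "t": c.t_stat, "p": c.p,
            "p_fdr": c.p_fdr, "fdr_q": config.fdr_q} for c in battery],
        "fisher_se_vs_ue": {k: {"z": f.z, "p": f.p, "r_SE": f.r1, "r_UE": f.r2,
                                "n": f.n1} for k, f in fisher.items()},
        "erp_peaks": erp_rows,
        "erp_alignment_correlations": {
            k: {"r": v.r, "n": v.n, "p": v.p, "label": v.label}
            for k, v in erp_corr.items()},
    }
    if truth is not None:
        report["ground_truth"] = {
            "kappa_SE_ratn": [float(p.kappa_SE.get(RATN, 0.0)) for p in truth],
            "kappa_UE_ratn": [float(p.kappa_UE.get(RATN, 0.0)) for p in truth],
            "pac_gain": [float(p.pac_gain) for p in truth],
        }

    if outdir:
        _write_outputs(report, erp_store, truth, outdir)
    logger.info("analysis finished in %.1f s", time.time() - t_start)
    return report


def _cluster_report(res, freqs, times, config: RunConfig) -> dict:
    clusters = []
    for c in res.clusters:
        f_idx, t_idx = c.points[:, 0], c.points[:, 1]
        clusters.append({
            "size": int(c.size), "sign": int(c.sign),
            "p": float(c.p_value),
            "freq_range_hz": [float(freqs[f_idx.min()]), float(freqs[f_idx.max()])],
            "time_range_s": [float(times[t_idx.min()]), float(times[t_idx.max()])],
        })
    clusters.sort(key=lambda d: d["p"])
    tm = (times >= config.late_window[0]) & (times <= config.late_window[1])
    fm = (freqs >= config.theta_band[0]) & (freqs <= config.theta_band[1])
    return {
        "n_permutations": res.n_permutations,
        "alpha": res.alpha,
        "clusters": clusters,
        "t_max_late_theta": float(res.t_map[np.ix_(fm, tm)].max())
        if tm.any() and fm.any() else None,
        "min_cluster_p": min((c["p"] for c in clusters), default=None),
    }


def _write_outputs(report: dict, erp_store: dict, truth, outdir: Path) -> None:
    (outdir / "summary.json").write_text(
        json.dumps(report, sort_keys=True, indent=1))
    rows = []
    for key, d in report["window_pai"].items():
        meta = report["window_defs"][key]
        for cond, vals in d.items():
            for pid, v in zip(report["participants"], vals):
                rows.append({"measure": key, "participant_id": pid,
                             "condition": cond, "channel": meta["channel"],
                             "pai": v})
    pd.DataFrame(rows).to_csv(outdir / "window_pai.tsv", sep="\t", index=False)
    pd.DataFrame(report["correlations"]).to_csv(
        outdir / "correlations.tsv", sep="\t", index=False)
    pd.DataFrame(report["erp_peaks"]).to_csv(
        outdir / "erp_peaks.tsv", sep="\t", index=False)
    wave_rows = []
    for (ch, cond), waves in erp_store.items():
        for w in waves:
            for t, v in zip(w.times, w.values):
                wave_rows.append({"participant_id": w.participant_id,
                                  "channel": ch, "condition": cond,
                                  "time_s": float(t), "uV": float(v)})
    pd.DataFrame(wave_rows).to_csv(outdir / "erp_waveforms.tsv", sep="\t",
                                   index=False)
    if truth is not None:
        write_truth_table(truth, outdir / "ground_truth.tsv")


def ratn_cluster_test(synth_cfg: SynthConfig, freqs=None, decim: int = 5,
                      n_permutations: int = 1000, alpha: float = 0.05,
                      perm_seed=None, channel: str = RATN):
    """SE-vs-UE cluster-size permutation test for one channel of one cohort.

    A focused path for calibration studies: generates the cohort, computes
    balanced PAI maps for ``channel`` only on a reduced frequency grid
    (default 2-21 Hz at 1 Hz), and runs the permutation test.  Returns
    ``(ClusterTestResult, freqs, times)``.
    """
    if freqs is None:
        freqs = np.arange(2.0, 22.0)
    cohort, _ = generate_cohort(synth_cfg)
    stacks = {c: [] for c in CONDITIONS}
    times = None
    for es in cohort:
        maps, tf = participant_pai_maps(es, channel, freqs, 5.0, decim)
        times = tf.times
        for c in CONDITIONS:
            stacks[c].append(maps[c].pai)
    res = cluster_size_permutation(np.stack(stacks["SE"]), np.stack(stacks["UE"]),
                                   n_permutations=n_permutations, alpha=alpha,
                                   seed=perm_seed)
    return res, np.asarray(freqs), times


def pai_cfc_correlation(synth_cfg: SynthConfig, condition: str = "SE",
                        late_window=(0.9, 1.1), theta_band=(4.0, 8.0),
                        cfc_phase_band=(7.0, 8.0), cfc_amp_band=(40.0, 50.0),
                        cfc_window=(0.5, 1.5), surrogate_seed=0):
    """Across-participant correlation of late-window RATN phase alignment
    with the surrogate-normalised theta-gamma coupling score.

    Returns ``(CorrelationResult, pai_values, mi_z_values)`` for one
    generated cohort.
    """
    cohort, _ = generate_cohort(synth_cfg)
    cfg = RunConfig(synth=synth_cfg, cfc_phase_band=cfc_phase_band,
                    cfc_amp_band=cfc_amp_band, cfc_window=cfc_window,
                    late_window=late_window, theta_band=theta_band)
    theta_grid = np.arange(theta_band[0], theta_band[1] + 0.5)
    sur_ss = np.random.SeedSequence(entropy=surrogate_seed)
    pai_vals, mi_vals = [], []
    for es, child in zip(cohort, sur_ss.spawn(len(cohort))):
        maps, _ = participant_pai_maps(es, RATN, theta_grid, 5.0, 5)
        pai_vals.append(window_mean_pai(maps[condition], late_window, theta_band))
        mi_vals.append(cfc_scores(es, cfg, child)[condition].mi_z)
    corr = pearson_r(pai_vals, mi_vals, label=f"late_ratn_pai_vs_mi_z_{condition}")
    return corr, np.array(pai_vals), np.array(mi_vals)


def simulate_to_container(config: RunConfig, path, truth_path=None) -> None:
    """Generate a synthetic cohort and write it to an HDF5 container."""
    cohort, params = generate_cohort(config.synth)
    write_epoch_container(cohort, path)
    if truth_path is not None:
        write_truth_table(params, truth_path)
    logger.info("wrote %d participants to %s", len(cohort), path)
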