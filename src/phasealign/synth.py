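"""Synthetic epoched iEEG-like cohorts with known injected effects.

Generates recordings that emulate a subsequent-memory experiment in which
anterior-thalamic and frontal channels show stimulus-locked phase structure:

* a late theta burst (default 7.5 Hz carrier, Gaussian envelope centred
  near 1.0 s poststimulus) whose phase at the envelope centre is drawn from
  a von Mises law -- the concentration ``kappa`` differs between
  successfully (SE) and unsuccessfully (UE) encoded trials, producing a
  condition difference in the phase-locking factor;
* an early broadband (4-20 Hz) burst that is phase-reset in both
  conditions alike, modelling a task-generic evoked reset;
* a gamma component (40-50 Hz band) on the right anterior thalamic channel
  whose amplitude envelope is ``1 + m cos(theta phase)`` -- multiplicative
  theta-gamma phase-amplitude coupling with depth ``m``;
* an ERP-like damped transient, identical in expectation across trials;
* stationary 1/f background noise.

Participant-level effect sizes (reset concentration, coupling gain) are
drawn around the configured means through a shared latent Gaussian factor,
so that their across-participant correlation targets
``participant_effect_rho``.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .io import CONDITIONS, EpochSet

#: channel roles, in recording order
CHANNEL_ROLES = ("frontal", "L-ATN", "R-ATN", "L-DMTN", "R-DMTN")

#: channels that receive the late theta burst
THETA_RESET_CHANNELS = ("frontal", "L-ATN", "R-ATN")

#: channels that receive the early broadband burst
EARLY_RESET_CHANNELS = ("frontal", "L-ATN", "R-ATN")

#: channel carrying theta-gamma coupling
PAC_CHANNEL = "R-ATN"


@dataclass
class SynthConfig:
    """Generative parameters for one synthetic cohort.

    Defaults mirror the study geometry being emulated: 7 participants,
    40 trials per condition, 5 channels at 500 Hz, epochs from -1.0 to
    +2.0 s around stimulus onset.
    """

    n_participants: int = 7
    n_trials_per_condition: int = 40
    channel_roles: tuple[str, ...] = CHANNEL_ROLES
    sampling_rate: float = 500.0
    epoch_window: tuple[float, float] = (-1.0, 2.0)

    # background
    noise_exponent: float = 1.0     # power-spectral 1/f^a slope
    noise_sigma: float = 4.0        # microvolts RMS

    # late theta reset: a sustained poststimulus theta oscillation whose
    # phase is pinned at reset_latency (von Mises draw) and decoheres away
    # from it through per-trial frequency jitter, so inter-trial alignment
    # is localised around reset_latency with width ~reset_width
    theta_band: tuple[float, float] = (4.0, 8.0)
    reset_latency: float = 1.0      # s, where trial phases are pinned
    reset_width: float = 0.3        # s, alignment localisation scale
    theta_onset: float = 0.3        # s, theta plateau start
    theta_offset: float = 1.7       # s, theta plateau end
    theta_amp: float = 6.0          # microvolts, plateau amplitude
    kappa_SE: float = 1.2           # von Mises concentration, successful
    kappa_UE: float = 0.4           # von Mises concentration, unsuccessful
    kappa_cv: float = 0.5           # participant-level spread of reset strength

    # early broadband reset (both conditions alike)
    early_reset_band: tuple[float, float] = (4.0, 20.0)
    early_reset_kappa: float = 2.0
    early_reset_latency: float = 0.2
    early_reset_width: float = 0.08
    early_amp: float = 5.0

    # theta-gamma coupling
    pac_phase_band: tuple[float, float] = (7.0, 8.0)
    pac_amp_band: tuple[float, float] = (40.0, 50.0)
    pac_gain_mean: float = 0.5      # coupling depth m, SE condition
    pac_gain_sd: float = 0.2
    pac_ue_scale: float = 0.3       # UE coupling depth relative to SE
    gamma_amp: float = 3.0          # microvolts, gamma envelope peak

    # correlation between participant reset strength and coupling gain
    participant_effect_rho: float = 0.9

    # evoked transient
    erp_amplitude: float = 4.0      # microvolts
    erp_freq: float = 5.0           # Hz
    erp_decay: float = 0.15         # s, exponential time constant
    erp_latency: float = 0.05       # s, onset

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        start, end = self.epoch_window
        if not (start < 0.0 < end):
            raise ValueError("epoch_window must straddle the stimulus at 0")
        if end - start < 1.5:
            raise ValueError("epoch_window must span at least 1.5 s")
        for name in ("kappa_SE", "kappa_UE", "early_reset_kappa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sampling_rate <= 2.0 * self.pac_amp_band[1]:
            raise ValueError("sampling_rate must exceed twice the upper PAC band edge")
        if self.n_trials_per_condition < 2:
            raise ValueError("need at least 2 trials per condition")
        if abs(self.participant_effect_rho) > 1:
            raise ValueError("participant_effect_rho must lie in [-1, 1]")
        if self.n_participants < 1:
            raise ValueError("need at least one participant")

    @property
    def times(self) -> np.ndarray:
        start, end = self.epoch_window
        n = int(round((end - start) * self.sampling_rate))
        return start + np.arange(n) / self.sampling_rate

    @property
    def theta_carrier(self) -> float:
        return 0.5 * (self.pac_phase_band[0] + self.pac_phase_band[1])

    @property
    def gamma_carrier(self) -> float:
        return 0.5 * (self.pac_amp_band[0] + self.pac_amp_band[1])

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class ParticipantParams:
    """Ground-truth effect sizes for one generated participant."""

    participant_id: str
    kappa_SE: dict = field(default_factory=dict)   # role -> concentration
    kappa_UE: dict = field(default_factory=dict)
    pac_gain: float = 0.0                          # SE coupling depth
    erp_gain: float = 1.0

    def __post_init__(self) -> None:
        vals = [self.pac_gain, self.erp_gain,
                *self.kappa_SE.values(), *self.kappa_UE.values()]
        arr = np.asarray(vals, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("participant parameters must be finite")
        if self.pac_gain < 0 or self.erp_gain < 0:
            raise ValueError("gains must be >= 0")


def sample_reset_phases(n: int, kappa: float, mu: float = 0.0,
                        seed=None) -> np.ndarray:
    """Draw ``n`` phases from von Mises(mu, kappa), wrapped to (-pi, pi].

    ``kappa = 0`` reduces to the uniform law on the circle.  Deterministic
    given ``seed`` (an int, SeedSequence, or Generator).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    rng = np.random.default_rng(seed)
    if kappa == 0.0:
        phases = rng.uniform(-np.pi, np.pi, size=n)
    else:
        phases = rng.vonmises(mu, kappa, size=n)
    # numpy returns [-pi, pi]; fold -pi onto pi to match (-pi, pi]
    phases = np.where(phases <= -np.pi, np.pi, phases)
    return phases


def one_over_f_noise(n_samples: int, exponent: float, sigma: float,
                     sfreq: float, rng: np.random.Generator,
                     n_series: int = 1) -> np.ndarray:
    """1/f^exponent noise via spectral shaping of circular white noise."""
    white = rng.standard_normal((n_series, n_samples))
    if sigma == 0.0:
        return np.zeros((n_series, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * shape, n=n_samples, axis=-1)
    rms = np.sqrt(np.mean(shaped**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return sigma * shaped / rms


def _gauss_env(t: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - centre) / width) ** 2)


def _plateau_env(t: np.ndarray, onset: float, offset: float,
                 ramp: float = 0.05) -> np.ndarray:
    """Smooth plateau between onset and offset (sigmoid ramps)."""
    rise = 1.0 / (1.0 + np.exp(-(t - onset) / ramp))
    fall = 1.0 / (1.0 + np.exp((t - offset) / ramp))
    return rise * fall


def _erp_transient(t: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    """Damped sinusoid starting at erp_latency; peak ~ erp_amplitude."""
    tt = t - cfg.erp_latency
    wave = np.where(
        tt >= 0,
        np.exp(-tt / cfg.erp_decay) * np.sin(2 * np.pi * cfg.erp_freq * tt),
        0.0,
    )
    peak = np.max(np.abs(wave)) or 1.0
    return cfg.erp_amplitude * wave / peak


def synthesize_epoch(config: SynthConfig, params: ParticipantParams,
                     condition: str, trial_seed) -> np.ndarray:
    """One epoch (channels x samples, microvolts) for one trial.

    Deterministic given ``trial_seed``.  The theta burst's phase at
    ``reset_latency`` is a fresh von Mises draw with the condition's
    concentration for that channel; the gamma envelope on the PAC channel
    is ``1 + m cos(theta phase)`` with ``m`` set by the participant's
    coupling gain (scaled down under UE).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    rng = np.random.default_rng(trial_seed)
    t = config.times
    n = t.size
    roles = config.channel_roles
    kappas = params.kappa_SE if condition == "SE" else params.kappa_UE

    epoch = one_over_f_noise(n, config.noise_exponent, config.noise_sigma,
                             config.sampling_rate, rng, n_series=len(roles))

    # early broadband burst: a common reset phase shared by a small comb of
    # frequencies spanning the band (same draw in both conditions' law)
    lo, hi = config.early_reset_band
    comb = np.linspace(lo + 1.0, hi - 1.0, 4)
    phi_early = sample_reset_phases(1, config.early_reset_kappa, 0.0, rng)[0]
    env_e = _gauss_env(t, config.early_reset_latency, config.early_reset_width)
    early = env_e * np.sum(
        [np.cos(2 * np.pi * f * (t - config.early_reset_latency) + phi_early)
         for f in comb], axis=0) * (config.early_amp / len(comb))

    # sustained poststimulus theta, one independent phase and frequency
    # jitter draw per reset channel; phases agree at reset_latency (up to
    # the von Mises draw) and decohere away from it at rate set by the
    # per-trial frequency jitter sigma_f = 1 / (2 pi reset_width)
    f_theta = config.theta_carrier
    sigma_f = 1.0 / (2.0 * np.pi * config.reset_width)
    env_t = _plateau_env(t, config.theta_onset, config.theta_offset)
    theta_phase_pac = None
    theta_by_role = {}
    for role in roles:
        if role not in THETA_RESET_CHANNELS:
            continue
        kappa = float(kappas.get(role, 0.0))
        phi = sample_reset_phases(1, kappa, 0.0, rng)[0]
        df = sigma_f * rng.standard_normal()
        inst_phase = 2 * np.pi * (f_theta + df) * (t - config.reset_latency) + phi
        theta_by_role[role] = config.theta_amp * env_t * np.cos(inst_phase)
        if role == PAC_CHANNEL:
            theta_phase_pac = inst_phase

    # gamma with theta-phase-dependent envelope on the PAC channel
    gamma = None
    if PAC_CHANNEL in roles and theta_phase_pac is not None:
        m = params.pac_gain if condition == "SE" else params.pac_gain * config.pac_ue_scale
        m = float(np.clip(m, 0.0, 0.95))
        phi_g = rng.uniform(0, 2 * np.pi)
        carrier = np.cos(2 * np.pi * config.gamma_carrier * t + phi_g)
        env_g = config.gamma_amp * env_t * (1.0 + m * np.cos(theta_phase_pac))
        gamma = env_g * carrier

    erp = params.erp_gain * _erp_transient(t, config)

    for i, role in enumerate(roles):
        epoch[i] += erp
        if role in EARLY_RESET_CHANNELS:
            epoch[i] += early
        if role in theta_by_role:
            epoch[i] += theta_by_role[role]
        if role == PAC_CHANNEL and gamma is not None:
            epoch[i] += gamma
    return epoch


def draw_participant_params(config: SynthConfig,
                            rng: np.random.Generator) -> list[ParticipantParams]:
    """Participant effect sizes via a shared latent Gaussian factor.

    ``z`` scales the reset concentrations; the coupling gain loads on
    ``rho * z + sqrt(1 - rho^2) * u`` with independent ``u``, so the
    across-participant correlation between reset strength and coupling
    gain targets ``participant_effect_rho``.
    """
    rho = config.participant_effect_rho
    out = []
    for p in range(config.n_participants):
        z, u = rng.standard_normal(2)
        a = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * u
        g = max(0.1, 1.0 + config.kappa_cv * z)
        pac = max(0.0, config.pac_gain_mean + config.pac_gain_sd * a)
        k_se = {"R-ATN": config.kappa_SE * g,
                "L-ATN": config.kappa_UE * g,
                "frontal": 0.5 * (config.kappa_SE + config.kappa_UE) * g}
        # frontal and L-ATN alignment does not differ by condition
        k_ue = {"R-ATN": config.kappa_UE * g,
                "L-ATN": k_se["L-ATN"],
                "frontal": k_se["frontal"]}
        out.append(ParticipantParams(
            participant_id=f"P{p + 1:02d}",
            kappa_SE=k_se, kappa_UE=k_ue,
            pac_gain=pac, erp_gain=1.0,
        ))
    return out


def generate_cohort(config: SynthConfig):
    """Generate a cohort; returns (list of EpochSet, list of ParticipantParams).

    Fully reproducible from ``config.seed``: participant-level parameters
    are drawn first, then every trial gets its own child seed.
    """
    root = np.random.SeedSequence(config.seed)
    param_ss, trial_ss = root.spawn(2)
    params = draw_participant_params(config, np.random.default_rng(param_ss))

    t = config.times
    n_tr = config.n_trials_per_condition
    epoch_sets = []
    trial_streams = trial_ss.spawn(config.n_participants)
    for p, (pp, ss) in enumerate(zip(params, trial_streams)):
        seeds = ss.spawn(2 * n_tr)
        data = np.empty((2 * n_tr, len(config.channel_roles), t.size))
        cond = np.empty(2 * n_tr, dtype=object)
        for k in range(2 * n_tr):
            c = "SE" if k < n_tr else "UE"
            data[k] = synthesize_epoch(config, pp, c, seeds[k])
            cond[k] = c
        epoch_sets.append(EpochSet(
            participant_id=pp.participant_id,
            channels=config.channel_roles,
            sampling_rate=config.sampling_rate,
            times=t,
            data=data,
            condition=cond,
        ))
    return epoch_sets, params


def write_truth_table(params: list[ParticipantParams], path) -> None:
    """Ground-truth parameter TSV (participant, kappas, coupling gain)."""
    import pandas as pd

    rows = [{
        "participant_id": p.participant_id,
        "kappa_SE": p.kappa_SE.get(PAC_CHANNEL, 0.0),
        "kappa_UE": p.kappa_UE.get(PAC_CHANNEL, 0.0),
        "pac_gain": p.pac_gain,
    } for p in params]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
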