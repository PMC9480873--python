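"""Synthetic MEG-like trial generator with recorded ground truth.

The generator emulates the statistical structure of epoched sensor data
from a visual delayed match-to-sample task with four events (cue ->
sample -> cue -> probe at a fixed 1.5 s SOA): a 1/f background, alpha
and beta oscillations whose power depends on cue condition and trial
segment, a slow (delta-band) oscillator that is partially phase-reset
at event times (von Mises-distributed event phase), a fast carrier
whose amplitude envelope is coupled to the slow oscillator's phase
(coupling strength differing by reaction-time class), additive
phase-locked evoked templates, and spatially patterned class
information whose amplitude depends on prestimulus band power.

Every latent draw (event phases, per-trial band power, pattern
amplitudes, generated RT) is recorded in a :class:`GroundTruth` table so
downstream estimators can be tested for parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .containers import EventTiming, SensorLayout, TrialSet

__all__ = [
    "ClassPattern",
    "PACConfig",
    "RTModel",
    "SimConfig",
    "GroundTruth",
    "simulate",
    "simulate_participant",
    "make_two_class_set",
    "occipital_channels",
]

CONDITION_CELLS = [
    (cue, feat, ori, freq)
    for cue in ("pre", "retro")
    for feat in ("orientation", "frequency")
    for ori in ("cw", "ccw")
    for freq in ("low", "high")
]


@dataclass(frozen=True)
class ClassPattern:
    """Spatially patterned class information injected into the signal.

    ``amplitude = base_snr * max(0, 1 + power_slope * z_power)`` where
    ``z_power`` is the trial's standardized log prestimulus power in
    ``modulating_band``; the pattern topography is multiplied by +1/-1
    according to the trial's value in ``label_column``.
    """

    label_column: str
    onset_s: float
    duration_s: float
    base_snr: float = 1.0
    power_slope: float = 0.0
    modulating_band: str = "beta"   # {"alpha", "beta", "theta"}


@dataclass(frozen=True)
class PACConfig:
    """Slow-phase to fast-amplitude coupling of the injected carrier.

    The carrier amplitude envelope is ``amp0 * (1 + m * cos(phi_slow))``
    with ``m`` depending on the trial's latent RT class.
    """

    phase_band: tuple[float, float] = (1.0, 3.0)
    amp_band: tuple[float, float] = (30.0, 35.0)
    carrier_hz: float = 32.5
    amp0: float = 0.3
    strength: dict = field(default_factory=lambda: {"fast": 0.6, "slow": 0.2})


@dataclass(frozen=True)
class RTModel:
    """Linear model generating RT from prestimulus state.

    ``rt = intercept + alpha_coef*z_alpha + beta_coef*z_beta
    + phase_coef*(1 - cos(probe event phase)) + slow-class offset + noise``.
    Positive power coefficients mean high prestimulus power slows
    responses. Accuracy follows a logistic decline with RT.
    """

    intercept: float = 0.65
    alpha_coef: float = 0.08
    beta_coef: float = 0.04
    phase_coef: float = 0.04
    slow_class_offset: float = 0.18
    sigma: float = 0.08
    accuracy_intercept: float = 4.0
    accuracy_rt_coef: float = -4.0
    no_response_rate: float = 0.02


def _default_band_amplitudes():
    # per band, per cue condition: gain in the five inter-event segments
    # [prestim, cue1->sample, sample->cue2, cue2->probe, probe->end];
    # the informative cue (cue1 for precue, cue2 for retro-cue trials)
    # is followed by a power decrease.
    return {
        "alpha": {
            "pre": (1.0, 0.55, 0.75, 0.70, 0.70),
            "retro": (1.0, 0.95, 0.95, 0.55, 0.70),
        },
        "beta": {
            "pre": (1.0, 0.60, 0.80, 0.70, 0.65),
            "retro": (1.0, 0.95, 0.95, 0.60, 0.70),
        },
    }


def _default_reset_kappa():
    # von Mises concentration of slow-oscillation phase at each of the
    # four events; the informative retro-cue (cue2) realigns more strongly.
    return {
        "pre": (1.5, 1.5, 1.0, 1.0),
        "retro": (1.5, 1.5, 2.5, 1.0),
    }


def _default_evoked():
    # per cue condition: template amplitude at each of the four events
    return {
        "pre": (1.2, 1.0, 0.8, 1.0),
        "retro": (0.8, 1.0, 1.2, 1.0),
    }


def _default_class_patterns():
    return (
        # cue-instruction information, gated (negatively) by alpha power
        ClassPattern("feature", onset_s=0.1, duration_s=0.4,
                     base_snr=1.0, power_slope=-0.5, modulating_band="alpha"),
        # sustained sample spatial-frequency information, gated by beta power
        ClassPattern("stim_frequency", onset_s=1.55, duration_s=2.0,
                     base_snr=0.8, power_slope=0.5, modulating_band="beta"),
        # transient sample orientation information
        ClassPattern("stim_orientation", onset_s=1.55, duration_s=0.5,
                     base_snr=0.6, power_slope=0.0, modulating_band="beta"),
    )


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults are the desk-scale study shape.

    Defaults: 10 participants x 400 trials x 64 channels on an 8x8 grid
    at 300 Hz, epoched -1..7 s around the first cue with events at a
    fixed 1.5 s SOA.
    """

    n_participants: int = 10
    n_trials: int = 400
    n_channels: int = 64
    fs: float = 300.0
    epoch_s: tuple[float, float] = (-1.0, 7.0)
    timing: EventTiming = field(default_factory=EventTiming)
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    shared_noise_frac: float = 0.4
    slow_freq_hz: float = 2.0
    slow_amp: float = 1.0
    alpha_peak_hz: float = 10.0
    beta_peak_hz: float = 20.0
    peak_jitter_hz: float = 0.0     # per-participant uniform jitter half-width
    alpha_amp: float = 1.6
    beta_amp: float = 1.1
    power_sigma: float = 0.5        # trial-to-trial log-power spread (latent z scale)
    band_amplitudes: dict = field(default_factory=_default_band_amplitudes)
    reset_kappa: dict = field(default_factory=_default_reset_kappa)
    pac: PACConfig = field(default_factory=PACConfig)
    evoked_amp: dict = field(default_factory=_default_evoked)
    evoked_scale: float = 1.5
    class_patterns: tuple = field(default_factory=_default_class_patterns)
    rt_model: RTModel = field(default_factory=RTModel)
    seed: int = 0

    def __post_init__(self):
        ny = int(round(np.sqrt(self.n_channels)))
        if ny * ny != self.n_channels:
            raise ValueError("n_channels must be a perfect square (grid layout)")
        nyq = self.fs / 2
        for lo, hi in (self.pac.phase_band, self.pac.amp_band):
            if not (0 < lo < hi < nyq):
                raise ValueError(f"band ({lo}, {hi}) outside (0, Nyquist={nyq})")
        if self.pac.phase_band[1] >= self.pac.amp_band[0]:
            raise ValueError("PAC phase band must lie below the amplitude band")
        for m in self.pac.strength.values():
            if not 0 <= m <= 1:
                raise ValueError("PAC strength m must be in [0, 1]")
        for cond, ks in self.reset_kappa.items():
            if np.any(np.asarray(ks) < 0):
                raise ValueError("reset_kappa must be >= 0")
        if self.n_trials % len(CONDITION_CELLS):
            raise ValueError(
                f"n_trials must be divisible by {len(CONDITION_CELLS)} condition cells")
        if not (0 < self.alpha_peak_hz < nyq and 0 < self.beta_peak_hz < nyq):
            raise ValueError("oscillation peaks must lie within (0, Nyquist)")

    @property
    def grid_shape(self) -> tuple[int, int]:
        n = int(round(np.sqrt(self.n_channels)))
        return (n, n)


@dataclass
class GroundTruth:
    """Per-trial latent draws plus the generating configuration."""

    trials: pd.DataFrame
    config: SimConfig

    def to_json(self) -> str:
        cfg = asdict(self.config)
        cfg["class_patterns"] = [asdict(p) for p in self.config.class_patterns]
        return json.dumps(
            {"config": cfg, "trials": json.loads(self.trials.to_json(orient="split"))}
        )


def occipital_channels(layout: SensorLayout, n_rows: int = 2) -> list[str]:
    """Posterior-row channel labels of a grid layout (the generator's
    convention marks the lowest-y rows as occipital)."""
    ys = np.unique(layout.positions[:, 1])[:n_rows]
    return [
        cid for cid, pos in zip(layout.channel_ids, layout.positions)
        if pos[1] in ys
    ]


# -- low-level building blocks -------------------------------------------

def _one_over_f(rng, n_samp, fs, chi, size):
    """FFT-shaped 1/f^chi noise, flat below 1 Hz, unit-ish variance."""
    freqs = np.fft.rfftfreq(n_samp, 1 / fs)
    shaping = np.maximum(freqs, 1.0) ** (-chi / 2.0)
    shaping[0] = 0.0
    white = rng.standard_normal(size + (n_samp,))
    spec = np.fft.rfft(white, axis=-1) * shaping
    x = np.fft.irfft(spec, n=n_samp, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _smooth_map(rng, grid_shape, sigma=1.2):
    """Spatially smooth random topography, unit RMS."""
    m = gaussian_filter(rng.standard_normal(grid_shape), sigma, mode="nearest")
    return (m / (np.sqrt(np.mean(m ** 2)) + 1e-30)).ravel()


def _segment_envelope(times, timing: EventTiming, gains, fs, ramp_s=0.2):
    """Piecewise-constant per-segment gain, smoothed with a Hann ramp."""
    bounds = [times[0] - 1] + list(timing.event_times()) + [times[-1] + 1]
    env = np.empty_like(times)
    for seg, g in enumerate(gains):
        mask = (times >= bounds[seg]) & (times < bounds[seg + 1])
        env[mask] = g
    n_ramp = max(3, int(ramp_s * fs) | 1)
    kernel = np.hanning(n_ramp)
    kernel /= kernel.sum()
    return np.convolve(env, kernel, mode="same")


def _slow_phase(times, timing: EventTiming, f_slow, deltas, phi0, fs, blend_s=0.25):
    """Instantaneous slow-oscillator phase with partial resets at events.

    Between events the oscillator runs freely; at event ``i`` the phase
    is re-drawn so that the phase AT the event equals ``deltas[i]``.
    Returns the phase array and a cross-fade weight array (0 -> old
    oscillation, 1 -> new) so the caller can blend the two sinusoids and
    avoid hard discontinuities.
    """
    phase = phi0 + 2 * np.pi * f_slow * (times - times[0])
    segments = [phase]
    weights = []
    ev_times = timing.event_times()
    for ev, delta in zip(ev_times, deltas):
        new_phase = delta + 2 * np.pi * f_slow * (times - ev)
        w = np.clip((times - ev) / blend_s, 0.0, 1.0)
        w = 0.5 - 0.5 * np.cos(np.pi * w)   # raised-cosine blend
        w[times < ev] = 0.0
        segments.append(new_phase)
        weights.append(w)
    return segments, weights


def _blend_oscillation(segments, weights, envelope):
    """Amplitude-modulated cosine with cross-faded phase resets."""
    x = np.cos(segments[0])
    for seg, w in zip(segments[1:], weights):
        x = (1 - w) * x + w * np.cos(seg)
    return envelope * x


def _evoked_template(fs, duration_s=0.5, f=4.0):
    """Biphasic Gaussian-windowed wave used as the phase-locked response."""
    t = np.arange(int(duration_s * fs)) / fs
    win = np.exp(-0.5 * ((t - duration_s / 3) / (duration_s / 5)) ** 2)
    return win * np.sin(2 * np.pi * f * t)


def _label_sign(values: pd.Series) -> np.ndarray:
    levels = sorted(values.unique())
    if len(levels) != 2:
        raise ValueError(f"label column must be binary, got levels {levels}")
    return np.where(values.to_numpy() == levels[0], 1.0, -1.0)


# -- main generator -------------------------------------------------------

def simulate_participant(config: SimConfig, participant: int) -> tuple[TrialSet, GroundTruth]:
    """Generate one participant's TrialSet plus its ground-truth table.

    Reproducible: the RNG stream is keyed by ``(config.seed, participant)``.
    """
    rng = np.random.default_rng([int(config.seed), int(participant)])
    fs, (t0, t1) = config.fs, config.epoch_s
    n_samp = int(round((t1 - t0) * fs))
    times = t0 + np.arange(n_samp) / fs
    ny, nx = config.grid_shape
    layout = SensorLayout.grid(nx, ny)
    n_tr, n_ch = config.n_trials, config.n_channels
    timing = config.timing
    ev_times = timing.event_times()

    # participant-level structure
    jit = config.peak_jitter_hz
    alpha_hz = config.alpha_peak_hz + (rng.uniform(-jit, jit) if jit else 0.0)
    beta_hz = config.beta_peak_hz + (rng.uniform(-jit, jit) if jit else 0.0)
    iy = layout.positions[:, 1]
    posterior_gain = 0.6 + 1.2 * np.exp(-(iy / max(ny - 1, 1)) ** 2 / 0.18)
    alpha_topo = posterior_gain * (1 + 0.15 * _smooth_map(rng, (ny, nx)))
    beta_topo = posterior_gain * (1 + 0.15 * _smooth_map(rng, (ny, nx)))
    slow_topo = 0.8 + 0.1 * _smooth_map(rng, (ny, nx))
    pac_topo = np.abs(0.7 + 0.3 * _smooth_map(rng, (ny, nx)))
    evoked_topo = _smooth_map(rng, (ny, nx))
    pattern_topos = {
        p.label_column: _smooth_map(rng, (ny, nx)) for p in config.class_patterns
    }
    template = _evoked_template(fs)
    n_tpl = len(template)
    i_events = [int(round((e - t0) * fs)) for e in ev_times]

    # balanced factorial metadata
    reps = n_tr // len(CONDITION_CELLS)
    cells = CONDITION_CELLS * reps
    order = rng.permutation(n_tr)
    meta = pd.DataFrame(
        [cells[i] for i in order],
        columns=["cue_condition", "feature", "stim_orientation", "stim_frequency"],
    )
    meta.insert(0, "participant_id", f"p{participant:02d}")

    # per-trial latents
    z = {b: rng.standard_normal(n_tr) for b in ("alpha", "beta", "theta")}
    rt_class = np.where(rng.random(n_tr) < 0.5, "fast", "slow")
    rtm = config.rt_model
    deltas = np.empty((n_tr, 4))
    data = np.empty((n_tr, n_ch, n_samp), dtype=np.float32)
    pattern_amp = {p.label_column: np.empty(n_tr) for p in config.class_patterns}
    pattern_sign = {
        p.label_column: _label_sign(meta[p.label_column]) for p in config.class_patterns
    }

    segs_bounds = None
    env_cache: dict = {}
    for i in range(n_tr):
        cond = meta.at[i, "cue_condition"]
        # background: independent + shared spatially smooth 1/f noise
        indep = _one_over_f(rng, n_samp, fs, config.noise_exponent, (n_ch,))
        shared = _one_over_f(rng, n_samp, fs, config.noise_exponent, ())
        shared_topo = _smooth_map(rng, (ny, nx))
        x = config.noise_scale * (
            (1 - config.shared_noise_frac) * indep
            + config.shared_noise_frac * shared_topo[:, None] * shared[None, :]
        )

        # alpha / beta oscillations: condition+segment envelope, trial power
        for band, f_hz, topo, amp in (
            ("alpha", alpha_hz, alpha_topo, config.alpha_amp),
            ("beta", beta_hz, beta_topo, config.beta_amp),
        ):
            key = (band, cond)
            if key not in env_cache:
                env_cache[key] = _segment_envelope(
                    times, timing, config.band_amplitudes[band][cond], fs)
            env = env_cache[key]
            power_mult = np.exp(config.power_sigma * z[band][i])
            phases = rng.uniform(0, 2 * np.pi, n_ch)
            x += (amp * power_mult * env)[None, :] * topo[:, None] * np.cos(
                2 * np.pi * f_hz * times[None, :] + phases[:, None])

        # slow oscillator with partial phase reset at events
        kappas = config.reset_kappa[cond]
        dl = np.array([rng.vonmises(0.0, k) if k > 0 else rng.uniform(-np.pi, np.pi)
                       for k in kappas])
        deltas[i] = dl
        phi0 = rng.uniform(0, 2 * np.pi)
        theta_mult = np.exp(config.power_sigma * z["theta"][i])
        segments, weights = _slow_phase(times, timing, config.slow_freq_hz, dl, phi0, fs)
        slow_env = np.full(n_samp, config.slow_amp * theta_mult)
        slow_wave = _blend_oscillation(segments, weights, slow_env)
        x += slow_topo[:, None] * slow_wave[None, :]

        # PAC carrier: envelope locked to the slow phase
        m = config.pac.strength[rt_class[i]]
        slow_phase = segments[0].copy()
        for seg, w in zip(segments[1:], weights):
            # blended effective phase for the envelope (angle interpolation)
            slow_phase = np.angle(
                (1 - w) * np.exp(1j * slow_phase) + w * np.exp(1j * seg) + 1e-12)
        carrier_env = config.pac.amp0 * (1 + m * np.cos(slow_phase))
        psi = rng.uniform(0, 2 * np.pi)
        x += pac_topo[:, None] * (carrier_env * np.cos(
            2 * np.pi * config.pac.carrier_hz * times + psi))[None, :]

        # evoked (phase-locked) templates at each event
        amps = config.evoked_amp[cond]
        for i_ev, a in zip(i_events, amps):
            hi = min(i_ev + n_tpl, n_samp)
            if i_ev < n_samp and hi > i_ev:
                x[:, i_ev:hi] += (config.evoked_scale * a) * (
                    evoked_topo[:, None] * template[None, : hi - i_ev])

        # class-information patterns, amplitude gated by prestimulus power
        for p in config.class_patterns:
            a = p.base_snr * max(0.0, 1.0 + p.power_slope * z[p.modulating_band][i])
            pattern_amp[p.label_column][i] = a
            key = ("pat", p.label_column)
            if key not in env_cache:
                e = np.zeros(n_samp)
                on = int(round((p.onset_s - t0) * fs))
                off = min(int(round((p.onset_s + p.duration_s - t0) * fs)), n_samp)
                e[on:off] = 1.0
                n_ramp = max(3, int(0.05 * fs) | 1)
                k = np.hanning(n_ramp); k /= k.sum()
                env_cache[key] = np.convolve(e, k, mode="same")
            x += (a * pattern_sign[p.label_column][i]) * (
                pattern_topos[p.label_column][:, None] * env_cache[key][None, :])

        data[i] = x

    # RT / accuracy from prestimulus state
    noise = rng.standard_normal(n_tr) * rtm.sigma
    rt = (
        rtm.intercept
        + rtm.alpha_coef * z["alpha"]
        + rtm.beta_coef * z["beta"]
        + rtm.phase_coef * (1 - np.cos(deltas[:, 3]))
        + np.where(rt_class == "slow", rtm.slow_class_offset, 0.0)
        + noise
    )
    rt = np.clip(rt, 0.15, None)
    p_correct = expit(rtm.accuracy_intercept + rtm.accuracy_rt_coef * rt)
    correct = rng.random(n_tr) < p_correct
    no_resp = rng.random(n_tr) < rtm.no_response_rate
    rt[no_resp] = np.nan
    correct[no_resp] = False
    meta["rt_s"] = rt
    meta["correct"] = correct

    truth = meta.copy()
    for b in ("alpha", "beta", "theta"):
        truth[f"{b}_z"] = z[b]
    for k, ev_name in enumerate(("cue1", "sample", "cue2", "probe")):
        truth[f"slow_phase_{ev_name}"] = deltas[:, k]
    truth["rt_class"] = rt_class
    for col, amp in pattern_amp.items():
        truth[f"pattern_amp_{col}"] = amp
    return TrialSet(data, fs, times, layout, meta), GroundTruth(truth, config)


def simulate(config: SimConfig) -> tuple[TrialSet, GroundTruth]:
    """Generate all participants into one concatenated TrialSet.

    Bit-reproducible for a fixed ``(config, config.seed)``.
    """
    sets, truths = [], []
    for p in range(config.n_participants):
        ts, gt = simulate_participant(config, p)
        sets.append(ts)
        truths.append(gt.trials)
    data = np.concatenate([s.data for s in sets], axis=0)
    meta = pd.concat([s.meta for s in sets], ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)
    first = sets[0]
    return (
        TrialSet(data, first.fs, first.times, first.layout, meta),
        GroundTruth(truth, config),
    )


def make_two_class_set(n_trials: int, d_prime: float, n_features: int, seed: int):
    """Two Gaussian classes separated by ``d_prime`` on the first feature.

    Returns ``(X, y)`` with unit-covariance features and balanced 0/1
    labels; the Bayes-optimal AUC is ``Phi(d_prime / sqrt(2))``.
    """
    if n_trials < 4:
        raise ValueError("need at least 4 trials")
    if d_prime < 0:
        raise ValueError("d_prime must be non-negative")
    rng = np.random.default_rng(seed)
    y = np.zeros(n_trials, dtype=int)
    y[n_trials // 2:] = 1
    X = rng.standard_normal((n_trials, n_features))
    X[:, 0] += np.where(y == 1, d_prime / 2, -d_prime / 2)
    return X, y
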