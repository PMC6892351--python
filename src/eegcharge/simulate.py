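"""Synthetic two-condition (reward/punishment) EEG sessions.

Generates IGT-like dense-array recordings with known ground-truth parcel
activity: for each trial, a band-limited Hann-windowed burst in the active
parcels of that trial's condition is projected through the lead field and
summed with Gaussian sensor noise.  Blink-like ocular artifacts can be
injected on frontal channels.  All randomness flows through one seeded
generator, so a fixed seed reproduces the session bit for bit.

Amplitudes use the package's "μA" reporting convention (one unit = 10 nA·m
equivalent dipole moment, see :mod:`eegcharge.forward`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .forward import LeadField, Montage, SourceSpace

__all__ = [
    "REWARD",
    "PUNISHMENT",
    "TrialSchedule",
    "ParcelActivation",
    "SimulationConfig",
    "RawSession",
    "default_activations",
    "make_trial_schedule",
    "simulate_session",
    "inject_ocular_artifacts",
    "make_charge_cohort",
    "BAND_CENTERS",
]

REWARD = "reward"  # TGT stimuli
PUNISHMENT = "punishment"  # STD stimuli
CONDITIONS = (REWARD, PUNISHMENT)

#: Default oscillation frequency per band (Hz), at each band's center
#: (γ has no upper edge in the band definition; 40 Hz is used).
BAND_CENTERS = {
    "delta": 1.5,
    "theta": 5.5,
    "alpha": 9.5,
    "beta": 21.0,
    "gamma": 40.0,
    "full": 9.5,
}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class TrialSchedule:
    events: tuple[tuple[float, str], ...]  # (onset_s, condition)

    def __post_init__(self) -> None:
        onsets = [t for t, _ in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ConfigError("event onsets must strictly increase")
        conds = {c for _, c in self.events}
        if not conds <= set(CONDITIONS):
            raise ConfigError(f"unknown conditions: {conds - set(CONDITIONS)}")
        if len(conds) < 2:
            raise ConfigError("both conditions must be present")

    @property
    def n_trials(self) -> int:
        return len(self.events)

    def onsets(self, condition: str | None = None) -> np.ndarray:
        return np.array([t for t, c in self.events
                         if condition is None or c == condition])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["onset_s", "condition"])


@dataclass(frozen=True)
class ParcelActivation:
    """One condition-locked source burst."""

    parcel: str
    band: str
    amplitude: float  # peak, μA convention
    latency_ms: float = 300.0  # burst center delay after stimulus
    duration_ms: float = 400.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ConfigError("amplitude must be >= 0")
        if self.band not in BAND_CENTERS:
            raise ConfigError(f"unknown band {self.band!r}")


@dataclass(frozen=True)
class SimulationConfig:
    sampling_rate: float = 500.0
    active_parcels: dict[str, tuple[ParcelActivation, ...]] = field(
        default_factory=dict)
    band_freqs: dict[str, float] = field(
        default_factory=lambda: dict(BAND_CENTERS))
    noise_sd: float = 5.0  # μV, i.i.d. Gaussian per channel/sample
    pink_noise_sd: float = 0.0  # μV, optional 1/f background
    blink_rate_per_min: float = 0.0
    blink_peak_uv: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        fmax = max(self.band_freqs.values())
        if self.sampling_rate <= 2.0 * fmax:
            raise ConfigError("sampling rate must exceed twice the highest "
                              "oscillation frequency")
        if self.noise_sd < 0 or self.pink_noise_sd < 0:
            raise ConfigError("noise sd must be >= 0")


@dataclass
class RawSession:
    data: np.ndarray  # (n_channels, n_samples), μV
    sampling_rate: float
    schedule: TrialSchedule
    montage: Montage
    source_tc: np.ndarray | None = None  # (M, n_samples) ground truth
    truth: dict = field(default_factory=dict)
    blink_onsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ConfigError("session data contains NaN/Inf")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


def default_activations(amplitude: float = 20.0, band: str = "gamma",
                        reward_parcel: str = "AMYGDALA",
                        punishment_parcel: str = "BA17") -> dict:
    """Condition-dependent single-parcel activity, amygdala-reward flavored."""
    return {
        REWARD: (ParcelActivation(reward_parcel, band, amplitude),),
        PUNISHMENT: (ParcelActivation(punishment_parcel, band, amplitude),),
    }


def make_trial_schedule(n_trials: int = 100, iti_s: float = 7.0,
                        start_s: float = 5.0, seed: int = 0) -> TrialSchedule:
    """Balanced, randomly ordered reward/punishment trials.

    Defaults give 100 trials over ~11.8 min, matching a typical IGT session.
    """
    if n_trials < 2:
        raise ConfigError("need at least 2 trials")
    rng = np.random.default_rng(seed)
    conds = np.array([REWARD, PUNISHMENT] * (n_trials // 2 + 1))[:n_trials]
    rng.shuffle(conds)
    if len(set(conds)) < 2:  # pathological shuffle cannot happen, but guard
        conds[0] = REWARD if conds[1] == PUNISHMENT else PUNISHMENT
    onsets = start_s + iti_s * np.arange(n_trials)
    return TrialSchedule(events=tuple(zip(onsets.tolist(), conds.tolist())))


def _burst(t: np.ndarray, onset: float, act: ParcelActivation,
           freq: float) -> np.ndarray:
    """Hann-windowed sinusoid centered ``latency_ms`` after the stimulus."""
    dur = act.duration_ms / 1000.0
    t0 = onset + act.latency_ms / 1000.0 - dur / 2.0
    rel = (t - t0) / dur
    win = np.where((rel >= 0) & (rel < 1),
                   0.5 * (1.0 - np.cos(2.0 * np.pi * rel)), 0.0)
    return act.amplitude * win * np.sin(2.0 * np.pi * freq * (t - t0))


def simulate_session(config: SimulationConfig, lead_field: LeadField,
                     source_space: SourceSpace, montage: Montage,
                     schedule: TrialSchedule | None = None,
                     keep_sources: bool = True) -> RawSession:
    """Project condition-locked parcel bursts through the lead field.

    Returns the scalp session plus the ground-truth source time courses
    (``keep_sources=False`` drops them to save memory on large cohorts).
    """
    if schedule is None:
        schedule = make_trial_schedule(seed=config.seed)
    for acts in config.active_parcels.values():
        for act in acts:
            if act.parcel not in source_space.parcels:
                raise ConfigError(f"parcel {act.parcel!r} not in source space")
    fs = config.sampling_rate
    tail_s = 3.0
    n_samp = int(round((schedule.onsets().max() + tail_s) * fs))
    t = np.arange(n_samp) / fs
    M = source_space.n_sources
    rng = np.random.default_rng(config.seed)

    amp = np.zeros((M, n_samp))  # signed source amplitude along b̂
    for onset, cond in schedule.events:
        for act in config.active_parcels.get(cond, ()):
            freq = config.band_freqs[act.band]
            wave = _burst(t, onset, act, freq)
            if not wave.any():
                continue
            for j in source_space.sources_of(act.parcel):
                amp[j] += wave

    # radial orientation: moment_j(t) = amp_j(t) * b̂_j
    b_hat = source_space.locations / np.linalg.norm(
        source_space.locations, axis=1, keepdims=True)
    n_ch = montage.n_channels
    data = np.zeros((n_ch, n_samp))
    if lead_field.orientation_mode == "free":
        for j in range(M):
            if not amp[j].any():
                continue
            g = lead_field.gain[:, 3 * j:3 * j + 3] @ b_hat[j]
            data += np.outer(g, amp[j])
    else:
        data = lead_field.gain @ amp

    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, data.shape)
    if config.pink_noise_sd > 0:
        data += _pink_noise(rng, data.shape, config.pink_noise_sd)

    truth = {
        "active_parcels": {
            cond: [(a.parcel, a.band, a.amplitude) for a in acts]
            for cond, acts in config.active_parcels.items()
        },
        "seed": config.seed,
    }
    return RawSession(data=data, sampling_rate=fs, schedule=schedule,
                      montage=montage,
                      source_tc=amp if keep_sources else None, truth=truth)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int],
                sd: float) -> np.ndarray:
    """1/f-shaped background, normalized to the requested per-sample sd."""
    n_ch, n_samp = shape
    spec = np.fft.rfft(rng.normal(0.0, 1.0, shape), axis=1)
    freqs = np.fft.rfftfreq(n_samp)
    freqs[0] = freqs[1]
    spec /= np.sqrt(freqs)
    x = np.fft.irfft(spec, n=n_samp, axis=1)
    x *= sd / x.std(axis=1, keepdims=True)
    return x


def inject_ocular_artifacts(raw: RawSession, rate_per_min: float,
                            peak_uv: float, seed: int = 0,
                            frontal_channels: list[str] | None = None
                            ) -> RawSession:
    """Add blink-shaped transients on frontal channels.

    Blink count is Poisson(rate × minutes); each blink is a 300 ms raised
    cosine with a frontally weighted spatial profile whose maximum equals
    ``peak_uv``.  ``rate_per_min=0`` returns the input unchanged.
    """
    if peak_uv <= 0:
        raise ConfigError("peak_uv must be > 0")
    if rate_per_min == 0:
        return raw
    if frontal_channels is None:
        frontal_channels = raw.montage.frontal_channels()
    if not frontal_channels:
        raise ConfigError("frontal channel subset is empty")
    rng = np.random.default_rng(seed)
    minutes = raw.duration_s / 60.0
    n_blinks = rng.poisson(rate_per_min * minutes)
    fs = raw.sampling_rate
    dur = int(round(0.300 * fs))
    template = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(dur) / dur))

    idx = [raw.montage.channel_ids.index(c) for c in frontal_channels]
    y = raw.montage.positions[idx, 1]
    profile = y / y.max()  # 1.0 at the most anterior channel

    data = raw.data.copy()
    onsets = np.sort(rng.uniform(0.0, raw.duration_s - 0.3, n_blinks))
    for t0 in onsets:
        k0 = int(round(t0 * fs))
        seg = slice(k0, k0 + dur)
        data[idx, seg] += peak_uv * np.outer(profile, template)
    return replace(raw, data=data, blink_onsets=onsets)


def make_charge_cohort(n_subjects: int = 71, parcels: tuple[str, ...] = None,
                       bands: tuple[str, ...] = ("full", "alpha", "beta",
                                                 "gamma", "delta", "theta"),
                       effect_parcel: str = "AMYGDALA",
                       effect_bands: tuple[str, ...] | None = None,
                       effect_sd: float = 2.0,
                       base_mean: float = 8.0, base_sd: float = 2.0,
                       seed: int = 0) -> pd.DataFrame:
    """Synthetic cohort of per-(subject, condition, band, parcel) ι values.

    Reward trials carry an extra ``effect_sd × base_sd`` μC of charge in
    ``effect_parcel`` (all bands unless ``effect_bands`` restricts it);
    everything else is i.i.d. noise around ``base_mean``.  Used for
    classifier parameter-recovery and null benchmarks without simulating
    full scalp sessions.
    """
    if parcels is None:
        parcels = ("AMYGDALA", "HIPPOCAMPUS", "BA04", "BA05", "BA09", "BA17",
                   "BA27", "BA29", "BA34", "BA36", "BA45", "BA46")
    if effect_bands is None:
        effect_bands = bands
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for cond in CONDITIONS:
            for band in bands:
                for parcel in parcels:
                    iota = max(rng.normal(base_mean, base_sd), 0.0)
                    if (parcel == effect_parcel and cond == REWARD
                            and band in effect_bands):
                        iota += effect_sd * base_sd
                    rows.append((f"S{s + 1:03d}", cond, band, parcel, iota))
    return pd.DataFrame(
        rows, columns=["subject", "condition", "band", "parcel", "iota_uC"])
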