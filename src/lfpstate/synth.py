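"""Synthetic LFP sessions and pose tracks with known ground truth.

The generator is phenomenological: each channel is a 1/f^alpha Gaussian
arrhythmic background plus band-limited oscillatory episodes (a gamma band
around 30-90 Hz and/or an HFO band around 130-160 Hz).  Episode timing is
shared across structures — mimicking the globally co-occurring HFOs of the
psychotomimetic state — while each structure carries a configurable phase
lag with von Mises concentration kappa around it.  Oscillation strength is
specified in dB above the fractal background at the band center
(``amplitude_db``), i.e. in the same dB_fractal units the analysis reports,
and is calibrated against the measured spectrum of the generated background.

Within a structure, consecutive channels carry the oscillation with gains
+1/2 and -1/2, so the bipolar difference of a pair carries it at unit gain
and with the structure's exact phase; the backgrounds are independent per
channel.  A :class:`GroundTruthLedger` records every injected episode, the
true structure-pair lags and kappa, the per-condition fractal exponent
(the entropy regime), and any behavior bout schedule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import Recording, ChannelMap, STRUCTURES
from .behavior import PoseTrack


# --------------------------------------------------------------------------
# configuration containers
# --------------------------------------------------------------------------

@dataclass
class OscillationSpec:
    """One band-limited oscillatory process, shared in time across structures.

    amplitude_db is the target height of the dB_fractal spectrum at the band
    center, measured on bipolar traces during episodes.  phase_lag_map gives
    each structure's lag (radians; positive = that structure leads) relative
    to the common carrier; kappa is the von Mises concentration of the
    per-episode deviations around those lags (``inf`` = fixed lags).
    """

    band_center: float
    bandwidth: float
    amplitude_db: float
    episode_rate: float = 0.0                     # episodes / min (Poisson)
    episode_duration_s: tuple[float, float] = (10.0, 60.0)
    episode_schedule: list[tuple[float, float]] | None = None  # overrides rate
    phase_lag_map: dict[str, float] = field(default_factory=dict)
    kappa: float = math.inf
    center_jitter_hz: float = 0.0                 # per-episode center jitter

    def __post_init__(self) -> None:
        if self.amplitude_db < 0:
            raise ValueError("amplitude_db must be >= 0")
        if not (0 < self.bandwidth < self.band_center):
            raise ValueError("need 0 < bandwidth < band_center")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


@dataclass
class ConditionSpec:
    """Per-condition generative regime."""

    label: str
    oscillations: list[OscillationSpec] = field(default_factory=list)
    fractal_exponent: float | None = None   # None -> session default


@dataclass
class SyntheticSessionConfig:
    sampling_rate: float = 2000.0
    duration_s: float = 600.0
    structures: list[tuple[str, str]] = field(
        default_factory=lambda: [("mPFC", "lesioned"), ("vStr", "lesioned")])
    channels_per_structure: int = 2
    fractal_exponent: float = 2.0
    fractal_scale: float = 50.0             # background RMS, uV
    conditions: list[ConditionSpec] = field(default_factory=list)
    condition_epochs: list[tuple[str, float, float]] = field(default_factory=list)
    seed: int = 0
    animal: str = "a01"
    session: str = "s01"

    def __post_init__(self) -> None:
        if self.channels_per_structure < 2:
            raise ValueError(
                "channels_per_structure must be >= 2 (bipolar derivation "
                "needs electrode pairs)")
        eps = sorted(self.condition_epochs, key=lambda e: e[1])
        for (_, s0, e0), (_, s1, _) in zip(eps, eps[1:]):
            if s1 < e0:
                raise ValueError("condition epochs overlap")
        for label, s0, e0 in eps:
            if not (0 <= s0 < e0 <= self.duration_s):
                raise ValueError(f"epoch {label!r} outside session duration")
        known = {c.label for c in self.conditions}
        missing = {lbl for lbl, _, _ in self.condition_epochs} - known
        if missing:
            raise ValueError(f"epochs reference unknown conditions: {sorted(missing)}")


@dataclass
class GroundTruthLedger:
    """Everything the generator injected, for downstream recovery checks."""

    episodes: list[dict] = field(default_factory=list)
    # entries: condition, structure, hemisphere, channel_id, start_s, end_s,
    #          center_hz, amplitude_db, phase_rad
    pair_lags: dict[str, float] = field(default_factory=dict)   # "A|B" -> rad
    kappa: dict[str, float] = field(default_factory=dict)       # condition -> kappa
    entropy_regime: dict[str, float] = field(default_factory=dict)  # condition -> alpha
    bout_schedule: list[tuple[float, float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticSession:
    recording: Recording
    channel_map: ChannelMap
    ledger: GroundTruthLedger


# --------------------------------------------------------------------------
# signal primitives
# --------------------------------------------------------------------------

def generate_fractal_signal(duration_s: float, fs: float, exponent: float,
                            scale: float = 1.0,
                            seed: int | np.random.Generator = 0) -> np.ndarray:
    """Stationary Gaussian signal with power spectrum ~ f^(-exponent).

    White Gaussian noise is shaped in the Fourier domain with
    ``|H(f)| = f^(-exponent/2)`` (DC removed), then rescaled to RMS
    ``scale``.  Identical seeds give bitwise-identical output.
    """
    for name, v in (("duration_s", duration_s), ("fs", fs), ("exponent", exponent),
                    ("scale", scale)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    if duration_s <= 0 or fs <= 0 or exponent < 0:
        raise ValueError("need duration_s > 0, fs > 0, exponent >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    rms = np.sqrt(np.mean(x ** 2))
    if rms > 0:
        x *= scale / rms
    return x


def _narrowband_analytic(n: int, fs: float, center_f: float, bandwidth: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Unit-variance complex analytic narrowband process at center_f."""
    # complex Gaussian envelope low-passed to +-bandwidth/2, then mixed up
    env = rng.standard_normal(n) + 1j * rng.standard_normal(n)
    spec = np.fft.fft(env)
    f = np.fft.fftfreq(n, d=1.0 / fs)
    sigma = max(bandwidth / 2.355, 1e-9)          # FWHM -> Gaussian sigma
    spec *= np.exp(-0.5 * (f / sigma) ** 2)
    env = np.fft.ifft(spec)
    env /= np.sqrt(np.mean(np.abs(env) ** 2))
    t = np.arange(n) / fs
    return env * np.exp(2j * np.pi * center_f * t)


def draw_episode_schedule(rate_per_min: float, duration_s: float,
                          dur_range: tuple[float, float],
                          rng: np.random.Generator) -> list[tuple[float, float]]:
    """Non-overlapping Poisson episode schedule within [0, duration_s)."""
    schedule: list[tuple[float, float]] = []
    if rate_per_min <= 0:
        return schedule
    t = 0.0
    rate_s = rate_per_min / 60.0
    while True:
        t += rng.exponential(1.0 / rate_s)
        d = rng.uniform(*dur_range)
        if t + d > duration_s:
            break
        schedule.append((t, t + d))
        t += d
    return schedule


def generate_oscillatory_component(
        fs: float, duration_s: float, center_f: float, bandwidth: float,
        amplitude_db: float, episode_schedule: list[tuple[float, float]],
        channel_phase_lags: list[float], kappa: float = math.inf,
        seed: int | np.random.Generator = 0,
        reference_psd: float | np.ndarray = 1.0,
        center_jitter_hz: float = 0.0,
        ) -> tuple[np.ndarray, list[dict]]:
    """Multichannel band-limited oscillation restricted to episodes.

    Returns ``(signals, episode_log)`` where ``signals`` is channels x time
    and each log entry records the episode bounds, realized center frequency
    and each channel's realized phase lag.  The component is scaled so its
    PSD at the band center, during episodes, sits ``amplitude_db`` above
    ``reference_psd`` (the arrhythmic PSD at that frequency, uV^2/Hz):
    target oscillation PSD = reference_psd * (10^(A/10) - 1).
    ``amplitude_db = 0`` therefore yields an all-zero component.
    ``reference_psd`` may be a scalar or one value per channel.
    """
    if center_f + bandwidth / 2 >= fs / 2:
        raise ValueError("band exceeds Nyquist")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    n_ch = len(channel_phase_lags)
    out = np.zeros((n_ch, n))
    log: list[dict] = []
    for s0, e0 in episode_schedule:
        if not (0 <= s0 < e0 <= duration_s + 1e-9):
            raise ValueError(f"episode [{s0}, {e0}) outside [0, {duration_s})")
    if amplitude_db == 0 or not episode_schedule:
        return out, log

    power_ratio = 10.0 ** (amplitude_db / 10.0) - 1.0
    target_psd = np.broadcast_to(np.asarray(reference_psd, float) * power_ratio,
                                 (n_ch,))
    for (s0, e0) in episode_schedule:
        i0, i1 = int(round(s0 * fs)), int(round(e0 * fs))
        m = i1 - i0
        fc = center_f + (rng.uniform(-center_jitter_hz, center_jitter_hz)
                         if center_jitter_hz else 0.0)
        z = _narrowband_analytic(m, fs, fc, bandwidth, rng)
        # calibrate once against the measured spectrum of this episode
        if m >= int(8 * fs):
            fz, pz = sps.welch(np.real(z), fs=fs, window="hann",
                               nperseg=int(8 * fs), noverlap=int(4 * fs),
                               detrend=False)
        else:
            fz, pz = sps.periodogram(np.real(z), fs=fs, window="hann",
                                     detrend=False)
        near = np.abs(fz - fc) <= max(1.0, bandwidth / 10.0)
        peak_psd = float(np.mean(pz[near])) if near.any() else float(np.max(pz))
        gains = np.sqrt(target_psd / peak_psd) if peak_psd > 0 else \
            np.zeros(n_ch)
        # taper episode edges to avoid clicks
        ramp = min(int(0.1 * fs), m // 4)
        win = np.ones(m)
        if ramp:
            edge = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
            win[:ramp] = edge
            win[-ramp:] = edge[::-1]
        phases = []
        for c, lag in enumerate(channel_phase_lags):
            dev = 0.0 if math.isinf(kappa) else float(rng.vonmises(0.0, kappa))
            phi = lag + dev
            out[c, i0:i1] += gains[c] * win * np.real(z * np.exp(1j * phi))
            phases.append(phi)
        log.append({"start_s": s0, "end_s": e0, "center_hz": fc,
                    "amplitude_db": amplitude_db, "phases_rad": phases})
    return out, log


# --------------------------------------------------------------------------
# full sessions
# --------------------------------------------------------------------------

def _channel_id(structure: str, hemisphere: str, k: int) -> str:
    return f"{structure}-{hemisphere[0].upper()}{k:02d}"


def generate_session(config: SyntheticSessionConfig) -> SyntheticSession:
    """Synthesize one multichannel session plus its ground-truth ledger."""
    fs = config.sampling_rate
    n = int(round(config.duration_s * fs))
    rng = np.random.default_rng(config.seed)
    cond_by_label = {c.label: c for c in config.conditions}

    chan_ids: list[str] = []
    chan_struct: list[tuple[str, str]] = []
    for structure, hemi in config.structures:
        for k in range(config.channels_per_structure):
            chan_ids.append(_channel_id(structure, hemi, k))
            chan_struct.append((structure, hemi))
    n_ch = len(chan_ids)
    samples = np.zeros((n_ch, n))
    ledger = GroundTruthLedger()

    # --- arrhythmic background, per condition epoch (exponent may differ) ---
    covered = np.zeros(n, dtype=bool)
    segments = [(lbl, s0, e0) for lbl, s0, e0 in config.condition_epochs]
    for lbl, s0, e0 in segments:
        i0, i1 = int(np.floor(s0 * fs)), int(np.floor(e0 * fs))
        covered[i0:i1] = True
        spec_c = cond_by_label[lbl]
        alpha = (spec_c.fractal_exponent if spec_c.fractal_exponent is not None
                 else config.fractal_exponent)
        ledger.entropy_regime[lbl] = alpha
        for c in range(n_ch):
            samples[c, i0:i1] = generate_fractal_signal(
                (i1 - i0) / fs, fs, alpha, config.fractal_scale, rng)
    # gaps between epochs: session-default background
    if not covered.all():
        gap_idx = np.flatnonzero(~covered)
        splits = np.split(gap_idx, np.flatnonzero(np.diff(gap_idx) > 1) + 1)
        for blk in splits:
            if blk.size == 0:
                continue
            for c in range(n_ch):
                samples[c, blk[0]:blk[-1] + 1] = generate_fractal_signal(
                    blk.size / fs, fs, config.fractal_exponent,
                    config.fractal_scale, rng)

    # oscillation gains: +1/2, -1/2 alternating within a structure so the
    # bipolar pair difference carries the oscillation at unit gain
    gains = np.where(np.arange(config.channels_per_structure) % 2 == 0, 0.5, -0.5)

    for lbl, s0, e0 in segments:
        spec_c = cond_by_label[lbl]
        i0 = int(np.floor(s0 * fs))
        epoch_len = int(np.floor(e0 * fs)) - i0
        for osc in spec_c.oscillations:
            if osc.amplitude_db <= 0:
                continue
            ledger.kappa[lbl] = osc.kappa
            if osc.episode_schedule is not None:
                schedule = list(osc.episode_schedule)
            else:
                schedule = draw_episode_schedule(
                    osc.episode_rate, epoch_len / fs, osc.episode_duration_s, rng)
            if not schedule:
                continue
            # arrhythmic reference PSD at band center, measured per structure
            # on its own bipolar background (difference of the first two
            # channels), so the dB target holds for every structure
            ref_per_channel = np.empty(n_ch)
            npc = config.channels_per_structure
            for si in range(len(config.structures)):
                c0 = si * npc
                ref_chan = (samples[c0, i0:i0 + epoch_len]
                            - samples[c0 + 1, i0:i0 + epoch_len])
                fgrid, pref = sps.welch(ref_chan, fs=fs, window="hann",
                                        nperseg=min(int(8 * fs), epoch_len),
                                        noverlap=min(int(4 * fs),
                                                     epoch_len // 2),
                                        detrend=False)
                band_sel = np.abs(fgrid - osc.band_center) <= max(
                    2.0, osc.bandwidth / 2)
                ref_per_channel[c0:c0 + npc] = float(np.mean(pref[band_sel]))

            structures = [s for s, _ in config.structures]
            lags = [osc.phase_lag_map.get(s, 0.0) for s, _ in config.structures]
            # one phase per structure, replicated over its channels
            struct_lags: list[float] = []
            for (s, h), lag in zip(config.structures, lags):
                struct_lags.extend([lag] * config.channels_per_structure)
            comp, log = generate_oscillatory_component(
                fs, epoch_len / fs, osc.band_center, osc.bandwidth,
                osc.amplitude_db, schedule,
                channel_phase_lags=struct_lags, kappa=osc.kappa, seed=rng,
                reference_psd=ref_per_channel,
                center_jitter_hz=osc.center_jitter_hz)
            g = np.tile(gains, len(config.structures))[:, None]
            samples[:, i0:i0 + epoch_len] += g * comp
            for ep in log:
                for c, cid in enumerate(chan_ids):
                    st, hm = chan_struct[c]
                    ledger.episodes.append({
                        "condition": lbl, "structure": st, "hemisphere": hm,
                        "channel_id": cid,
                        "start_s": s0 + ep["start_s"], "end_s": s0 + ep["end_s"],
                        "center_hz": ep["center_hz"],
                        "amplitude_db": ep["amplitude_db"],
                        "phase_rad": ep["phases_rad"][c]})
            for i, a in enumerate(structures):
                for b in structures[i + 1:]:
                    ledger.pair_lags[f"{a}|{b}"] = (
                        osc.phase_lag_map.get(a, 0.0) - osc.phase_lag_map.get(b, 0.0))

    epochs = pd.DataFrame(segments, columns=["label", "start_s", "end_s"])
    rec = Recording(samples=samples, fs=fs, channel_ids=chan_ids, epochs=epochs,
                    session=config.session, animal=config.animal)
    vocab = tuple(dict.fromkeys([s for s, _ in config.structures] + list(STRUCTURES)))
    cmap = ChannelMap(pd.DataFrame({
        "channel_id": chan_ids,
        "structure": [s for s, _ in chan_struct],
        "hemisphere": [h for _, h in chan_struct],
        "animal": config.animal, "session": config.session,
    }), vocabulary=vocab)
    return SyntheticSession(recording=rec, channel_map=cmap, ledger=ledger)


# --------------------------------------------------------------------------
# pose tracks
# --------------------------------------------------------------------------

def generate_pose_track(bout_schedule: list[tuple[float, float, float]],
                        duration_s: float, fps: float = 25.0,
                        arena_diameter_cm: float = 100.0,
                        turn_rate_deg_s: float = 0.0,
                        noise_cm: float = 0.0,
                        seed: int | np.random.Generator = 0,
                        body_parts: tuple[str, ...] = ("head", "body", "tailbase"),
                        ) -> PoseTrack:
    """Open-field centroid trajectory with scheduled locomotion bouts.

    ``bout_schedule`` entries are ``(start_s, end_s, speed_cm_s)``; between
    bouts the animal is stationary apart from per-part tracking jitter of
    standard deviation ``noise_cm``.  A constant ``turn_rate_deg_s`` rotates
    the heading during bouts (positive = counterclockwise), producing a
    controllable turning bias.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sched = sorted(bout_schedule)
    for (s0, e0, _), (s1, _, _) in zip(sched, sched[1:]):
        if s1 < e0:
            raise ValueError("bout schedule entries overlap")
    for s0, e0, v in sched:
        if not (0 <= s0 < e0 <= duration_s):
            raise ValueError("bout outside track duration")
        if v <= 0:
            raise ValueError("bout speed must be positive")
    n = int(round(duration_s * fps))
    dt = 1.0 / fps
    pos = np.zeros((n, 2))
    heading = 0.0
    r_max = arena_diameter_cm / 2.0 - 1.0
    xy = np.array([0.0, 0.0])
    omega = np.deg2rad(turn_rate_deg_s)
    in_bout = np.zeros(n, dtype=bool)
    speed_of = np.zeros(n)
    for s0, e0, v in sched:
        i0, i1 = int(round(s0 * fps)), int(round(e0 * fps))
        in_bout[i0:i1] = True
        speed_of[i0:i1] = v
    for i in range(n):
        pos[i] = xy
        if in_bout[i]:
            heading += omega * dt
            step = speed_of[i] * dt * np.array([np.cos(heading), np.sin(heading)])
            nxt = xy + step
            if np.hypot(*nxt) > r_max:         # steer back toward the center
                heading = math.atan2(-xy[1], -xy[0])
                nxt = xy + speed_of[i] * dt * np.array([np.cos(heading),
                                                        np.sin(heading)])
            xy = nxt
    # body parts: offsets along the instantaneous heading
    offsets = np.linspace(2.0, -2.0, len(body_parts))
    frames = {}
    for off, part in zip(offsets, body_parts):
        ox = pos[:, 0] + off * np.cos(heading)
        oy = pos[:, 1] + off * np.sin(heading)
        if noise_cm > 0:
            ox = ox + rng.normal(0, noise_cm, n)
            oy = oy + rng.normal(0, noise_cm, n)
        frames[(part, "x")] = ox
        frames[(part, "y")] = oy
    df = pd.DataFrame(frames)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["bodypart", "coord"])
    return PoseTrack(data=df, fps=fps)
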