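"""Synthetic sleep-EEG sessions with known ground truth.

The generator emulates the statistical structure the analysis assumes for
R6/1 (Huntington's-model) and wild-type mice:

* a semi-Markov alternation of four vigilance states (active wake, quiet
  wake, SWS, REM) with exponential dwell times and REM reachable only from
  SWS;
* a 1/f^2 aperiodic background on every electrophysiology channel;
* a hippocampal θ oscillation during REM and active wake, at a
  genotype-specific peak frequency (7.5 Hz wild-type, 6.75 Hz transgenic)
  with slow 5% frequency wander;
* a low-frequency-weighted 2–8 Hz broadband component during SWS on both
  brain channels;
* for transgenic mice past their β-onset age, Hann-enveloped β bursts on
  frontal and hippocampal channels whose rate, duration and amplitude grow
  as vigilance decreases (active wake < quiet wake <= SWS <= REM) and whose
  centre frequency falls / amplitude rises with age;
* EMG as Gaussian noise at a state-specific RMS, and a position random walk
  whose speed is state-dependent.

All randomness flows from a single integer seed (or Generator); identical
seeds give bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .errors import ConfigError
from .io import (
    ACTIVE_WAKE,
    QUIET_WAKE,
    REM,
    STATES,
    SWS,
    ClaspingRecord,
    Hypnogram,
    SessionRecording,
    write_clasping,
    write_manifest,
    write_session,
)

__all__ = [
    "BetaBurstParams",
    "GeneratorConfig",
    "simulate_state_sequence",
    "synthesize_signals",
    "simulate_session",
    "simulate_cohort",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class BetaBurstParams:
    """β-burst statistics for one vigilance state."""

    rate_per_min: float
    duration_mean_s: float
    amp_scale: float  # multiplies the age-dependent base amplitude


@dataclass
class GeneratorConfig:
    """All knobs of the session generator; use the genotype presets.

    Amplitudes are µV (RMS for noise components, peak for sinusoids);
    dwell means are seconds; ages are weeks.
    """

    genotype: str = "WT"
    age_weeks: float = 17.5
    fs_signal: float = 500.0
    fs_position: float = 50.0
    duration_s: float = 600.0

    # --- vigilance-state dynamics ------------------------------------
    dwell_mean_s: dict = field(
        default_factory=lambda: {ACTIVE_WAKE: 25.0, QUIET_WAKE: 15.0, SWS: 60.0, REM: 50.0}
    )
    transitions: dict = field(
        default_factory=lambda: {
            ACTIVE_WAKE: {QUIET_WAKE: 1.0},
            QUIET_WAKE: {ACTIVE_WAKE: 0.25, SWS: 0.75},
            SWS: {REM: 0.75, QUIET_WAKE: 0.15, ACTIVE_WAKE: 0.10},
            REM: {ACTIVE_WAKE: 0.5, QUIET_WAKE: 0.5},
        }
    )
    initial_state: str = ACTIVE_WAKE
    epoch_len_s: float = 2.0

    # --- oscillatory content -----------------------------------------
    theta_freq: float = 7.5
    theta_amp: dict = field(default_factory=lambda: {REM: 42.0, ACTIVE_WAKE: 32.0})
    theta_freq_jitter: float = 0.05  # relative slow wander of instantaneous freq
    theta_frontal_scale: float = 0.8  # volume-conducted θ share on the frontal channel
    sws_band: tuple = (2.0, 8.0)
    sws_amp: float = 65.0  # RMS of the SWS broadband component
    qw_delta_band: tuple = (2.0, 5.0)
    qw_delta_amp: float = 30.0  # hippocampal δ during quiet wake
    background_exponent: float = 2.0
    background_amp: float = 25.0  # RMS of the 1/f background

    # --- β bursts ------------------------------------------------------
    beta: dict = field(
        default_factory=lambda: {
            ACTIVE_WAKE: BetaBurstParams(0.0, 0.3, 0.3),
            QUIET_WAKE: BetaBurstParams(0.0, 0.6, 0.8),
            SWS: BetaBurstParams(0.0, 0.8, 1.4),
            REM: BetaBurstParams(0.0, 1.5, 1.7),
        }
    )
    beta_amp_base: float = 16.0  # peak envelope amplitude at age_young, µV
    beta_onset_weeks: float = np.inf  # bursts only at age >= onset
    # age model: centre frequency falls 27 -> 23 Hz, amplitude triples,
    # linearly between age_young and age_old
    beta_freq_young: float = 27.0
    beta_freq_old: float = 23.0
    beta_amp_gain_old: float = 3.0
    age_young: float = 9.0
    age_old: float = 26.0
    beta_hipp_scale: float = 0.7  # bursts are weaker on the hippocampal channel
    beta_edge_margin_s: float = 2.0  # bursts end at least this long before a state change

    # --- EMG & movement ------------------------------------------------
    emg_rms: dict = field(
        default_factory=lambda: {ACTIVE_WAKE: 40.0, QUIET_WAKE: 20.0, SWS: 10.0, REM: 5.0}
    )
    speed_mean: dict = field(
        default_factory=lambda: {ACTIVE_WAKE: 8.0, QUIET_WAKE: 0.0, SWS: 0.0, REM: 0.0}
    )
    position_jitter_cm: float = 0.01  # tracker noise per sample
    arena_cm: tuple = (33.0, 15.0)

    # --- longitudinal design -------------------------------------------
    session_ages_weeks: tuple = (9.0, 13.0, 17.0, 22.0, 26.0)
    beta_onset_range: tuple = (10.0, 19.0)
    clasp_lag_weeks: float = 6.67

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        for st in STATES:
            if self.dwell_mean_s.get(st, 0.0) <= 0:
                raise ConfigError(f"dwell mean for {st} must be positive")
            bp = self.beta[st]
            if bp.rate_per_min < 0 or bp.duration_mean_s < 0 or bp.amp_scale < 0:
                raise ConfigError("β burst parameters must be non-negative")
            if self.emg_rms.get(st, -1) < 0 or self.speed_mean.get(st, -1) < 0:
                raise ConfigError("EMG RMS and speeds must be non-negative")
        rates = {st: self.beta[st].rate_per_min for st in STATES}
        if self.genotype == "WT":
            if any(r > 0 for r in rates.values()):
                raise ConfigError("WT preset must have zero β burst rates")
        elif any(r > 0 for r in rates.values()):
            ok = (
                rates[ACTIVE_WAKE] < rates[QUIET_WAKE] <= rates[SWS] <= rates[REM]
            )
            if not ok:
                raise ConfigError(
                    "R6/1 β rates must satisfy ACTIVE_WAKE < QUIET_WAKE <= SWS <= REM"
                )
        self._check_reachability()

    def _check_reachability(self) -> None:
        reached = {self.initial_state}
        frontier = [self.initial_state]
        while frontier:
            st = frontier.pop()
            for nxt, p in self.transitions.get(st, {}).items():
                if p > 0 and nxt not in reached:
                    reached.add(nxt)
                    frontier.append(nxt)
        targets = {s for s in STATES if self.dwell_mean_s.get(s, 0) > 0}
        missing = targets - reached
        # absorbing single-state configs are legal (degenerate chains)
        if missing and len(self.transitions.get(self.initial_state, {})) > 0:
            raise ConfigError(f"states unreachable from {self.initial_state}: {sorted(missing)}")

    # --- age model -----------------------------------------------------
    def _age_frac(self, age_weeks: float) -> float:
        span = self.age_old - self.age_young
        return float(np.clip((age_weeks - self.age_young) / span, 0.0, 1.0))

    def beta_center_freq(self, age_weeks: float | None = None) -> float:
        """β burst centre frequency at `age_weeks` (default: config age)."""
        a = self._age_frac(self.age_weeks if age_weeks is None else age_weeks)
        return self.beta_freq_young + (self.beta_freq_old - self.beta_freq_young) * a

    def beta_amp(self, age_weeks: float | None = None) -> float:
        a = self._age_frac(self.age_weeks if age_weeks is None else age_weeks)
        return self.beta_amp_base * (1.0 + (self.beta_amp_gain_old - 1.0) * a)

    def beta_active(self) -> bool:
        return (
            self.genotype == "R6/1"
            and self.age_weeks >= self.beta_onset_weeks
            and any(self.beta[st].rate_per_min > 0 for st in STATES)
        )

    # --- presets --------------------------------------------------------
    @classmethod
    def wild_type(cls, age_weeks: float = 17.5, **kw) -> "GeneratorConfig":
        """Wild-type littermate: θ at 7.5 Hz, no β bursts ever."""
        return cls(genotype="WT", age_weeks=age_weeks, theta_freq=7.5, **kw)

    @classmethod
    def r61(cls, age_weeks: float, beta_onset_weeks: float = 10.0, **kw) -> "GeneratorConfig":
        """R6/1 transgenic: θ at 6.75 Hz; β bursts once past onset age."""
        beta = {
            ACTIVE_WAKE: BetaBurstParams(0.5, 0.3, 0.3),
            QUIET_WAKE: BetaBurstParams(12.0, 0.6, 0.8),
            SWS: BetaBurstParams(18.0, 0.8, 1.4),
            REM: BetaBurstParams(24.0, 1.5, 1.7),
        }
        kw.setdefault("beta", beta)
        return cls(
            genotype="R6/1",
            age_weeks=age_weeks,
            theta_freq=6.75,
            beta_onset_weeks=beta_onset_weeks,
            **kw,
        )

    @classmethod
    def r61_symptomatic(cls, **kw) -> "GeneratorConfig":
        """Mid-symptomatic transgenic preset: β centre frequency 25 Hz."""
        return cls.r61(age_weeks=17.5, **kw)


# ---------------------------------------------------------------------------
# State sequence


def sample_dwell(config: GeneratorConfig, state: str, rng: np.random.Generator) -> float:
    """One dwell time: epoch_len + Exp(mean − epoch_len), so the mean is the
    configured value and no bout is shorter than one epoch."""
    mean = config.dwell_mean_s[state]
    floor = min(config.epoch_len_s, mean)
    return floor + rng.exponential(max(mean - floor, 1e-12))


def simulate_state_sequence(config: GeneratorConfig, duration_s=None, seed=0) -> Hypnogram:
    """Semi-Markov vigilance-state sequence, quantized to the epoch grid.

    Epoch labels are the state occupying each epoch's midpoint.  REM is
    reachable only from SWS under the default transition graph.
    """
    rng = _as_rng(seed)
    duration = float(config.duration_s if duration_s is None else duration_s)
    if duration <= 0:
        raise ConfigError("duration must be positive")
    times, states = [], []
    t, st = 0.0, config.initial_state
    while t < duration:
        times.append(t)
        states.append(st)
        t += sample_dwell(config, st, rng)
        out = config.transitions.get(st, {})
        if not out:
            t = duration  # absorbing state
            break
        nxt = list(out)
        probs = np.array([out[k] for k in nxt], dtype=float)
        st = nxt[rng.choice(len(nxt), p=probs / probs.sum())]
    n_epochs = int(round(duration / config.epoch_len_s))
    mids = config.epoch_len_s * (np.arange(n_epochs) + 0.5)
    idx = np.searchsorted(np.asarray(times), mids, side="right") - 1
    labels = np.array(states, dtype="U11")[idx]
    return Hypnogram(labels, config.epoch_len_s, 0.0)


# ---------------------------------------------------------------------------
# Signal synthesis


def _shaped_noise(
    n: int,
    fs: float,
    rng: np.random.Generator,
    rms: float,
    band: tuple[float, float] | None = None,
    exponent: float = 0.0,
    f_floor: float = 0.5,
) -> np.ndarray:
    """Gaussian noise spectrally shaped as f^(−exponent/2) inside `band`."""
    if rms == 0.0:
        rng.standard_normal(n)  # keep the stream layout seed-stable
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.maximum(f, f_floor) ** (-exponent / 2.0)
    shape[0] = 0.0
    if band is not None:
        shape = shape * ((f >= band[0]) & (f <= band[1]))
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _state_gate(hyp: Hypnogram, states, n: int, fs: float, ramp_s: float = 0.25) -> np.ndarray:
    """Per-sample 0/1 gate for `states`, with edges softened over `ramp_s`."""
    if isinstance(states, str):
        states = (states,)
    per_epoch = np.isin(hyp.labels, list(states)).astype(float)
    reps = int(round(hyp.epoch_len_s * fs))
    g = np.repeat(per_epoch, reps)
    g = g[:n] if len(g) >= n else np.pad(g, (0, n - len(g)), mode="edge")
    size = max(1, int(round(ramp_s * fs)))
    return uniform_filter1d(g, size=size)


def _theta_trace(hyp, config, n, fs, rng):
    """Phase-continuous θ oscillator with slow relative frequency wander."""
    jitter = rng.standard_normal(n)
    jitter = uniform_filter1d(jitter, size=max(1, int(round(0.5 * fs))))
    sd = jitter.std()
    if sd > 0:
        jitter = jitter / sd
    inst_freq = config.theta_freq * (1.0 + config.theta_freq_jitter * jitter)
    phase = 2.0 * np.pi * np.cumsum(inst_freq) / fs
    amp = np.zeros(n)
    for st, a in config.theta_amp.items():
        if a:
            amp += a * _state_gate(hyp, st, n, fs)
    return amp * np.sin(phase + rng.uniform(0, 2 * np.pi))


def _beta_bursts(hyp, config, n, fs, rng):
    """Hann-enveloped β bursts; returns (trace, ground-truth DataFrame)."""
    trace = np.zeros(n)
    rows = []
    if not config.beta_active():
        return trace, pd.DataFrame(columns=["start_s", "end_s", "center_hz", "state"])
    f_c = config.beta_center_freq()
    base_amp = config.beta_amp()
    for state, run_start, run_end in hyp.runs():
        params = config.beta[state]
        if params.rate_per_min <= 0:
            continue
        run_start_eff = run_start + config.beta_edge_margin_s
        run_end_eff = run_end - config.beta_edge_margin_s
        run_len = run_end_eff - run_start_eff
        if run_len <= 0.4:
            continue
        k = rng.poisson(params.rate_per_min / 60.0 * run_len)
        if k == 0:
            continue
        starts = np.sort(rng.uniform(run_start_eff, run_end_eff, size=k))
        durs = np.clip(rng.exponential(params.duration_mean_s, size=k), 0.2, None)
        for s0, d in zip(starts, durs):
            e0 = min(s0 + d, run_end_eff)
            i0, i1 = int(round(s0 * fs)), int(round(e0 * fs))
            if i1 - i0 < 4 or i1 > n:
                continue
            env = np.hanning(i1 - i0)
            t = np.arange(i0, i1) / fs
            phase = rng.uniform(0, 2 * np.pi)
            trace[i0:i1] += (
                base_amp * params.amp_scale * env * np.sin(2 * np.pi * f_c * t + phase)
            )
            rows.append({"start_s": s0, "end_s": e0, "center_hz": f_c, "state": state})
    return trace, pd.DataFrame(rows, columns=["start_s", "end_s", "center_hz", "state"])


def _position_track(hyp, config, rng):
    """State-speed-driven random walk with reflecting arena walls."""
    fs = config.fs_position
    n = int(round(hyp.duration_s * fs))
    speed = np.zeros(n)
    for st, v in config.speed_mean.items():
        if v:
            speed += v * _state_gate(hyp, st, n, fs, ramp_s=0.5)
    heading = np.cumsum(rng.normal(0.0, 0.4, size=n))
    steps = speed[:, None] / fs * np.column_stack([np.cos(heading), np.sin(heading)])
    steps += rng.normal(0.0, config.position_jitter_cm, size=(n, 2))
    pos = np.cumsum(steps, axis=0) + np.asarray(config.arena_cm) / 2.0
    # reflect into the arena (triangle-wave fold)
    for j, width in enumerate(config.arena_cm):
        pos[:, j] = np.abs((pos[:, j] - width) % (2 * width) - width)
    return pos


def synthesize_signals(
    hyp: Hypnogram, config: GeneratorConfig, seed=0, mouse_id: str = "m0"
) -> tuple[SessionRecording, pd.DataFrame]:
    """Render a session's channels from a hypnogram and a config.

    Returns the recording and the ground-truth β burst table
    (columns start_s, end_s, center_hz, state).
    """
    fs = config.fs_signal
    if fs < 200:
        raise ConfigError("fs_signal must be >= 200 Hz (Nyquist margin over β)")
    rng = _as_rng(seed)
    n = int(round(hyp.duration_s * fs))

    def background():
        return _shaped_noise(
            n, fs, rng, config.background_amp, exponent=config.background_exponent
        )

    sws_gate = _state_gate(hyp, SWS, n, fs)
    qw_gate = _state_gate(hyp, QUIET_WAKE, n, fs)

    frontal = background()
    frontal += sws_gate * _shaped_noise(n, fs, rng, config.sws_amp, band=config.sws_band, exponent=2.0)
    hippo = background()
    hippo += sws_gate * _shaped_noise(n, fs, rng, config.sws_amp, band=config.sws_band, exponent=2.0)
    hippo += qw_gate * _shaped_noise(n, fs, rng, config.qw_delta_amp, band=config.qw_delta_band, exponent=2.0)
    theta = _theta_trace(hyp, config, n, fs, rng)
    hippo += theta
    frontal += config.theta_frontal_scale * theta  # volume conduction

    beta_trace, bursts = _beta_bursts(hyp, config, n, fs, rng)
    frontal += beta_trace
    hippo += config.beta_hipp_scale * beta_trace

    emg_rms = np.zeros(n)
    for st, r in config.emg_rms.items():
        if r:
            emg_rms += r * _state_gate(hyp, st, n, fs, ramp_s=0.1)
    emg = emg_rms * rng.standard_normal(n)

    position = _position_track(hyp, config, rng)

    rec = SessionRecording(
        mouse_id=mouse_id,
        genotype=config.genotype,
        age_weeks=config.age_weeks,
        channels={"frontal_eeg": frontal, "hippocampus_lfp": hippo, "emg": emg},
        fs_signal=fs,
        position=position,
        fs_position=config.fs_position,
        duration_s=hyp.duration_s,
    )
    return rec, bursts


def simulate_session(
    config: GeneratorConfig, seed=0, mouse_id: str = "m0"
) -> tuple[SessionRecording, Hypnogram, pd.DataFrame]:
    """State sequence + signals in one call (independent substreams)."""
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    rng_states, rng_signals = (np.random.default_rng(c) for c in ss.spawn(2))
    hyp = simulate_state_sequence(config, seed=rng_states)
    rec, bursts = synthesize_signals(hyp, config, seed=rng_signals, mouse_id=mouse_id)
    return rec, hyp, bursts


# ---------------------------------------------------------------------------
# Longitudinal cohort


def simulate_cohort(
    out_dir,
    n_r61: int = 10,
    n_wt: int = 8,
    session_ages_weeks=None,
    seed=0,
    base_config: GeneratorConfig | None = None,
) -> dict:
    """Write a full longitudinal cohort to `out_dir`.

    Per transgenic mouse a β-onset age is drawn uniformly from the
    configured range and the clasping age follows after a fixed lag.
    Bursts appear only in sessions at or past the onset age; wild-type
    mice never clasp and never show bursts.

    Returns a dict with the manifest DataFrame, clasping records,
    ground-truth onset table, burst table and hypnograms keyed by
    (mouse_id, age).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    template = base_config if base_config is not None else GeneratorConfig.r61_symptomatic()
    ages = tuple(
        template.session_ages_weeks if session_ages_weeks is None else session_ages_weeks
    )
    if len(ages) == 0:
        raise ConfigError("session age list is empty")
    if any(b <= a for a, b in zip(ages, ages[1:])):
        raise ConfigError("session ages must be strictly increasing")

    ss = np.random.SeedSequence(seed)
    rng_design = np.random.default_rng(ss.spawn(1)[0])
    lo, hi = template.beta_onset_range
    onsets = rng_design.uniform(lo, hi, size=n_r61)

    manifest_rows, onset_rows, burst_rows = [], [], []
    clasping, hypnograms = [], {}
    mice = [("R6/1", f"r61_{i:02d}", onsets[i]) for i in range(n_r61)]
    mice += [("WT", f"wt_{i:02d}", None) for i in range(n_wt)]

    session_seeds = iter(ss.spawn(len(mice) * len(ages)))
    for genotype, mouse_id, onset in mice:
        clasp_age = None if onset is None else onset + template.clasp_lag_weeks
        for age in ages:
            if genotype == "R6/1":
                beta = template.beta
                if not any(b.rate_per_min > 0 for b in beta.values()):
                    beta = GeneratorConfig.r61(age_weeks=age).beta
                cfg = replace(
                    template,
                    genotype="R6/1",
                    age_weeks=age,
                    theta_freq=6.75,
                    beta=beta,
                    beta_onset_weeks=onset,
                )
            else:
                wt_beta = {st: BetaBurstParams(0.0, b.duration_mean_s, b.amp_scale)
                           for st, b in template.beta.items()}
                cfg = replace(
                    template,
                    genotype="WT",
                    age_weeks=age,
                    theta_freq=7.5,
                    beta=wt_beta,
                    beta_onset_weeks=np.inf,
                )
            rec, hyp, bursts = simulate_session(cfg, seed=next(session_seeds), mouse_id=mouse_id)
            path = out_dir / f"{mouse_id}_{age:g}w.edf"
            write_session(rec, path)
            hypnograms[(mouse_id, age)] = hyp
            manifest_rows.append(
                {"mouse_id": mouse_id, "genotype": genotype, "age_weeks": age, "path": str(path)}
            )
            for _, b in bursts.iterrows():
                burst_rows.append({"mouse_id": mouse_id, "age_weeks": age, **b.to_dict()})
        obs = [(a, clasp_age is not None and a >= clasp_age) for a in ages]
        clasping.append(ClaspingRecord(mouse_id, obs))
        onset_rows.append(
            {
                "mouse_id": mouse_id,
                "beta_onset_weeks": np.nan if onset is None else onset,
                "clasp_onset_weeks": np.nan if clasp_age is None else clasp_age,
            }
        )

    manifest = pd.DataFrame(manifest_rows)
    onsets_df = pd.DataFrame(onset_rows)
    bursts_df = pd.DataFrame(
        burst_rows, columns=["mouse_id", "age_weeks", "start_s", "end_s", "center_hz", "state"]
    )
    meta = {"seed": seed}
    write_manifest(manifest, out_dir / "manifest.csv", meta)
    write_clasping(clasping, out_dir / "clasping.csv", meta)
    bursts_df.to_csv(out_dir / "bursts_truth.csv", index=False)
    onsets_df.to_csv(out_dir / "onsets_truth.csv", index=False)
    return {
        "manifest": manifest,
        "clasping": clasping,
        "onsets": onsets_df,
        "bursts": bursts_df,
        "hypnograms": hypnograms,
    }
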