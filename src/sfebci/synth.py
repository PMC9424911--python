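"""Synthetic annotated EEG sessions with the structure the decoder assumes.

The generator emulates the statistical contrasts the paradigm exploits:

* a stationary multichannel background (stable MVAR(6) plus 1/f-shaped
  noise) common to every state;
* eight distinguishable slight-facial-expression (sFE) classes, each a
  narrow-band oscillation inside the 5-50 Hz decoding band with its own
  spatial mixing pattern;
* an EMG-like broadband burst (white noise band-passed to 20-95 Hz with a
  150 ms rise envelope) concentrated on the frontal/temporal reference
  channels and scaled by an intensity gain -- "slight" expressions carry a
  small burst, "regular"-amplitude expressions a much larger one, which is
  what the screening step thresholds on;
* relaxing segments with large low-frequency frontal transients carrying
  little energy above 55 Hz, so screening lets them through while the ON
  detector labels them "else".

All randomness flows from one seed through per-trial spawned streams, so a
configuration reproduces byte-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_core import (
    EEGRecording,
    MONTAGE_30,
    REFERENCE_CHANNELS,
    SFE_CLASSES,
    StateInterval,
    bandpass_array,
)


@dataclass(frozen=True)
class ClassPattern:
    """Spatial mixing vector (unit norm) and center frequency of one sFE."""

    weights: np.ndarray
    center_hz: float


@dataclass
class SynthConfig:
    """Generator configuration; defaults define the study conditions.

    ``artifact_gain_regular / artifact_gain_slight`` must be >= 3: the
    regular-amplitude expressions have to dominate the 55-95 Hz screening
    band by a clear margin, which is the premise of the screening step.
    """

    n_channels: int = 30
    rate: float = 1000.0
    channels: tuple[str, ...] = MONTAGE_30
    artifact_gain_slight: float = 0.4
    artifact_gain_regular: float = 6.0
    background_order: int = 6
    noise_sd: float = 1.2          # MVAR innovation scale, uV
    pink_sd: float = 6.0           # 1/f background scale, uV
    osc_amp: float = 18.0          # sFE oscillation amplitude, uV
    burst_sd: float = 5.0          # EMG burst scale at gain 1, uV
    relax_amp: float = 30.0        # low-frequency frontal transient, uV
    seed: int = 0
    class_patterns: dict[str, ClassPattern] = field(default_factory=dict)
    artifact_channels_weight: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.artifact_gain_slight > 0 and (
            self.artifact_gain_regular / self.artifact_gain_slight < 3
        ):
            raise ValueError("regular/slight artifact gain ratio must be >= 3")
        if len(self.channels) != self.n_channels:
            raise ValueError("channel list length must equal n_channels")
        if self.artifact_channels_weight is None:
            w = np.full(self.n_channels, 0.02)
            for name in REFERENCE_CHANNELS:
                if name in self.channels:
                    w[self.channels.index(name)] = 1.0
            self.artifact_channels_weight = w
        if not self.class_patterns:
            self.class_patterns = _default_class_patterns(
                self.n_channels, np.random.default_rng(
                    np.random.SeedSequence([self.seed, 0xC1A55]))
            )


def _default_class_patterns(n_channels: int,
                            rng: np.random.Generator) -> dict[str, ClassPattern]:
    """Distinct unit-norm spatial vectors and spread center frequencies.

    Centers avoid the background alpha band (9-11 Hz) so class content is
    not confounded with the ongoing rhythm, and stay at or below 35 Hz:
    faster carriers are irregular enough at a 1000 Hz sampling rate to
    blur the sample-entropy contrast between brain and muscle components.
    The state-switching class (s-RB) sits in the quietest high region,
    mirroring its role as the most robustly decoded expression.
    """
    centers = {"s-RB": 35.0, "s-FB": 18.0, "s-LS": 13.0, "s-RS": 16.0,
               "s-OM": 27.0, "s-S": 30.0, "s-PM": 21.0, "s-DM": 24.0}
    ref_idx = [i for i, c in enumerate(MONTAGE_30[:n_channels])
               if c in REFERENCE_CHANNELS]
    patterns: dict[str, ClassPattern] = {}
    for name in SFE_CLASSES:
        v = rng.normal(size=n_channels)
        # expression-related activity concentrates over the facial muscles
        v[ref_idx] *= 3.0
        v /= np.linalg.norm(v)
        patterns[name] = ClassPattern(weights=v, center_hz=centers[name])
    return patterns


@dataclass(frozen=True)
class TrialPlan:
    """One trial: countdown, rest, sFE and relax segments (seconds)."""

    sfe_class: str
    countdown: float = 3.0
    rest: float = 4.0
    sfe: float = 4.0
    relax: float = 4.0

    @property
    def duration(self) -> float:
        return self.countdown + self.rest + self.sfe + self.relax


# ---------------------------------------------------------------------------
# Background model
# ---------------------------------------------------------------------------

def stable_random_mvar(n_channels: int, order: int,
                       rng: np.random.Generator,
                       radius: float = 0.8) -> list[np.ndarray]:
    """Random MVAR coefficient matrices rescaled to spectral radius ``radius``."""
    coeffs = [rng.normal(scale=0.15 / (r + 1), size=(n_channels, n_channels))
              for r in range(order)]
    rho = companion_spectral_radius(coeffs)
    if rho > 0:
        scale = radius / rho
        coeffs = [a * scale ** (r + 1) for r, a in enumerate(coeffs)]
    return coeffs


def companion_spectral_radius(coeffs: list[np.ndarray]) -> float:
    """Spectral radius of the companion matrix of an MVAR coefficient set."""
    ch = coeffs[0].shape[0]
    m = len(coeffs)
    comp = np.zeros((ch * m, ch * m))
    comp[:ch, :] = np.hstack(coeffs)
    if m > 1:
        comp[ch:, :-ch] = np.eye(ch * (m - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def simulate_mvar(coeffs: list[np.ndarray], n_samples: int,
                  rng: np.random.Generator, noise_sd: float = 1.0,
                  burn_in: int = 500) -> np.ndarray:
    """Realization (channels x samples) of a stable MVAR process."""
    ch = coeffs[0].shape[0]
    m = len(coeffs)
    total = n_samples + burn_in
    y = np.zeros((total, ch))
    w = rng.normal(scale=noise_sd, size=(total, ch))
    for n in range(total):
        acc = w[n].copy()
        for r, a in enumerate(coeffs, start=1):
            if n - r >= 0:
                acc += a @ y[n - r]
        y[n] = acc
    return y[burn_in:].T


def generate_known_mvar(coeffs: list[np.ndarray], n_samples: int,
                        seed: int, noise_sd: float = 1.0,
                        rate: float = 1000.0) -> EEGRecording:
    """Oracle input for MVAR fitting and connectivity tests."""
    if companion_spectral_radius(coeffs) >= 1.0:
        raise ValueError("MVAR specification is not stable (spectral radius >= 1)")
    rng = np.random.default_rng(seed)
    data = simulate_mvar(coeffs, n_samples, rng, noise_sd=noise_sd)
    names = [f"ch{i + 1}" for i in range(data.shape[0])]
    return EEGRecording(data, rate, names)


def _pink_noise(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Steep background noise (power ~ 1/f^2) via spectral shaping.

    The slope matches the strongly low-frequency-dominated spectrum of
    resting EEG; it is what keeps the 5-50 Hz band content smooth enough
    that its sample entropy sits below the EMG decision threshold.
    """
    ch, n = shape
    white = rng.normal(size=(ch, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz][0] / freqs[nz]
    out = np.fft.irfft(spec * scale, n=n, axis=1)
    sd = out.std()
    return out / sd if sd > 0 else out


class _BackgroundModel:
    """Config-level stationary EEG background.

    Four ingredients, mixed per channel with profiles fixed by the config
    seed:

    * a stable MVAR(order) process low-passed below 12 Hz -- carries the
      cross-channel directed structure the connectivity analysis sees;
    * slow 1/f drift (the bulk of the amplitude, as in resting EEG);
    * a narrow-band alpha (9-11 Hz) rhythm -- the fast end of the
      background spectrum is rhythmic, not broadband, which is what keeps
      the sample entropy of 5-50 Hz mode components below the EMG
      threshold (broadband content above ~18 Hz is irregular enough to
      cross it);
    * a small broadband 1/f noise floor.
    """

    def __init__(self, cfg: SynthConfig):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xB6]))
        self.coeffs = stable_random_mvar(cfg.n_channels, cfg.background_order,
                                         rng)
        self.alpha_amp = 2.5 * rng.uniform(0.6, 1.4, size=cfg.n_channels)
        self.cfg = cfg

    def _narrowband(self, band: tuple[float, float], n: int,
                    rng: np.random.Generator) -> np.ndarray:
        x = rng.normal(size=(self.cfg.n_channels, n))
        pad = min(500, n - 1)
        x = np.pad(x, ((0, 0), (pad, pad)), mode="reflect")
        x = bandpass_array(x, band, self.cfg.rate)[:, pad:pad + n]
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return x / sd

    def sample(self, n_samples: int, rng: np.random.Generator) -> np.ndarray:
        from scipy import signal as _sps

        bg = simulate_mvar(self.coeffs, n_samples, rng,
                           noise_sd=self.cfg.noise_sd)
        sos = _sps.butter(4, 12.0, btype="lowpass", fs=self.cfg.rate,
                          output="sos")
        bg = _sps.sosfiltfilt(sos, bg, axis=1)
        bg += self.cfg.pink_sd * _pink_noise(
            (self.cfg.n_channels, n_samples), rng)
        bg += self.alpha_amp[:, None] * self._narrowband((9.0, 11.0),
                                                         n_samples, rng)
        bg += 0.15 * rng.normal(size=bg.shape)  # sensor noise floor
        return bg


# ---------------------------------------------------------------------------
# Trial / session generation
# ---------------------------------------------------------------------------

def _rise_envelope(n: int, rate: float, rise_s: float = 0.15) -> np.ndarray:
    env = np.ones(n)
    k = min(n, int(round(rise_s * rate)))
    if k > 0:
        env[:k] = np.linspace(0.0, 1.0, k)
    return env


def _emg_burst(n: int, cfg: SynthConfig, gain: float,
               rng: np.random.Generator) -> np.ndarray:
    """Broadband 20-95 Hz burst weighted onto the reference channels."""
    if gain == 0 or n == 0:
        return np.zeros((cfg.n_channels, n))
    noise = rng.normal(scale=1.0, size=(1, n))
    pad = min(200, n - 1)
    padded = np.pad(noise, ((0, 0), (pad, pad)), mode="reflect")
    shaped = bandpass_array(padded, (20.0, 95.0), cfg.rate)[:, pad:pad + n]
    # per-channel independent high-band noise avoids rank-1 artifacts
    indep = rng.normal(scale=1.0, size=(cfg.n_channels, n))
    indep = bandpass_array(np.pad(indep, ((0, 0), (pad, pad)), mode="reflect"),
                           (20.0, 95.0), cfg.rate)[:, pad:pad + n]
    mix = 0.4 * shaped + 0.6 * indep
    env = _rise_envelope(n, cfg.rate)
    w = cfg.artifact_channels_weight[:, None]
    return cfg.burst_sd * gain * w * mix * env[None, :]


def _class_oscillation(n: int, cfg: SynthConfig, pattern: ClassPattern,
                       rng: np.random.Generator) -> np.ndarray:
    """Narrow-band oscillation at the class center frequency, AM-modulated."""
    t = np.arange(n) / cfg.rate
    phase = rng.uniform(0, 2 * np.pi)
    jitter = rng.normal(scale=0.3)
    carrier = np.sin(2 * np.pi * (pattern.center_hz + jitter) * t + phase)
    am = 1.0 + 0.2 * np.sin(2 * np.pi * rng.uniform(0.5, 1.5) * t
                            + rng.uniform(0, 2 * np.pi))
    env = _rise_envelope(n, cfg.rate)
    osc = cfg.osc_amp * carrier * am * env
    return pattern.weights[:, None] * osc[None, :]


def _relax_transients(n: int, cfg: SynthConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Slow (0.5-3 Hz) large frontal bumps emulating volunteer movement."""
    out = np.zeros((cfg.n_channels, n))
    t = np.arange(n) / cfg.rate
    frontal = [i for i, name in enumerate(cfg.channels)
               if name in ("Fp1", "Fp2", "F7", "F8")] or [0]
    n_events = rng.integers(2, 6)
    for _ in range(n_events):
        f = rng.uniform(0.5, 3.0)
        center = rng.uniform(0.1, max(0.2, n / cfg.rate - 0.1))
        width = rng.uniform(0.2, 0.6)
        bump = np.exp(-0.5 * ((t - center) / width) ** 2)
        wave = cfg.relax_amp * bump * np.sin(2 * np.pi * f * (t - center))
        ch = frontal[rng.integers(len(frontal))]
        out[ch] += wave
    return out


def generate_trial(plan: TrialPlan, cfg: SynthConfig,
                   intensity: str = "slight",
                   rng: np.random.Generator | None = None,
                   background: _BackgroundModel | None = None) -> EEGRecording:
    """One annotated trial: countdown+rest, expression, relax segments."""
    if plan.sfe_class not in cfg.class_patterns:
        raise ValueError(f"unknown sFE class {plan.sfe_class!r}")
    if intensity not in ("slight", "regular"):
        raise ValueError(f"intensity must be 'slight' or 'regular', got {intensity!r}")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7A1]))
    if background is None:
        background = _BackgroundModel(cfg)

    n_total = int(round(plan.duration * cfg.rate))
    data = background.sample(n_total, rng)

    i_rest_end = int(round((plan.countdown + plan.rest) * cfg.rate))
    i_sfe_end = int(round((plan.countdown + plan.rest + plan.sfe) * cfg.rate))

    gain = (cfg.artifact_gain_slight if intensity == "slight"
            else cfg.artifact_gain_regular)
    n_sfe = i_sfe_end - i_rest_end
    pattern = cfg.class_patterns[plan.sfe_class]
    data[:, i_rest_end:i_sfe_end] += _class_oscillation(n_sfe, cfg, pattern, rng)
    data[:, i_rest_end:i_sfe_end] += _emg_burst(n_sfe, cfg, gain, rng)
    data[:, i_sfe_end:] += _relax_transients(n_total - i_sfe_end, cfg, rng)

    state = ("sfe" if intensity == "slight" else "regularFE")
    annotations = [
        StateInterval(0.0, (plan.countdown + plan.rest), "rest"),
        StateInterval(plan.countdown + plan.rest,
                      plan.countdown + plan.rest + plan.sfe,
                      f"{state}:{plan.sfe_class}"),
        StateInterval(plan.countdown + plan.rest + plan.sfe, plan.duration,
                      "relax"),
    ]
    return EEGRecording(data, cfg.rate, list(cfg.channels), annotations)


def generate_session(classes: list[str], trials_per_class: int,
                     cfg: SynthConfig,
                     intensity: str = "slight") -> EEGRecording:
    """Concatenated trials in randomized (seeded) class order."""
    if not classes:
        raise ValueError("class list must not be empty")
    if trials_per_class < 1:
        raise ValueError("trials_per_class must be >= 1")
    for c in classes:
        if c not in cfg.class_patterns:
            raise ValueError(f"unknown sFE class {c!r}")

    order = [c for c in classes for _ in range(trials_per_class)]
    root = np.random.SeedSequence([cfg.seed, 0x5E55])
    shuffle_rng = np.random.default_rng(root.spawn(1)[0])
    shuffle_rng.shuffle(order)

    background = _BackgroundModel(cfg)
    streams = root.spawn(len(order) + 1)[1:]
    chunks: list[np.ndarray] = []
    annotations: list[StateInterval] = []
    t0 = 0.0
    for cls, ss in zip(order, streams):
        plan = TrialPlan(sfe_class=cls)
        trial = generate_trial(plan, cfg, intensity,
                               rng=np.random.default_rng(ss),
                               background=background)
        chunks.append(trial.data)
        for iv in trial.annotations:
            annotations.append(StateInterval(iv.start + t0, iv.end + t0,
                                             iv.label))
        t0 += plan.duration
    data = np.hstack(chunks)
    return EEGRecording(data, cfg.rate, list(cfg.channels), annotations)


def generate_scripted_stream(script: list[tuple[str, float]],
                             cfg: SynthConfig,
                             seed_offset: int = 0) -> EEGRecording:
    """Arbitrary state sequence for streaming tests.

    ``script`` is a list of (state, seconds) where state is ``rest``,
    ``relax``, ``sfe:<class>`` or ``regularFE:<class>``.  The background is
    continuous across segments; expression content is added per segment.
    """
    background = _BackgroundModel(cfg)
    root = np.random.SeedSequence([cfg.seed, 0x5C1, seed_offset])
    streams = root.spawn(len(script) + 1)
    bg_rng = np.random.default_rng(streams[0])
    n_total = int(round(sum(d for _, d in script) * cfg.rate))
    data = background.sample(n_total, bg_rng)

    annotations: list[StateInterval] = []
    t0 = 0.0
    i0 = 0
    for (state, dur), ss in zip(script, streams[1:]):
        rng = np.random.default_rng(ss)
        n = int(round(dur * cfg.rate))
        if state.startswith("sfe:") or state.startswith("regularFE:"):
            kind, cls = state.split(":", 1)
            if cls not in cfg.class_patterns:
                raise ValueError(f"unknown sFE class {cls!r}")
            gain = (cfg.artifact_gain_slight if kind == "sfe"
                    else cfg.artifact_gain_regular)
            pattern = cfg.class_patterns[cls]
            data[:, i0:i0 + n] += _class_oscillation(n, cfg, pattern, rng)
            data[:, i0:i0 + n] += _emg_burst(n, cfg, gain, rng)
        elif state == "relax":
            data[:, i0:i0 + n] += _relax_transients(n, cfg, rng)
        elif state != "rest":
            raise ValueError(f"unknown scripted state {state!r}")
        annotations.append(StateInterval(t0, t0 + dur, state))
        t0 += dur
        i0 += n
    return EEGRecording(data, cfg.rate, list(cfg.channels), annotations)


def windows_by_state(rec: EEGRecording, state_prefix: str,
                     length: int = 100, stride: int = 100,
                     band: tuple[float, float] | None = None) -> dict[str, np.ndarray]:
    """Stack 100 ms windows per annotation label matching ``state_prefix``.

    Returns {label: windows x channels x length}.  If ``band`` is given the
    whole recording is zero-phase filtered once before slicing so window
    edges carry no filter transients.
    """
    data = rec.data
    if band is not None:
        data = bandpass_array(data, band, rec.rate)
    out: dict[str, list[np.ndarray]] = {}
    for iv in rec.annotations:
        if not iv.label.startswith(state_prefix):
            continue
        i0 = int(round(iv.start * rec.rate))
        i1 = int(round(iv.end * rec.rate))
        for s in range(i0, i1 - length + 1, stride):
            out.setdefault(iv.label, []).append(data[:, s:s + length])
    return {k: np.stack(v) for k, v in out.items()}
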