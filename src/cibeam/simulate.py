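"""Synthetic acoustic scenes for the two-microphone array.

Stands in for a hardware measurement rig: a far-field plane wave from a
chosen incidence angle is "recorded" by two microphones 1 cm apart (the
rear signal lags by d cos(theta)/c, realized with a band-limited
fractional-delay interpolator), optionally with additive noise at a stated
SNR, and a time-domain delay-and-subtract beamformer whose empirical
probe-tone response validates the closed-form model in :mod:`cibeam.beam`.

Free-field plane-wave propagation only: no room reverberation, microphone
mismatch or self-noise.  Noise realizations are independent between the
microphones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .beam import ArrayConfig, BeamParams
from .filterbank import FilterBankSpec

__all__ = [
    "SceneConfig",
    "MicPair",
    "fractional_delay",
    "make_source",
    "simulate_plane_wave",
    "add_noise",
    "time_domain_beamform",
    "measure_tone_response",
    "simulate_scene",
]

SOURCE_KINDS = ("white_noise", "tone_set", "speech_like")
NOISE_KINDS = ("white", "lowpass_colored")


@dataclass(frozen=True)
class SceneConfig:
    """One acoustic scene: source angle, sampling, duration, noise."""

    theta_deg: float = 0.0
    fs: float = 16000.0
    duration: float = 1.0
    snr_db: float | None = None
    noise_kind: str = "white"
    seed: int = 0
    source_kind: str = "tone_set"

    def __post_init__(self) -> None:
        if self.fs < 16000:
            raise ValueError("sample rate must be at least 16 kHz (band plan tops at 7769 Hz)")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.noise_kind not in NOISE_KINDS:
            raise ValueError(f"noise_kind must be one of {NOISE_KINDS}")
        if self.source_kind not in SOURCE_KINDS:
            raise ValueError(f"source_kind must be one of {SOURCE_KINDS}")


@dataclass(frozen=True)
class MicPair:
    """Two equal-length microphone channels at sample rate ``fs``."""

    fs: float
    mic1: np.ndarray
    mic2: np.ndarray

    def __post_init__(self) -> None:
        if len(self.mic1) != len(self.mic2):
            raise ValueError("mic1 and mic2 must have equal length")
        if not (np.all(np.isfinite(self.mic1)) and np.all(np.isfinite(self.mic2))):
            raise ValueError("microphone signals must be finite")


def fractional_delay(x: np.ndarray, delay_samples: float, n_taps: int = 31,
                     kaiser_beta: float = 8.6) -> np.ndarray:
    """Delay ``x`` by a (possibly negative, non-integer) number of samples.

    Band-limited interpolation with a Kaiser-windowed sinc of ``n_taps``
    taps, normalized to unit DC gain.  The output has the same length as the
    input; samples shifted in from beyond the edges are zero.
    """
    x = np.asarray(x, dtype=float)
    n0 = int(np.floor(delay_samples))
    frac = float(delay_samples) - n0
    mid = (n_taps - 1) // 2
    if frac == 0.0:
        h = np.zeros(n_taps)
        h[mid] = 1.0
    else:
        k = np.arange(n_taps)
        h = np.sinc(k - mid - frac) * np.kaiser(n_taps, kaiser_beta)
        h /= h.sum()
    y = np.convolve(x, h, mode="full")
    # convolution delays by mid + frac; shift so the net delay is delay_samples
    pad = abs(n0) + n_taps
    y = np.concatenate([np.zeros(pad), y, np.zeros(pad)])
    start = pad + mid - n0
    return y[start:start + len(x)]


def make_source(kind: str, fs: float, duration: float, seed: int = 0,
                bank: FilterBankSpec | None = None, f0: float = 100.0) -> np.ndarray:
    """Deterministic (seeded) test sources.

    ``white_noise``
        flat-spectrum Gaussian noise, the roll-off probe signal.
    ``tone_set``
        equal-amplitude tones at the 8 filter-bank centre frequencies with
        seeded random phases.
    ``speech_like``
        harmonic complex (fundamental ``f0`` = 100 Hz) with flat amplitude
        up to 1 kHz and a -6 dB/octave tilt above, emulating the
        low-frequency concentration of speech spectra; seeded random phases.
    """
    n = int(round(fs * duration))
    if n <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    if kind == "white_noise":
        return rng.standard_normal(n)
    if kind == "tone_set":
        centers = (bank or FilterBankSpec.default_8()).centers
        phases = rng.uniform(0.0, 2.0 * np.pi, size=len(centers))
        return np.sum(np.sin(2.0 * np.pi * centers[:, None] * t[None, :]
                             + phases[:, None]), axis=0)
    if kind == "speech_like":
        harmonics = np.arange(1, int(min(7000.0, 0.45 * fs) // f0) + 1) * f0
        amps = np.where(harmonics <= 1000.0, 1.0, 1000.0 / harmonics)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=len(harmonics))
        x = np.sum(amps[:, None] * np.sin(2.0 * np.pi * harmonics[:, None] * t[None, :]
                                          + phases[:, None]), axis=0)
        return x / np.sqrt(np.mean(x**2))
    raise ValueError(f"unknown source kind {kind!r}; expected one of {SOURCE_KINDS}")


def simulate_plane_wave(source: np.ndarray, theta_deg: float, fs: float,
                        array: ArrayConfig | None = None) -> MicPair:
    """Record a far-field plane wave on both microphones.

    Microphone 1 sees the source as-is; microphone 2 sees it delayed by
    d cos(theta)/c seconds (negative for rear incidence, i.e. mic 2 leads).
    """
    array = array or ArrayConfig()
    source = np.asarray(source, dtype=float)
    delay_s = array.d * np.cos(np.deg2rad(theta_deg)) / array.c
    if abs(delay_s) >= len(source) / fs:
        raise ValueError("inter-microphone delay exceeds the signal duration")
    mic2 = fractional_delay(source, delay_s * fs)
    return MicPair(fs=fs, mic1=source.copy(), mic2=mic2)


def add_noise(pair: MicPair, snr_db: float | None, noise_kind: str = "white",
              seed: int = 0, cutoff_hz: float = 500.0) -> MicPair:
    """Add independent per-microphone noise at an exact SNR.

    The noise realization on each microphone is scaled so that the measured
    per-microphone SNR equals ``snr_db`` exactly.  ``lowpass_colored`` noise
    is white noise low-passed below ``cutoff_hz`` — a surrogate for car/fan
    noise, whose energy concentrates at low frequencies.  ``snr_db=None``
    returns the pair unchanged.
    """
    if snr_db is None:
        return pair
    if noise_kind not in NOISE_KINDS:
        raise ValueError(f"noise_kind must be one of {NOISE_KINDS}")
    rng = np.random.default_rng(seed)
    out = []
    for sig in (pair.mic1, pair.mic2):
        p_sig = float(np.mean(sig**2))
        if p_sig <= 0:
            raise ValueError("signal power must be positive to set an SNR")
        noise = rng.standard_normal(len(sig))
        if noise_kind == "lowpass_colored":
            sos = sps.butter(4, cutoff_hz, btype="lowpass", fs=pair.fs, output="sos")
            noise = sps.sosfilt(sos, noise)
        target_p = p_sig / 10.0 ** (snr_db / 10.0)
        noise *= np.sqrt(target_p / np.mean(noise**2))
        out.append(sig + noise)
    return MicPair(fs=pair.fs, mic1=out[0], mic2=out[1])


def time_domain_beamform(pair: MicPair, params: BeamParams,
                         array: ArrayConfig | None = None) -> np.ndarray:
    """Delay-and-subtract output y(t) = mic1(t) - beta * mic2(t - tau)."""
    return pair.mic1 - params.beta * fractional_delay(pair.mic2, params.tau * pair.fs)


def measure_tone_response(
    array: ArrayConfig,
    params: BeamParams,
    theta_deg: float,
    f: float,
    fs: float = 48000.0,
    duration: float = 0.4,
    settle: float = 0.1,
) -> float:
    """Empirical magnitude response via a pure-tone probe.

    Simulates a unit tone at incidence ``theta_deg``, beamforms it and
    returns the RMS ratio of output to source after discarding ``settle``
    seconds of interpolation transient at each end.
    """
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    tone = np.sin(2.0 * np.pi * f * t)
    pair = simulate_plane_wave(tone, theta_deg, fs, array)
    y = time_domain_beamform(pair, params, array)
    k = int(round(settle * fs))
    if n - 2 * k < 16:
        raise ValueError("duration too short for the requested settle time")
    sl = slice(k, n - k)
    return float(np.sqrt(np.mean(y[sl] ** 2) / np.mean(tone[sl] ** 2)))


def simulate_scene(scene: SceneConfig, array: ArrayConfig | None = None,
                   bank: FilterBankSpec | None = None) -> tuple[np.ndarray, MicPair]:
    """Build a full scene: source, plane-wave pair, optional noise.

    Returns ``(source, noisy_pair)``; the clean source doubles as the
    omnidirectional reference signal in evaluation pipelines.
    """
    array = array or ArrayConfig()
    source = make_source(scene.source_kind, scene.fs, scene.duration,
                         seed=scene.seed, bank=bank)
    pair = simulate_plane_wave(source, scene.theta_deg, scene.fs, array)
    pair = add_noise(pair, scene.snr_db, scene.noise_kind, seed=scene.seed + 1)
    return source, pair
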