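"""8-channel CI filter bank, envelope extraction and CIS modulation.

The evaluation chain mirrors a cochlear-implant CIS (continuous interleaved
sampling) front end: the broadband signal is split into 8 contiguous bands,
each band's envelope is extracted (full-wave rectification + low-pass), and
the envelopes amplitude-modulate sinusoids at the channel centre
frequencies.  The resulting "line spectrum" (one discrete component per
channel) is measured with the Welch PSD estimate, which is how the effect of
beamforming roll-off and of the per-channel compensation gains is judged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "FilterBankSpec",
    "ChannelEnvelopes",
    "CISLineSpectrum",
    "build_filter_bank",
    "apply_filter_bank",
    "extract_envelopes",
    "cis_modulate",
    "apply_channel_gains",
    "welch_psd",
    "line_spectrum",
    "psd_channel_errors",
]

# 8-channel CI band plan: (low edge, high edge, centre), Hz.  Centres are the
# device's printed values, kept as published even where they differ by <= 2 Hz
# from the arithmetic midpoint of the edges.
CI_8_CHANNEL_BANDS: tuple[tuple[float, float, float], ...] = (
    (156.0, 396.0, 274.0),
    (396.0, 639.0, 517.5),
    (639.0, 883.0, 761.0),
    (883.0, 1127.0, 1005.0),
    (1127.0, 1797.0, 1462.0),
    (1797.0, 2955.0, 2376.0),
    (2955.0, 4783.0, 3869.0),
    (4783.0, 7769.0, 6276.0),
)


@dataclass(frozen=True)
class FilterBankSpec:
    """Ordered, contiguous band plan of the CI filter bank."""

    channels: tuple[tuple[float, float, float], ...] = CI_8_CHANNEL_BANDS

    def __post_init__(self) -> None:
        for i, (lo, hi, cen) in enumerate(self.channels):
            if not (0 < lo < hi):
                raise ValueError(f"channel {i + 1}: edges must satisfy 0 < low < high")
            if not (lo < cen < hi):
                raise ValueError(f"channel {i + 1}: centre {cen} outside [{lo}, {hi}]")
            if i and self.channels[i - 1][1] != lo:
                raise ValueError(f"channel {i + 1}: bands must be contiguous")

    @classmethod
    def default_8(cls) -> "FilterBankSpec":
        return cls()

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def centers(self) -> np.ndarray:
        return np.array([c for _, _, c in self.channels])

    @property
    def edges(self) -> np.ndarray:
        """All band edges, length n_channels + 1."""
        return np.array([self.channels[0][0]] + [hi for _, hi, _ in self.channels])

    def reference_channel_index(self, target_hz: float = 1000.0) -> int:
        """Index of the channel whose centre is nearest ``target_hz``."""
        return int(np.argmin(np.abs(self.centers - target_hz)))


@dataclass(frozen=True)
class ChannelEnvelopes:
    """Per-channel nonnegative envelope sequences at sample rate ``fs``."""

    fs: float
    envelopes: np.ndarray  # shape (n_channels, n_samples)

    def __post_init__(self) -> None:
        if self.envelopes.ndim != 2:
            raise ValueError("envelopes must be a 2-D (n_channels, n_samples) array")
        if np.any(self.envelopes < 0):
            raise ValueError("envelopes must be nonnegative")

    @property
    def n_channels(self) -> int:
        return self.envelopes.shape[0]


@dataclass(frozen=True)
class CISLineSpectrum:
    """Amplitude of the discrete CIS component at each channel centre."""

    center_frequencies: np.ndarray
    amplitudes: np.ndarray  # linear power units
    db: bool = False

    def __post_init__(self) -> None:
        if len(self.center_frequencies) != len(self.amplitudes):
            raise ValueError("one amplitude per channel required")


def build_filter_bank(spec: FilterBankSpec, fs: float, order: int = 4) -> list[np.ndarray]:
    """Design one Butterworth band-pass (as SOS) per channel.

    The -3 dB points of each single-pass filter sit at the band edges.
    Requires ``fs/2`` above the highest band edge.
    """
    nyq = fs / 2.0
    top = spec.edges[-1]
    if nyq <= top:
        raise ValueError(
            f"sample rate {fs} Hz too low: Nyquist must exceed the top band edge {top} Hz"
        )
    return [
        sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
        for lo, hi, _ in spec.channels
    ]


def apply_filter_bank(x: np.ndarray, bank: list[np.ndarray]) -> np.ndarray:
    """Zero-phase filtering of ``x`` through every channel; rows are channels."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("input signal is empty")
    return np.stack([sps.sosfiltfilt(sos, x) for sos in bank])


def extract_envelopes(
    band_signals: np.ndarray,
    fs: float,
    cutoff_hz: float = 400.0,
    order: int = 2,
) -> ChannelEnvelopes:
    """Full-wave rectification followed by a zero-phase Butterworth low-pass.

    A 400 Hz envelope cutoff is standard CIS practice: it keeps the temporal
    modulations that carry speech information while removing the carrier.
    Zero-phase filtering can undershoot slightly below zero; the result is
    clipped at zero to keep envelopes physical.
    """
    band_signals = np.atleast_2d(np.asarray(band_signals, dtype=float))
    if band_signals.shape[-1] == 0:
        raise ValueError("input signal is empty")
    sos = sps.butter(order, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    env = sps.sosfiltfilt(sos, np.abs(band_signals), axis=-1)
    return ChannelEnvelopes(fs=fs, envelopes=np.maximum(env, 0.0))


def cis_modulate(envelopes: ChannelEnvelopes, spec: FilterBankSpec) -> np.ndarray:
    """Sum of sinusoids at the channel centres, each amplitude-modulated.

    output(t) = sum_i envelope_i(t) * sin(2 pi f_cen_i t); linear in the
    envelopes by construction.
    """
    if envelopes.n_channels != spec.n_channels:
        raise ValueError(
            f"envelope count {envelopes.n_channels} != channel count {spec.n_channels}"
        )
    n = envelopes.envelopes.shape[1]
    t = np.arange(n) / envelopes.fs
    carriers = np.sin(2.0 * np.pi * spec.centers[:, None] * t[None, :])
    return np.sum(envelopes.envelopes * carriers, axis=0)


def apply_channel_gains(envelopes: ChannelEnvelopes, gains) -> ChannelEnvelopes:
    """Scale each channel envelope by its compensation gain.

    ``gains`` is a positive array with one entry per channel, or any object
    with a ``gains`` attribute (e.g. :class:`cibeam.compensation.ChannelGains`).
    """
    g = np.asarray(getattr(gains, "gains", gains), dtype=float)
    if g.shape != (envelopes.n_channels,):
        raise ValueError(f"need {envelopes.n_channels} gains, got shape {g.shape}")
    if np.any(g <= 0):
        raise ValueError("channel gains must be positive")
    return ChannelEnvelopes(fs=envelopes.fs, envelopes=envelopes.envelopes * g[:, None])


def welch_psd(
    x: np.ndarray,
    fs: float,
    nperseg: int = 1024,
    noverlap: int | None = None,
    window: str = "hann",
):
    """Welch PSD estimate (averaged windowed periodograms, 50% overlap default)."""
    x = np.asarray(x, dtype=float)
    if x.size < nperseg:
        raise ValueError(f"signal length {x.size} shorter than segment length {nperseg}")
    if noverlap is None:
        noverlap = nperseg // 2
    return sps.welch(x, fs=fs, window=window, nperseg=nperseg, noverlap=noverlap)


def line_spectrum(
    x: np.ndarray,
    fs: float,
    spec: FilterBankSpec,
    nperseg: int = 1024,
    halfwidth_bins: int = 4,
) -> CISLineSpectrum:
    """Measure the CIS line amplitudes from a Welch PSD.

    Each line's power is integrated over ``halfwidth_bins`` bins either side
    of the bin nearest the channel centre, which makes the measurement
    insensitive to window scalloping when a centre falls between bins.
    """
    freqs, pxx = welch_psd(x, fs, nperseg=nperseg)
    amps = np.empty(spec.n_channels)
    for i, fc in enumerate(spec.centers):
        k = int(np.argmin(np.abs(freqs - fc)))
        lo, hi = max(k - halfwidth_bins, 0), min(k + halfwidth_bins + 1, len(pxx))
        amps[i] = float(np.sum(pxx[lo:hi]))
    return CISLineSpectrum(center_frequencies=spec.centers, amplitudes=amps)


def psd_channel_errors(test: CISLineSpectrum, reference: CISLineSpectrum) -> np.ndarray:
    """Per-channel dB difference after total line-power equalization.

    The test spectrum is first rescaled so its summed line power equals the
    reference's (overall level is irrelevant to the roll-off shape); the
    result is 10*log10(test_i / ref_i) per channel.
    """
    ref = np.asarray(reference.amplitudes, dtype=float)
    tst = np.asarray(test.amplitudes, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference line amplitudes must be positive")
    tst = tst * (np.sum(ref) / np.sum(tst))
    return 10.0 * np.log10(tst / ref)
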