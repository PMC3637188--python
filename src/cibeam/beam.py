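"""Closed-form response of the delay-and-subtract two-microphone array.

A first-order differential array records a far-field plane wave on two
microphones a distance ``d`` apart.  The rear signal is delayed by an
algorithm delay ``tau``, weighted by ``beta`` and subtracted from the front
signal, giving the narrowband magnitude response

    |H(theta, f)| = |1 - beta * exp(-j*2*pi*f*(d*cos(theta)/c + tau))|
                  = sqrt(1 + beta**2 - 2*beta*cos(2*pi*f*(d*cos(theta)/c + tau)))

where ``theta`` is the incidence angle measured from the endfire axis through
the two microphones and ``c`` is the speed of sound.  The family of canonical
first-order patterns is selected by the delay: dipole ``tau = 0``,
supercardioid ``tau = 0.342*d/c``, cardioid ``tau = d/c``.

The response is approximately proportional to ``f`` at low frequency (the
low-frequency roll-off that the :mod:`cibeam.compensation` module corrects),
and is bounded below by ``|1 - beta|``, the exact response at 0 Hz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ArrayConfig",
    "BeamParams",
    "BeamPattern",
    "system_response",
    "small_f_approximation",
    "response_lower_bound",
    "reciprocal_equivalent",
    "compute_beam_pattern",
    "normalize_pattern_at_dc",
    "far_field_min_distance",
    "far_field_cutoff_frequency",
]

#: Delay factor producing the supercardioid pattern (tau = 0.342 d / c).
SUPERCARDIOID_FACTOR = 0.342

_PATTERN_NAMES = ("dipolar", "supercardioid", "cardioid", "custom")


@dataclass(frozen=True)
class ArrayConfig:
    """Physical geometry of the two-microphone array.

    Parameters
    ----------
    d : float
        Inter-microphone distance in metres.  Default 0.01 m, the spacing
        practical for a cochlear-implant headpiece.
    c : float
        Speed of sound in m/s.  Default 340 m/s.
    """

    d: float = 0.01
    c: float = 340.0

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError(f"inter-microphone distance must be positive, got {self.d}")
        if not self.c > 0:
            raise ValueError(f"speed of sound must be positive, got {self.c}")

    @property
    def transit_delay(self) -> float:
        """Acoustic transit time d/c between the microphones, in seconds."""
        return self.d / self.c


@dataclass(frozen=True)
class BeamParams:
    """Delay ``tau`` (seconds) and weight ``beta`` defining one beam family."""

    tau: float
    beta: float = 1.0
    pattern_name: str = "custom"

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError(f"algorithm delay tau must be >= 0, got {self.tau}")
        if self.beta < 0:
            raise ValueError(f"weight beta must be >= 0, got {self.beta}")
        if self.pattern_name not in _PATTERN_NAMES:
            raise ValueError(
                f"pattern_name must be one of {_PATTERN_NAMES}, got {self.pattern_name!r}"
            )

    # -- named-pattern constructors ------------------------------------
    @classmethod
    def dipolar(cls, beta: float = 1.0) -> "BeamParams":
        return cls(tau=0.0, beta=beta, pattern_name="dipolar")

    @classmethod
    def supercardioid(cls, array: ArrayConfig, beta: float = 1.0) -> "BeamParams":
        return cls(tau=SUPERCARDIOID_FACTOR * array.transit_delay, beta=beta,
                   pattern_name="supercardioid")

    @classmethod
    def cardioid(cls, array: ArrayConfig, beta: float = 1.0) -> "BeamParams":
        return cls(tau=array.transit_delay, beta=beta, pattern_name="cardioid")

    @classmethod
    def from_pattern(cls, name: str, array: ArrayConfig, beta: float = 1.0) -> "BeamParams":
        if name == "dipolar":
            return cls.dipolar(beta)
        if name == "supercardioid":
            return cls.supercardioid(array, beta)
        if name == "cardioid":
            return cls.cardioid(array, beta)
        raise ValueError(f"unknown named pattern {name!r}")

    def validate_pattern(self, array: ArrayConfig, rtol: float = 1e-9) -> None:
        """Check that a named pattern's tau matches the array geometry."""
        expected = {
            "dipolar": 0.0,
            "supercardioid": SUPERCARDIOID_FACTOR * array.transit_delay,
            "cardioid": array.transit_delay,
        }.get(self.pattern_name)
        if expected is None:
            return
        if not np.isclose(self.tau, expected, rtol=rtol, atol=1e-15):
            raise ValueError(
                f"{self.pattern_name} pattern requires tau={expected:.6g} s "
                f"for this array, got {self.tau:.6g} s"
            )


def system_response(array: ArrayConfig, params: BeamParams, theta_deg, f):
    """Narrowband magnitude response |H| at incidence ``theta_deg`` and frequency ``f``.

    Broadcasts over ``theta_deg`` and ``f``.  ``f`` must be nonnegative;
    0 Hz is evaluated literally and equals ``|1 - beta|``.
    """
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be nonnegative")
    phase = 2.0 * np.pi * f * (array.d * np.cos(theta) / array.c + params.tau)
    mag_sq = 1.0 + params.beta**2 - 2.0 * params.beta * np.cos(phase)
    out = np.sqrt(np.maximum(mag_sq, 0.0))
    return out if out.ndim else float(out)


def small_f_approximation(array: ArrayConfig, params: BeamParams, theta_deg, f):
    """Low-frequency approximation 2*pi*f*|d cos(theta)/c + tau| for beta = 1.

    The equally-weighted response is 2|sin(pi f (d cos(theta)/c + tau))|,
    which is proportional to ``f`` as ``f -> 0``: the roll-off slope.
    """
    if params.beta != 1.0:
        raise ValueError("the small-frequency approximation holds for beta = 1 only")
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be nonnegative")
    out = 2.0 * np.pi * f * np.abs(array.d * np.cos(theta) / array.c + params.tau)
    return out if out.ndim else float(out)


def response_lower_bound(beta: float) -> float:
    """Infimum |1 - beta| of the response over all angles, frequencies and delays."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    return abs(1.0 - beta)


def reciprocal_equivalent(beta: float) -> tuple[float, float]:
    """Map a weight ``beta < 1`` to its reciprocal-equivalent weight and scale.

    The response family has a reciprocity: |H(beta)| = beta * |H(1/beta)|
    pointwise in (theta, f), so the normalized roll-off of ``beta`` and
    ``1/beta`` are identical.  Returns ``(1/beta, beta)``.
    """
    if beta <= 0:
        raise ValueError("beta must be positive; beta = 0 has no reciprocal equivalent")
    return 1.0 / beta, beta


@dataclass(frozen=True)
class BeamPattern:
    """Magnitude response on an angle grid, one row per frequency."""

    angles_deg: np.ndarray
    frequencies: np.ndarray
    magnitudes: np.ndarray  # shape (n_frequencies, n_angles)
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.magnitudes.shape != (len(self.frequencies), len(self.angles_deg)):
            raise ValueError("magnitudes must have shape (n_frequencies, n_angles)")
        if np.any(self.magnitudes < 0):
            raise ValueError("magnitudes must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: theta_deg column plus one column per frequency."""
        data = {"theta_deg": self.angles_deg}
        for f, row in zip(self.frequencies, self.magnitudes):
            data[f"{f:g}Hz"] = row
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "angles_deg": np.asarray(self.angles_deg).tolist(),
            "frequencies": np.asarray(self.frequencies).tolist(),
            "magnitudes": np.asarray(self.magnitudes).tolist(),
            "normalized": self.normalized,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def compute_beam_pattern(
    array: ArrayConfig,
    params: BeamParams,
    frequencies=None,
    angle_step: float = 1.0,
) -> BeamPattern:
    """Evaluate the response on the full [-180, 180] degree grid.

    ``frequencies`` defaults to the 8 centre frequencies of the CI filter
    bank.  ``angle_step`` (degrees) must divide 360.
    """
    if frequencies is None:
        from .filterbank import FilterBankSpec

        frequencies = FilterBankSpec.default_8().centers
    frequencies = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if frequencies.size == 0:
        raise ValueError("frequency list must not be empty")
    n = 360.0 / angle_step
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"angle_step must divide 360, got {angle_step}")
    angles = np.arange(-180.0, 180.0 + angle_step / 2, angle_step)
    mags = system_response(array, params, angles[None, :], frequencies[:, None])
    return BeamPattern(angles_deg=angles, frequencies=frequencies, magnitudes=mags)


def normalize_pattern_at_dc(pattern: BeamPattern, beta: float) -> BeamPattern:
    """Scale a pattern so that its 0 Hz level is 1.

    The 0 Hz response is ``|1 - beta|`` at every angle, so its circular
    average equals it; dividing by it puts every weight's pattern on a
    common low-frequency reference.  Degenerate for ``beta = 1``.
    """
    dc = response_lower_bound(beta)
    if dc == 0:
        raise ValueError("normalization is degenerate for beta = 1 (0 Hz response is 0)")
    return replace(pattern, magnitudes=pattern.magnitudes / dc, normalized=True)


def far_field_min_distance(f: float, c: float = 340.0):
    """Minimum source distance 2*c/f (two wavelengths) for plane-wave validity."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    out = 2.0 * c / f
    return out if out.ndim else float(out)


def far_field_cutoff_frequency(distance: float, c: float = 340.0) -> float:
    """Frequency above which a source at ``distance`` metres is far-field (2 lambda)."""
    if distance <= 0:
        raise ValueError("distance must be positive")
    return 2.0 * c / distance
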