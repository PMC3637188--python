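"""Piecewise-linear compensation of the low-frequency roll-off.

The on-axis (theta = 0) response of the delay-and-subtract array,

    H(beta, f) = sqrt(1 + beta^2 - 2 beta cos(2 pi f (d/c + tau))),

rolls off towards |1 - beta| at 0 Hz.  Over the speech band [0, f_max]
(f_max = 6000 Hz) the f->H curves form a nearly linear, equally spaced
family in the weight beta, which admits a two-segment linear model cheap
enough for a real-time CI speech processor:

* the 0 Hz intercept is exactly ``1 - beta`` (for beta <= 1);
* the f_max endpoint varies piecewise linearly in beta with a turning
  weight ``beta_turn`` at which the endpoint response is minimal
  (``beta_turn = cos(2 pi f_max (d/c + tau))`` clamped to [0, 1], which is
  0.45 to two decimals for the default geometry);
* the model ``H_eva(beta, f)`` is the straight line joining the two.

Accuracy is quantified by a relative error, an energy-normalized error
(after scaling the exact response by a coefficient G that balances signal
energy over [0, f_max]) and a per-weight average error.  The compensation
itself is a scalar gain per filter-bank channel referenced to the channel
near 1000 Hz, where speech energy peaks.

Weights beta > 1 are reduced to 1/beta through the reciprocity
|H(beta)| = beta |H(1/beta)| before linearization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beam import ArrayConfig, reciprocal_equivalent
from .filterbank import FilterBankSpec

__all__ = [
    "ExtrapolationWarning",
    "LinearizedModel",
    "ErrorReport",
    "ChannelGains",
    "find_turning_weight",
    "endpoint_response",
    "linearized_response",
    "relative_error",
    "normalization_coefficient",
    "normalized_error",
    "average_error",
    "error_report",
    "channel_gains",
]

DEFAULT_F_MAX = 6000.0
DEFAULT_BETA_STEP = 0.02
DEFAULT_F_STEP = 50.0
DEFAULT_N_AVERAGE = 50
DEFAULT_N_ENERGY = 1000


class ExtrapolationWarning(UserWarning):
    """Linearized response evaluated above its band limit f_max."""


def find_turning_weight(array: ArrayConfig | None = None, tau: float = 0.0,
                        f_max: float = DEFAULT_F_MAX) -> float:
    """Weight minimizing the exact on-axis response at ``f_max``.

    d/d(beta) [1 + beta^2 - 2 beta cos(phi)] = 0 gives beta = cos(phi) with
    phi = 2 pi f_max (d/c + tau), clamped to [0, 1].  Default geometry gives
    0.4457 (printed as 0.45 at two decimals).
    """
    if f_max < 0:
        raise ValueError("f_max must be nonnegative")
    array = array or ArrayConfig()
    phi = 2.0 * np.pi * f_max * (array.transit_delay + tau)
    return float(np.clip(np.cos(phi), 0.0, 1.0))


@dataclass(frozen=True)
class LinearizedModel:
    """Two-segment linear f->H model for one array geometry and delay.

    ``H2`` is the exact endpoint response at ``beta_turn`` and ``H3`` at
    beta = 1; the beta = 0 endpoint is identically 1 (``H1``).  By default
    ``beta_turn`` is the exact endpoint minimizer rounded to two decimals,
    the resolution at which the weight family is tabulated.
    """

    array: ArrayConfig = field(default_factory=ArrayConfig)
    tau: float = 0.0
    f_max: float = DEFAULT_F_MAX
    beta_turn: float = 0.45
    H2: float = 0.0
    H3: float = 0.0

    H1: float = 1.0

    @classmethod
    def from_array(
        cls,
        array: ArrayConfig | None = None,
        tau: float = 0.0,
        f_max: float = DEFAULT_F_MAX,
        beta_turn: float | None = None,
    ) -> "LinearizedModel":
        array = array or ArrayConfig()
        if beta_turn is None:
            beta_turn = round(find_turning_weight(array, tau, f_max), 2)
        if not 0.0 <= beta_turn <= 1.0:
            raise ValueError("beta_turn must lie in [0, 1]")
        phi = 2.0 * np.pi * f_max * (array.transit_delay + tau)
        h_exact = lambda b: float(np.sqrt(1.0 + b * b - 2.0 * b * np.cos(phi)))
        # beta_turn = 0 degenerates to a single segment from H1 to H3.
        h2 = h_exact(beta_turn) if beta_turn > 0 else 1.0
        return cls(array=array, tau=tau, f_max=f_max, beta_turn=beta_turn,
                   H2=h2, H3=h_exact(1.0))

    # -- exact on-axis response ----------------------------------------
    def exact_response(self, beta, f):
        """Exact |H| at theta = 0 for this geometry and delay."""
        f = np.asarray(f, dtype=float)
        phase = 2.0 * np.pi * f * (self.array.transit_delay + self.tau)
        out = np.sqrt(np.maximum(1.0 + beta**2 - 2.0 * beta * np.cos(phase), 0.0))
        return out if out.ndim else float(out)

    # -- model ----------------------------------------------------------
    def endpoint_response(self, beta: float) -> float:
        """Piecewise-linear-in-beta interpolation of the f_max endpoint."""
        if not 0.0 <= beta <= 1.0:
            raise ValueError(
                "endpoint model is defined for 0 <= beta <= 1; reduce larger "
                "weights with reciprocal_equivalent first"
            )
        bt = self.beta_turn
        if bt > 0 and beta <= bt:
            return 1.0 - (beta / bt) * (1.0 - self.H2)
        return self.H2 + (beta - bt) / (1.0 - bt) * (self.H3 - self.H2)

    def evaluate(self, beta: float, f, extrapolate: str = "warn"):
        """Linearized response H_eva(beta, f): the line from (0, |1-beta|) to
        (f_max, endpoint).  beta > 1 is reduced via reciprocity."""
        if beta < 0:
            raise ValueError("beta must be >= 0")
        if beta > 1.0:
            inv, scale = reciprocal_equivalent(beta)
            # reciprocity: H(beta) = beta * H(1/beta)
            return beta * self.evaluate(inv, f, extrapolate=extrapolate)
        f = np.asarray(f, dtype=float)
        if np.any(f > self.f_max):
            if extrapolate == "raise":
                raise ValueError(f"frequency above band limit f_max={self.f_max}")
            if extrapolate == "warn":
                warnings.warn(
                    f"evaluating linearized response above f_max={self.f_max:g} Hz",
                    ExtrapolationWarning,
                    stacklevel=2,
                )
        intercept = 1.0 - beta
        slope = (self.endpoint_response(beta) - intercept) / self.f_max
        out = intercept + slope * f
        return out if out.ndim else float(out)

    def slope_coefficients(self) -> dict[str, float]:
        """Closed-form coefficients of the model's frequency slope.

        For beta <= beta_turn the slope is ``low_beta * beta``; above it the
        slope is ``high_beta * beta - high_const``.  With the default
        geometry these are 1.278e-4, 2.145e-4 and 3.897e-5 (1/Hz).
        """
        bt, h2, h3, fm = self.beta_turn, self.H2, self.H3, self.f_max
        if bt <= 0:
            hb = (1.0 + (h3 - h2)) / fm
            return {"low_beta": hb, "high_beta": hb, "high_const": (1.0 - h2) / fm}
        low = (1.0 - (1.0 - h2) / bt) / fm
        if bt >= 1.0:
            return {"low_beta": low, "high_beta": low, "high_const": 0.0}
        high_beta = (1.0 + (h3 - h2) / (1.0 - bt)) / fm
        high_const = (1.0 + bt * (h3 - h2) / (1.0 - bt) - h2) / fm
        return {"low_beta": low, "high_beta": high_beta, "high_const": high_const}

    def to_dict(self) -> dict:
        return {
            "d": self.array.d,
            "c": self.array.c,
            "tau": self.tau,
            "f_max": self.f_max,
            "beta_turn": self.beta_turn,
            "H1": self.H1,
            "H2": self.H2,
            "H3": self.H3,
            "slope_coefficients": self.slope_coefficients(),
        }


# ---------------------------------------------------------------------------
# module-level operations (thin wrappers over the model)
# ---------------------------------------------------------------------------

def _default_model(model: LinearizedModel | None) -> LinearizedModel:
    return model if model is not None else LinearizedModel.from_array()


def endpoint_response(beta: float, model: LinearizedModel | None = None) -> float:
    return _default_model(model).endpoint_response(beta)


def linearized_response(beta: float, f, model: LinearizedModel | None = None,
                        extrapolate: str = "warn"):
    return _default_model(model).evaluate(beta, f, extrapolate=extrapolate)


def relative_error(beta: float, f, model: LinearizedModel | None = None,
                   on_zero: str = "raise"):
    """Relative error 100 (H_eva - H) / H in percent, at theta = 0.

    Undefined where the exact response vanishes (beta = 1, f = 0); that
    point raises by default, or yields NaN with ``on_zero='nan'``.
    """
    model = _default_model(model)
    h = np.asarray(model.exact_response(beta, f), dtype=float)
    h_eva = np.asarray(model.evaluate(beta, f, extrapolate="allow"), dtype=float)
    zero = h == 0.0
    if np.any(zero):
        if on_zero == "raise":
            raise ValueError("exact response is zero (beta = 1, f = 0): error undefined")
        h = np.where(zero, np.nan, h)
    out = 100.0 * (h_eva - h) / h
    return out if out.ndim else float(out)


def normalization_coefficient(beta: float, model: LinearizedModel | None = None,
                              n_points: int = DEFAULT_N_ENERGY) -> float:
    """Energy-balancing amplitude coefficient G(beta).

    G scales the exact response so that the energy of G*H matches the
    linearized response's energy over the uniform grid f_i = (i/N) f_max,
    i = 0..N:  G = sqrt(sum H_eva^2 / sum H^2).  G(0) = 1 exactly, and G
    converges quickly in N ("large N" regime well within 1e-3 by N = 500).
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    model = _default_model(model)
    f = np.arange(n_points + 1) / n_points * model.f_max
    h = model.exact_response(beta, f)
    h_eva = model.evaluate(beta, f, extrapolate="allow")
    denom = float(np.sum(h**2))
    if denom == 0.0:
        raise ValueError("exact response identically zero; G undefined")
    return float(np.sqrt(np.sum(np.asarray(h_eva) ** 2) / denom))


def normalized_error(beta: float, f, G: float | None = None,
                     model: LinearizedModel | None = None, on_zero: str = "raise"):
    """Energy-normalized error 100 (H_eva - G H) / H in percent."""
    model = _default_model(model)
    if G is None:
        G = normalization_coefficient(beta, model)
    h = np.asarray(model.exact_response(beta, f), dtype=float)
    h_eva = np.asarray(model.evaluate(beta, f, extrapolate="allow"), dtype=float)
    zero = h == 0.0
    if np.any(zero):
        if on_zero == "raise":
            raise ValueError("exact response is zero (beta = 1, f = 0): error undefined")
        h = np.where(zero, np.nan, h)
    out = 100.0 * (h_eva - G * h) / h
    return out if out.ndim else float(out)


def average_error(beta: float, model: LinearizedModel | None = None,
                  n_points: int = DEFAULT_N_AVERAGE,
                  n_points_energy: int = DEFAULT_N_ENERGY) -> float:
    """Mean normalized error over the N-point uniform frequency grid.

    The grid f_i = (i/N) f_max, i = 1..N excludes f = 0, where the error is
    undefined for beta = 1.  N defaults to 50.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    model = _default_model(model)
    G = normalization_coefficient(beta, model, n_points=n_points_energy)
    f = np.arange(1, n_points + 1) / n_points * model.f_max
    return float(np.mean(normalized_error(beta, f, G=G, model=model)))


@dataclass(frozen=True)
class ErrorReport:
    """Error surfaces of the linearization on a (beta, f) grid."""

    beta_grid: np.ndarray
    f_grid: np.ndarray
    relative_errors: np.ndarray    # percent, shape (n_beta, n_f)
    normalized_errors: np.ndarray  # percent, same shape
    G_values: np.ndarray           # one per beta
    average_errors: np.ndarray     # percent, one per beta
    tau: float

    def to_frames(self) -> dict[str, pd.DataFrame]:
        cols = [f"{f:g}Hz" for f in self.f_grid]
        rel = pd.DataFrame(self.relative_errors, index=self.beta_grid, columns=cols)
        nor = pd.DataFrame(self.normalized_errors, index=self.beta_grid, columns=cols)
        for df in (rel, nor):
            df.index.name = "beta"
        summary = pd.DataFrame(
            {"beta": self.beta_grid, "G": self.G_values,
             "average_error_pct": self.average_errors}
        )
        return {"relative": rel, "normalized": nor, "summary": summary}

    def to_csv(self, prefix) -> None:
        frames = self.to_frames()
        frames["relative"].to_csv(f"{prefix}_relative_error.csv")
        frames["normalized"].to_csv(f"{prefix}_normalized_error.csv")
        frames["summary"].to_csv(f"{prefix}_summary.csv", index=False)

    def to_json(self, path) -> None:
        payload = {
            "tau": self.tau,
            "beta_grid": self.beta_grid.tolist(),
            "f_grid": self.f_grid.tolist(),
            "relative_errors_pct": self.relative_errors.tolist(),
            "normalized_errors_pct": self.normalized_errors.tolist(),
            "G_values": self.G_values.tolist(),
            "average_errors_pct": self.average_errors.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def error_report(
    model: LinearizedModel | None = None,
    betas=None,
    freqs=None,
    n_points_average: int = DEFAULT_N_AVERAGE,
) -> ErrorReport:
    """Relative/normalized/average errors on the standard evaluation grid.

    Defaults: beta from 0 to 1 in steps of 0.02; f from 50 Hz to f_max in
    steps of 50 Hz (f = 0 excluded so the beta = 1 row stays defined).
    """
    model = _default_model(model)
    if betas is None:
        betas = np.round(np.arange(0.0, 1.0 + DEFAULT_BETA_STEP / 2, DEFAULT_BETA_STEP), 10)
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    if freqs is None:
        freqs = np.arange(DEFAULT_F_STEP, model.f_max + DEFAULT_F_STEP / 2, DEFAULT_F_STEP)
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(betas < 0) or np.any(betas > 1):
        raise ValueError("error grids are defined for beta in [0, 1]")

    rel = np.empty((betas.size, freqs.size))
    nor = np.empty_like(rel)
    gvals = np.empty(betas.size)
    avg = np.empty(betas.size)
    for i, b in enumerate(betas):
        gvals[i] = normalization_coefficient(b, model)
        rel[i] = relative_error(b, freqs, model=model)
        nor[i] = normalized_error(b, freqs, G=gvals[i], model=model)
        avg[i] = average_error(b, model=model, n_points=n_points_average)
    return ErrorReport(beta_grid=betas, f_grid=freqs, relative_errors=rel,
                       normalized_errors=nor, G_values=gvals, average_errors=avg,
                       tau=model.tau)


@dataclass(frozen=True)
class ChannelGains:
    """Per-channel compensation gains referenced to the ~1000 Hz channel."""

    reference_channel_index: int
    gains: np.ndarray
    mode: str  # "linearized" (model-based) or "ideal" (exact response)

    def __post_init__(self) -> None:
        if self.mode not in ("linearized", "ideal"):
            raise ValueError("mode must be 'linearized' or 'ideal'")
        if np.any(self.gains <= 0):
            raise ValueError("gains must be positive")

    def to_dict(self) -> dict:
        return {
            "reference_channel_index": self.reference_channel_index,
            "mode": self.mode,
            "gains": self.gains.tolist(),
        }


def channel_gains(
    beta: float,
    bank: FilterBankSpec | None = None,
    reference_channel: int | None = None,
    mode: str = "linearized",
    model: LinearizedModel | None = None,
) -> ChannelGains:
    """Roll-off compensation gain for each filter-bank channel.

    gain_i = R(f_cen_ref) / R(f_cen_i) with R the linearized model response
    (cheap, real-time) or the exact on-axis response ("ideal").  The
    reference channel defaults to the one centred nearest 1000 Hz, where
    speech energy is concentrated.  Centres above f_max (channel 8 of the
    default bank) use the model's linear extension, flagged by an
    :class:`ExtrapolationWarning`.
    """
    model = _default_model(model)
    bank = bank or FilterBankSpec.default_8()
    if reference_channel is None:
        reference_channel = bank.reference_channel_index()
    if not 0 <= reference_channel < bank.n_channels:
        raise ValueError(f"reference channel index {reference_channel} out of range")
    centers = bank.centers
    if mode == "linearized":
        resp = np.asarray(model.evaluate(beta, centers))
    elif mode == "ideal":
        resp = np.asarray(model.exact_response(beta, centers))
    else:
        raise ValueError("mode must be 'linearized' or 'ideal'")
    if np.any(resp == 0):
        raise ValueError("zero response at a channel centre; gains undefined")
    gains = resp[reference_channel] / resp
    return ChannelGains(reference_channel_index=reference_channel, gains=gains, mode=mode)
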