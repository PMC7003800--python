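"""Illumination protocols: static, sinusoidal and square-wave regimes.

All three kinds can deliver the same integrated photon dose — the
equal-dose contract that underlies the fluctuating-light comparisons —
when the duration spans whole modulation periods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "LightProtocol",
    "make_static",
    "make_sinusoidal",
    "make_square_wave",
]

KINDS = ("static", "sinusoidal", "square_wave")


@dataclass(frozen=True)
class LightProtocol:
    """Light intensity as a function of time, umol photons m-2 s-1.

    ``params`` are kind-specific:

    * static: ``intensity``
    * sinusoidal: ``mean``, ``amplitude``, ``period`` (starts at the
      minimum — simulations begin from darkness)
    * square_wave: ``low``, ``high``, ``period``, ``duty_fraction``
      (each period starts in the low phase)
    """

    kind: str
    duration: float  # s
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise InvalidParameterError(
                f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.duration < 0:
            raise InvalidParameterError(
                f"duration must be >= 0, got {self.duration}")

    # -- evaluation ---------------------------------------------------------

    def intensity(self, t: Union[float, np.ndarray]):
        """Intensity at time ``t`` (scalar or array), >= 0 everywhere."""
        p = self.params
        if self.kind == "static":
            return p["intensity"] * np.ones_like(t) if np.ndim(t) else p["intensity"]
        if self.kind == "sinusoidal":
            phase = 2.0 * np.pi * np.asarray(t, dtype=float) / p["period"]
            out = p["mean"] + p["amplitude"] * np.sin(phase - np.pi / 2.0)
            return out if np.ndim(t) else float(out)
        # square_wave: low phase first within each period
        frac = np.mod(np.asarray(t, dtype=float), p["period"]) / p["period"]
        out = np.where(frac < 1.0 - p["duty_fraction"], p["low"], p["high"])
        return out if np.ndim(t) else float(out)

    @property
    def total_dose(self) -> float:
        """Integrated photon dose over [0, duration], umol m-2 (closed form)."""
        p = self.params
        if self.kind == "static":
            return p["intensity"] * self.duration
        if self.kind == "sinusoidal":
            period, mean, amp = p["period"], p["mean"], p["amplitude"]
            n_full, rem = divmod(self.duration, period)
            dose = mean * n_full * period
            if rem > 0:  # integral of mean + amp*sin(w*t - pi/2) over [0, rem]
                w = 2.0 * math.pi / period
                dose += mean * rem - (amp / w) * math.sin(w * rem)
            return dose
        low, high, period, duty = p["low"], p["high"], p["period"], p["duty_fraction"]
        n_full, rem = divmod(self.duration, period)
        dose = (low * (1.0 - duty) + high * duty) * n_full * period
        if rem > 0:
            t_switch = (1.0 - duty) * period
            dose += low * min(rem, t_switch) + high * max(0.0, rem - t_switch)
        return dose

    @property
    def mean_intensity(self) -> float:
        return self.total_dose / self.duration if self.duration > 0 else 0.0

    def breakpoints(self) -> list:
        """Discontinuity times in (0, duration) the integrator must restart at."""
        if self.kind != "square_wave":
            return []
        period = self.params["period"]
        duty = self.params["duty_fraction"]
        pts = []
        k = 0
        while k * period < self.duration:
            for tp in (k * period, (k + 1.0 - duty) * period):
                if 0.0 < tp < self.duration:
                    pts.append(tp)
            k += 1
        return sorted(set(pts))

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {"kind": self.kind, "duration": self.duration, **self.params}

    @classmethod
    def from_dict(cls, d: dict) -> "LightProtocol":
        d = dict(d)
        kind = d.pop("kind", None)
        duration = d.pop("duration", None)
        d.pop("name", None)
        if kind == "static":
            return make_static(d.pop("intensity"), duration, **d)
        if kind == "sinusoidal":
            return make_sinusoidal(d.pop("mean"), d.pop("amplitude"),
                                   d.pop("period"), duration, **d)
        if kind == "square_wave":
            return make_square_wave(d.pop("low"), d.pop("high"), d.pop("period"),
                                    d.pop("duty_fraction"), duration, **d)
        raise InvalidParameterError(f"unknown protocol kind {kind!r}")


def make_static(intensity: float, duration: float) -> LightProtocol:
    """Constant illumination; dose = intensity * duration."""
    if intensity < 0:
        raise InvalidParameterError(f"intensity must be >= 0, got {intensity}")
    return LightProtocol("static", duration, {"intensity": float(intensity)})


def make_sinusoidal(mean: float, amplitude: float, period: float,
                    duration: float) -> LightProtocol:
    """Sinusoidal illumination starting at its minimum (mean - amplitude).

    Over whole periods the dose equals ``mean * duration`` — identical to a
    static protocol at ``mean``.
    """
    if not 0.0 <= amplitude <= mean:
        raise InvalidParameterError(
            f"need 0 <= amplitude <= mean for non-negative light, got "
            f"amplitude={amplitude}, mean={mean}")
    if period <= 0:
        raise InvalidParameterError(f"period must be > 0, got {period}")
    return LightProtocol("sinusoidal", duration,
                         {"mean": float(mean), "amplitude": float(amplitude),
                          "period": float(period)})


def make_square_wave(low: float, high: float, period: float,
                     duty_fraction: float, duration: float) -> LightProtocol:
    """Alternating low/high illumination (low phase first in each period).

    Mean intensity is ``low + duty_fraction * (high - low)``; over whole
    periods the dose matches a static protocol at that mean.
    """
    if not 0.0 <= low <= high:
        raise InvalidParameterError(
            f"need 0 <= low <= high, got low={low}, high={high}")
    if not 0.0 <= duty_fraction <= 1.0:
        raise InvalidParameterError(
            f"duty_fraction must lie in [0, 1], got {duty_fraction}")
    if period <= 0:
        raise InvalidParameterError(f"period must be > 0, got {period}")
    return LightProtocol("square_wave", duration,
                         {"low": float(low), "high": float(high),
                          "period": float(period),
                          "duty_fraction": float(duty_fraction)})
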