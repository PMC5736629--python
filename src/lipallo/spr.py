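"""Langmuir 1:1 surface plasmon resonance kinetics.

Pseudo-first-order binding of an analyte at constant concentration C to an
immobilised partner, ``dR/dt = kon*C*(Rmax - R) - koff*R``, has the closed
form

    association  (t <= t_a):  R(t) = Req * (1 - exp(-(kon*C + koff) * t)),
                              Req  = Rmax * C / (C + KD)
    dissociation (t >  t_a):  R(t) = R(t_a) * exp(-koff * (t - t_a))

with KD = koff/kon.  Mass-transport limitation, baseline drift and bulk
refractive-index jumps are not modelled; input traces are assumed reference-
and buffer-subtracted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .equilibrium import ValidationError

__all__ = [
    "KineticParams",
    "Sensorgram",
    "simulate_sensorgram",
    "LangmuirFitter",
    "fit_langmuir",
    "kd_from_rates",
]


@dataclass(frozen=True)
class KineticParams:
    """Langmuir 1:1 rate constants: kon (M^-1 s^-1), koff (s^-1), Rmax (RU)."""

    kon: float
    koff: float
    rmax: float

    def __post_init__(self) -> None:
        if self.kon <= 0 or self.koff <= 0 or self.rmax <= 0:
            raise ValidationError("kon, koff and Rmax must be positive")

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant KD = koff/kon (M)."""
        return self.koff / self.kon


@dataclass(frozen=True)
class Sensorgram:
    """One SPR trace: analyte concentration, times (s), response (RU)."""

    concentration: float
    times: np.ndarray
    response: np.ndarray
    t_assoc_end: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "response", np.asarray(self.response, dtype=float))
        if self.times.size != self.response.size:
            raise ValidationError("times and response must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if not np.all(np.isfinite(self.response)):
            raise ValidationError("response must be finite")


def _model_response(
    kon: float, koff: float, rmax: float, conc: float, times: np.ndarray, t_a: float
) -> np.ndarray:
    kd = koff / kon
    req = rmax * conc / (conc + kd) if conc > 0 else 0.0
    kobs = kon * conc + koff
    r = req * (1.0 - np.exp(-kobs * np.minimum(times, t_a)))
    dissoc = times > t_a
    if np.any(dissoc):
        r_ta = req * (1.0 - np.exp(-kobs * t_a))
        r[dissoc] = r_ta * np.exp(-koff * (times[dissoc] - t_a))
    return r


def simulate_sensorgram(
    p: KineticParams, concentration: float, times: Sequence[float], t_assoc_end: float
) -> Sensorgram:
    """Noise-free closed-form sensorgram at one analyte concentration."""
    if concentration < 0:
        raise ValidationError("analyte concentration must be >= 0")
    times = np.asarray(times, dtype=float)
    response = _model_response(
        p.kon, p.koff, p.rmax, concentration, times, t_assoc_end
    )
    return Sensorgram(
        concentration=concentration,
        times=times,
        response=response,
        t_assoc_end=t_assoc_end,
    )


class LangmuirFitter(BaseEstimator):
    """Global nonlinear least-squares Langmuir 1:1 fit across sensorgrams.

    (kon, koff) are optimised on the log10 scale with Rmax shared across all
    concentrations.  A single-concentration series is accepted with an
    identifiability warning (kon and Rmax are then correlated).

    Attributes (after ``fit``): ``kon_``, ``koff_``, ``rmax_``, ``kd_``,
    ``params_``.
    """

    def __init__(self, kon_guess: float = 1e4):
        self.kon_guess = kon_guess

    def fit(self, sensorgrams: Sequence[Sensorgram], y=None) -> "LangmuirFitter":
        grams = list(sensorgrams)
        if not grams:
            raise ValidationError("at least one sensorgram is required")
        r_all = np.concatenate([g.response for g in grams])
        if np.all(r_all == 0):
            raise ValidationError("all responses are zero; nothing to fit")
        if len({g.concentration for g in grams}) < 2:
            warnings.warn(
                "single analyte concentration: kon and Rmax are poorly identifiable",
                stacklevel=2,
            )

        def residuals(x: np.ndarray) -> np.ndarray:
            kon, koff = 10.0 ** x[0], 10.0 ** x[1]
            rmax = x[2]
            return np.concatenate(
                [
                    _model_response(
                        kon, koff, rmax, g.concentration, g.times, g.t_assoc_end
                    )
                    - g.response
                    for g in grams
                ]
            )

        rmax0 = max(float(r_all.max()) * 1.2, 1e-6)
        koff0 = _koff_from_tail(grams)
        best = None
        for kon0 in (self.kon_guess, self.kon_guess * 30, self.kon_guess / 30):
            x0 = np.array([np.log10(kon0), np.log10(koff0), rmax0])
            res = least_squares(
                residuals,
                x0,
                bounds=([-2, -8, 1e-9], [10, 4, np.inf]),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
            if best is None or res.cost < best.cost:
                best = res
        if best is None or not np.all(np.isfinite(best.x)):
            raise RuntimeError("Langmuir fit did not converge")
        self.kon_ = float(10.0 ** best.x[0])
        self.koff_ = float(10.0 ** best.x[1])
        self.rmax_ = float(best.x[2])
        self.kd_ = self.koff_ / self.kon_
        self.params_ = KineticParams(kon=self.kon_, koff=self.koff_, rmax=self.rmax_)
        return self

    def predict(self, sensorgrams: Sequence[Sensorgram]) -> list[np.ndarray]:
        p = self.params_
        return [
            _model_response(
                p.kon, p.koff, p.rmax, g.concentration, g.times, g.t_assoc_end
            )
            for g in sensorgrams
        ]


def _koff_from_tail(grams: Sequence[Sensorgram]) -> float:
    """Crude koff estimate from the log-linear dissociation tail of the largest trace."""
    g = max(grams, key=lambda s: float(np.max(np.abs(s.response))))
    mask = (g.times > g.t_assoc_end) & (g.response > 0)
    if mask.sum() >= 3:
        slope, _ = np.polyfit(g.times[mask], np.log(g.response[mask]), 1)
        if slope < 0:
            return float(-slope)
    return 1e-2


def fit_langmuir(sensorgrams: Sequence[Sensorgram], **options) -> KineticParams:
    """Thin functional wrapper around :class:`LangmuirFitter`."""
    return LangmuirFitter(**options).fit(sensorgrams).params_


def kd_from_rates(kon: float, koff: float) -> float:
    """KD = koff/kon (M)."""
    if kon <= 0:
        raise ValidationError("kon must be positive")
    if koff < 0:
        raise ValidationError("koff must be >= 0")
    return koff / kon
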