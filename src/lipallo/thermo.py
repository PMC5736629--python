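"""Binding thermodynamics from the temperature dependence of association constants.

The nonlinear van't Hoff model with a constant heat-capacity change dCp,

    ln K_A(T) = (dH_T0 - T0*dCp)/R * (1/T0 - 1/T)
              + dCp/R * ln(T/T0) + ln K0,

reduces to the classical linear van't Hoff line (ln K_A vs 1/T) when
dCp = 0.  A nonzero dCp curves the plot and signals conformational and/or
solvation changes accompanying binding.  The model is linear in the
transformed parameters a = (dH_T0 - T0*dCp)/R, b = dCp/R and c = ln K0, so
the fit on ln K_A is an exact linear least-squares problem; r^2 is reported
on the ln K_A scale.  Derived quantities: dG(T0) = -R*T0*ln K0 and
dS(T0) = (dH_T0 - dG(T0))/T0.

Gas constant R = 8.31446 J mol^-1 K^-1 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .equilibrium import ValidationError
from .titration import IdentifiabilityError, aggregate_replicates

__all__ = [
    "R_GAS",
    "ThermoParams",
    "VantHoffSeries",
    "VantHoffFitter",
    "VantHoffResult",
    "LinearVantHoffResult",
    "vant_hoff_ln_k",
    "vant_hoff_nonlinear",
    "vant_hoff_linear",
    "gibbs_from_k",
    "entropy_back_calc",
    "r_squared",
]

R_GAS = 8.31446  # J mol^-1 K^-1


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic parameters of binding at a reference temperature T0.

    ``dH_T0`` (J/mol), ``dCp`` (J/mol/K) and ``K0`` (M^-1, the association
    constant at T0) are the fitted quantities; ``dG_T0`` and ``dS_T0`` are
    derived identities and therefore always internally consistent.
    """

    dH_T0: float
    dCp: float
    K0: float
    T0: float = 298.0
    r2: float = float("nan")

    def __post_init__(self) -> None:
        if self.K0 <= 0:
            raise ValidationError("K0 must be positive")
        if self.T0 <= 0:
            raise ValidationError("T0 must be positive (kelvin)")

    @property
    def dG_T0(self) -> float:
        return -R_GAS * self.T0 * float(np.log(self.K0))

    @property
    def dS_T0(self) -> float:
        return (self.dH_T0 - self.dG_T0) / self.T0

    def ln_k(self, temperature) -> np.ndarray:
        return vant_hoff_ln_k(temperature, self.dH_T0, self.dCp, self.K0, self.T0)


def vant_hoff_ln_k(temperature, dH_T0: float, dCp: float, K0: float, T0: float = 298.0):
    """Forward nonlinear van't Hoff model: ln K_A at the given temperature(s)."""
    t = np.asarray(temperature, dtype=float)
    return (
        (dH_T0 - T0 * dCp) / R_GAS * (1.0 / T0 - 1.0 / t)
        + dCp / R_GAS * np.log(t / T0)
        + np.log(K0)
    )


@dataclass
class VantHoffSeries:
    """Replicated (temperature, association constant) measurements.

    ``data`` columns: ``replicate``, ``T_K``, ``K_A_per_M``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("replicate", "T_K", "K_A_per_M") if c not in self.data]
        if missing:
            raise ValidationError(f"van't Hoff table missing column(s): {missing}")
        if np.any(self.data["K_A_per_M"].to_numpy(dtype=float) <= 0):
            raise ValidationError("association constants must be positive")

    @classmethod
    def from_replicates(
        cls, replicates: Iterable[tuple[Sequence[float], Sequence[float]]]
    ) -> "VantHoffSeries":
        frames = [
            pd.DataFrame({"replicate": f"r{i + 1}", "T_K": t, "K_A_per_M": k})
            for i, (t, k) in enumerate(replicates)
        ]
        return cls(pd.concat(frames, ignore_index=True))

    def groups(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        out = []
        for rep, df in self.data.groupby("replicate"):
            out.append(
                (
                    str(rep),
                    df["T_K"].to_numpy(dtype=float),
                    df["K_A_per_M"].to_numpy(dtype=float),
                )
            )
        return out


def r_squared(obs: Sequence[float], pred: Sequence[float]) -> float:
    """Coefficient of determination ``1 - SS_res/SS_tot`` on the supplied scale.

    By convention a zero-variance target with (numerically) zero residuals is
    a perfect fit (r^2 = 1); zero variance with nonzero residuals is an error.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValidationError("obs and pred must have equal length >= 2")
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        scale = max(float(np.max(np.abs(obs))), 1.0)
        if ss_res <= (1e-12 * scale) ** 2 * obs.size:
            return 1.0
        raise ValidationError("zero total variance with nonzero residuals")
    return 1.0 - ss_res / ss_tot


class VantHoffFitter(BaseEstimator):
    """Nonlinear van't Hoff fit of one replicate's (T, K_A) measurements.

    The model is linear in ((dH - T0*dCp)/R, dCp/R, ln K0), so ``fit`` solves
    an exact least-squares problem on ln K_A.  Requires >= 4 distinct
    temperatures to constrain the three parameters.

    Attributes (after ``fit``): ``dH_``, ``dCp_``, ``K0_``, ``r2_``,
    ``thermo_`` (a :class:`ThermoParams`).
    """

    def __init__(self, T0: float = 298.0):
        self.T0 = T0

    def fit(self, temperature: Sequence[float], k_a: Sequence[float]) -> "VantHoffFitter":
        t = np.asarray(temperature, dtype=float)
        k = np.asarray(k_a, dtype=float)
        if np.unique(t).size < 4:
            raise IdentifiabilityError(
                "nonlinear van't Hoff needs >= 4 distinct temperatures"
            )
        if np.any(k <= 0):
            raise ValidationError("association constants must be positive")
        y = np.log(k)
        x1 = 1.0 / self.T0 - 1.0 / t
        x2 = np.log(t / self.T0)
        design = np.column_stack([x1, x2, np.ones_like(t)])
        coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rank < 3:
            raise ValidationError("singular van't Hoff design (degenerate temperatures)")
        a, b, c = coef
        self.dCp_ = float(R_GAS * b)
        self.dH_ = float(R_GAS * a + self.T0 * self.dCp_)
        self.K0_ = float(np.exp(c))
        self.r2_ = r_squared(y, design @ coef)
        self.thermo_ = ThermoParams(
            dH_T0=self.dH_, dCp=self.dCp_, K0=self.K0_, T0=self.T0, r2=self.r2_
        )
        return self

    def predict(self, temperature) -> np.ndarray:
        return self.thermo_.ln_k(temperature)


@dataclass
class VantHoffResult:
    """Replicate-aggregated nonlinear van't Hoff fit."""

    mean: ThermoParams
    per_replicate: list[ThermoParams]
    sem: dict[str, float] = field(default_factory=dict)


def vant_hoff_nonlinear(series: VantHoffSeries, T0: float = 298.0) -> VantHoffResult:
    """Fit each replicate, then aggregate parameters as mean +/- s.e.m.

    ``K0`` is averaged on the log scale (geometric mean), matching the scale
    the fit is performed on.
    """
    fits = [VantHoffFitter(T0=T0).fit(t, k).thermo_ for _, t, k in series.groups()]
    dh, dh_sem = aggregate_replicates([f.dH_T0 for f in fits])
    dcp, dcp_sem = aggregate_replicates([f.dCp for f in fits])
    lnk0, lnk0_sem = aggregate_replicates([np.log(f.K0) for f in fits])
    r2, r2_sem = aggregate_replicates([f.r2 for f in fits])
    mean = ThermoParams(dH_T0=dh, dCp=dcp, K0=float(np.exp(lnk0)), T0=T0, r2=r2)
    sem = {"dH_T0": dh_sem, "dCp": dcp_sem, "ln_K0": lnk0_sem, "r2": r2_sem}
    return VantHoffResult(mean=mean, per_replicate=fits, sem=sem)


@dataclass
class LinearVantHoffResult:
    dH: float
    dS: float
    r2: float
    per_replicate: list[tuple[float, float, float]] = field(default_factory=list)


def vant_hoff_linear(series: VantHoffSeries) -> LinearVantHoffResult:
    """Classical linear van't Hoff fit: OLS of ln K_A against 1/T.

    ``dH = -slope * R`` and ``dS = intercept * R``; assumes temperature-
    independent enthalpy (dCp = 0).  Fitted per replicate then averaged.
    """
    per_rep = []
    for _, t, k in series.groups():
        if np.unique(t).size < 2:
            raise IdentifiabilityError("linear van't Hoff needs >= 2 temperatures")
        y = np.log(k)
        x = 1.0 / t
        if np.ptp(y) == 0:
            slope, intercept = 0.0, float(y.mean())
        else:
            slope, intercept = np.polyfit(x, y, 1)
        r2 = r_squared(y, slope * x + intercept)
        per_rep.append((float(-slope * R_GAS), float(intercept * R_GAS), float(r2)))
    dh, _ = aggregate_replicates([p[0] for p in per_rep])
    ds, _ = aggregate_replicates([p[1] for p in per_rep])
    r2, _ = aggregate_replicates([p[2] for p in per_rep])
    return LinearVantHoffResult(dH=dh, dS=ds, r2=r2, per_replicate=per_rep)


def gibbs_from_k(k: float, temperature: float, kind: str = "association") -> float:
    """Binding free energy (J/mol): ``dG = -R*T*ln K_A = R*T*ln K_D``."""
    if k <= 0:
        raise ValidationError("equilibrium constant must be positive")
    if temperature <= 0:
        raise ValidationError("temperature must be positive (kelvin)")
    if kind == "association":
        return float(-R_GAS * temperature * np.log(k))
    if kind == "dissociation":
        return float(R_GAS * temperature * np.log(k))
    raise ValidationError(f"kind must be 'association' or 'dissociation', got {kind!r}")


def entropy_back_calc(dH: float, dG: float, temperature: float) -> float:
    """Binding entropy from enthalpy and free energy: ``dS = (dH - dG)/T``."""
    if temperature <= 0:
        raise ValidationError("temperature must be positive (kelvin)")
    return (dH - dG) / temperature
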