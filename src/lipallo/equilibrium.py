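"""Coupled binding equilibria for a membrane protein, a soluble partner, and lipids.

The model describes a membrane protein A (the trimeric ammonia channel AmtB,
treated as a single binding entity) that can bind one copy of a soluble
regulatory protein G (trimeric GlnK) and up to ``n_max`` lipids L.  Every
species is characterised by its lipid count ``n`` and whether G is bound:

* ``AL_n``  — A with n lipids, no G (``AL_0`` is apo A),
* ``AGL_n`` — the A-G complex with n lipids (``AGL_0`` is AG).

Three families of equilibrium association constants (M^-1) connect them:

* ``K_A,ALnG = [AL_n G] / ([AL_n][G])`` — G binding to A carrying n lipids
  (``K_A,AL0G`` is written ``K_A,AG``),
* ``K_A,ALn  = [AL_n] / ([AL_(n-1)][L])`` — the n-th lipid binding to A,
* ``K_A,AGLn = [AGL_n] / ([AGL_(n-1)][L])`` — the n-th lipid binding to AG.

The three are not independent: going around the thermodynamic cycle
A L_(n-1) -> AL_n -> AL_n G versus AL_(n-1) -> AL_(n-1)G -> AGL_n must give
the same free energy, so ``K_A,AGLn * K_A,AL(n-1)G = K_A,ALn * K_A,ALnG``.
The model is therefore parameterised by ``{K_A,AG, K_A,ALn, K_A,ALnG}`` and
``K_A,AGLn`` is derived (:func:`derived_agl_constants`).

Given free concentrations ``[G]`` and ``[L]``, the unnormalised statistical
weight of each species relative to apo A follows from mass action,

    w(AL_n)  = [L]^n * prod_{j<=n} K_A,ALj
    w(AGL_n) = K_A,ALnG * [G] * [L]^n * prod_{j<=n} K_A,ALj

and mole fractions are weights divided by the binding polynomial (the sum of
all weights).  :func:`compute_equilibrium` closes the system with the mass
balances for total A, G and L.

Apparent-constant semantics: the experiments fix a background nucleotide
(ADP, 50 uM) that is required for complex formation; its effect is folded
into the apparent constants rather than modelled as an explicit species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

__all__ = [
    "ValidationError",
    "ConvergenceError",
    "InconsistentFractionsError",
    "BindingModelParams",
    "Totals",
    "EquilibriumState",
    "SequentialBindingSpec",
    "compute_equilibrium",
    "mole_fractions_from_free",
    "free_concentrations_from_fractions",
    "derived_agl_constants",
    "sequential_binding_fractions",
]


class ValidationError(ValueError):
    """Invalid model parameters, totals, or observed fractions."""


class ConvergenceError(RuntimeError):
    """The free-concentration solver failed to converge."""


class InconsistentFractionsError(ValueError):
    """Observed fractions imply a negative free concentration."""


def _as_positive_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValidationError(f"{name} must be strictly positive and finite")
    return arr


@dataclass(frozen=True)
class BindingModelParams:
    """Equilibrium association constants of the coupled binding scheme.

    Parameters
    ----------
    k_ag : float
        ``K_A,AG`` (M^-1): G binding to lipid-free A.
    k_al : sequence of float, length n_max
        ``K_A,ALn`` (M^-1): the n-th lipid binding to A (n = 1..n_max).
    k_alng : sequence of float, length n_max
        ``K_A,ALnG`` (M^-1): G binding to A carrying n lipids (n = 1..n_max).
    """

    k_ag: float
    k_al: np.ndarray = field(default_factory=lambda: np.empty(0))
    k_alng: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if not math.isfinite(self.k_ag) or self.k_ag <= 0:
            raise ValidationError("k_ag must be strictly positive and finite")
        object.__setattr__(self, "k_al", _as_positive_array(self.k_al, "k_al"))
        object.__setattr__(self, "k_alng", _as_positive_array(self.k_alng, "k_alng"))
        if self.k_al.shape != self.k_alng.shape:
            raise ValidationError("k_al and k_alng must have equal length (n_max)")

    @property
    def n_max(self) -> int:
        return self.k_al.size

    @property
    def glnk_constants(self) -> np.ndarray:
        """``K_A,ALnG`` for n = 0..n_max (index 0 is ``K_A,AG``)."""
        return np.concatenate([[self.k_ag], self.k_alng])

    def log10(self) -> np.ndarray:
        """Flat log10 parameter vector ``[k_ag, k_al..., k_alng...]``."""
        return np.log10(np.concatenate([[self.k_ag], self.k_al, self.k_alng]))

    @classmethod
    def from_log10(cls, x: Sequence[float], n_max: int) -> "BindingModelParams":
        x = np.asarray(x, dtype=float)
        if x.size != 1 + 2 * n_max:
            raise ValidationError("log10 vector length must be 1 + 2*n_max")
        k = 10.0 ** x
        return cls(k_ag=k[0], k_al=k[1 : 1 + n_max], k_alng=k[1 + n_max :])


@dataclass(frozen=True)
class Totals:
    """Total concentrations (M; trimer units for the proteins) at one condition."""

    a_total: float
    g_total: float
    l_total: float
    temperature: float = 298.0

    def __post_init__(self) -> None:
        for name in ("a_total", "g_total", "l_total"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v!r}")
        if not math.isfinite(self.temperature) or self.temperature <= 0:
            raise ValidationError("temperature must be positive (kelvin)")


@dataclass(frozen=True)
class EquilibriumState:
    """Free concentrations and species mole fractions at one condition."""

    free_a: float
    free_g: float
    free_l: float
    f_al: np.ndarray
    f_agl: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "f_al", np.asarray(self.f_al, dtype=float))
        object.__setattr__(self, "f_agl", np.asarray(self.f_agl, dtype=float))

    @property
    def fraction_sum(self) -> float:
        return float(self.f_al.sum() + self.f_agl.sum())

    def bound_totals(self, totals: Totals) -> tuple[float, float, float]:
        """Recompute (A, G, L) totals implied by this state (conservation check)."""
        ns = np.arange(self.f_al.size)
        a = totals.a_total * self.fraction_sum
        g = self.free_g + totals.a_total * self.f_agl.sum()
        lipid = self.free_l + totals.a_total * (ns @ self.f_al + ns @ self.f_agl)
        return a, g, lipid


@dataclass(frozen=True)
class SequentialBindingSpec:
    """Sequential 1:m ligand binding described by stepwise dissociation constants.

    Models a protein P with m sequential ligand sites (e.g. the trimeric
    regulatory protein binding up to three nucleotides), given per-step
    ``K_D`` values (M) for events 1..m.
    """

    p_total: float
    stepwise_kd: np.ndarray
    l_total: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "stepwise_kd", _as_positive_array(self.stepwise_kd, "stepwise_kd")
        )
        if self.stepwise_kd.size < 1:
            raise ValidationError("at least one stepwise K_D is required")
        if self.p_total < 0 or self.l_total < 0:
            raise ValidationError("totals must be >= 0")


# ---------------------------------------------------------------------------
# Forward model


def _log_weights(
    params: BindingModelParams, free_g: float, free_l: float
) -> tuple[np.ndarray, np.ndarray]:
    """Log statistical weights of (AL_n, AGL_n) relative to apo A.

    Evaluated in log space so that large ``(K*L)^n`` products do not overflow.
    """
    n = params.n_max
    ns = np.arange(n + 1, dtype=float)
    cum_log_kal = np.concatenate([[0.0], np.cumsum(np.log(params.k_al))])
    pow_l = np.zeros(n + 1)
    if free_l > 0:
        pow_l = ns * np.log(free_l)
    else:
        pow_l[1:] = -np.inf
    log_w_al = cum_log_kal + pow_l
    if free_g > 0:
        log_w_agl = np.log(params.glnk_constants) + np.log(free_g) + log_w_al
    else:
        log_w_agl = np.full(n + 1, -np.inf)
    return log_w_al, log_w_agl


def mole_fractions_from_free(
    params: BindingModelParams, free_g: float, free_l: float
) -> tuple[np.ndarray, np.ndarray]:
    """Species mole fractions given free [G] and [L].

    Returns ``(f_al, f_agl)``, each of length ``n_max + 1`` (lipid count
    0..n_max), normalised by the binding polynomial so they sum to one.
    """
    if free_g < 0 or free_l < 0:
        raise ValidationError("free concentrations must be >= 0")
    log_w_al, log_w_agl = _log_weights(params, free_g, free_l)
    log_z = logsumexp(np.concatenate([log_w_al, log_w_agl]))
    f_al = np.exp(log_w_al - log_z)
    f_agl = np.exp(log_w_agl - log_z)
    if np.any(np.isnan(f_al)) or np.any(np.isnan(f_agl)):
        raise ConvergenceError("mole fraction evaluation produced NaN")
    return f_al, f_agl


def free_concentrations_from_fractions(
    totals: Totals,
    f_al: Sequence[float],
    f_agl: Sequence[float],
    sum_tol: float = 1e-6,
) -> tuple[float, float]:
    """Free [G] and [L] implied by observed mole fractions (mass balance).

    ``free_G = G_total - A_total * sum(F_AGLn)`` and
    ``free_L = L_total - A_total * (sum n*F_ALn + sum n*F_AGLn)``.
    Negative results are not clamped: they indicate fractions incompatible
    with the stated totals and raise :class:`InconsistentFractionsError`.
    """
    f_al = np.asarray(f_al, dtype=float)
    f_agl = np.asarray(f_agl, dtype=float)
    total = f_al.sum() + f_agl.sum()
    if abs(total - 1.0) > sum_tol:
        raise ValidationError(f"fractions must sum to 1 (got {total!r})")
    ns_al = np.arange(f_al.size)
    ns_agl = np.arange(f_agl.size)
    free_g = totals.g_total - totals.a_total * f_agl.sum()
    free_l = totals.l_total - totals.a_total * (ns_al @ f_al + ns_agl @ f_agl)
    if free_g < 0:
        raise InconsistentFractionsError(
            f"implied free G is negative ({free_g:.3e} M): fractions are "
            "incompatible with the stated totals"
        )
    if free_l < 0:
        raise InconsistentFractionsError(
            f"implied free L is negative ({free_l:.3e} M): fractions are "
            "incompatible with the stated totals"
        )
    return float(free_g), float(free_l)


def derived_agl_constants(params: BindingModelParams) -> np.ndarray:
    """Lipid-binding constants of the complex, ``K_A,AGLn`` for n = 1..n_max.

    Fixed by thermodynamic cycle closure:
    ``K_A,AGLn = K_A,ALn * K_A,ALnG / K_A,AL(n-1)G``.
    """
    glnk = params.glnk_constants
    return params.k_al * glnk[1:] / glnk[:-1]


# ---------------------------------------------------------------------------
# Self-consistent solver


def _bound_amounts(
    params: BindingModelParams, totals: Totals, g: float, lipid: float
) -> tuple[np.ndarray, np.ndarray, float, float]:
    f_al, f_agl = mole_fractions_from_free(params, g, lipid)
    ns = np.arange(f_al.size)
    bound_g = totals.a_total * f_agl.sum()
    bound_l = totals.a_total * (ns @ f_al + ns @ f_agl)
    return f_al, f_agl, bound_g, bound_l


def _solve_free_fixed_point(
    params: BindingModelParams,
    totals: Totals,
    rtol: float,
    max_iter: int,
) -> tuple[float, float] | None:
    """Damped fixed-point iteration on (free_G, free_L); None if it stalls."""
    gt, lt = totals.g_total, totals.l_total
    scale_g = max(gt, totals.a_total, 1e-300)
    scale_l = max(lt, totals.a_total, 1e-300)
    g, lipid = gt, lt
    damping = 0.5
    prev_res = math.inf
    for _ in range(max_iter):
        _, _, bound_g, bound_l = _bound_amounts(params, totals, g, lipid)
        res_g = g + bound_g - gt
        res_l = lipid + bound_l - lt
        res = abs(res_g) / scale_g + abs(res_l) / scale_l
        if res <= rtol:
            return g, lipid
        if res > prev_res:
            damping *= 0.5
            if damping < 1e-3:
                return None
        prev_res = res
        g = (1.0 - damping) * g + damping * max(gt - bound_g, 0.0)
        lipid = (1.0 - damping) * lipid + damping * max(lt - bound_l, 0.0)
    return None


def _solve_free_bisection(
    params: BindingModelParams, totals: Totals, xtol: float
) -> tuple[float, float]:
    """Nested bounded root finding: outer on free L, inner on free G.

    Both residuals are monotone in their own variable (binding polynomials
    are monotone in the free concentrations), so the bracketed roots are the
    unique physical solution.
    """
    gt, lt = totals.g_total, totals.l_total

    def solve_g(lipid: float) -> float:
        if gt == 0:
            return 0.0

        def res_g(g: float) -> float:
            _, _, bound_g, _ = _bound_amounts(params, totals, g, lipid)
            return g + bound_g - gt

        if res_g(gt) <= 0:
            return gt
        return brentq(res_g, 0.0, gt, xtol=xtol * max(gt, 1e-300), rtol=1e-15)

    if lt == 0:
        return solve_g(0.0), 0.0

    def res_l(lipid: float) -> float:
        g = solve_g(lipid)
        _, _, _, bound_l = _bound_amounts(params, totals, g, lipid)
        return lipid + bound_l - lt

    if res_l(lt) <= 0:
        lipid = lt
    else:
        lipid = brentq(res_l, 0.0, lt, xtol=xtol * max(lt, 1e-300), rtol=1e-15)
    return solve_g(lipid), lipid


def compute_equilibrium(
    params: BindingModelParams,
    totals: Totals,
    mode: str = "self_consistent",
    observed: tuple[Sequence[float], Sequence[float]] | None = None,
    rtol: float = 1e-12,
    max_iter: int = 2000,
) -> EquilibriumState:
    """Solve the coupled equilibria at one titration condition.

    Parameters
    ----------
    mode : {"self_consistent", "measured_fractions"}
        ``self_consistent`` finds the unique free-concentration root of the
        mass-balance system (damped fixed-point iteration with a bounded
        root-finding fallback).  ``measured_fractions`` takes free [G] and
        [L] from *observed* mole fractions via the mass balances and then
        evaluates the model fractions at those free concentrations — the
        mode used when fitting experimental data.
    observed : (f_al, f_agl), required for ``measured_fractions``.
    """
    if not isinstance(params, BindingModelParams):
        params = BindingModelParams(*params)
    if mode == "measured_fractions":
        if observed is None:
            raise ValidationError("measured_fractions mode requires observed fractions")
        free_g, free_l = free_concentrations_from_fractions(totals, *observed)
    elif mode == "self_consistent":
        sol = _solve_free_fixed_point(params, totals, rtol=rtol, max_iter=max_iter)
        if sol is None:
            try:
                sol = _solve_free_bisection(params, totals, xtol=rtol)
            except Exception as exc:  # pragma: no cover - defensive
                raise ConvergenceError(
                    f"free-concentration solver failed at totals {totals}"
                ) from exc
        free_g, free_l = sol
    else:
        raise ValidationError(f"unknown solver mode {mode!r}")

    f_al, f_agl = mole_fractions_from_free(params, free_g, free_l)
    free_a = totals.a_total * f_al[0]
    return EquilibriumState(
        free_a=float(free_a),
        free_g=float(free_g),
        free_l=float(free_l),
        f_al=f_al,
        f_agl=f_agl,
    )


# ---------------------------------------------------------------------------
# Sequential (stepwise) binding, used for nucleotide occupancy predictions


def sequential_binding_fractions(spec: SequentialBindingSpec) -> np.ndarray:
    """Mole fractions of P(L)_0..m under stepwise binding with free-ligand mass balance.

    The weight of the k-ligand state relative to apo is
    ``prod_{j<=k} [L]/K_D,j``; free [L] is solved self-consistently from
    ``[L] + P_total * sum_k k*F_k = L_total``.
    """
    kds = spec.stepwise_kd
    m = kds.size
    ks = np.arange(m + 1, dtype=float)

    def fractions(lipid: float) -> np.ndarray:
        if lipid == 0:
            out = np.zeros(m + 1)
            out[0] = 1.0
            return out
        log_w = np.concatenate([[0.0], np.cumsum(np.log(lipid) - np.log(kds))])
        return np.exp(log_w - logsumexp(log_w))

    if spec.l_total == 0:
        return fractions(0.0)

    def residual(lipid: float) -> float:
        return lipid + spec.p_total * (ks @ fractions(lipid)) - spec.l_total

    if residual(spec.l_total) <= 0:
        free_l = spec.l_total
    else:
        free_l = brentq(
            residual, 0.0, spec.l_total, xtol=1e-15 * max(spec.l_total, 1e-300)
        )
    return fractions(free_l)
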