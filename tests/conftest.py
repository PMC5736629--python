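"""Shared fixtures and independent brute-force oracles.

The oracle solves the coupled equilibria by nested interval bisection on the
free concentrations, with statistical weights evaluated in plain linear
arithmetic — an implementation path deliberately disjoint from the package's
log-space damped fixed-point solver.
"""

from __future__ import annotations

import numpy as np
import pytest

from lipallo.equilibrium import BindingModelParams, Totals


def bisect(f, lo: float, hi: float, iters: int = 80) -> float:
    """Plain interval bisection assuming f(lo) <= 0 <= f(hi)."""
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def oracle_fractions(k_ag, k_al, k_alng, free_g, free_l):
    """Mole fractions from mass-action weights, linear arithmetic."""
    n = len(k_al)
    w_al = [1.0]
    for j in range(n):
        w_al.append(w_al[-1] * k_al[j] * free_l)
    glnk = [k_ag] + list(k_alng)
    w_agl = [glnk[m] * free_g * w_al[m] for m in range(n + 1)]
    z = sum(w_al) + sum(w_agl)
    return np.array(w_al) / z, np.array(w_agl) / z


def oracle_equilibrium(k_ag, k_al, k_alng, a_total, g_total, l_total, iters=80):
    """Nested-bisection solution of the mass-balance system."""

    def bound(g, lipid):
        f_al, f_agl = oracle_fractions(k_ag, k_al, k_alng, g, lipid)
        ns = np.arange(f_al.size)
        return a_total * f_agl.sum(), a_total * (ns @ f_al + ns @ f_agl)

    def solve_g(lipid):
        if g_total == 0:
            return 0.0
        return bisect(lambda g: g + bound(g, lipid)[0] - g_total, 0.0, g_total, iters)

    if l_total == 0:
        free_l = 0.0
    else:
        free_l = bisect(
            lambda lipid: lipid + bound(solve_g(lipid), lipid)[1] - l_total,
            0.0,
            l_total,
            iters,
        )
    free_g = solve_g(free_l)
    f_al, f_agl = oracle_fractions(k_ag, k_al, k_alng, free_g, free_l)
    return free_g, free_l, f_al, f_agl


def two_state_closed_form(k_a, a_total, g_total):
    """Quadratic closed form for A + G <-> AG: returns (F_A, F_AG, free_G)."""
    kd = 1.0 / k_a
    b = a_total + g_total + kd
    ag = (b - np.sqrt(b * b - 4 * a_total * g_total)) / 2.0
    return (a_total - ag) / a_total, ag / a_total, g_total - ag


def random_system(rng: np.random.Generator, n_max: int):
    """A random coupled system: (params, totals) over realistic ranges."""
    k = 10.0 ** rng.uniform(3.0, 8.0, size=1 + 2 * n_max)
    params = BindingModelParams(
        k_ag=k[0], k_al=k[1 : 1 + n_max], k_alng=k[1 + n_max :]
    )
    a = 10.0 ** rng.uniform(-7.0, -5.0)
    g = 10.0 ** rng.uniform(-7.0, -5.0)
    lipid = 0.0 if (n_max > 0 and rng.random() < 0.1) else 10.0 ** rng.uniform(-7.0, -4.0)
    if n_max == 0:
        lipid = 0.0
    return params, Totals(a_total=a, g_total=g, l_total=lipid)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def simple_params():
    return BindingModelParams(k_ag=1e6, k_al=[1e5, 5e4], k_alng=[2e6, 4e6])
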