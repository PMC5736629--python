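"""From deconvoluted species-abundance tables to globally fitted binding constants.

The measurement chain this module models: native mass spectra of the
protein-protein complex titrated with a lipid are deconvoluted upstream into
per-species intensities (one row per detected stoichiometry).  Intensities
are converted to mole fractions per titration point, after folding
non-specific nucleotide adduct satellites into their parent species, and the
coupled-equilibrium model is fitted globally to all points of a titration by
minimising the pseudo chi-square

    chi2 = sum_points sum_n (F_ALn^exp - F_ALn^calc)^2
                           + (F_AGLn^exp - F_AGLn^calc)^2

over log10-parameterised association constants.

Two evaluation modes for the calculated fractions are provided:
``measured_fractions`` (default for fitting) takes the free concentrations
from the *experimental* fractions via the mass balances, the literal reading
of the analysis; ``self_consistent`` solves the full mass-balance system.
Both agree at the optimum on noise-free data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize
from sklearn.base import BaseEstimator

from .equilibrium import (
    BindingModelParams,
    EquilibriumState,
    Totals,
    ValidationError,
    compute_equilibrium,
    free_concentrations_from_fractions,
)

__all__ = [
    "IdentifiabilityError",
    "SpeciesAbundanceTable",
    "TitrationPoint",
    "TitrationSeries",
    "ReplicateFit",
    "FitResult",
    "CoupledBindingFitter",
    "fold_adducts",
    "table_to_point",
    "chi_square",
    "fit_binding_model",
    "kd_ag_from_point",
    "aggregate_replicates",
]

REQUIRED_COLUMNS = (
    "n_glnk",
    "n_lipid",
    "n_adp_specific",
    "n_adp_nonspecific",
    "intensity",
)


class IdentifiabilityError(ValueError):
    """The requested parameters are not constrained by the supplied data."""


@dataclass
class SpeciesAbundanceTable:
    """Deconvoluted species intensities at one titration point.

    ``data`` has one row per detected species with columns
    ``n_glnk`` (0 or 1: soluble partner bound), ``n_lipid`` (>= 0),
    ``n_adp_specific`` (nucleotides that are part of the complex),
    ``n_adp_nonspecific`` (ionisation adducts) and ``intensity``
    (arbitrary units, >= 0).
    """

    data: pd.DataFrame
    totals: Totals
    replicate: str = "r1"

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"species table missing column(s): {missing}")
        inten = self.data["intensity"].to_numpy(dtype=float)
        if np.any(~np.isfinite(inten)) or np.any(inten < 0):
            raise ValidationError("intensities must be finite and >= 0")

    @property
    def total_intensity(self) -> float:
        return float(self.data["intensity"].sum())

    def is_folded(self) -> bool:
        return bool((self.data["n_adp_nonspecific"] == 0).all())


def fold_adducts(table: SpeciesAbundanceTable) -> SpeciesAbundanceTable:
    """Fold +1 non-specific nucleotide satellites into their parent species.

    Each row with ``n_adp_nonspecific == 1`` has its intensity added to the
    row with the same ``(n_glnk, n_lipid, n_adp_specific)`` and
    ``n_adp_nonspecific == 0`` (created if absent).  Rows with two or more
    non-specific adducts are not expected from the ionisation conditions
    modelled here and are dropped with a warning.  Total intensity is
    conserved apart from any dropped rows.
    """
    df = table.data.copy()
    bad = df["n_adp_nonspecific"] >= 2
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} row(s) with >= 2 non-specific adducts",
            stacklevel=2,
        )
        df = df.loc[~bad]
    df = df.assign(n_adp_nonspecific=0)
    folded = (
        df.groupby(["n_glnk", "n_lipid", "n_adp_specific", "n_adp_nonspecific"])[
            "intensity"
        ]
        .sum()
        .reset_index()
    )
    return SpeciesAbundanceTable(
        data=folded[list(REQUIRED_COLUMNS)],
        totals=table.totals,
        replicate=table.replicate,
    )


@dataclass(frozen=True)
class TitrationPoint:
    """Observed mole fractions (per lipid count, with/without G) at one condition."""

    totals: Totals
    f_al: np.ndarray
    f_agl: np.ndarray
    replicate: str = "r1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "f_al", np.asarray(self.f_al, dtype=float))
        object.__setattr__(self, "f_agl", np.asarray(self.f_agl, dtype=float))
        for arr in (self.f_al, self.f_agl):
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValidationError("mole fractions must lie in [0, 1]")
        total = self.f_al.sum() + self.f_agl.sum()
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(f"mole fractions must sum to 1 (got {total!r})")


def table_to_point(
    table: SpeciesAbundanceTable,
    totals: Totals | None = None,
    n_max: int | None = None,
) -> TitrationPoint:
    """Convert a folded species table to observed mole fractions.

    Fractions are intensity per ``(n_glnk, n_lipid)`` class divided by the
    summed intensity of all complex-containing species; classes not observed
    get fraction 0.
    """
    if not table.is_folded():
        raise ValidationError("table contains unfolded adduct rows; fold_adducts first")
    totals = totals if totals is not None else table.totals
    grouped = table.data.groupby(["n_glnk", "n_lipid"])["intensity"].sum()
    total = float(grouped.sum())
    if total <= 0:
        raise ValidationError("all intensities are zero")
    n_obs = int(table.data["n_lipid"].max())
    n = n_obs if n_max is None else int(n_max)
    if n_obs > n:
        raise ValidationError(f"table contains lipid count {n_obs} > n_max={n}")
    f_al = np.zeros(n + 1)
    f_agl = np.zeros(n + 1)
    for (n_g, n_l), inten in grouped.items():
        (f_agl if n_g else f_al)[int(n_l)] += inten / total
    return TitrationPoint(totals=totals, f_al=f_al, f_agl=f_agl, replicate=table.replicate)


@dataclass
class TitrationSeries:
    """An ordered lipid titration (possibly several replicates) at one temperature."""

    lipid: str
    points: list[TitrationPoint]
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if len({p.totals.l_total for p in self.points}) < 2:
            raise ValidationError(
                "a titration needs >= 2 distinct total lipid concentrations"
            )

    @property
    def replicates(self) -> dict[str, list[TitrationPoint]]:
        groups: dict[str, list[TitrationPoint]] = {}
        for p in self.points:
            groups.setdefault(p.replicate, []).append(p)
        return groups


# ---------------------------------------------------------------------------
# Objective


class _ChiSquareObjective:
    """Vectorised pseudo chi-square over the points of one replicate."""

    def __init__(self, points: Sequence[TitrationPoint], n_max: int, mode: str):
        if mode not in ("measured_fractions", "self_consistent"):
            raise ValidationError(f"unknown solver mode {mode!r}")
        self.mode = mode
        self.n_max = n_max
        self.points = list(points)
        p = len(self.points)
        self.f_al_exp = np.zeros((p, n_max + 1))
        self.f_agl_exp = np.zeros((p, n_max + 1))
        for i, pt in enumerate(self.points):
            if pt.f_al.size > n_max + 1:
                raise ValidationError("point has more lipid classes than n_max")
            self.f_al_exp[i, : pt.f_al.size] = pt.f_al
            self.f_agl_exp[i, : pt.f_agl.size] = pt.f_agl
        if mode == "measured_fractions":
            free = [
                free_concentrations_from_fractions(pt.totals, pt.f_al, pt.f_agl)
                for pt in self.points
            ]
            self.free_g = np.array([f[0] for f in free])
            self.free_l = np.array([f[1] for f in free])

    def calc_fractions(self, params: BindingModelParams) -> tuple[np.ndarray, np.ndarray]:
        n = self.n_max
        if self.mode == "self_consistent":
            f_al = np.empty_like(self.f_al_exp)
            f_agl = np.empty_like(self.f_agl_exp)
            for i, pt in enumerate(self.points):
                st = compute_equilibrium(params, pt.totals, mode="self_consistent")
                f_al[i], f_agl[i] = st.f_al, st.f_agl
            return f_al, f_agl
        # measured_fractions: free concentrations fixed by the data; the model
        # fractions are an explicit function of the parameters (vectorised).
        ns = np.arange(n + 1, dtype=float)
        cum_log_kal = np.concatenate([[0.0], np.cumsum(np.log(params.k_al))])
        with np.errstate(divide="ignore", invalid="ignore"):
            log_l = np.log(self.free_l)[:, None]  # -inf where free_l == 0
            log_g = np.log(self.free_g)[:, None]
            pow_l = np.where(ns == 0, 0.0, ns * log_l)
        log_w_al = cum_log_kal + pow_l
        log_w_agl = np.log(params.glnk_constants) + log_g + log_w_al
        log_w = np.concatenate([log_w_al, log_w_agl], axis=1)
        m = log_w.max(axis=1, keepdims=True)
        w = np.exp(log_w - m)
        w /= w.sum(axis=1, keepdims=True)
        return w[:, : n + 1], w[:, n + 1 :]

    def residuals(self, x_log10: np.ndarray) -> np.ndarray:
        params = BindingModelParams.from_log10(x_log10, self.n_max)
        f_al, f_agl = self.calc_fractions(params)
        return np.concatenate(
            [(f_al - self.f_al_exp).ravel(), (f_agl - self.f_agl_exp).ravel()]
        )

    def chi2(self, x_log10: np.ndarray) -> float:
        r = self.residuals(x_log10)
        return float(r @ r)


def chi_square(
    series: TitrationSeries | Sequence[TitrationPoint],
    params: BindingModelParams,
    mode: str = "measured_fractions",
) -> float:
    """Pseudo chi-square of the model against observed mole fractions."""
    points = series.points if isinstance(series, TitrationSeries) else list(series)
    obj = _ChiSquareObjective(points, params.n_max, mode)
    return obj.chi2(params.log10())


# ---------------------------------------------------------------------------
# Global fit


@dataclass
class ReplicateFit:
    replicate: str
    params: BindingModelParams
    chi2: float
    n_evaluations: int
    best_start: int


@dataclass
class FitResult:
    """Globally fitted association constants with per-replicate statistics."""

    params_hat: BindingModelParams
    chi2: float
    per_replicate: list[ReplicateFit]
    log10_mean: np.ndarray
    log10_sem: np.ndarray
    mode: str
    seed: int
    n_starts: int
    lipid: str = "unknown"

    @property
    def n_replicates(self) -> int:
        return len(self.per_replicate)


def aggregate_replicates(values: Iterable[float]) -> tuple[float, float]:
    """Mean and standard error of the mean across replicates.

    The s.e.m. is the sample standard deviation over sqrt(n); for a single
    value it is undefined and reported as NaN.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("at least one value is required")
    mean = float(arr.mean())
    if arr.size == 1:
        return mean, float("nan")
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size))
    return mean, sem


class CoupledBindingFitter(BaseEstimator):
    """Global fit of the coupled-equilibrium binding model to a lipid titration.

    Association constants are optimised as log10 values within ``log10_bounds``
    (enforcing positivity and conditioning the search) by a derivative-free
    simplex started from ``n_starts`` seeded draws plus one heuristic start;
    the best solution is polished with bounded trust-region least squares.
    Each replicate is fitted independently and constants are summarised as
    mean +/- s.e.m. over replicates (on the log10 scale, and as constants).

    Attributes (after ``fit``)
    --------------------------
    params_ : BindingModelParams
        Constants at the mean log10 parameters across replicates.
    chi2_ : float
        Pseudo chi-square of ``params_`` over the whole series.
    result_ : FitResult
    """

    def __init__(
        self,
        n_max: int = 3,
        mode: str = "measured_fractions",
        n_starts: int = 16,
        seed: int = 1234,
        log10_bounds: tuple[float, float] = (0.0, 12.0),
        simplex_options: dict | None = None,
    ):
        self.n_max = n_max
        self.mode = mode
        self.n_starts = n_starts
        self.seed = seed
        self.log10_bounds = log10_bounds
        self.simplex_options = simplex_options

    # -- internals ---------------------------------------------------------

    def _check_identifiable(self, points: Sequence[TitrationPoint]) -> None:
        n = self.n_max
        seen = np.zeros(n + 1, dtype=bool)
        for pt in points:
            for arr in (pt.f_al, pt.f_agl):
                k = min(arr.size, n + 1)
                seen[:k] |= arr[:k] > 0
        missing = [i for i in range(1, n + 1) if not seen[i]]
        if missing:
            names = ", ".join(f"K_A,AL{i} / K_A,AL{i}G" for i in missing)
            raise IdentifiabilityError(
                f"no species with lipid count {missing} observed; "
                f"unidentifiable parameter(s): {names}"
            )

    def _heuristic_start(self, points: Sequence[TitrationPoint]) -> np.ndarray:
        k_ag = 1e6
        for pt in points:
            if pt.totals.l_total == 0 and pt.f_agl[0] > 0 and pt.f_al[0] > 0:
                try:
                    k_ag = 1.0 / kd_ag_from_point(pt)
                except (ValidationError, ZeroDivisionError):
                    pass
                break
        x0 = np.full(1 + 2 * self.n_max, 5.0)
        x0[0] = np.log10(k_ag)
        x0[1 + self.n_max :] = x0[0]
        lo, hi = self.log10_bounds
        return np.clip(x0, lo, hi)

    def _fit_replicate(
        self, replicate: str, points: Sequence[TitrationPoint], rng: np.random.Generator
    ) -> ReplicateFit:
        obj = _ChiSquareObjective(points, self.n_max, self.mode)
        dim = 1 + 2 * self.n_max
        lo, hi = self.log10_bounds
        starts = [self._heuristic_start(points)]
        starts += list(rng.uniform(2.0, 8.0, size=(self.n_starts, dim)))
        options = dict(maxiter=400 * dim, xatol=1e-8, fatol=1e-14, adaptive=True)
        if self.simplex_options:
            options.update(self.simplex_options)
        best_x, best_chi2, best_start, n_eval = None, np.inf, -1, 0
        bounds = [(lo, hi)] * dim
        for k, x0 in enumerate(starts):
            res = minimize(
                obj.chi2, x0, method="Nelder-Mead", bounds=bounds, options=options
            )
            n_eval += res.nfev
            if res.fun < best_chi2:
                best_x, best_chi2, best_start = res.x, float(res.fun), k
        if best_x is None or not np.isfinite(best_chi2):
            raise RuntimeError(
                f"global fit did not converge for replicate {replicate!r}"
            )
        polish = least_squares(
            obj.residuals,
            best_x,
            bounds=(np.full(dim, lo), np.full(dim, hi)),
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
        n_eval += polish.nfev
        if polish.cost * 2 < best_chi2:
            best_x, best_chi2 = polish.x, float(polish.cost * 2)
        return ReplicateFit(
            replicate=replicate,
            params=BindingModelParams.from_log10(best_x, self.n_max),
            chi2=best_chi2,
            n_evaluations=n_eval,
            best_start=best_start,
        )

    # -- sklearn-style API ---------------------------------------------------

    def fit(self, series: TitrationSeries, y=None) -> "CoupledBindingFitter":
        self._check_identifiable(series.points)
        groups = series.replicates
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(groups))
        fits = [
            self._fit_replicate(rep, pts, np.random.default_rng(child))
            for (rep, pts), child in zip(sorted(groups.items()), children)
        ]
        logs = np.array([f.params.log10() for f in fits])
        mean_sem = [aggregate_replicates(logs[:, j]) for j in range(logs.shape[1])]
        log10_mean = np.array([m for m, _ in mean_sem])
        log10_sem = np.array([s for _, s in mean_sem])
        params_hat = BindingModelParams.from_log10(log10_mean, self.n_max)
        chi2 = chi_square(series, params_hat, mode=self.mode)
        self.result_ = FitResult(
            params_hat=params_hat,
            chi2=chi2,
            per_replicate=fits,
            log10_mean=log10_mean,
            log10_sem=log10_sem,
            mode=self.mode,
            seed=self.seed,
            n_starts=self.n_starts,
            lipid=series.lipid,
        )
        self.params_ = params_hat
        self.chi2_ = chi2
        return self

    def predict(self, totals_list: Sequence[Totals]) -> list[EquilibriumState]:
        """Model-predicted equilibrium states at new conditions."""
        if not hasattr(self, "params_"):
            raise RuntimeError("fit the estimator before calling predict")
        return [
            compute_equilibrium(self.params_, t, mode="self_consistent")
            for t in totals_list
        ]


def fit_binding_model(series: TitrationSeries, n_max: int, **options) -> FitResult:
    """Thin functional wrapper around :class:`CoupledBindingFitter`."""
    return CoupledBindingFitter(n_max=n_max, **options).fit(series).result_


# ---------------------------------------------------------------------------
# Single-point dissociation constant


def kd_ag_from_point(point: TitrationPoint) -> float:
    """Dissociation constant of the protein-protein complex from a lipid-free point.

    ``K_D = [A][G]/[AG]`` with ``[A] = A_total*F_A``, ``[AG] = A_total*F_AG``
    and ``[G] = G_total - [AG]``.
    """
    if point.f_al[1:].sum() > 1e-9 or point.f_agl[1:].sum() > 1e-9:
        raise ValidationError("K_D,AG requires a lipid-free titration point")
    f_a, f_ag = float(point.f_al[0]), float(point.f_agl[0])
    if f_ag <= 0:
        raise ValidationError("no complex observed; K_D,AG undefined")
    ag = point.totals.a_total * f_ag
    free_g = point.totals.g_total - ag
    if free_g <= 0:
        raise ValidationError("implied free G <= 0; K_D,AG undefined")
    free_a = point.totals.a_total * f_a
    return float(free_a * free_g / ag)
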