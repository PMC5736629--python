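"""Synthetic data with the statistical structure of the native-MS experiments.

Raw spectra are not deposited with the study this analysis targets, so every
fixture is generated: deconvolved species-abundance tables from known
association constants (with multiplicative intensity noise and +1 nucleotide
adduct satellites), temperature series from known thermodynamics, and
sensorgrams from known kinetics.  Ground truth is carried alongside every
generated object so round-trip recovery can be asserted.

Study conditions emulated by the defaults: both proteins at 2 uM (trimer
units), a 12-point lipid titration from 0 to 150 uM, a protein-protein
K_D of 1.12 uM (the lipid-free value at the 50 uM nucleotide background),
three replicates, 5% multiplicative intensity noise, and a 5% +1-adduct
satellite mass fraction.  Intensity noise is lognormal per species and
median-unbiased (multiplier exp(sigma*Z) with median 1), matching the
multiplicative error character of MS peak intensities; a Dirichlet
resampling of the composition is offered as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .equilibrium import (
    BindingModelParams,
    Totals,
    ValidationError,
    compute_equilibrium,
)
from .spr import KineticParams, Sensorgram, simulate_sensorgram
from .thermo import ThermoParams, VantHoffSeries
from .titration import (
    REQUIRED_COLUMNS,
    SpeciesAbundanceTable,
    TitrationPoint,
    TitrationSeries,
    fold_adducts,
    table_to_point,
)

__all__ = [
    "NoiseSpec",
    "TitrationBundle",
    "Scenario",
    "params_from_coupling",
    "default_study_params",
    "default_lipid_grid",
    "generate_titration",
    "generate_vant_hoff_series",
    "generate_sensorgrams",
    "paperlike_scenario",
    "SCENARIO_NAMES",
]

INTENSITY_SCALE = 1e4
KD_AG_DEFAULT = 1.12e-6  # M, lipid-free protein-protein K_D
PROTEIN_TOTAL_DEFAULT = 2e-6  # M, trimer units


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model for synthetic species-abundance tables.

    ``lognormal_intensity`` multiplies each species intensity by
    ``exp(sigma*Z)`` (median 1); ``dirichlet`` resamples the composition with
    concentration parameter ``concentration`` (larger = less noise).
    ``adduct_fraction`` is the intensity mass moved from each species to its
    +1 non-specific nucleotide satellite.
    """

    model: str = "lognormal_intensity"
    sigma: float = 0.05
    concentration: float = 500.0
    adduct_fraction: float = 0.05
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.model not in ("lognormal_intensity", "dirichlet"):
            raise ValidationError(f"unknown noise model {self.model!r}")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if not 0.0 <= self.adduct_fraction < 0.5:
            raise ValidationError("adduct_fraction must lie in [0, 0.5)")


@dataclass
class TitrationBundle:
    """A generated titration plus the truth it was generated from."""

    series: TitrationSeries
    tables: list[SpeciesAbundanceTable]
    truth: BindingModelParams
    noise: NoiseSpec


def params_from_coupling(
    k_ag: float, k_al: Sequence[float], alpha: Sequence[float]
) -> BindingModelParams:
    """Build model constants from per-event coupling factors.

    ``alpha_i = K_A,ALiG / K_A,AL(i-1)G`` (the per-lipid-event convention),
    so ``K_A,ALnG = K_A,AG * prod_{i<=n} alpha_i``.
    """
    alpha = np.asarray(alpha, dtype=float)
    k_alng = k_ag * np.cumprod(alpha)
    return BindingModelParams(k_ag=k_ag, k_al=np.asarray(k_al, float), k_alng=k_alng)


def default_study_params() -> BindingModelParams:
    """Positive-coupling truth under the default study conditions."""
    return params_from_coupling(
        k_ag=1.0 / KD_AG_DEFAULT, k_al=[2.0e5, 1.4e5, 9.0e4], alpha=[1.4, 1.8, 2.2]
    )


def default_lipid_grid() -> list[float]:
    """12 total-lipid concentrations (M), 0 to 150 uM."""
    return [
        0.0,
        1e-6,
        2e-6,
        4e-6,
        7e-6,
        1.2e-5,
        2e-5,
        3.2e-5,
        5e-5,
        7.5e-5,
        1e-4,
        1.5e-4,
    ]


def default_totals_grid(
    a_total: float = PROTEIN_TOTAL_DEFAULT,
    g_total: float = PROTEIN_TOTAL_DEFAULT,
    lipid_grid: Sequence[float] | None = None,
    temperature: float = 298.0,
) -> list[Totals]:
    grid = default_lipid_grid() if lipid_grid is None else list(lipid_grid)
    return [
        Totals(a_total=a_total, g_total=g_total, l_total=lt, temperature=temperature)
        for lt in grid
    ]


def _species_rows(state, adduct_fraction: float) -> pd.DataFrame:
    """Exact intensities per species, with optional +1 adduct satellites.

    GlnK-containing species carry 3 specific nucleotides (the complex binds
    with its regulatory sites occupied); satellites move ``adduct_fraction``
    of each species' intensity to an ``n_adp_nonspecific = 1`` row.
    """
    rows = []
    for n_glnk, fracs in ((0, state.f_al), (1, state.f_agl)):
        n_spec = 3 if n_glnk else 0
        for n_lipid, f in enumerate(fracs):
            inten = INTENSITY_SCALE * float(f)
            if adduct_fraction > 0:
                rows.append((n_glnk, n_lipid, n_spec, 0, inten * (1 - adduct_fraction)))
                rows.append((n_glnk, n_lipid, n_spec, 1, inten * adduct_fraction))
            else:
                rows.append((n_glnk, n_lipid, n_spec, 0, inten))
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def _apply_noise(df: pd.DataFrame, noise: NoiseSpec, rng: np.random.Generator) -> pd.DataFrame:
    inten = df["intensity"].to_numpy(dtype=float)
    if noise.model == "lognormal_intensity":
        if noise.sigma > 0:
            inten = inten * np.exp(noise.sigma * rng.standard_normal(inten.size))
    else:
        total = inten.sum()
        p = np.clip(inten / total, 1e-12, None)
        inten = total * rng.dirichlet(noise.concentration * p / p.sum())
    return df.assign(intensity=inten)


def generate_titration(
    true_params: BindingModelParams,
    totals_grid: Sequence[Totals] | None = None,
    noise: NoiseSpec | None = None,
    replicates: int = 3,
    lipid: str = "synthetic",
) -> TitrationBundle:
    """Generate species-abundance tables and observed fractions for one lipid.

    Per point: exact fractions from the self-consistent equilibrium solve ->
    intensities (scale 1e4) -> optional adduct satellites -> noise -> table;
    the series' observed fractions come from folding and normalising the
    tables exactly as real data would be processed.
    """
    totals_grid = default_totals_grid() if totals_grid is None else list(totals_grid)
    if not totals_grid:
        raise ValidationError("totals_grid must be nonempty")
    noise = NoiseSpec() if noise is None else noise
    rng = np.random.default_rng(noise.seed)
    tables: list[SpeciesAbundanceTable] = []
    points: list[TitrationPoint] = []
    for r in range(replicates):
        rep = f"r{r + 1}"
        for totals in totals_grid:
            state = compute_equilibrium(true_params, totals, mode="self_consistent")
            df = _species_rows(state, noise.adduct_fraction)
            df = _apply_noise(df, noise, rng)
            table = SpeciesAbundanceTable(data=df, totals=totals, replicate=rep)
            tables.append(table)
            points.append(
                table_to_point(fold_adducts(table), n_max=true_params.n_max)
            )
    series = TitrationSeries(
        lipid=lipid, points=points, temperature=totals_grid[0].temperature
    )
    return TitrationBundle(series=series, tables=tables, truth=true_params, noise=noise)


def generate_vant_hoff_series(
    thermo: ThermoParams,
    temps: Sequence[float],
    sigma: float = 0.0,
    replicates: int = 1,
    seed: int = 1234,
) -> VantHoffSeries:
    """K_A(T) from the nonlinear van't Hoff forward model with lognormal noise."""
    temps = np.asarray(temps, dtype=float)
    if np.any(temps < 270) or np.any(temps > 320):
        raise ValidationError("temperatures must lie within 270-320 K")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(replicates):
        ln_k = thermo.ln_k(temps)
        if sigma > 0:
            ln_k = ln_k + sigma * rng.standard_normal(temps.size)
        reps.append((temps, np.exp(ln_k)))
    return VantHoffSeries.from_replicates(reps)


def generate_sensorgrams(
    p: KineticParams,
    concs: Sequence[float],
    times: Sequence[float],
    t_assoc_end: float,
    sigma: float = 0.0,
    seed: int = 1234,
) -> list[Sensorgram]:
    """Closed-form Langmuir traces with additive Gaussian noise (RU)."""
    concs = np.asarray(concs, dtype=float)
    if np.any(concs <= 0):
        raise ValidationError("analyte concentrations must be positive")
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    out = []
    for c in concs:
        g = simulate_sensorgram(p, float(c), times, t_assoc_end)
        resp = g.response
        if sigma > 0:
            resp = resp + sigma * rng.standard_normal(times.size)
        out.append(
            Sensorgram(
                concentration=float(c),
                times=times,
                response=resp,
                t_assoc_end=t_assoc_end,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Preconfigured study-like scenarios

SCENARIO_NAMES = (
    "headgroup_panel",
    "tail_length_panel",
    "stereochemistry_panel",
    "adp_titration",
)

# lipid label -> (lipid-binding constants K_A,ALn, per-event coupling factors)
_PANELS: dict[str, dict[str, tuple[list[float], list[float]]]] = {
    "headgroup_panel": {
        "PE-like": ([2.0e5, 1.4e5, 9.0e4], [1.4, 1.8, 2.2]),
        "PS-like": ([1.6e5, 1.1e5, 7.0e4], [1.0, 1.0, 1.0]),
        "PA-like": ([1.8e5, 1.2e5, 8.0e4], [0.78, 0.72, 0.66]),
    },
    "tail_length_panel": {
        "12C-PG-like": ([2.2e5, 1.5e5, 1.0e5], [1.3, 1.6, 1.9]),
        "14C-PG-like": ([1.9e5, 1.3e5, 8.5e4], [1.0, 1.0, 1.0]),
        "16C-PG-like": ([2.1e5, 1.4e5, 9.5e4], [1.35, 1.65, 1.95]),
    },
    "stereochemistry_panel": {
        "trans-18:1-PE-like": ([2.0e5, 1.4e5, 9.0e4], [1.6, 2.6, 5.28]),
        "cis-18:1-PE-like": ([2.0e5, 1.4e5, 9.0e4], [1.25, 1.5, 1.71]),
        "18:0-18:1-PE-like": ([1.9e5, 1.3e5, 8.5e4], [1.2, 1.45, 1.65]),
    },
}

# Nucleotide-titration scenario: apparent protein-protein K_D per nominal
# nucleotide level, decreasing toward an ~80 nM asymptote at high levels.
ADP_LEVELS_UM = (5.0, 10.0, 25.0, 50.0, 100.0, 200.0)
ADP_TRUE_KD_M = (3.8e-6, 2.2e-6, 1.5e-6, 1.12e-6, 8.3e-8, 7.768e-8)


def _expected_class(alpha: float) -> str:
    if alpha > 1:
        return "positive"
    if alpha < 1:
        return "negative"
    return "neutral"


@dataclass
class Scenario:
    """A preconfigured synthetic study with embedded ground truth."""

    name: str
    lipids: dict[str, TitrationBundle] = field(default_factory=dict)
    truth_alpha: dict[str, np.ndarray] = field(default_factory=dict)
    expected_class: dict[str, tuple[str, ...]] = field(default_factory=dict)
    # adp_titration only:
    adp_levels_uM: tuple[float, ...] = ()
    adp_true_kd_M: tuple[float, ...] = ()
    adp_tables: dict[float, list[SpeciesAbundanceTable]] = field(default_factory=dict)
    adp_points: dict[float, list[TitrationPoint]] = field(default_factory=dict)


def paperlike_scenario(
    name: str,
    seed: int = 1234,
    sigma: float = 0.02,
    replicates: int = 3,
    adduct_fraction: float = 0.05,
) -> Scenario:
    """Build one of the preconfigured synthetic studies.

    The three lipid panels contain one synthetic lipid per allostery class
    (or per tail variant) with documented truth; ``adp_titration`` generates
    lipid-free points whose protein-protein K_D decreases monotonically with
    the nominal nucleotide level.
    """
    if name not in SCENARIO_NAMES:
        raise ValidationError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    ss = np.random.SeedSequence(seed)
    scenario = Scenario(name=name)

    if name == "adp_titration":
        scenario.adp_levels_uM = ADP_LEVELS_UM
        scenario.adp_true_kd_M = ADP_TRUE_KD_M
        children = ss.spawn(len(ADP_LEVELS_UM))
        for level, kd, child in zip(ADP_LEVELS_UM, ADP_TRUE_KD_M, children):
            rng = np.random.default_rng(child)
            params = BindingModelParams(k_ag=1.0 / kd, k_al=[], k_alng=[])
            totals = Totals(
                a_total=PROTEIN_TOTAL_DEFAULT,
                g_total=PROTEIN_TOTAL_DEFAULT,
                l_total=0.0,
            )
            noise = NoiseSpec(sigma=sigma, adduct_fraction=adduct_fraction, seed=seed)
            tables, points = [], []
            for r in range(replicates):
                state = compute_equilibrium(params, totals)
                df = _species_rows(state, adduct_fraction)
                df = _apply_noise(df, noise, rng)
                table = SpeciesAbundanceTable(
                    data=df, totals=totals, replicate=f"r{r + 1}"
                )
                tables.append(table)
                points.append(table_to_point(fold_adducts(table), n_max=0))
            scenario.adp_tables[level] = tables
            scenario.adp_points[level] = points
        return scenario

    panel = _PANELS[name]
    children = ss.spawn(len(panel))
    for (label, (k_al, alpha)), child in zip(panel.items(), children):
        truth = params_from_coupling(1.0 / KD_AG_DEFAULT, k_al, alpha)
        noise = NoiseSpec(
            sigma=sigma,
            adduct_fraction=adduct_fraction,
            seed=int(child.generate_state(1)[0] % (2**31 - 1)),
        )
        scenario.lipids[label] = generate_titration(
            truth, noise=noise, replicates=replicates, lipid=label
        )
        scenario.truth_alpha[label] = np.asarray(alpha, dtype=float)
        scenario.expected_class[label] = tuple(_expected_class(a) for a in alpha)
    return scenario
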