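"""Reading and writing the plain-text formats the analysis consumes and produces.

Formats (all CSV/JSON/YAML; the upstream deconvolution tools export CSV-like
tables):

* species table CSV: ``n_glnk,n_lipid,n_adp_specific,n_adp_nonspecific,intensity``
* titration manifest YAML: lipid, temperature, per-point table paths and
  totals (molar, with explicit unit-suffixed keys)
* van't Hoff CSV: ``replicate,T_K,K_A_per_M``
* sensorgram CSV (long): ``concentration_M,t_s,response_RU``
* JSON reports embed full provenance (package version, seed, mode, options).
"""

from __future__ import annotations

import dataclasses
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .allostery import CouplingFactorSet
from .equilibrium import Totals, ValidationError
from .spr import KineticParams, Sensorgram
from .synthetic import NoiseSpec, TitrationBundle
from .thermo import VantHoffResult, VantHoffSeries
from .titration import (
    REQUIRED_COLUMNS,
    FitResult,
    SpeciesAbundanceTable,
    TitrationPoint,
    TitrationSeries,
    fold_adducts,
    table_to_point,
)

__all__ = [
    "ParseError",
    "read_species_table",
    "write_species_table",
    "write_titration_bundle",
    "read_titration_manifest",
    "read_vant_hoff_csv",
    "write_vant_hoff_csv",
    "read_sensorgrams_csv",
    "write_sensorgrams_csv",
    "fit_result_to_dict",
    "coupling_to_dict",
    "thermo_result_to_dict",
    "kinetics_to_dict",
    "save_json",
]


class ParseError(ValueError):
    """Malformed input file."""


def _package_version() -> str:
    try:
        return version("lipallo")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


_KEY_COLUMNS = ["n_glnk", "n_lipid", "n_adp_specific", "n_adp_nonspecific"]


def read_species_table(
    path, totals: Totals | None = None, replicate: str = "r1"
) -> SpeciesAbundanceTable:
    """Read and validate a deconvoluted species-abundance CSV.

    Row order is irrelevant; parse failures report the offending column or
    the 1-based file line (header is line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing required column(s) {missing}")
    inten = df["intensity"].to_numpy(dtype=float)
    bad = np.where(~np.isfinite(inten) | (inten < 0))[0]
    if bad.size:
        raise ParseError(
            f"{path.name}, line {int(bad[0]) + 2}: negative or non-finite intensity"
        )
    dup = df.duplicated(subset=_KEY_COLUMNS)
    if dup.any():
        line = int(np.where(dup.to_numpy())[0][0]) + 2
        raise ParseError(f"{path.name}, line {line}: duplicate species key")
    if totals is None:
        totals = Totals(a_total=0.0, g_total=0.0, l_total=0.0)
    return SpeciesAbundanceTable(
        data=df[list(REQUIRED_COLUMNS)], totals=totals, replicate=replicate
    )


def write_species_table(table: SpeciesAbundanceTable, path) -> None:
    table.data.to_csv(path, index=False)


def _totals_to_dict(t: Totals) -> dict:
    return {
        "a_total_M": t.a_total,
        "g_total_M": t.g_total,
        "l_total_M": t.l_total,
        "temperature_K": t.temperature,
    }


def _totals_from_dict(d: dict) -> Totals:
    return Totals(
        a_total=float(d["a_total_M"]),
        g_total=float(d["g_total_M"]),
        l_total=float(d["l_total_M"]),
        temperature=float(d.get("temperature_K", 298.0)),
    )


def write_titration_bundle(bundle: TitrationBundle, outdir) -> Path:
    """Write per-point species CSVs plus a YAML manifest; returns the manifest path."""
    outdir = Path(outdir)
    tables_dir = outdir / "tables"
    tables_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, table in enumerate(bundle.tables):
        fname = f"{bundle.series.lipid}_{table.replicate}_p{i:03d}.csv"
        write_species_table(table, tables_dir / fname)
        entries.append(
            {
                "table": f"tables/{fname}",
                "replicate": table.replicate,
                "totals": _totals_to_dict(table.totals),
            }
        )
    manifest = {
        "lipid": bundle.series.lipid,
        "temperature_K": bundle.series.temperature,
        "n_max": bundle.truth.n_max,
        "truth_log10_K": [float(v) for v in bundle.truth.log10()],
        "noise": dataclasses.asdict(bundle.noise),
        "points": entries,
        "version": _package_version(),
    }
    manifest_path = outdir / f"{bundle.series.lipid}_manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def read_titration_manifest(path) -> tuple[TitrationSeries, list[SpeciesAbundanceTable], dict]:
    """Load a manifest: read, fold, and normalise every referenced table."""
    path = Path(path)
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    n_max = int(manifest["n_max"])
    tables: list[SpeciesAbundanceTable] = []
    points: list[TitrationPoint] = []
    for entry in manifest["points"]:
        totals = _totals_from_dict(entry["totals"])
        table = read_species_table(
            path.parent / entry["table"], totals=totals, replicate=entry["replicate"]
        )
        tables.append(table)
        points.append(table_to_point(fold_adducts(table), n_max=n_max))
    series = TitrationSeries(
        lipid=manifest["lipid"],
        points=points,
        temperature=float(manifest.get("temperature_K", 298.0)),
    )
    return series, tables, manifest


def read_vant_hoff_csv(path) -> VantHoffSeries:
    df = pd.read_csv(path)
    missing = [c for c in ("replicate", "T_K", "K_A_per_M") if c not in df.columns]
    if missing:
        raise ParseError(f"{Path(path).name}: missing required column(s) {missing}")
    return VantHoffSeries(data=df)


def write_vant_hoff_csv(series: VantHoffSeries, path) -> None:
    series.data.to_csv(path, index=False)


def read_sensorgrams_csv(path, t_assoc_end: float) -> list[Sensorgram]:
    df = pd.read_csv(path)
    missing = [c for c in ("concentration_M", "t_s", "response_RU") if c not in df.columns]
    if missing:
        raise ParseError(f"{Path(path).name}: missing required column(s) {missing}")
    grams = []
    for conc, grp in df.groupby("concentration_M"):
        grp = grp.sort_values("t_s")
        grams.append(
            Sensorgram(
                concentration=float(conc),
                times=grp["t_s"].to_numpy(dtype=float),
                response=grp["response_RU"].to_numpy(dtype=float),
                t_assoc_end=t_assoc_end,
            )
        )
    return grams


def write_sensorgrams_csv(grams: Sequence[Sensorgram], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "concentration_M": g.concentration,
                "t_s": g.times,
                "response_RU": g.response,
            }
        )
        for g in grams
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# JSON reports


def _provenance(seed: int | None = None, **extra) -> dict:
    prov = {"package": "lipallo", "version": _package_version()}
    if seed is not None:
        prov["seed"] = seed
    prov.update(extra)
    return prov


def fit_result_to_dict(fit: FitResult) -> dict:
    return {
        "lipid": fit.lipid,
        "n_max": fit.params_hat.n_max,
        "log10_K_mean": [float(v) for v in fit.log10_mean],
        "log10_K_sem": [float(v) for v in fit.log10_sem],
        "K_A_AG_per_M": fit.params_hat.k_ag,
        "K_A_AL_per_M": [float(v) for v in fit.params_hat.k_al],
        "K_A_ALnG_per_M": [float(v) for v in fit.params_hat.k_alng],
        "chi2": fit.chi2,
        "per_replicate": [
            {
                "replicate": rf.replicate,
                "log10_K": [float(v) for v in rf.params.log10()],
                "chi2": rf.chi2,
                "n_evaluations": rf.n_evaluations,
                "best_start": rf.best_start,
            }
            for rf in fit.per_replicate
        ],
        "provenance": _provenance(
            seed=fit.seed, mode=fit.mode, n_starts=fit.n_starts
        ),
    }


def fit_result_from_dict(d: dict) -> FitResult:
    from .equilibrium import BindingModelParams
    from .titration import ReplicateFit

    n_max = int(d["n_max"])
    per_rep = [
        ReplicateFit(
            replicate=r["replicate"],
            params=BindingModelParams.from_log10(r["log10_K"], n_max),
            chi2=float(r["chi2"]),
            n_evaluations=int(r["n_evaluations"]),
            best_start=int(r["best_start"]),
        )
        for r in d["per_replicate"]
    ]
    return FitResult(
        params_hat=BindingModelParams.from_log10(d["log10_K_mean"], n_max),
        chi2=float(d["chi2"]),
        per_replicate=per_rep,
        log10_mean=np.asarray(d["log10_K_mean"], dtype=float),
        log10_sem=np.asarray(d["log10_K_sem"], dtype=float),
        mode=d["provenance"].get("mode", "measured_fractions"),
        seed=int(d["provenance"].get("seed", 0)),
        n_starts=int(d["provenance"].get("n_starts", 0)),
        lipid=d.get("lipid", "unknown"),
    )


def coupling_to_dict(cfs: CouplingFactorSet, lipid: str = "unknown") -> dict:
    return {
        "lipid": lipid,
        "convention": cfs.convention,
        "events": [int(i) for i in cfs.events],
        "alpha": [float(a) for a in cfs.alpha],
        "alpha_sem": [None if np.isnan(s) else float(s) for s in cfs.alpha_sem],
        "classification": list(cfs.classification),
        "provenance": _provenance(),
    }


def thermo_result_to_dict(result: VantHoffResult) -> dict:
    m = result.mean
    return {
        "T0_K": m.T0,
        "dH_T0_J_per_mol": m.dH_T0,
        "dCp_J_per_mol_K": m.dCp,
        "K0_per_M": m.K0,
        "dG_T0_J_per_mol": m.dG_T0,
        "dS_T0_J_per_mol_K": m.dS_T0,
        "r2_lnKA": m.r2,
        "sem": {k: (None if np.isnan(v) else float(v)) for k, v in result.sem.items()},
        "n_replicates": len(result.per_replicate),
        "provenance": _provenance(),
    }


def kinetics_to_dict(p: KineticParams) -> dict:
    return {
        "kon_per_M_s": p.kon,
        "koff_per_s": p.koff,
        "Rmax_RU": p.rmax,
        "KD_M": p.kd,
        "provenance": _provenance(),
    }


def save_json(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
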