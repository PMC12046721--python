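"""End-to-end orchestration: classify -> covariates -> fit -> diagnose -> report.

Driven by a single YAML config; every run writes the resolved config back
out alongside its outputs so the run is reproducible from the output
directory alone. Any stage failure removes partial outputs and re-raises
with the stage name.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adjacency import Adjacency, generate_adjacency
from .bym import MCMCSettings, ModelSpec, fit_bym, summarize_relative_risks
from .covariates import RACE_COLUMNS, adi_decile, expected_counts_and_smr, simpson_diversity
from .design import build_design
from .diagnostics import diagnose_fit
from .io import (
    assign_points_to_tracts,
    read_neighbor_list,
    read_tract_table,
    write_neighbor_list,
    write_tract_table,
)
from .synthetic import SimulationConfig, simulate_study
from .trajectory import classify_tracts

log = logging.getLogger("lendingrisk")

# Stepwise model ladder: name -> (fixed-effect terms, CAR term, iid term)
MODEL_LADDER: dict[str, tuple[tuple[str, ...], bool, bool]] = {
    "model1": ((), False, True),  # unstructured heterogeneity only
    "model2": ((), True, True),  # + spatially structured CAR term
    "model3": (("trajectory",), True, True),  # + lending trajectory
    "model4": (("adi_decile",), True, True),  # + area deprivation
    "model5": (("trajectory", "adi_decile", "diversity"), True, True),  # full
}


@dataclass
class ReportBundle:
    """In-memory pipeline result; files live under ``output_dir``."""

    classified: pd.DataFrame
    comparison: pd.DataFrame
    fixed_effects: dict[str, pd.DataFrame]
    tract_summaries: dict[str, pd.DataFrame]
    diagnostics: dict[str, dict]
    output_dir: Path


def add_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Append diversity, ADI decile, expected counts and SMR columns."""
    out = df.copy()
    out["diversity"] = simpson_diversity(out[list(RACE_COLUMNS)].to_numpy())
    out["adi_decile"] = adi_decile(out["adi"].to_numpy())
    expected, smr = expected_counts_and_smr(
        out["homicide_count"].to_numpy(), out["population"].to_numpy()
    )
    out["expected_count"] = expected
    out["smr"] = smr
    return out


def _resolve_inputs(cfg: dict, out_dir: Path):
    """Simulate or load the tract table + adjacency per the config."""
    if "simulate" in cfg:
        sim = SimulationConfig(seed=cfg.get("seed", 0), **cfg["simulate"])
        table, adj, truth = simulate_study(sim)
        truth.to_json(out_dir / "truth.json")
        write_tract_table(table, out_dir / "simulated_tracts.csv")
        write_neighbor_list(adj, out_dir / "adjacency.txt", table["tract_id"].tolist())
        return table, adj
    inputs = cfg["input"]
    table = read_tract_table(inputs["tract_csv"], inputs.get("schema_map"))
    if "neighbor_list" in inputs:
        adj, ids = read_neighbor_list(inputs["neighbor_list"])
    elif "geojson" in inputs:
        from .io import adjacency_from_polygons

        adj, ids = adjacency_from_polygons(
            inputs["geojson"], inputs.get("contiguity", "queen")
        )
    else:
        raise ValueError("input must provide 'neighbor_list' or 'geojson'")
    order = {t: i for i, t in enumerate(table["tract_id"])}
    if set(ids) != set(order):
        raise ValueError("adjacency tract ids do not match the tract table")
    # reorder adjacency to the table's row order
    perm = [ids.index(t) for t in table["tract_id"]]
    adj = adj.subgraph(perm)
    if "points_csv" in inputs:
        pts = pd.read_csv(inputs["points_csv"])
        counts, unassigned = assign_points_to_tracts(pts, inputs["geojson"])
        table = table.copy()
        table["homicide_count"] = table["tract_id"].map(counts).fillna(0).astype(int)
        log.info("aggregated %d points (%d unassigned)", len(pts), unassigned)
    return table, adj


def run_pipeline(config_path) -> ReportBundle:
    """Run the full analysis described by a YAML config file."""
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    out_dir = Path(cfg.get("output_dir", "pipeline_output"))
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        seed = int(cfg.get("seed", 0))
        mcmc_cfg = cfg.get("mcmc", {})
        mcmc = MCMCSettings(
            chains=int(mcmc_cfg.get("chains", 4)),
            iterations=int(mcmc_cfg.get("iterations", 25_000)),
            burn_in=int(mcmc_cfg.get("burn_in", 5_000)),
            thin=int(mcmc_cfg.get("thin", 5)),
            seed=seed,
        )
        model_names = cfg.get("models", ["model1", "model2", "model3", "model4", "model5"])

        stage = "inputs"
        table, adj = _resolve_inputs(cfg, out_dir)
        for p in ("truth.json", "simulated_tracts.csv", "adjacency.txt"):
            if (out_dir / p).exists():
                written.append(out_dir / p)

        stage = "classify"
        cls_cfg = cfg.get("classification", {})
        result = classify_tracts(
            table,
            hrs_percentile=float(cls_cfg.get("hrs_percentile", 25.0)),
            decile_cut=float(cls_cfg.get("decile_cut", 10.0)),
            cost_threshold=float(cls_cfg.get("cost_threshold", 0.15)),
        )
        log.info(
            "classified %d tracts, excluded %d (%s)",
            len(result.table) - result.n_excluded,
            result.n_excluded,
            result.exclusion_reasons or "none",
        )

        stage = "covariates"
        classified = add_covariates(result.table)
        classified.to_csv(out_dir / "classified_tracts.csv", index=False)
        written.append(out_dir / "classified_tracts.csv")

        included_mask = (classified["exclusion_reason"] == "") & (
            classified["expected_count"] > 0
        )
        included = classified[included_mask].reset_index(drop=True)
        if (~included_mask).any():
            log.info("excluded %d tracts from modeling", int((~included_mask).sum()))
        sub_adj = adj.subgraph(np.flatnonzero(included_mask.to_numpy()))
        y = included["homicide_count"].to_numpy(dtype=float)
        E = included["expected_count"].to_numpy(dtype=float)

        comparison_rows = []
        fixed_effects: dict[str, pd.DataFrame] = {}
        tract_summaries: dict[str, pd.DataFrame] = {}
        diag_out: dict[str, dict] = {}
        for name in model_names:
            stage = f"fit:{name}"
            if name not in MODEL_LADDER:
                raise ValueError(f"unknown model {name!r}; choose from {sorted(MODEL_LADDER)}")
            terms, structured, unstructured = MODEL_LADDER[name]
            spec = ModelSpec(
                likelihood=cfg.get("likelihood", "poisson"),
                covariates=terms,
                include_structured=structured,
                include_unstructured=unstructured,
            )
            X, names = build_design(included, terms)
            draws = fit_bym(y, E, X, sub_adj, spec, mcmc, coefficient_names=names)
            summary = summarize_relative_risks(draws, X)
            fixed_effects[name] = summary.coefficients
            tracts = pd.concat(
                [included[["tract_id"]].reset_index(drop=True), summary.tracts], axis=1
            )
            tract_summaries[name] = tracts
            summary.coefficients.to_csv(out_dir / f"fixed_effects_{name}.csv", index=False)
            tracts.to_csv(out_dir / f"tract_rr_{name}.csv", index=False)
            written += [out_dir / f"fixed_effects_{name}.csv", out_dir / f"tract_rr_{name}.csv"]

            stage = f"diagnose:{name}"
            diag = diagnose_fit(draws, y, E, X, pit_seed=seed)
            diag.to_json(out_dir / f"diagnostics_{name}.json")
            written.append(out_dir / f"diagnostics_{name}.json")
            diag_out[name] = {
                "dic": diag.dic,
                "p_d": diag.p_d,
                "waic": diag.waic,
                "p_waic": diag.p_waic,
                "mae": diag.mae,
                "rmse": diag.rmse,
                "variance_to_mean": diag.variance_to_mean,
            }
            comparison_rows.append({"model": name, **diag_out[name]})

        stage = "report"
        comparison = pd.DataFrame(comparison_rows)
        comparison.to_csv(out_dir / "model_comparison.csv", index=False)
        written.append(out_dir / "model_comparison.csv")

        resolved = dict(cfg)
        resolved["mcmc"] = {
            "chains": mcmc.chains,
            "iterations": mcmc.iterations,
            "burn_in": mcmc.burn_in,
            "thin": mcmc.thin,
        }
        resolved["seed"] = seed
        with open(out_dir / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(resolved, fh)
        with open(out_dir / "run_log.json", "w") as fh:
            json.dump(
                {
                    "lendingrisk_version": __version__,
                    "python": platform.python_version(),
                    "numpy": np.__version__,
                    "seed": seed,
                    "n_tracts_input": int(len(table)),
                    "n_tracts_modeled": int(len(included)),
                    "models": list(model_names),
                },
                fh,
                indent=1,
            )
        return ReportBundle(
            classified=classified,
            comparison=comparison,
            fixed_effects=fixed_effects,
            tract_summaries=tract_summaries,
            diagnostics=diag_out,
            output_dir=out_dir,
        )
    except Exception as err:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
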