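"""End-to-end workflow: FBA -> capacitance MILP -> decomposition -> comparison.

Mirrors the two study workflows: the desk-sized worked example (find the
capacitance, decompose it over a known-reaction database) and the screening
workflow (find a compartment-restricted capacitance for a genome-scale model
and quantify the flux-variability reclassification it causes).
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import scipy

from . import __version__
from .capacitance import (
    Capacitance,
    CapacitanceConfig,
    enumerate_capacitances,
    find_capacitance,
)
from .comparison import compare_classifications, render_reports
from .decomposition import build_database, decompose, verify_decomposition
from .flux_analysis import solve_fba
from .io import apply_gibbs_table, load_gibbs_table, load_sbml, load_toy_model, render_equation
from .model import MetabolicModel, Metabolite, Reaction

__all__ = ["RunConfig", "run_pipeline", "load_model_auto", "capacitance_to_json"]


def load_model_auto(path: str | Path) -> MetabolicModel:
    """Load a model from either dialect: toy directory or SBML file."""
    path = Path(path)
    if path.is_dir():
        return load_toy_model(path)
    return load_sbml(path)


@dataclass
class RunConfig:
    model_path: str
    output_dir: str
    deltag_table_path: Optional[str] = None
    objective_reaction: Optional[str] = None  # override: put weight 1 on this reaction
    mu: int = 4
    lam: float = 1000.0
    allowed: Optional[Sequence[str]] = None  # metabolite ids
    compartment: Optional[str] = None  # or: restrict to one compartment
    thermo: Optional[bool] = None
    alternatives: int = 1
    time_limit: Optional[float] = None
    database_reactions: Optional[str] = None  # reactions TSV (see io docs)
    database_metabolites: Optional[str] = None


def capacitance_to_json(cap: Capacitance) -> dict:
    return {
        "rho": cap.rho,
        "r_int": cap.r_int,
        "support": sorted(cap.support),
        "tau_star_r": cap.tau_star_r,
        "baseline_tau": cap.baseline_tau,
        "delta_g_kj_mol": cap.delta_g,
        "increase_percent": cap.increase_percent,
        "equation": render_equation(cap.r_int) if cap.r_int else None,
        "suboptimal": cap.suboptimal,
    }


def _resolve_allowed(model: MetabolicModel, config: RunConfig) -> Optional[frozenset[str]]:
    if config.allowed:
        return frozenset(config.allowed)
    if config.compartment:
        members = frozenset(
            m.id
            for m in model.metabolites.values()
            if m.is_internal and m.compartment == config.compartment
        )
        if not members:
            raise ValueError(f"no internal metabolites in compartment {config.compartment!r}")
        return members
    return None


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Run all stages and write the artifact bundle; returns artifact paths.

    Stages: baseline FBA; capacitance MILP (with alternatives when requested);
    decomposition over the database (when given); classification comparison.
    Each stage failure aborts with the stage name in the exception message.
    A provenance record (solver, versions, config echo) accompanies the bundle.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def stage(name: str):
        class _Stage:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return _Stage()

    with stage("load"):
        model = load_model_auto(config.model_path)
        if config.deltag_table_path:
            model = apply_gibbs_table(model, load_gibbs_table(config.deltag_table_path))
        if config.objective_reaction:
            model.objective = {config.objective_reaction: 1.0}

    with stage("fba"):
        fba = solve_fba(model)
        path = out / "fba.json"
        path.write_text(
            json.dumps(
                {"tau_star": fba.tau_star, "status": fba.status, "flux": fba.flux},
                indent=2,
            )
        )
        artifacts["fba"] = str(path)

    with stage("capacitance"):
        cap_config = CapacitanceConfig(
            mu=config.mu,
            lam=config.lam,
            allowed_set=_resolve_allowed(model, config),
            thermo_enabled=config.thermo,
            max_alternatives=max(1, config.alternatives),
            time_limit=config.time_limit,
        )
        if config.alternatives > 1:
            caps = enumerate_capacitances(model, cap_config)
        else:
            caps = [find_capacitance(model, cap_config)]
        cap = caps[0]
        path = out / "capacitance.json"
        path.write_text(
            json.dumps(
                {
                    "best": capacitance_to_json(cap),
                    "alternatives": [capacitance_to_json(c) for c in caps[1:]],
                },
                indent=2,
            )
        )
        artifacts["capacitance"] = str(path)
        if cap.r_int:
            eq_path = out / "capacitance_equation.txt"
            eq_path.write_text(render_equation(cap.r_int) + "\n")
            artifacts["equation"] = str(eq_path)

    if config.database_reactions and not cap.is_trivial and cap.r_int:
        with stage("decomposition"):
            from .io import parse_equation, parse_formula
            import pandas as pd

            extra: list[Metabolite] = []
            if config.database_metabolites:
                mets = pd.read_csv(
                    config.database_metabolites, sep="\t", dtype=str, keep_default_na=False
                )
                for row in mets.itertuples(index=False):
                    extra.append(
                        Metabolite(
                            id=row.id,
                            is_internal=False,
                            formula=parse_formula(row.formula) if row.formula else None,
                            gibbs_formation=float(row.gibbs_formation)
                            if getattr(row, "gibbs_formation", "")
                            else None,
                        )
                    )
            rxns_df = pd.read_csv(
                config.database_reactions, sep="\t", dtype=str, keep_default_na=False
            )
            known = set(model.metabolites) | {m.id for m in extra}
            db_reactions = [
                Reaction(
                    row.id,
                    parse_equation(row.equation, known),
                    -1000.0 if row.reversible and int(row.reversible) else 0.0,
                    1000.0,
                )
                for row in rxns_df.itertuples(index=False)
            ]
            db = build_database(db_reactions, model, extra)
            result = decompose(cap.r_int, db)
            payload = {
                "feasible": result.feasible,
                "alpha": result.alpha,
                "beta": result.beta,
                "residual_norm": result.residual_norm if result.feasible else None,
                "support": list(result.support),
                "certificate": result.certificate,
            }
            if result.feasible:
                payload["exact_residuals"] = verify_decomposition(cap.r_int, db, result)
            path = out / "decomposition.json"
            path.write_text(json.dumps(payload, indent=2))
            artifacts["decomposition"] = str(path)

    with stage("comparison"):
        table = compare_classifications(
            model,
            cap,
            flux_bound=config.lam / max((abs(v) for v in (cap.r_int or {"": 1}).values()), default=1),
        )
        df, summary = render_reports(table)
        tsv = out / "comparison.tsv"
        df.to_csv(tsv, sep="\t", index=False)
        (out / "comparison.json").write_text(summary)
        artifacts["comparison"] = str(tsv)
        artifacts["comparison_summary"] = str(out / "comparison.json")

    with stage("provenance"):
        prov = {
            "stoichcap_version": __version__,
            "scipy_version": scipy.__version__,
            "solver": "HiGHS (scipy.optimize, deterministic single-solve settings)",
            "python": platform.python_version(),
            "tolerances": {"classification": 1e-6, "support": 1e-6, "milp_rel_gap": 0.0},
            "config": dataclasses.asdict(config),
        }
        path = out / "provenance.json"
        path.write_text(json.dumps(prov, indent=2))
        artifacts["provenance"] = str(path)
    return artifacts
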