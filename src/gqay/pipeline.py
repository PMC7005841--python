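"""End-to-end pipeline: configuration, schema validation, stage orchestration.

A run executes simulate -> evaluate -> aggregate -> fit -> economics and
writes one CSV per stage plus a provenance manifest.  Every output CSV
starts with a comment line carrying the configuration hash and master seed,
so any table can be traced back to the exact run that produced it; read
them back with :func:`read_table`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregate import (DEFAULT_MIN_BIOMASS, aggregate_annual,
                        dropped_richness_histogram, filter_swards)
from .chemistry import DEFAULT_NEL_PER_KG_MILK, add_quality_columns
from .diversity import DiversityModel, legume_robustness, select_diversity_form
from .economics import (EconomicRates, equivalent_diversity_change,
                        hay_transfer_cost, management_switch_cost_euro,
                        reseeding_process_cost, revenue)
from .experiment import (MANAGEMENT_NAMES, SimulationParams, build_design,
                         build_swards, design_table, simulate_cuts)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig", "SchemaError", "PipelineStageError",
    "validate_table", "run_all", "write_table", "read_table", "SCHEMAS",
]


class SchemaError(ValueError):
    """A table violates its registered schema; lists offending rows."""

    def __init__(self, schema: str, problems: list[str]):
        self.schema = schema
        self.problems = problems
        super().__init__(
            f"table violates schema {schema!r}: " + "; ".join(problems[:20])
            + ("; ..." if len(problems) > 20 else "")
        )


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; partial outputs remain on disk."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


# schema registry: name -> (required columns, column -> (min, max) range checks)
SCHEMAS: dict[str, tuple[tuple[str, ...], dict[str, tuple[float, float]]]] = {
    "design": (
        ("plot_id", "block", "richness", "n_functional_groups",
         "legume_present", "legume_share", "grass_present", "tall_herb_present"),
        {"richness": (1, 60), "block": (1, 4), "legume_share": (0, 1),
         "n_functional_groups": (1, 4)},
    ),
    "cuts": (
        ("sward_id", "plot_id", "block", "management", "cuts_per_year",
         "richness", "cut", "biomass", "gas", "cp", "ee", "ndf", "ash"),
        {"biomass": (0, np.inf), "gas": (0, np.inf), "cp": (0, np.inf),
         "ee": (0, np.inf), "ndf": (0, np.inf), "ash": (0, 1000),
         "cut": (1, 4)},
    ),
    "quality": (
        ("sward_id", "cut", "biomass", "me", "nel", "milk_potential", "om", "ndf"),
        {"me": (0, np.inf), "nel": (0, np.inf), "om": (0, 1000),
         "milk_potential": (0, np.inf)},
    ),
    "annual": (
        ("sward_id", "biomass_yield", "n_cuts_used", "management", "richness",
         "quality_me", "qa_me"),
        {"biomass_yield": (0, np.inf), "n_cuts_used": (1, 4)},
    ),
}


def validate_table(table: pd.DataFrame, schema_name: str) -> pd.DataFrame:
    """Check required columns and value ranges; raise :class:`SchemaError`.

    Range checks skip missing values (NaN is legitimate for optional fields
    such as the first-cut-only incubation inputs).
    """
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_name!r}; known: {sorted(SCHEMAS)}")
    required, ranges = SCHEMAS[schema_name]
    problems: list[str] = []
    missing = [c for c in required if c not in table.columns]
    if missing:
        problems.append(f"missing columns {missing}")
    for col, (lo, hi) in ranges.items():
        if col not in table.columns:
            continue
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[(vals < lo) | (vals > hi)]
        if len(bad):
            ids = (
                table.loc[bad, "sward_id"].tolist()[:5]
                if "sward_id" in table.columns else bad.tolist()[:5]
            )
            problems.append(
                f"{col} outside [{lo}, {hi}] in {len(bad)} rows (e.g. {ids})"
            )
    if problems:
        raise SchemaError(schema_name, problems)
    return table


@dataclass
class RunConfig:
    """Full configuration of one pipeline run."""

    seed: int = 0
    simulation: SimulationParams = field(default_factory=SimulationParams)
    nel_per_kg_milk: float = DEFAULT_NEL_PER_KG_MILK
    min_biomass: float = DEFAULT_MIN_BIOMASS
    diversity_form: str = "sqrt"
    legume_term: str = "presence"
    n_tests_quality: int = 6
    responses: tuple[str, ...] = ("biomass_yield", "qa_me", "qa_milk_potential")
    rates: EconomicRates = field(default_factory=EconomicRates)
    run_form_selection: bool = True
    run_legume_robustness: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["responses"] = list(self.responses)
        d["rates"]["tasks"] = {k: list(v) for k, v in self.rates.tasks.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationParams(**d["simulation"])
        if "rates" in d and isinstance(d["rates"], dict):
            rates = dict(d["rates"])
            if "tasks" in rates:
                rates["tasks"] = {k: tuple(v) for k, v in rates["tasks"].items()}
            d["rates"] = EconomicRates(**rates)
        if "responses" in d:
            d["responses"] = tuple(d["responses"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_table(df: pd.DataFrame, path, config_hash: str, seed: int) -> None:
    """Write a CSV with a provenance comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# gqay config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a pipeline CSV, skipping provenance comment lines."""
    return pd.read_csv(path, comment="#")


def run_all(config: RunConfig, out_dir) -> Path:
    """Execute the full pipeline into ``out_dir``; returns the directory.

    Stages: simulate (design + per-cut table) -> evaluate (quality columns)
    -> aggregate (filter + annual table) -> fit (diversity models per
    response, form race, legume robustness) -> economics (revenue fit,
    switch costs, diversity-change equivalences).  A stage failure raises
    :class:`PipelineStageError`; outputs of completed stages stay on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    seed = int(config.seed)
    manifest: dict = {
        "config_hash": chash,
        "seed": seed,
        "gqay_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }

    stage = "simulate"
    try:
        params = config.simulation.with_seed(seed)
        plots = build_design(seed=seed)
        swards = build_swards(plots)
        cuts = simulate_cuts(swards, params)
        validate_table(design_table(plots), "design")
        validate_table(cuts, "cuts")
        write_table(design_table(plots), out / "design.csv", chash, seed)
        write_table(cuts, out / "cuts.csv", chash, seed)
        manifest["stages"][stage] = {"n_plots": len(plots), "n_swards": len(swards),
                                     "n_cut_rows": len(cuts)}

        stage = "evaluate"
        quality = add_quality_columns(cuts, config.nel_per_kg_milk)
        validate_table(quality, "quality")
        write_table(quality, out / "quality.csv", chash, seed)
        manifest["stages"][stage] = {"nel_per_kg_milk": config.nel_per_kg_milk}

        stage = "aggregate"
        kept, dropped = filter_swards(quality, config.min_biomass)
        annual = aggregate_annual(kept)
        # revenue response for the economic fit (Euro / ha / a)
        annual["revenue"] = annual["qa_milk_potential"] * 1.0e4 * config.rates.milk_price
        validate_table(annual, "annual")
        write_table(annual, out / "annual.csv", chash, seed)
        write_table(dropped, out / "dropped_swards.csv", chash, seed)
        manifest["stages"][stage] = {
            "min_biomass": config.min_biomass,
            "n_swards_kept": int(annual.shape[0]),
            "n_swards_dropped": int(dropped.shape[0]),
            "dropped_by_richness": {
                int(k): int(v)
                for k, v in dropped_richness_histogram(dropped).items()
            },
        }

        stage = "fit"
        effect_rows, coef_rows, pred_rows, wald_rows = [], [], [], []
        fit_info = {}
        for response in config.responses:
            res = DiversityModel(
                annual, response, config.diversity_form, config.legume_term
            ).fit()
            n_tests = 1 if response == "biomass_yield" else config.n_tests_quality
            et = res.effect_table(n_tests=n_tests)
            et.insert(0, "response", response)
            effect_rows.append(et)
            pw = res.pairwise_wald()
            pw.insert(0, "response", response)
            wald_rows.append(pw)
            coef = pd.DataFrame({
                "response": response, "term": res.fe_params.index,
                "estimate": res.fe_params.values,
                "se_model": res.bse.values, "se_robust": res.bse_robust.values,
            })
            coef_rows.append(coef)
            grid = res.predict_grid([1, 2, 4, 8, 16, 60])
            grid.insert(0, "response", response)
            pred_rows.append(grid)
            fit_info[response] = {
                "converged": bool(res.converged),
                "sigma2_block": res.sigma2_block,
                "sigma2_plot": res.sigma2_plot,
                "sigma2_resid": res.sigma2_resid,
                "aic": res.aic, "bic": res.bic,
            }
        write_table(pd.concat(effect_rows), out / "effects.csv", chash, seed)
        write_table(pd.concat(wald_rows), out / "wald_pairs.csv", chash, seed)
        write_table(pd.concat(coef_rows), out / "coefficients.csv", chash, seed)
        write_table(pd.concat(pred_rows), out / "predictions.csv", chash, seed)
        if config.run_form_selection:
            race = select_diversity_form(annual, config.responses[0],
                                         legume_term=config.legume_term)
            write_table(race, out / "form_selection.csv", chash, seed)
            fit_info["form_selection_best_bic"] = str(race.iloc[0]["form"])
        if config.run_legume_robustness:
            robust = legume_robustness(annual, config.responses[0],
                                       config.diversity_form)
            write_table(robust.reset_index(names="management"),
                        out / "legume_robustness.csv", chash, seed)
        manifest["stages"][stage] = fit_info

        stage = "economics"
        rev_fit = DiversityModel(
            annual, "revenue", config.diversity_form, config.legume_term
        ).fit()
        rev_grid = rev_fit.predict_grid([1, 2, 4, 8, 16, 60])
        rev_grid = rev_grid.rename(columns={"predicted": "revenue"})
        write_table(rev_grid, out / "revenue_predictions.csv", chash, seed)
        switch_rows = [
            {"from": a, "to": b,
             "profit_change_euro": management_switch_cost_euro(a, b, config.rates)}
            for a in MANAGEMENT_NAMES for b in MANAGEMENT_NAMES if a != b
        ]
        write_table(pd.DataFrame(switch_rows), out / "switch_costs.csv", chash, seed)
        hay = hay_transfer_cost(config.rates)
        restoration = pd.DataFrame(
            list(hay.items)
            + [("hay_transfer_total", hay.total),
               ("reseeding_process", reseeding_process_cost(config.rates)),
               ("mixture_price_diverse", config.rates.mixture_price_diverse),
               ("mixture_price_standard_adjusted",
                config.rates.mixture_price_standard_adjusted)],
            columns=["item", "euro_per_ha"],
        )
        write_table(restoration, out / "restoration_costs.csv", chash, seed)
        equiv_rows = []
        for target in ("intensive", "very_highly_intensive"):
            eq = equivalent_diversity_change(rev_fit, "less_intensive", target, 1.0)
            equiv_rows.append({
                "m_base": "less_intensive", "m_target": target,
                "d_start": eq.d_start, "d_star": eq.d_star,
                "species_rounded": eq.species_rounded,
                "revenue_gap": eq.revenue_gap, "extrapolated": eq.extrapolated,
                "no_solution": eq.no_solution,
            })
        write_table(pd.DataFrame(equiv_rows), out / "diversity_equivalents.csv",
                    chash, seed)
        manifest["stages"][stage] = {"milk_price": config.rates.milk_price}
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
        raise PipelineStageError(stage, exc) from exc

    config.to_yaml(out / "config.yaml")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    logger.info("pipeline run complete: %s", out)
    return out
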