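"""File plumbing and the end-to-end pipeline.

Tabular artifacts are CSV, fits and diagnostics JSON, configuration YAML.
Every pipeline run writes a manifest recording the configuration hash, the
derived per-stage seeds, and a hash of every artifact, so identical
configurations produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregation as agg
from . import defaults
from .cohort import PopulationConfig, simulate_dataset, simulate_selection_frame
from .data import ChoiceDataset, DATA_COLUMNS, ChoiceDataError
from .models import (
    EstimationConfig,
    FitResult,
    RPLParams,
    fit_conditional_logit,
    fit_rpl,
    lr_test,
)
from .scenario import (
    DesignConfig,
    ScenarioAttributes,
    generate_design,
    read_design,
    write_design,
)
from .selection import compute_pdiff, fit_selection_model, interaction_lr_test
from .welfare import simulate_wtp_distribution

log = logging.getLogger("cohowtp")

__all__ = [
    "read_choice_data",
    "write_choice_data",
    "read_fit",
    "write_fit",
    "RunConfig",
    "run_pipeline",
]


def read_choice_data(path) -> ChoiceDataset:
    """Read and validate a long-format choice dataset CSV."""
    df = pd.read_csv(path)
    try:
        return ChoiceDataset(df)
    except ChoiceDataError as e:
        raise ChoiceDataError(f"{path}: {e}") from None


def write_choice_data(dataset: ChoiceDataset, path) -> None:
    dataset.rows.to_csv(path, index=False, columns=DATA_COLUMNS)


def write_fit(fit: FitResult, path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=1))


def read_fit(path) -> FitResult:
    return FitResult.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Run configuration


def _sub_seed(master: int, stage: str) -> int:
    """Stable per-stage seed derived from the master seed (below 2^31)."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Nested configuration for the full design-to-benefits pipeline."""

    seed: int = 0
    design: dict = field(default_factory=dict)
    population: dict = field(default_factory=dict)
    estimation: dict = field(default_factory=dict)
    welfare: dict = field(default_factory=lambda: {"n_draws": 50_000})
    aggregation: dict = field(default_factory=dict)
    diagnostics: dict = field(
        default_factory=lambda: {"model": "clogit", "frame_size": 2000}
    )
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def canonical_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _default_scenarios() -> list[ScenarioAttributes]:
    out = []
    for (status, fish, rate) in defaults.SCENARIO_WTP:
        out.append(
            ScenarioAttributes(
                price=0.0,
                recovered=1 if status == "recovered" else 0,
                returning_fish=fish,
                quick=1 if rate == "quick" else 0,
            )
        )
    return out


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Design -> simulate -> fit -> LR test -> WTP -> aggregate -> diagnostics.

    Emits design.csv, data.csv, frame.csv, fit_clogit.json, fit_rpl.json,
    wtp.csv, benefits.csv, diag.json and manifest.json under ``outdir``.
    On a stage failure the completed artifacts are left in place and the
    error re-raised with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    seeds = {s: _sub_seed(config.seed, s) for s in
             ("design", "population", "estimation", "welfare", "diagnostics")}
    artifacts: dict[str, Path] = {}
    stage = "design"
    try:
        design_cfg = DesignConfig(**({"seed": seeds["design"]} | config.design))
        design = generate_design(design_cfg)
        artifacts["design"] = outdir / "design.csv"
        write_design(design, artifacts["design"])
        log.info("design: %d tasks", len(design))

        stage = "simulate"
        pop_kwargs = dict(config.population)
        if "params" in pop_kwargs:
            pop_kwargs["params"] = RPLParams(**pop_kwargs["params"])
        pop_cfg = PopulationConfig(**({"seed": seeds["population"]} | pop_kwargs))
        respondents, data = simulate_dataset(pop_cfg, design)
        artifacts["data"] = outdir / "data.csv"
        write_choice_data(data, artifacts["data"])
        frame = simulate_selection_frame(
            pop_cfg, config.diagnostics.get("frame_size", 2000)
        )
        artifacts["frame"] = outdir / "frame.csv"
        frame.to_csv(artifacts["frame"], index=False)

        stage = "fit"
        est_cfg = EstimationConfig(**({"seed": seeds["estimation"]} | config.estimation))
        cl = fit_conditional_logit(data, est_cfg)
        artifacts["fit_clogit"] = outdir / "fit_clogit.json"
        write_fit(cl, artifacts["fit_clogit"])
        rpl = fit_rpl(data, est_cfg)
        artifacts["fit_rpl"] = outdir / "fit_rpl.json"
        write_fit(rpl, artifacts["fit_rpl"])
        lr_stat, lr_p = lr_test(cl.loglik, rpl.loglik, df=9)
        log.info("fit: clogit LL %.2f, RPL LL %.2f, LR %.1f", cl.loglik,
                 rpl.loglik, lr_stat)

        stage = "welfare"
        scenarios = _default_scenarios()
        wtp_source = rpl if rpl.converged else rpl.to_params()
        if not rpl.converged:
            log.warning("RPL fit not converged; WTP uses point parameters")
        wtp_rows = []
        for i, sc in enumerate(scenarios):
            summ = simulate_wtp_distribution(
                wtp_source, sc,
                n_draws=config.welfare.get("n_draws", 50_000),
                seed=seeds["welfare"] + i,
            )
            wtp_rows.append(
                sc.as_row()
                | {
                    "wtp_mean": summ.mean,
                    "wtp_median": summ.median,
                    "ci_low": summ.ci_low,
                    "ci_high": summ.ci_high,
                }
            )
        wtp_df = pd.DataFrame(wtp_rows)
        artifacts["wtp"] = outdir / "wtp.csv"
        wtp_df.to_csv(artifacts["wtp"], index=False)

        stage = "aggregate"
        inputs = agg.AggregationInputs(**config.aggregation)
        lower_hh = agg.lower_bound_households(inputs)
        ben_rows = []
        for row in wtp_rows:
            wtp = max(row["wtp_mean"], 0.0)
            for bound, hh in (("lower", lower_hh), ("upper", inputs.households_total)):
                est = agg.aggregate_benefits(wtp, hh, bound=bound)
                ben_rows.append(
                    {k: row[k] for k in ("recovered", "returning_fish", "quick")}
                    | {
                        "bound": bound,
                        "households": hh,
                        "household_wtp": est.household_wtp,
                        "total": est.total,
                        "presented": est.present(),
                    }
                )
        artifacts["benefits"] = outdir / "benefits.csv"
        pd.DataFrame(ben_rows).to_csv(artifacts["benefits"], index=False)

        stage = "diagnostics"
        sel = fit_selection_model(frame)
        pdiff = compute_pdiff(sel)
        diag: dict = {
            "selection": {
                "exclusion_variable": sel.exclusion_variable,
                "exclusion_coef": sel.exclusion_coef,
                "exclusion_pvalue": sel.exclusion_pvalue,
                "mean_propensity": sel.mean_propensity,
            },
            "lr_rpl_vs_clogit": {"statistic": lr_stat, "df": 9, "p_value": lr_p},
        }
        # pdiff of frame responders, assigned to the survey respondents in
        # order (preferences and propensities are independent streams)
        pdiff_responders = pdiff[frame["responded"].to_numpy() == 1]
        resp_ids = np.sort(data.rows["resp_id"].unique())
        if len(pdiff_responders) >= len(resp_ids):
            moderator = pd.Series(
                pdiff_responders[: len(resp_ids)].astype(float), index=resp_ids
            )
            test = interaction_lr_test(
                data,
                moderator,
                config=est_cfg,
                model=config.diagnostics.get("model", "clogit"),
            )
            diag["pdiff_interaction"] = {
                "statistic": test.statistic,
                "df": test.df,
                "p_value": test.p_value,
            }
        artifacts["diag"] = outdir / "diag.json"
        artifacts["diag"].write_text(json.dumps(diag, indent=1))

        manifest = {
            "config": json.loads(config.canonical_json()),
            "config_hash": config.config_hash(),
            "seeds": seeds,
            "artifacts": {k: {"path": p.name, "sha256": _sha256(p)}
                          for k, p in artifacts.items()},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest
    except Exception as e:
        raise RuntimeError(
            f"pipeline failed at stage '{stage}' "
            f"(completed artifacts kept in {outdir}): {e}"
        ) from e
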