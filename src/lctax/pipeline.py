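"""Top-level pipeline: model selection, seven-method covariate table, and the
taxometric suite, in one reproducible run."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import __version__
from .ccfi import run_taxometric_suite
from .datasets import indicator_matrix_from_dataset
from .io import RunConfig, curves_to_frame, read_dataset, suite_report, write_json_report
from .lca import select_model
from .stepwise import compare_methods

log = logging.getLogger(__name__)


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Execute the configured stages and assemble one master report.

    Stages run in order (LCA model selection, step-wise covariate table,
    taxometric suite); a stage is skipped when its config block is absent.
    A stage failure aborts the stages that depend on it but partial outputs
    are retained in the report.
    """
    if config.input is None:
        raise ValueError("config.input is required")
    if config.seed is None and (config.lca or config.stepwise or config.taxometrics):
        raise ValueError("a seed is required for stochastic stages")
    outdir = Path(config.output_dir)
    report: dict = {
        "lctax_version": __version__,
        "seed": config.seed,
        "settings": {
            "input": str(config.input),
            "items": config.items,
            "covariates": config.covariates,
            "lca": config.lca,
            "stepwise": config.stepwise,
            "taxometrics": config.taxometrics,
        },
        "stages": {},
    }
    data, ingestion = read_dataset(config.input, config.items or None,
                                   config.covariates or None, config.id_column)
    report["ingestion"] = {
        "n_rows_read": ingestion.n_rows_read,
        "n_rows_kept": ingestion.n_rows_kept,
        "n_rows_dropped_missing": ingestion.n_rows_dropped_missing,
    }

    chosen_c = config.stepwise.get("n_classes") if config.stepwise else None
    if config.lca:
        lca_cfg = dict(config.lca)
        c_range = lca_cfg.pop("c_range", [1, 2, 3])
        table = select_model(data, c_range, seed=config.stage_seed("lca"), **lca_cfg)
        report["stages"]["lca"] = table.to_dict(orient="records")
        if write:
            outdir.mkdir(parents=True, exist_ok=True)
            table.to_csv(outdir / "model_selection.csv", index=False)
        ok = table[table.get("error", "") == ""] if "error" in table else table
        if chosen_c is None and not ok.empty and "bic" in ok:
            chosen_c = int(ok.loc[ok["bic"].idxmin(), "n_classes"])
            log.info("BIC selects %d classes", chosen_c)

    if config.stepwise:
        if chosen_c is None:
            report["stages"]["stepwise"] = {"error": "no class count available"}
        else:
            sw_cfg = {k: v for k, v in config.stepwise.items() if k != "n_classes"}
            try:
                table = compare_methods(data, chosen_c,
                                        seed=config.stage_seed("stepwise"), **sw_cfg)
                report["stages"]["stepwise"] = table.to_dict(orient="records")
                if write:
                    outdir.mkdir(parents=True, exist_ok=True)
                    table.to_csv(outdir / "stepwise_methods.csv", index=False)
            except ValueError as exc:
                log.warning("step-wise stage failed: %s", exc)
                report["stages"]["stepwise"] = {"error": str(exc)}

    if config.taxometrics:
        tx_cfg = dict(config.taxometrics)
        if "procedures" in tx_cfg:
            tx_cfg["procedures"] = tuple(tx_cfg["procedures"])
        indicators = indicator_matrix_from_dataset(data)
        suite = run_taxometric_suite(indicators, seed=config.stage_seed("taxometrics"),
                                     **tx_cfg)
        report["stages"]["taxometrics"] = suite_report(suite)
        if write:
            outdir.mkdir(parents=True, exist_ok=True)
            emp = curves_to_frame({p: c for p, c in suite["empirical_curves"].items()})
            emp["role"] = "empirical"
            frames = [emp]
            for role, block in [("categorical", suite["categorical_curves"]),
                                ("dimensional", suite["dimensional_curves"])]:
                for proc, entry in block.items():
                    if "mean" not in entry:
                        continue
                    mf = curves_to_frame([entry["mean"]], proc)
                    mf["role"] = f"{role}_mean"
                    mf["sd"] = entry["sd"]
                    frames.append(mf)
            import pandas as pd

            pd.concat(frames, ignore_index=True).to_csv(outdir / "curves.csv",
                                                        index=False)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        write_json_report(report, outdir / "report.json")
    return report
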