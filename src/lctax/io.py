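"""Dataset ingestion, run configuration, and report/curve export."""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .curves import TaxometricCurve
from .datasets import CategoricalDataset, IndicatorMatrix

log = logging.getLogger(__name__)


@dataclass
class IngestionReport:
    n_rows_read: int
    n_rows_kept: int
    n_rows_dropped_missing: int
    category_ranges: dict[str, tuple[int, int]]


@dataclass
class RunConfig:
    """Typed configuration for the pipeline and CLI commands.

    A flat YAML document with the same keys; every stochastic command requires
    a seed so results can be reproduced from the embedded settings record.
    """

    input: str | None = None
    items: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    id_column: str | None = None
    seed: int | None = None
    output_dir: str = "lctax_output"
    lca: dict = field(default_factory=dict)
    stepwise: dict = field(default_factory=dict)
    taxometrics: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def stage_seed(self, stage: str) -> int | None:
        """Stage-name-keyed substream of the master seed.

        Each stage draws from its own deterministic stream, so adding a stage
        never perturbs another stage's random numbers.
        """
        if self.seed is None:
            return None
        return int(
            np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
            .generate_state(1)[0] & 0x7FFFFFFF
        )


def read_dataset(
    path: str | Path,
    items: list[str] | None = None,
    covariates: list[str] | None = None,
    id_column: str | None = None,
) -> tuple[CategoricalDataset, IngestionReport]:
    """Read a case-by-item CSV into a validated dataset.

    Item columns must be integer category codes; rows with any missing value
    in the selected columns are dropped (complete-case ingestion) and counted
    in the report.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty input file: {path}")
    items = items or [c for c in df.columns if c != id_column]
    covariates = covariates or []
    for col in items + covariates + ([id_column] if id_column else []):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    n_read = len(df)
    used = items + covariates
    keep = df[used].notna().all(axis=1)
    if (~keep).any():
        log.warning("dropping %d rows with missing values", int((~keep).sum()))
    df = df[keep].copy()
    if df.empty:
        raise ValueError("no complete cases after dropping missing values")
    for col in items:
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.isna() | (num != num.round())
        if bad.any():
            row = int(df.index[bad][0])
            raise ValueError(f"non-integer item value in column {col!r}, row {row}")
        df[col] = num.astype(np.int64)
    responses = df[items].to_numpy(dtype=np.int64)
    cov = df[covariates].to_numpy(dtype=float) if covariates else None
    ids = df[id_column].to_numpy() if id_column else None
    data = CategoricalDataset(responses, case_ids=ids, covariates=cov,
                              item_labels=list(items),
                              covariate_labels=list(covariates) or None)
    report = IngestionReport(
        n_rows_read=n_read,
        n_rows_kept=len(df),
        n_rows_dropped_missing=n_read - len(df),
        category_ranges={c: (int(df[c].min()), int(df[c].max())) for c in items},
    )
    return data, report


def read_indicator_matrix(
    path: str | Path, columns: list[str] | None = None
) -> IndicatorMatrix:
    """Read numeric indicator columns for taxometric analysis."""
    df = pd.read_csv(path)
    cols = columns or list(df.columns)
    sub = df[cols].dropna()
    if len(sub) < len(df):
        log.warning("dropping %d rows with missing values", len(df) - len(sub))
    return IndicatorMatrix(sub.to_numpy(dtype=float), list(cols))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json_report(report: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, cls=_NumpyEncoder)


def curves_to_frame(curves: dict | list, procedure: str | None = None) -> pd.DataFrame:
    """Tidy export of taxometric curves: one row per curve point."""
    rows = []

    def _add(curve: TaxometricCurve, source: str) -> None:
        for g, x, y in zip(curve.grid, curve.x, curve.y):
            rows.append({
                "procedure": curve.procedure,
                "source": source,
                "input": curve.input_label,
                "outputs": "|".join(curve.output_labels),
                "grid": g,
                "x": x,
                "y": y,
            })

    if isinstance(curves, dict):
        for name, curve in curves.items():
            _add(curve, name)
    else:
        for curve in curves:
            _add(curve, procedure or curve.procedure)
    return pd.DataFrame(rows)


def suite_report(suite: dict) -> dict:
    """JSON-serializable summary of a taxometric suite run."""
    return {
        "seed": suite["seed"],
        "base_rate": suite["base_rate"],
        "base_rate_source": suite["base_rate_source"],
        "procedures": suite["procedures"],
        "ccfi": {
            r.procedure: {
                "rmsr_cat": r.rmsr_cat,
                "rmsr_dim": r.rmsr_dim,
                "ccfi": r.ccfi,
                "verdict": r.verdict,
                "ccfi_se": None if np.isnan(r.ccfi_se) else r.ccfi_se,
                "n_comparison_samples": r.n_comparison_samples,
                "population_size": r.population_size,
            }
            for r in suite["results"]
        },
        "mean_ccfi": suite["mean"].ccfi,
        "mean_verdict": suite["mean"].verdict,
        "pooled_ccfi": suite["pooled"].ccfi,
        "pooled_verdict": suite["pooled"].verdict,
        "comparison_tolerances": {
            "categorical_rms": suite["categorical_population"].achieved_rms,
            "dimensional_rms": suite["dimensional_population"].achieved_rms,
        },
    }
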