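"""CSV readers/writers and pipeline configuration.

All interchange formats are flat CSV tables:

* Kinetics: long format with columns (condition, medium, time_h, replicate,
  observable, value); observable is ``live_cells`` or
  ``pct_differentiated``; times in hours.
* Expression: one gene x cell matrix per condition-timepoint (first column
  ``gene``, remaining columns cells), listed in a manifest CSV with columns
  (file, condition, timepoint_h).
* Entropy / relative-entropy / selection reports are written as plain CSVs.

Configuration is a YAML mapping that round-trips unchanged; every random
operation receives an explicit seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .entropy import ExpressionMatrix
from .exceptions import SchemaError
from .kinetics import MEDIA, SELF_RENEWAL
from .likelihood import OBSERVABLES, PCT_DIFFERENTIATED, KineticsDataset

__all__ = [
    "PipelineConfig",
    "read_kinetics_csv",
    "write_kinetics_csv",
    "read_expression_csvs",
    "write_expression_csvs",
    "load_config",
    "save_config",
]

KINETICS_COLUMNS = ("condition", "medium", "time_h", "replicate", "observable", "value")


@dataclass
class PipelineConfig:
    """Settings shared by the CLI subcommands; round-trips through YAML."""

    kinetics_control: str | None = None
    kinetics_treatment: str | None = None
    expression_manifest: str | None = None
    output_dir: str = "results"
    seed: int = 0
    n_restarts: int = 50
    n_restarts_variant: int = 10
    threshold: float = 0.95
    fit_strategy: str = "joint"
    bounds: dict = field(default_factory=dict)
    gtol: float = 1e-8
    max_iter: int = 1000
    epsilon: float = 0.01
    clearance_T: float = 48.0
    Nc: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = PipelineConfig().to_dict()
    unknown = set(raw) - set(known)
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def _schema_fail(path, problems):
    lines = "; ".join(problems[:10])
    raise SchemaError(f"{path}: {lines}")


def read_kinetics_csv(path, y0: dict | None = None) -> KineticsDataset:
    """Read and validate a long-format kinetics CSV.

    ``y0`` maps medium to the initial number of seeded cells; when omitted
    it is taken as the mean live-cell count at t = 0 per medium.
    """
    df = pd.read_csv(path)
    problems = []
    missing = set(KINETICS_COLUMNS) - set(df.columns)
    if missing:
        _schema_fail(path, [f"missing columns {sorted(missing)}"])
    for col in ("time_h", "value"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        for i in bad:
            problems.append(f"row {i + 2}: non-numeric {col} = {df.loc[i, col]!r}")
    bad_obs = df.index[~df["observable"].isin(OBSERVABLES)]
    for i in bad_obs:
        problems.append(f"row {i + 2}: unknown observable {df.loc[i, 'observable']!r}")
    bad_med = df.index[~df["medium"].isin(MEDIA)]
    for i in bad_med:
        problems.append(f"row {i + 2}: unknown medium {df.loc[i, 'medium']!r}")
    if problems:
        _schema_fail(path, problems)
    df["time_h"] = df["time_h"].astype(float)
    df["value"] = df["value"].astype(float)
    pct = df["observable"] == PCT_DIFFERENTIATED
    bad_pct = df.index[pct & ~df["value"].between(0, 100)]
    for i in bad_pct:
        problems.append(f"row {i + 2}: percent differentiated {df.loc[i, 'value']} outside [0, 100]")
    bad_counts = df.index[~pct & (df["value"] <= 0)]
    for i in bad_counts:
        problems.append(f"row {i + 2}: non-positive cell count {df.loc[i, 'value']}")
    if problems:
        _schema_fail(path, problems)
    if y0 is None:
        at0 = df[(df["time_h"] == 0) & ~pct]
        if at0.empty:
            _schema_fail(path, ["no t = 0 live-cell rows to derive y0 from"])
        y0 = at0.groupby("medium")["value"].mean().to_dict()
    condition = str(df["condition"].iloc[0]) if len(df) else "control"
    return KineticsDataset(data=df[list(KINETICS_COLUMNS)], y0=y0, condition=condition)


def write_kinetics_csv(dataset: KineticsDataset, path) -> None:
    dataset.data.to_csv(path, index=False, columns=list(KINETICS_COLUMNS))


def read_expression_csvs(manifest_path) -> list[ExpressionMatrix]:
    """Read the expression matrices listed in a manifest CSV.

    The manifest has columns (file, condition, timepoint_h); file paths are
    resolved relative to the manifest.  All matrices must share an
    identical gene set.
    """
    manifest_path = Path(manifest_path)
    man = pd.read_csv(manifest_path)
    missing = {"file", "condition", "timepoint_h"} - set(man.columns)
    if missing:
        _schema_fail(manifest_path, [f"missing manifest columns {sorted(missing)}"])
    matrices = []
    for _, row in man.iterrows():
        fpath = manifest_path.parent / row["file"]
        df = pd.read_csv(fpath)
        if df.columns[0] != "gene":
            _schema_fail(fpath, ["first column must be 'gene'"])
        df = df.set_index("gene")
        df.index.name = None
        if not np.issubdtype(df.to_numpy().dtype, np.number):
            _schema_fail(fpath, ["non-numeric expression values"])
        matrices.append(
            ExpressionMatrix(
                values=df,
                condition=str(row["condition"]),
                timepoint=float(row["timepoint_h"]),
            )
        )
    genes0 = matrices[0].genes
    for m in matrices[1:]:
        if m.genes != genes0:
            diff = sorted(set(m.genes) ^ set(genes0))
            raise SchemaError(
                f"gene sets differ between matrices; offending genes: {diff[:20]}"
            )
    return matrices


def write_expression_csvs(
    matrices: list[ExpressionMatrix], out_dir, manifest_name: str = "manifest.csv"
) -> Path:
    """Write matrices and their manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for m in matrices:
        fname = f"expression_{m.condition}_{m.timepoint:g}h.csv"
        m.values.rename_axis("gene").to_csv(out_dir / fname)
        records.append({"file": fname, "condition": m.condition, "timepoint_h": m.timepoint})
    manifest = out_dir / manifest_name
    pd.DataFrame(records).to_csv(manifest, index=False)
    return manifest
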