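"""Readers and writers for expression matrices, annotations, DEG tables and configs.

Formats are delimited text (tab or comma, auto-detected), plus a flat YAML-ish
key-value file for :class:`~txsig.datatypes.RunConfig`. Floats are written at six
significant digits and round-trip to that precision.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .datatypes import DEGTable, ExpressionMatrix, GroupAnnotation, RunConfig, ValidationError

__all__ = [
    "read_expression_matrix",
    "read_sample_annotation",
    "read_deg_table",
    "read_config",
    "write_table",
    "write_run_summary",
]

FLOAT_FORMAT = "%.6g"


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    has_tab, has_comma = "\t" in header, "," in header
    if has_tab and has_comma:
        raise ValidationError(
            f"{path}: ambiguous delimiter (header contains both tab and comma)"
        )
    if has_tab:
        return "\t"
    if has_comma:
        return ","
    # single-column files: delimiter irrelevant
    return "\t"


def read_expression_matrix(path: str | Path, unit: str) -> ExpressionMatrix:
    """Read a genes-in-rows, samples-in-columns delimited matrix.

    First column holds gene ids, header row holds sample ids. Duplicated ids,
    non-numeric cells and missing values are hard errors (no imputation).
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.empty:
        raise ValidationError(f"{path}: empty matrix")
    genes = [str(g) for g in df.index]
    samples = [str(s) for s in df.columns]
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                raise ValidationError(
                    f"{path}: missing value at gene {genes[i]!r}, sample {samples[j]!r}"
                )
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: non-numeric cell {cell!r} at gene {genes[i]!r}, "
                    f"sample {samples[j]!r}"
                ) from None
    return ExpressionMatrix(tuple(genes), tuple(samples), values, unit)


def read_sample_annotation(path: str | Path, *, extensible: bool = False) -> GroupAnnotation:
    """Read a two-column (sample_id, group) table into a :class:`GroupAnnotation`."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no annotations (empty file)") from None
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected two columns (sample_id, group)")
    if df.empty:
        raise ValidationError(f"{path}: no annotations")
    mapping: dict[str, str] = {}
    for sample, group in zip(df.iloc[:, 0], df.iloc[:, 1]):
        sample, group = str(sample), str(group)
        if sample in mapping and mapping[sample] != group:
            raise ValidationError(
                f"{path}: sample {sample!r} annotated with conflicting groups "
                f"{mapping[sample]!r} and {group!r}"
            )
        mapping[sample] = group
    return GroupAnnotation(mapping, extensible=extensible)


def read_deg_table(path: str | Path) -> DEGTable:
    """Read a three-column (gene, log2fc, p_value) DEG table."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 3:
        raise ValidationError(f"{path}: expected columns gene, log2fc, p_value")
    df = df.iloc[:, :3].copy()
    df.columns = ["gene", "log2fc", "p_value"]
    df["gene"] = df["gene"].astype(str)
    for col in ("log2fc", "p_value"):
        try:
            df[col] = df[col].astype(float)
        except (TypeError, ValueError):
            raise ValidationError(f"{path}: non-numeric {col} column") from None
    return DEGTable(df)


def read_config(path: str | Path) -> RunConfig:
    """Read a flat key-value config file (YAML syntax) into a RunConfig."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a flat key-value mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
    for key in ("oversamplers", "classifiers"):
        if key in data and isinstance(data[key], str):
            data[key] = tuple(x.strip() for x in data[key].split(","))
    return RunConfig(**data)


def write_table(result: pd.DataFrame, path: str | Path, *, index: bool = False) -> None:
    """Write a tabular result as TSV with deterministic column order and
    floats at six significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        result.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT,
                      lineterminator="\n")
    except OSError as exc:
        raise ValidationError(f"cannot write {path}: {exc}") from exc


def write_run_summary(path: str | Path, *, seed: int, config: RunConfig,
                      extra: dict[str, Any] | None = None) -> None:
    """JSON run summary: seed, library versions, config echo."""
    import sklearn

    payload: dict[str, Any] = {
        "seed": seed,
        "versions": {
            "txsig": _version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
    }
    if extra:
        payload.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _version() -> str:
    from . import __version__

    return __version__
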