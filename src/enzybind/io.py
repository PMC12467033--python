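"""CSV loaders, the JSON report writer and the table schemas.

All tabular input is RFC-4180 CSV with a header row; column names carry the
unit (``substrate_mmol_per_l``, ``temperature_k``, ...) so that a file is
self-describing.  Errors report 1-based data-row indices.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    DoseResponseSeries,
    FtirSpectrum,
    KineticSeries,
    QuenchTitration,
    ReversibilitySeries,
)
from .errors import EmptyTableError, SchemaError, TableParseError

#: required (and optional) columns per table kind
TABLE_SCHEMAS: dict[str, dict[str, tuple[str, ...]]] = {
    "kinetics": {
        "required": (
            "inhibitor_ug_per_ml",
            "substrate_mmol_per_l",
            "velocity_dod_per_min",
        ),
        "optional": (),
    },
    "titration": {
        "required": ("temperature_k", "quencher_mol_per_l", "intensity"),
        "optional": ("a_ex", "a_em"),
    },
    "dose_response": {
        "required": ("concentration_ug_per_ml", "inhibition_percent"),
        "optional": ("compound", "enzyme"),
    },
    "vant_hoff": {
        "required": ("temperature_k", "ka_l_per_mol"),
        "optional": (),
    },
    "reversibility": {
        "required": (
            "inhibitor_ug_per_ml",
            "enzyme_activity_u_per_l",
            "velocity_dod_per_min",
        ),
        "optional": (),
    },
    "ftir": {
        "required": ("wavenumber_cm_1", "absorbance"),
        "optional": (),
    },
}

_NON_NUMERIC = ("compound", "enzyme")


def _read_validated(path, kind: str) -> pd.DataFrame:
    if kind not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown table kind {kind!r}")
    schema = TABLE_SCHEMAS[kind]
    df = pd.read_csv(path)
    for col in schema["required"]:
        if col not in df.columns:
            raise SchemaError(
                f"{path}: table kind {kind!r} requires column {col!r}"
            )
    if df.empty:
        raise EmptyTableError(f"{path}: table has a header but no data rows")
    keep = [c for c in df.columns
            if c in schema["required"] + schema["optional"]]
    df = df[keep]
    for col in keep:
        if col in _NON_NUMERIC:
            continue
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()]
        if len(bad):
            raise TableParseError(
                f"{path}: non-numeric value {df[col][bad[0]]!r} in column "
                f"{col!r} at row {bad[0] + 1}",
                row=int(bad[0]) + 1,
            )
        df[col] = numeric
    return df


def _check_nonnegative(path, df: pd.DataFrame, column: str) -> None:
    bad = df.index[df[column] < 0]
    if len(bad):
        raise TableParseError(
            f"{path}: negative value in column {column!r} at row {bad[0] + 1}",
            row=int(bad[0]) + 1,
        )


def load_table(path, kind: str):
    """Load and validate one CSV table.

    Returns the container type matching ``kind``: a list of
    :class:`KineticSeries` / :class:`QuenchTitration` /
    :class:`ReversibilitySeries` (grouped by inhibitor level or
    temperature, in order of first appearance), a
    :class:`DoseResponseSeries`, a list of (T, Ka) pairs, or an
    :class:`FtirSpectrum`.
    """
    df = _read_validated(path, kind)
    if kind == "kinetics":
        _check_nonnegative(path, df, "inhibitor_ug_per_ml")
        out = []
        for conc in df["inhibitor_ug_per_ml"].unique():
            g = df[df["inhibitor_ug_per_ml"] == conc]
            out.append(
                KineticSeries(
                    float(conc),
                    tuple(g["substrate_mmol_per_l"]),
                    tuple(g["velocity_dod_per_min"]),
                )
            )
        return out
    if kind == "titration":
        _check_nonnegative(path, df, "quencher_mol_per_l")
        has_if = "a_ex" in df.columns and "a_em" in df.columns
        out = []
        for t in df["temperature_k"].unique():
            g = df[df["temperature_k"] == t]
            out.append(
                QuenchTitration(
                    float(t),
                    tuple(g["quencher_mol_per_l"]),
                    tuple(g["intensity"]),
                    tuple(g["a_ex"]) if has_if else None,
                    tuple(g["a_em"]) if has_if else None,
                )
            )
        return out
    if kind == "dose_response":
        _check_nonnegative(path, df, "concentration_ug_per_ml")
        compound = str(df["compound"].iloc[0]) if "compound" in df.columns else "unknown"
        enzyme = str(df["enzyme"].iloc[0]) if "enzyme" in df.columns else "alpha_amylase"
        return DoseResponseSeries(
            compound=compound,
            enzyme=enzyme,
            concentrations=tuple(df["concentration_ug_per_ml"]),
            inhibition=tuple(df["inhibition_percent"]),
        )
    if kind == "vant_hoff":
        return list(zip(df["temperature_k"].astype(float), df["ka_l_per_mol"].astype(float)))
    if kind == "reversibility":
        out = []
        for conc in df["inhibitor_ug_per_ml"].unique():
            g = df[df["inhibitor_ug_per_ml"] == conc]
            out.append(
                ReversibilitySeries(
                    float(conc),
                    tuple(g["enzyme_activity_u_per_l"]),
                    tuple(g["velocity_dod_per_min"]),
                )
            )
        return out
    if kind == "ftir":
        return FtirSpectrum(tuple(df["wavenumber_cm_1"]), tuple(df["absorbance"]))
    raise SchemaError(f"unknown table kind {kind!r}")  # pragma: no cover


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None  # JSON has no NaN/inf
    return obj


def write_report(results, path, config=None) -> None:
    """Serialize stage results (dataclasses, dicts, arrays) to a JSON report.

    The output is deterministic for identical inputs: keys are sorted and
    floats use repr round-tripping, so two runs with the same config and
    seed produce byte-identical files.
    """
    payload = {"config": _jsonable(config), "results": _jsonable(results)}
    text = json.dumps(payload, sort_keys=True, indent=2, allow_nan=False)
    Path(path).write_text(text + "\n", encoding="utf-8")


def read_report(path) -> dict:
    """Parse a report written by :func:`write_report`."""
    return json.loads(Path(path).read_text(encoding="utf-8"))
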