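"""CSV schemas and strict, attributable table I/O.

Every table in the pipeline has a fixed schema (exact header match,
UTF-8, RFC-4180 quoting). Reads fail loudly, naming missing/extra
columns, and malformed values are reported with their line numbers.
Writes can attach a JSON sidecar (``<file>.meta.json``) recording the
tool version, seed and config hash so reruns are attributable; the CSV
itself stays clean so that read(write(x)) == x.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import SchemaError

__all__ = ["SCHEMAS", "TableSchema", "read_table", "write_table"]


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[str, ...]
    dtypes: dict  # column -> "int" | "float" | "bool" | "str"
    nullable: tuple[str, ...] = ()


SCHEMAS = {
    s.name: s
    for s in [
        TableSchema(
            "habitat_evidence",
            (
                "species_id", "life_stage", "method", "habitat_kind", "substrate",
                "coral_assoc", "live_coral_dependent", "live_coral_obligate",
                "source_ref",
            ),
            {
                "species_id": "str", "life_stage": "str", "method": "str",
                "habitat_kind": "str", "substrate": "str", "coral_assoc": "bool",
                "live_coral_dependent": "bool", "live_coral_obligate": "bool",
                "source_ref": "str",
            },
        ),
        TableSchema(
            "group_map",
            ("group_label", "member_species", "resolution"),
            {"group_label": "str", "member_species": "str", "resolution": "str"},
        ),
        TableSchema(
            "catch",
            ("taxon_label", "region", "sector", "year", "quantity", "basis"),
            {
                "taxon_label": "str", "region": "str", "sector": "str",
                "year": "int", "quantity": "float", "basis": "str",
            },
        ),
        TableSchema(
            "region",
            ("region", "reef_pct"),
            {"region": "str", "reef_pct": "float"},
        ),
        TableSchema(
            "cpue",
            ("stock_id", "year", "catch_t", "cpue"),
            {"stock_id": "str", "year": "int", "catch_t": "float", "cpue": "float"},
            nullable=("cpue",),
        ),
        TableSchema(
            "catalog",
            ("group_label", "category"),
            {"group_label": "str", "category": "int"},
        ),
        TableSchema(
            "rejects",
            ("group_label", "reason"),
            {"group_label": "str", "reason": "str"},
        ),
        TableSchema(
            "profiles",
            ("key", "category", "percent", "total", "excluded", "basis"),
            {
                "key": "str", "category": "int", "percent": "float",
                "total": "float", "excluded": "float", "basis": "str",
            },
            nullable=("percent",),
        ),
        TableSchema(
            "regression_summary",
            ("category", "median_slope", "p_positive", "p_negative",
             "ci_low", "ci_high"),
            {
                "category": "int", "median_slope": "float", "p_positive": "float",
                "p_negative": "float", "ci_low": "float", "ci_high": "float",
            },
        ),
        TableSchema(
            "spm_draws",
            ("chain", "draw", "r", "K", "q_pre", "q_post", "sigma_obs", "psi",
             "msy", "depletion"),
            {
                "chain": "int", "draw": "int", "r": "float", "K": "float",
                "q_pre": "float", "q_post": "float", "sigma_obs": "float",
                "psi": "float", "msy": "float", "depletion": "float",
            },
        ),
        TableSchema(
            "regression_draws",
            ("chain", "draw", "alpha", "beta", "sigma"),
            {
                "chain": "int", "draw": "int", "alpha": "float",
                "beta": "float", "sigma": "float",
            },
        ),
        TableSchema(
            "risk",
            ("stock_id", "reduction_pct", "probability"),
            {"stock_id": "str", "reduction_pct": "int", "probability": "float"},
        ),
        TableSchema(
            "truth",
            ("taxon_label", "true_category"),
            {"taxon_label": "str", "true_category": "int"},
        ),
    ]
}

_BOOL_MAP = {"True": True, "False": False, "true": True, "false": False}


def read_table(path, schema: TableSchema | str) -> pd.DataFrame:
    """Read a schema'd CSV strictly.

    Raises SchemaError naming missing/extra columns, or listing the
    1-based file line numbers of rows whose values fail type conversion.
    An empty file with a valid header yields an empty table.
    """
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    got, want = list(df.columns), list(schema.columns)
    if got != want:
        missing = sorted(set(want) - set(got))
        extra = sorted(set(got) - set(want))
        raise SchemaError(
            f"{path.name}: header does not match schema {schema.name!r}; "
            f"missing columns {missing}, unknown columns {extra}"
        )
    bad_lines: list[int] = []
    out = {}
    for col in want:
        kind = schema.dtypes[col]
        raw = df[col]
        if kind == "str":
            out[col] = raw
            continue
        if kind == "bool":
            vals = raw.map(_BOOL_MAP)
            bad = vals.isna()
        else:
            vals = pd.to_numeric(raw.replace("", None), errors="coerce")
            bad = vals.isna() & (raw != "")
            if col in schema.nullable:
                pass
            else:
                bad = bad | (raw == "")
            if kind == "int" and not bad.any() and len(vals):
                vals = vals.astype(int)
        if len(df) and bad.any():
            # +2: header line plus 1-based indexing
            bad_lines.extend((df.index[bad] + 2).tolist())
            continue
        out[col] = vals
    if bad_lines:
        raise SchemaError(
            f"{path.name}: malformed values at line(s) {sorted(set(bad_lines))}"
        )
    result = pd.DataFrame(out, columns=want)
    if len(result) == 0:
        # keep declared dtypes on empty tables
        for col in want:
            kind = schema.dtypes[col]
            if kind in ("int", "float"):
                result[col] = result[col].astype(float if kind == "float" else int)
            elif kind == "bool":
                result[col] = result[col].astype(bool)
    return result


def write_table(df: pd.DataFrame, path, schema: TableSchema | str,
                meta: dict | None = None) -> Path:
    """Write a schema'd CSV (plus an optional provenance sidecar)."""
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    path = Path(path)
    missing = set(schema.columns) - set(df.columns)
    if missing:
        raise SchemaError(
            f"cannot write {schema.name!r}: missing columns {sorted(missing)}"
        )
    path.parent.mkdir(parents=True, exist_ok=True)
    df[list(schema.columns)].to_csv(path, index=False, encoding="utf-8")
    if meta is not None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        payload = {"tool": "reefcatch", "version": __version__, **meta}
        sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
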