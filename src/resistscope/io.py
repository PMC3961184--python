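"""Table schemas, validation and serialization.

All pipeline I/O is plain UTF-8 tab-separated text with a header row
('.' decimal); the assay tables are small, so transparency beats
compactness.  :func:`load_and_validate` checks column presence, value
types and row-level invariants and reports failures with file, line
and column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["load_and_validate", "write_table", "SCHEMAS", "ValidationError"]


class ValidationError(ValueError):
    pass


_CONTROL_TYPES = {"none", "SS", "GG", "NTC"}
_PHENOTYPES = {"alive", "dead", "untested"}


def _finite(s: pd.Series) -> pd.Series:
    return np.isfinite(s.astype(float))


# schema: column -> (dtype, row predicate or None, description)
SCHEMAS: dict[str, dict] = {
    "mvalues": {
        "columns": {
            "probe_id": (str, None, ""),
            "array_id": (str, None, ""),
            "M": (float, _finite, "finite"),
        },
        "unique": ["probe_id", "array_id"],
    },
    "scheme": {
        "columns": {
            "array_id": (str, None, ""),
            "cy3_sample": (str, None, ""),
            "cy5_sample": (str, None, ""),
        },
        "unique": ["array_id"],
        "row_check": (
            lambda r: r["cy3_sample"] != r["cy5_sample"],
            "cy3 and cy5 samples must differ",
        ),
    },
    "samples": {
        "columns": {"sample_id": (str, None, ""), "group": (str, None, "")},
        "unique": ["sample_id"],
    },
    "probe2gene": {
        "columns": {"probe_id": (str, None, ""), "gene_id": (str, None, "")},
        "unique": ["probe_id"],
    },
    "ct": {
        "columns": {
            "sample_id": (str, None, ""),
            "amplicon": (str, None, ""),
            "replicate": (int, lambda s: s >= 1, ">= 1"),
            "ct": (float, lambda s: _finite(s) & (s > 0), "positive"),
        },
        "unique": ["sample_id", "amplicon", "replicate"],
    },
    "efficiencies": {
        "columns": {
            "amplicon": (str, None, ""),
            "efficiency": (float, lambda s: (s > 0.5) & (s <= 1.2), "in (0.5, 1.2]"),
        },
        "unique": ["amplicon"],
    },
    "taqman": {
        "columns": {
            "sample_id": (str, None, ""),
            "fam_dR": (float, lambda s: _finite(s) & (s >= 0), ">= 0"),
            "vic_dR": (float, lambda s: _finite(s) & (s >= 0), ">= 0"),
            "control_type": (str, lambda s: s.isin(_CONTROL_TYPES), str(_CONTROL_TYPES)),
            "phenotype": (str, lambda s: s.isin(_PHENOTYPES), str(_PHENOTYPES)),
        },
        "unique": ["sample_id"],
    },
    "bioassay": {
        "columns": {
            "insecticide": (str, None, ""),
            "season": (str, None, ""),
            "pbo": (bool, None, ""),
            "replicate": (int, lambda s: s >= 1, ">= 1"),
            "n_exposed": (int, lambda s: s > 0, "positive"),
            "n_dead": (int, lambda s: s >= 0, ">= 0"),
        },
        "row_check": (
            lambda r: r["n_dead"] <= r["n_exposed"],
            "n_dead must not exceed n_exposed",
        ),
    },
    "dose": {
        "columns": {
            "line_id": (str, None, ""),
            "dose_ug": (float, lambda s: s > 0, "positive"),
            "n": (int, lambda s: s > 0, "positive"),
            "n_survived": (float, lambda s: s >= 0, ">= 0"),
        },
        "row_check": (
            lambda r: r["n_survived"] <= r["n"],
            "n_survived must not exceed n",
        ),
    },
    "hplc": {
        "columns": {
            "condition": (str, None, ""),
            "nadph": (bool, None, ""),
            "replicate": (int, lambda s: s >= 1, ">= 1"),
            "peak_area": (float, lambda s: _finite(s) & (s >= 0), ">= 0"),
        },
    },
}

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False,
}


def load_and_validate(path: str | Path, schema_id: str) -> pd.DataFrame:
    """Read a TSV and enforce its schema; errors name the file, the
    1-based data line and the offending column."""
    if schema_id not in SCHEMAS:
        raise ValidationError(f"unknown schema {schema_id!r}")
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file does not exist")
    schema = SCHEMAS[schema_id]
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(schema["columns"]) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")

    for col, (dtype, check, desc) in schema["columns"].items():
        series = df[col]
        if dtype is bool:
            lowered = series.str.lower().map(_BOOL_MAP)
            bad = lowered.isna()
            if bad.any():
                line = int(bad.idxmax()) + 2
                raise ValidationError(
                    f"{path}: line {line}, column {col!r}: not a boolean"
                )
            df[col] = lowered.astype(bool)
        elif dtype in (int, float):
            converted = pd.to_numeric(series, errors="coerce")
            bad = converted.isna()
            if bad.any():
                line = int(bad.idxmax()) + 2
                raise ValidationError(
                    f"{path}: line {line}, column {col!r}: not numeric"
                )
            if dtype is int:
                if (converted % 1 != 0).any():
                    line = int((converted % 1 != 0).idxmax()) + 2
                    raise ValidationError(
                        f"{path}: line {line}, column {col!r}: not an integer"
                    )
                converted = converted.astype(int)
            df[col] = converted
        if check is not None:
            ok = check(df[col])
            if not ok.all():
                line = int((~ok).idxmax()) + 2
                raise ValidationError(
                    f"{path}: line {line}, column {col!r}: value must be {desc}"
                )

    if "unique" in schema:
        dup = df.duplicated(schema["unique"])
        if dup.any():
            line = int(dup.idxmax()) + 2
            raise ValidationError(
                f"{path}: line {line}: duplicate key on {schema['unique']}"
            )
    if "row_check" in schema:
        pred, msg = schema["row_check"]
        ok = df.apply(pred, axis=1)
        if not ok.all():
            line = int((~ok).idxmax()) + 2
            raise ValidationError(f"{path}: line {line}: {msg}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))
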