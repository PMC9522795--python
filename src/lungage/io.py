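"""Readers/writers for record tables and model files.

Tabular data is comma-separated text with a header (UTF-8, LF, decimal
point); lines starting with ``#`` carry provenance (tool version, producing
command, generator seed) and are skipped on read.  Models, ULN parameters
and knots are serialized as JSON with full-precision coefficients; a
write → read → write cycle is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .equation import LungAgeEquation
from .norms import UlnModel

__all__ = [
    "RecordTable",
    "ModelFile",
    "read_records",
    "write_records",
    "read_model",
    "write_model",
    "MANDATORY_COLUMNS",
]

MODEL_FORMAT_VERSION = 1

MANDATORY_COLUMNS = (
    "id", "sex", "age", "height", "fev1", "fvc", "fev1_fvc", "mmef", "fef50", "fef75",
)
OPTIONAL_NUMERIC = ("weight", "fev1_pct_pred")
OPTIONAL_BOOL = ("fev1_normal", "fvc_normal", "fev1_fvc_normal", "mmef_normal", "smoker")
_NUMERIC = ("age", "height", "fev1", "fvc", "fev1_fvc", "mmef", "fef50", "fef75") + OPTIONAL_NUMERIC

#: plausibility windows for unit sanity checks
_SANITY = {
    "age": (0.0, 120.0),
    "height": (120.0, 210.0),   # cm, adults
    "fev1": (0.05, 10.0),       # L
    "fvc": (0.05, 12.0),        # L
    "fev1_fvc": (0.0, 1.0),
    "mmef": (0.0, 15.0),        # L/s
    "fef50": (0.0, 15.0),
    "fef75": (0.0, 15.0),
}


@dataclass
class RecordTable:
    """Validated spirometry records plus provenance metadata."""

    data: pd.DataFrame
    source: str | None = None
    meta: dict = field(default_factory=dict)
    errors: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.data)


def read_records(path, require_unique_ids: bool = True) -> RecordTable:
    """Read and validate a record CSV.

    Missing mandatory columns raise; malformed rows (unparseable numbers,
    implausible units, FEV1 > FVC, inconsistent FEV1/FVC ratio) are moved to
    the ``errors`` report rather than aborting the read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#", dtype={"id": str})
    if len(df) == 0:
        raise ValueError(f"{path}: no records")
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column: {col}")

    bad = pd.Series(pd.NA, index=df.index, dtype="object")

    def mark(mask, reason):
        sel = np.asarray(mask, dtype=bool) & bad.isna().to_numpy()
        bad.iloc[sel] = reason

    sex_ok = df["sex"].isin(["male", "female"])
    mark(~sex_ok, "sex must be the literal 'male' or 'female'")
    for col in _NUMERIC:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        mark(coerced.isna() & df[col].notna(), f"non-numeric {col}")
        mark(df[col].isna() if col not in OPTIONAL_NUMERIC else np.zeros(len(df), bool),
             f"missing {col}")
        df[col] = coerced
    for col, (lo, hi) in _SANITY.items():
        if col in df.columns:
            v = df[col]
            mark(v.notna() & ((v < lo) | (v > hi)), f"{col} outside plausible range [{lo:g}, {hi:g}]")
    mark((df["fev1"] > df["fvc"]).fillna(False), "fev1 > fvc")
    ratio_gap = (df["fev1"] / df["fvc"] - df["fev1_fvc"]).abs()
    mark((ratio_gap > 0.02).fillna(False), "fev1_fvc inconsistent with fev1/fvc (>0.02)")
    for col in OPTIONAL_BOOL:
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map(
                {"True": True, "False": False, True: True, False: False}
            )

    if require_unique_ids and df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].unique()[:5]
        raise ValueError(f"duplicate ids: {', '.join(map(str, dups))} ...")

    is_bad = bad.notna()
    errors = pd.DataFrame({"id": df.loc[is_bad, "id"], "reason": bad[is_bad]})
    return RecordTable(
        data=df.loc[~is_bad].reset_index(drop=True),
        source=str(path),
        errors=errors.reset_index(drop=True),
    )


def write_records(records, path, command: str | None = None, meta: dict | None = None) -> None:
    """Write records as CSV with a provenance comment header."""
    df = records.data if isinstance(records, RecordTable) else records
    path = Path(path)
    header = f"# lungage {__version__}"
    if command:
        header += f" | command: {command}"
    extra = dict(meta or {})
    if isinstance(records, pd.DataFrame):
        extra.update({k: v for k, v in records.attrs.items() if v is not None})
    if extra:
        header += " | " + ", ".join(f"{k}={v}" for k, v in sorted(extra.items()))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


@dataclass
class ModelFile:
    """Serialized lung-age equations with optional ULN models."""

    equations: dict[str, LungAgeEquation]  # keyed by sex
    uln: dict[str, UlnModel] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    format_version: int = MODEL_FORMAT_VERSION


def write_model(path, equations, uln=None, provenance=None, command: str | None = None) -> None:
    """Serialize equations (a dict keyed by sex, a single equation, or a
    ModelFile) plus optional ULN models to structured text (JSON)."""
    if isinstance(equations, ModelFile):
        mf = equations
    else:
        if isinstance(equations, LungAgeEquation):
            equations = {equations.sex: equations}
        mf = ModelFile(
            equations=dict(equations),
            uln=dict(uln or {}),
            provenance=dict(provenance or {}),
        )
    prov = dict(mf.provenance)
    prov.setdefault("tool", f"lungage {__version__}")
    if command:
        prov["command"] = command
    payload = {
        "format_version": mf.format_version,
        "equations": {sex: eq.to_dict() for sex, eq in mf.equations.items()},
        "uln": {name: u.to_dict() for name, u in mf.uln.items()},
        "provenance": prov,
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_model(path) -> ModelFile:
    """Read a model file; a corrupted file raises without a partial model."""
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: corrupted model file ({exc})") from None
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: model format version {version!r} is not supported "
            f"(this build reads version {MODEL_FORMAT_VERSION})"
        )
    return ModelFile(
        equations={
            sex: LungAgeEquation.from_dict(d)
            for sex, d in payload.get("equations", {}).items()
        },
        uln={name: UlnModel.from_dict(d) for name, d in payload.get("uln", {}).items()},
        provenance=payload.get("provenance", {}),
        format_version=version,
    )
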