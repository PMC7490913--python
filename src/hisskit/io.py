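"""CSV/JSON exchange formats.

The canonical cohort CSV carries unit-bearing headers::

    patient_id,glucose_mg_dl,lactate_mmol_l,ph,potassium_mmol_l,po2_mmhg

Optional columns: ``hidden_seed`` (testing exports only), expert score
columns ``D1..Dk`` (cells may hold the literal ``UD`` for undeclared
scores), fused ``mode`` and possibility columns ``u0..u4``.  A
``table2_headers`` switch emits/accepts the typeset display headers
instead of the canonical ones.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .domain import ANALYTES, AnalytePanel
from .sfrp import SFRPRecord

BIOMARKER_COLUMNS = {
    "glucose": "glucose_mg_dl",
    "lactate": "lactate_mmol_l",
    "ph": "ph",
    "potassium": "potassium_mmol_l",
    "po2": "po2_mmhg",
}

TABLE2_HEADERS = {
    "patient_id": "Fictitious Patient",
    "glucose_mg_dl": "Glucose (mg/dl)",
    "lactate_mmol_l": "Lactate (mmol/l)",
    "ph": "pH",
    "potassium_mmol_l": "Potassium (mmol/l)",
    "po2_mmhg": "pO2 (mmHg)",
}

_EXPERT_COL = re.compile(r"^D\d+$")
UD = "UD"


def expert_columns(df: pd.DataFrame) -> list[str]:
    """Expert score columns (D1, D2, ...) in numeric order."""
    cols = [c for c in df.columns if _EXPERT_COL.match(str(c))]
    return sorted(cols, key=lambda c: int(c[1:]))


def records_to_frame(records: Sequence[SFRPRecord], reveal_seeds: bool = False) -> pd.DataFrame:
    rows = {
        "patient_id": [r.patient_id for r in records],
        "glucose_mg_dl": [r.panel.glucose for r in records],
        "lactate_mmol_l": [r.panel.lactate for r in records],
        "ph": [r.panel.ph for r in records],
        "potassium_mmol_l": [r.panel.potassium for r in records],
        "po2_mmhg": [r.panel.po2 for r in records],
    }
    df = pd.DataFrame(rows)
    if reveal_seeds:
        df["hidden_seed"] = [r.hidden_seed for r in records]
    return df


def frame_to_records(df: pd.DataFrame) -> list[SFRPRecord]:
    records = []
    has_seed = "hidden_seed" in df.columns
    for _, row in df.iterrows():
        panel = AnalytePanel(
            glucose=float(row["glucose_mg_dl"]),
            lactate=float(row["lactate_mmol_l"]),
            ph=float(row["ph"]),
            potassium=float(row["potassium_mmol_l"]),
            po2=float(row["po2_mmhg"]),
        )
        seed = int(row["hidden_seed"]) if has_seed else -1
        records.append(SFRPRecord(patient_id=int(row["patient_id"]), panel=panel,
                                  hidden_seed=seed))
    return records


def write_sfrp_csv(path: str | Path, df: pd.DataFrame, table2_headers: bool = False) -> None:
    out = df.copy()
    for col in expert_columns(out):
        out[col] = out[col].astype(object)
        out.loc[out[col].isna(), col] = UD
    if table2_headers:
        out = out.rename(columns=TABLE2_HEADERS)
    out.to_csv(path, index=False)


def read_sfrp_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV into a frame with canonical column names.

    ``UD`` score cells become missing values (nullable integers), not 0.
    Unknown columns are preserved.  A missing mandatory biomarker column
    or an unparseable cell raises a descriptive error.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    inverse = {v: k for k, v in TABLE2_HEADERS.items()}
    df = df.rename(columns=inverse)
    missing = [c for c in BIOMARKER_COLUMNS.values() if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing mandatory column(s): {', '.join(missing)}")
    for col in list(BIOMARKER_COLUMNS.values()):
        df[col] = _parse_numeric(df, col, path)
    if "patient_id" in df.columns:
        df["patient_id"] = _parse_numeric(df, "patient_id", path).astype(int)
    if "hidden_seed" in df.columns:
        df["hidden_seed"] = _parse_numeric(df, "hidden_seed", path).astype(int)
    for col in expert_columns(df):
        cleaned = df[col].replace({UD: None, "": None})
        parsed = pd.to_numeric(cleaned, errors="coerce")
        bad = parsed.isna() & cleaned.notna()
        if bad.any():
            rownum = int(np.flatnonzero(bad)[0]) + 2  # 1-based + header line
            raise ValueError(f"{path.name}: unparseable score cell in column {col}, line {rownum}")
        df[col] = parsed.astype("Int64")
    for col in [c for c in df.columns if re.match(r"^u[0-4]$", str(c))]:
        df[col] = _parse_numeric(df, col, path)
    if "mode" in df.columns:
        df["mode"] = _parse_numeric(df, "mode", path).astype(int)
    return df


def _parse_numeric(df: pd.DataFrame, col: str, path: Path) -> pd.Series:
    parsed = pd.to_numeric(df[col], errors="coerce")
    bad = parsed.isna()
    if bad.any():
        rownum = int(np.flatnonzero(bad)[0]) + 2
        raise ValueError(f"{path.name}: unparseable cell in column {col}, line {rownum}")
    return parsed


def scores_from_frame(df: pd.DataFrame) -> np.ndarray:
    """Expert score matrix (n, k); raises if any score is missing."""
    cols = expert_columns(df)
    if not cols:
        raise ValueError("no expert score columns (D1..Dk) present")
    block = df[cols]
    if block.isna().any().any():
        raise ValueError("expert score columns contain undeclared (UD) cells")
    return block.to_numpy(dtype=int)


def features_from_frame(df: pd.DataFrame) -> np.ndarray:
    """Panel feature matrix (n, 5) in canonical analyte order."""
    return df[[BIOMARKER_COLUMNS[a] for a in ANALYTES]].to_numpy(dtype=float)


def config_hash(doc: dict) -> str:
    """Stable short hash of a JSON-serialisable config."""
    canon = json.dumps(doc, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
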