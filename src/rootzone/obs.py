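"""Tidy observation tables shared by the generators and the inference.

An observation set is a pandas DataFrame with one measurement per row:

    condition    'ammonium' | 'nitrate'
    tissue       'epidermis' | 'cortex'
    position     int >= 1 (cells from the QC)
    replicate    int (root id within the set)
    measurement  'length' | 'pin2_intensity' | 'relative_auxin'
    face         'apical' | 'lateral' for pin2_intensity, '' otherwise
    value        float; > 0 for lengths/intensities, (0, 1] for relative auxin

The 'lateral' face label abstracts the file-exchange membrane (inner face
of the epidermis, outer face of the cortex).
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd

COLUMNS = ["condition", "tissue", "position", "replicate",
           "measurement", "face", "value"]
CONDITIONS = ("ammonium", "nitrate")
TISSUES = ("epidermis", "cortex")
MEASUREMENTS = ("length", "pin2_intensity", "relative_auxin")
FACE_LABELS = ("apical", "lateral", "basal", "outer", "inner")

CONDITION_N = {"ammonium": 0, "nitrate": 1}
N_CONDITION = {0: "ammonium", 1: "nitrate"}

#: detection floor for fluorescence-like measurements: model predictions of
#: exactly zero (e.g. lateral PIN2 on ammonium) are reported at this level,
#: mimicking instrument background, and the likelihood floors its
#: predictions identically.
DETECTION_FLOOR = 1e-6


class SchemaError(ValueError):
    pass


def empty_observations() -> pd.DataFrame:
    return pd.DataFrame(columns=COLUMNS)


def validate_observations(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an observation table; returns it with canonical dtypes.

    Raises :class:`SchemaError` listing the offending rows.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    df = df[COLUMNS].copy()
    if len(df) == 0:
        return df
    df["position"] = df["position"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    df["value"] = df["value"].astype(float)
    df["face"] = df["face"].fillna("").astype(str)

    bad = []
    bad += list(df.index[~df["condition"].isin(CONDITIONS)])
    bad += list(df.index[~df["tissue"].isin(TISSUES)])
    bad += list(df.index[~df["measurement"].isin(MEASUREMENTS)])
    bad += list(df.index[df["position"] < 1])
    is_pin = df["measurement"] == "pin2_intensity"
    bad += list(df.index[is_pin & ~df["face"].isin(FACE_LABELS)])
    bad += list(df.index[~is_pin & (df["face"] != "")])
    bad += list(df.index[df["value"] <= 0])
    is_rel = df["measurement"] == "relative_auxin"
    bad += list(df.index[is_rel & (df["value"] > 1.0)])
    if bad:
        rows = sorted(set(bad))
        raise SchemaError(
            f"{len(rows)} invalid observation rows: {rows[:20]}"
            + (" ..." if len(rows) > 20 else ""))
    return df


def write_observations(df: pd.DataFrame, path: Union[str, Path]) -> None:
    validate_observations(df).to_csv(path, index=False)


def read_observations(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False,
                     dtype={"face": str, "condition": str,
                            "tissue": str, "measurement": str})
    return validate_observations(df)
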