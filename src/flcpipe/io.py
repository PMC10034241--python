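"""Plain-text readers and writers for the pipeline's tables.

All tables are CSV (labs timestamps ISO-8601, patient codes semicolon-joined)
and round-trip losslessly through these functions.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .cohort import PatientRecord


def write_patients(patients: Sequence[PatientRecord], path) -> None:
    df = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "age": [p.age_at_diagnosis for p in patients],
            "codes": [";".join(sorted(p.codes)) for p in patients],
            "label": [p.label for p in patients],
            "zip3": [p.zip3 if p.zip3 is not None else "" for p in patients],
        }
    )
    df.to_csv(path, index=False)


def read_patients(path) -> list[PatientRecord]:
    df = pd.read_csv(path, dtype={"zip3": str}, keep_default_na=False)
    return [
        PatientRecord(
            patient_id=str(r.patient_id),
            age_at_diagnosis=int(r.age),
            codes=frozenset(c for c in str(r.codes).split(";") if c),
            label=str(r.label),
            zip3=str(r.zip3) if str(r.zip3) else None,
        )
        for r in df.itertuples()
    ]


def write_claims(claims: pd.DataFrame, path) -> None:
    claims.to_csv(path, index=False)


def read_claims(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"year": int, "age_bin": str, "count": int})


def write_labs(events: pd.DataFrame, path) -> None:
    out = events.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_labs(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"encounter_id": str, "patient_id": str})
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def write_centroids(centroids: pd.DataFrame, path) -> None:
    centroids.to_csv(path, index=False)


def read_centroids(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"zip3": str})


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(x):
    try:
        import numpy as np

        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        if isinstance(x, np.ndarray):
            return x.tolist()
    except ImportError:  # pragma: no cover
        pass
    if isinstance(x, (set, frozenset)):
        return sorted(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")
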