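"""Tabular I/O: CSV record readers/writers and JSON fit export.

CSV dialect: comma-separated, UTF-8, header row mandatory, "." decimal.
Times are unit-agnostic — whatever unit the file uses must be shared by
the budget, fixed cost and rates passed alongside it.

Detection (timed-search) records:
    observer,quadrat,time_to_first_detection,session_length,censored[,species]
Survey count records:
    site,visit,detections,search_time[,abundance]
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence, Union

import pandas as pd

from .estimate import DetectionRecord, RateFit, SurveyCountRecord

__all__ = [
    "read_detection_records",
    "write_detection_records",
    "read_count_records",
    "write_count_records",
    "write_rate_fit",
    "read_rate_fit",
]

PathLike = Union[str, Path]

_DET_REQUIRED = ["observer", "quadrat", "time_to_first_detection",
                 "session_length", "censored"]
_CNT_REQUIRED = ["site", "visit", "detections", "search_time"]


def _check_columns(df: pd.DataFrame, required: Sequence[str], kind: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{kind} CSV is missing required column(s): {', '.join(missing)}"
        )


def read_detection_records(path: PathLike) -> List[DetectionRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, _DET_REQUIRED, "detection-record")
    out = []
    for r in df.itertuples(index=False):
        species = getattr(r, "species", "")
        if species is None or (isinstance(species, float) and pd.isna(species)):
            species = ""
        out.append(DetectionRecord(
            observer=str(r.observer),
            quadrat=str(r.quadrat),
            time_to_first_detection=float(r.time_to_first_detection),
            session_length=float(r.session_length),
            censored=bool(r.censored),
            species=str(species),
        ))
    return out


def write_detection_records(records: Sequence[DetectionRecord],
                            path: PathLike) -> None:
    pd.DataFrame([
        {
            "observer": r.observer, "quadrat": r.quadrat,
            "time_to_first_detection": r.time_to_first_detection,
            "session_length": r.session_length,
            "censored": r.censored, "species": r.species,
        }
        for r in records
    ]).to_csv(path, index=False, float_format="%.17g")


def read_count_records(path: PathLike) -> List[SurveyCountRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, _CNT_REQUIRED, "survey-count")
    has_abund = "abundance" in df.columns
    out = []
    for r in df.itertuples(index=False):
        abund = getattr(r, "abundance", None) if has_abund else None
        out.append(SurveyCountRecord(
            site=str(r.site), visit=int(r.visit),
            detections=int(r.detections),
            search_time=float(r.search_time),
            abundance=(None if abund is None or pd.isna(abund)
                       else float(abund)),
        ))
    return out


def write_count_records(records: Sequence[SurveyCountRecord],
                        path: PathLike) -> None:
    pd.DataFrame([
        {
            "site": r.site, "visit": r.visit, "detections": r.detections,
            "search_time": r.search_time, "abundance": r.abundance,
        }
        for r in records
    ]).to_csv(path, index=False, float_format="%.17g")


def write_rate_fit(fit: RateFit, path: PathLike) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2) + "\n")


def read_rate_fit(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())
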