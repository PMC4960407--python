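"""CSV/JSON readers and writers with schema validation, plus run manifests.

All CSVs are UTF-8, comma-separated, with a header row and ISO-8601 dates.
Readers validate eagerly and report the file, row and column of the first
violations so bad exports fail fast instead of corrupting a run.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from .risk_model import LookupTable
from .synthetic import Cohort

logger = logging.getLogger(__name__)

ASSESSMENT_COLUMNS = [
    "assessment_id",
    "patient_id",
    "assessment_date",
    "clinical_score",
    "outcome",
]
DIAGNOSIS_COLUMNS = ["patient_id", "diagnosis_date", "icd10_code"]


class SchemaError(ValueError):
    """A CSV violated the documented schema; the message names file/row/column."""


def _require_columns(df: pd.DataFrame, required: list[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _check_dates(df: pd.DataFrame, column: str, path: str) -> None:
    parsed = pd.to_datetime(df[column], format="%Y-%m-%d", errors="coerce")
    bad = df.index[parsed.isna()]
    if len(bad):
        row = int(bad[0])
        raise SchemaError(
            f"{path}: row {row + 2}, column {column!r}: "
            f"not an ISO-8601 date: {df.loc[row, column]!r}"
        )


def read_assessments(path: str | Path) -> pd.DataFrame:
    """Read and validate an assessments CSV."""
    path = str(path)
    df = pd.read_csv(path, dtype={"assessment_id": str, "patient_id": str})
    _require_columns(df, ASSESSMENT_COLUMNS, path)
    _check_dates(df, "assessment_date", path)
    for column, allowed in (("clinical_score", range(5)), ("outcome", range(2))):
        vals = pd.to_numeric(df[column], errors="coerce")
        bad = df.index[vals.isna() | ~vals.isin(list(allowed))]
        if len(bad):
            row = int(bad[0])
            raise SchemaError(
                f"{path}: row {row + 2}, column {column!r}: value "
                f"{df.loc[row, column]!r} outside {list(allowed)}"
            )
        df[column] = vals.astype(int)
    if df["assessment_id"].duplicated().any():
        dup = df["assessment_id"][df["assessment_id"].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate assessment_id {dup!r}")
    return df


def read_diagnoses(path: str | Path) -> pd.DataFrame:
    """Read and validate a diagnoses CSV."""
    path = str(path)
    df = pd.read_csv(path, dtype={"patient_id": str, "icd10_code": str})
    _require_columns(df, DIAGNOSIS_COLUMNS, path)
    if len(df):
        _check_dates(df, "diagnosis_date", path)
    return df


def write_cohort(cohort: Cohort, outdir: str | Path) -> tuple[Path, Path]:
    """Write assessments.csv and diagnoses.csv; deterministic byte-for-byte."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    a_path = outdir / "assessments.csv"
    d_path = outdir / "diagnoses.csv"
    a = cohort.assessments.copy()
    a["assessment_date"] = a["assessment_date"].astype(str)
    a.to_csv(a_path, index=False, lineterminator="\n")
    d = cohort.diagnoses.copy()
    if len(d):
        d["diagnosis_date"] = d["diagnosis_date"].astype(str)
    d.to_csv(d_path, index=False, lineterminator="\n")
    return a_path, d_path


def read_cohort(outdir: str | Path) -> Cohort:
    outdir = Path(outdir)
    return Cohort(
        assessments=read_assessments(outdir / "assessments.csv"),
        diagnoses=read_diagnoses(outdir / "diagnoses.csv"),
    )


def write_lookup(table: LookupTable, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(table.to_json())
    return path


def read_lookup(path: str | Path) -> LookupTable:
    return LookupTable.from_json(Path(path).read_text())


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    outdir: str | Path,
    config: dict,
    seeds: dict[str, int],
    inputs: dict[str, str | Path] | None = None,
) -> Path:
    """Write the run manifest: config hash, seeds, version, input digests.

    Exactly one manifest per output directory; reruns with identical inputs
    and seeds reproduce identical outputs (the manifest's timestamp is the
    only field that may differ).
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    canonical = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "package_version": __version__,
        "config": config,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seeds": seeds,
        "input_digests": {
            str(k): file_digest(v) for k, v in (inputs or {}).items()
        },
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
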