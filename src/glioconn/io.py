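"""File layer: TSV matrices, subject metadata, summary tables and reports.

Matrix files are plain TSV with region ids in the first row and column and
``NA`` for missing entries; one file per subject per input kind
(``<subject>_counts.tsv``, ``<subject>_fa.tsv``, ``<subject>_ts.tsv``).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .summarize import SUMMARY_COLUMNS, SubjectRecord


class ParseError(ValueError):
    """Raised when an input file does not match the expected layout."""


def write_matrix_tsv(path, values: np.ndarray, region_ids=None) -> None:
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if region_ids is None:
        region_ids = np.arange(1, n + 1)
    frame = pd.DataFrame(values, index=region_ids, columns=region_ids)
    frame.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g",
                 index_label="region_id")


def read_matrix_tsv(path, expected_r: int | None = None) -> np.ndarray:
    """Read a symmetric region x region matrix; ``NA`` becomes NaN."""
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ParseError(f"{path}: cannot parse matrix TSV ({exc})") from exc
    if frame.shape[0] != frame.shape[1]:
        raise ParseError(f"{path}: matrix is {frame.shape[0]} x "
                         f"{frame.shape[1]}, expected square")
    row_ids = frame.index.to_numpy()
    col_ids = np.array([int(c) for c in frame.columns])
    if not np.array_equal(row_ids, col_ids):
        raise ParseError(f"{path}: row and column region ids disagree")
    if expected_r is not None and frame.shape[0] != expected_r:
        raise ParseError(f"{path}: expected {expected_r} regions, "
                         f"found {frame.shape[0]}")
    values = frame.to_numpy(dtype=float)
    finite = np.nan_to_num(values)
    if np.abs(finite - finite.T).max() > 1e-9:
        raise ParseError(f"{path}: matrix is asymmetric beyond 1e-9")
    return values


def write_timeseries_tsv(path, values: np.ndarray, region_ids=None) -> None:
    values = np.asarray(values, dtype=float)
    if region_ids is None:
        region_ids = np.arange(1, values.shape[1] + 1)
    frame = pd.DataFrame(values, columns=region_ids)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_timeseries_tsv(path, expected_r: int | None = None) -> np.ndarray:
    try:
        frame = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"{path}: cannot parse time-series TSV "
                         f"({exc})") from exc
    if expected_r is not None and frame.shape[1] != expected_r:
        raise ParseError(f"{path}: expected {expected_r} regions, "
                         f"found {frame.shape[1]}")
    return frame.to_numpy(dtype=float)


def write_subjects_csv(path, records) -> None:
    frame = pd.DataFrame([dataclasses.asdict(r) for r in records])
    frame.to_csv(path, index=False)


def read_subjects_csv(path):
    frame = pd.read_csv(path)
    needed = {"subject_id", "group", "lesion_hemisphere", "age", "sex"}
    missing = needed - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return [SubjectRecord(str(r.subject_id), str(r.group),
                          str(r.lesion_hemisphere), float(r.age), str(r.sex))
            for r in frame.itertuples()]


def write_summary_csv(path, table: pd.DataFrame, sidecar: dict | None = None,
                      sidecar_path=None) -> None:
    """Write the 13-column summary CSV plus an optional JSON sidecar."""
    table[SUMMARY_COLUMNS].to_csv(path, index=False, float_format="%.10g")
    if sidecar is not None and sidecar_path is not None:
        write_json(sidecar_path, sidecar)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        value = float(obj)
        return value if np.isfinite(value) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def write_json(path, payload) -> None:
    Path(path).write_text(
        json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")


def write_cohort(cohort, outdir) -> None:
    """Write a simulated cohort in the layout the pipeline reads back."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    region_ids = cohort.atlas.region_ids
    write_subjects_csv(outdir / "subjects.csv", cohort.records)
    cohort.atlas.table.to_csv(outdir / "atlas.csv", index=False)
    for bundle in cohort.bundles:
        sid = bundle.record.subject_id
        write_matrix_tsv(outdir / f"{sid}_counts.tsv",
                         bundle.counts.counts.astype(float), region_ids)
        write_matrix_tsv(outdir / f"{sid}_fa.tsv", bundle.fa.fa, region_ids)
        write_timeseries_tsv(outdir / f"{sid}_ts.tsv",
                             bundle.timeseries.values, region_ids)
    ground_truth = {
        "seed": cohort.seed,
        "config": {"n_regions": cohort.config.n_regions,
                   "n_timepoints": cohort.config.n_timepoints,
                   "group_sizes": cohort.config.group_sizes},
        "targets": {b.record.subject_id:
                    {f"{m}_{c}": v for (m, c), v in b.targets.items()}
                    for b in cohort.bundles},
        "factors": {b.record.subject_id: b.factors for b in cohort.bundles},
    }
    write_json(outdir / "ground_truth.json", ground_truth)
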