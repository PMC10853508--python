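"""Cohort and results I/O.

Tables are TSV with headers; per-subject time series go into a single
portable ``.npz`` container; reports are JSON.  Floats are written with
their shortest round-trip representation and parsed back with the
round-trip parser, so tables survive a save/load cycle bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import BetaMatrix
from .simulate import Cohort, SubjectRecord, SubjectTimeSeries, TaskDesign

__all__ = [
    "CohortFormatError",
    "MissingColumnError",
    "DuplicateSubjectError",
    "LabelDomainError",
    "MissingArrayError",
    "save_cohort",
    "load_cohort",
    "save_beta_matrix",
    "load_beta_matrix",
    "save_report",
]

class CohortFormatError(ValueError):
    """Malformed cohort artifacts."""


class MissingColumnError(CohortFormatError):
    """A required column is absent from a table."""


class DuplicateSubjectError(CohortFormatError):
    """Subject ids are not unique."""


class LabelDomainError(CohortFormatError):
    """Labels are outside a two-class domain."""


class MissingArrayError(CohortFormatError):
    """A metadata row has no matching time-series array."""


def save_cohort(cohort: Cohort, path) -> None:
    """Write a cohort directory: metadata.tsv, design.tsv, design.json,
    timeseries.npz, and truth.json when generator ground truth is present."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = pd.DataFrame(
        {
            "subject_id": cohort.subject_ids,
            "group": cohort.labels,
            "severity": cohort.severity,
        }
    )
    meta.to_csv(path / "metadata.tsv", sep="\t", index=False)

    d = cohort.design
    pd.DataFrame(
        {
            "sample": np.arange(d.n_samples),
            "boxcar": d.boxcar,
            "regressor": d.regressor,
        }
    ).to_csv(path / "design.tsv", sep="\t", index=False)
    (path / "design.json").write_text(
        json.dumps(
            {
                "sample_rate": d.sample_rate,
                "total_duration": d.total_duration,
                "task_epoch": d.task_epoch,
                "rest_epoch": d.rest_epoch,
                "truncated": d.truncated,
                "sub_epoch": d.sub_epoch,
            },
            indent=2,
        )
    )

    arrays = {}
    for rec in cohort.records:
        if rec.timeseries is not None:
            arrays[f"{rec.subject_id}__oxy"] = rec.timeseries.oxy
            arrays[f"{rec.subject_id}__deoxy"] = rec.timeseries.deoxy
    np.savez(path / "timeseries.npz", **arrays)

    if cohort.truth:
        truth = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in cohort.truth.items()
        }
        (path / "truth.json").write_text(json.dumps(truth, indent=2))


def load_cohort(path) -> Cohort:
    """Load a cohort directory written by :func:`save_cohort`, validating
    schema, id uniqueness, the two-class label domain, and the presence of a
    time-series array for every metadata row."""
    path = Path(path)
    meta = pd.read_csv(path / "metadata.tsv", sep="\t", float_precision="round_trip")
    for col in ("subject_id", "group"):
        if col not in meta.columns:
            raise MissingColumnError(f"metadata.tsv lacks required column {col!r}")
    if meta["subject_id"].duplicated().any():
        dups = meta.loc[meta["subject_id"].duplicated(), "subject_id"].tolist()
        raise DuplicateSubjectError(f"duplicate subject ids: {dups}")
    groups = meta["group"].unique()
    if len(groups) > 2:
        raise LabelDomainError(
            f"labels must come from at most two classes, got {sorted(groups)}"
        )

    djs = json.loads((path / "design.json").read_text())
    dtab = pd.read_csv(path / "design.tsv", sep="\t", float_precision="round_trip")
    design = TaskDesign(
        sample_rate=djs["sample_rate"],
        total_duration=djs["total_duration"],
        task_epoch=djs["task_epoch"],
        rest_epoch=djs["rest_epoch"],
        boxcar=dtab["boxcar"].to_numpy(float),
        regressor=dtab["regressor"].to_numpy(float),
        truncated=djs.get("truncated", False),
        sub_epoch=djs.get("sub_epoch"),
    )

    arrays = np.load(path / "timeseries.npz")
    records = []
    for row in meta.itertuples(index=False):
        sid = str(row.subject_id)
        okey, dkey = f"{sid}__oxy", f"{sid}__deoxy"
        if okey not in arrays or dkey not in arrays:
            raise MissingArrayError(f"no time-series arrays for subject {sid!r}")
        sev = getattr(row, "severity", np.nan)
        ts = SubjectTimeSeries(
            oxy=arrays[okey], deoxy=arrays[dkey], subject_id=sid, group=str(row.group)
        )
        records.append(
            SubjectRecord(
                subject_id=sid,
                group=str(row.group),
                severity=None if pd.isna(sev) else float(sev),
                timeseries=ts,
            )
        )

    truth = {}
    truth_path = path / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        if "amplitude_maps" in truth:
            truth["amplitude_maps"] = np.asarray(truth["amplitude_maps"], float)
        if "effect_pattern" in truth:
            truth["effect_pattern"] = np.asarray(truth["effect_pattern"], float)
    return Cohort(records=records, design=design, truth=truth)


def save_beta_matrix(beta: BetaMatrix, path) -> None:
    """Write a subjects-x-channels beta TSV (id column + channel_XX columns)."""
    cols = {f"channel_{j + 1:02d}": beta.values[:, j] for j in range(beta.values.shape[1])}
    df = pd.DataFrame({"subject_id": beta.subject_ids, **cols})
    if beta.labels is not None:
        df.insert(1, "group", beta.labels)
    df.to_csv(path, sep="\t", index=False)


def load_beta_matrix(path) -> BetaMatrix:
    """Read a beta TSV written by :func:`save_beta_matrix` (or any TSV with a
    subject_id column, optional group column, and numeric channel columns)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "subject_id" not in df.columns:
        raise MissingColumnError("beta table lacks required column 'subject_id'")
    if df["subject_id"].duplicated().any():
        raise DuplicateSubjectError("duplicate subject ids in beta table")
    labels = df["group"].to_numpy() if "group" in df.columns else None
    chan_cols = [c for c in df.columns if c not in ("subject_id", "group")]
    values = df[chan_cols].to_numpy(float)
    return BetaMatrix(
        values=values, subject_ids=df["subject_id"].astype(str).tolist(), labels=labels
    )


def save_report(report: dict, path) -> None:
    """Deterministically serialized JSON report (sorted keys, no timestamps)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
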