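"""Delimited-file readers/writers and quality scoring.

Datasets are plain CSV files. Because primary literature uses no fixed
schema, the reader takes a ``column_map`` relating semantic roles
(``study_id``, ``mean_treatment`` ...) to the file's column names.
Columns not consumed by the map are carried along as covariates.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import Dataset, N_QUALITY_ITEMS, QualityScore, StudyRecord

logger = logging.getLogger(__name__)

__all__ = ["read_dataset", "write_dataset", "quality_score", "DEFAULT_COLUMN_MAP"]

#: Roles understood by :func:`read_dataset`; identity mapping by default.
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "study_id": "study_id",
    "mean_treatment": "mean_treatment",
    "sd_treatment": "sd_treatment",
    "n_treatment": "n_treatment",
    "mean_control": "mean_control",
    "sd_control": "sd_control",
    "n_control": "n_control",
    "uncertainty_type": "uncertainty_type",
}

_MANDATORY = ("study_id", "mean_treatment", "sd_treatment", "n_treatment")
_RANGE_RE = re.compile(r"^\s*(\d+)\s*[-–—]\s*(\d+)\s*$")


def _parse_n(value, *, row: int, what: str):
    """Parse a sample size; a range 'a-b' yields the lower value."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str):
        m = _RANGE_RE.match(value)
        if m:
            return min(int(m.group(1)), int(m.group(2)))
        value = value.strip()
        if value == "":
            return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"row {row}: non-numeric {what}: {value!r}")
    if not float(f).is_integer():
        raise ValueError(f"row {row}: non-integer {what}: {value!r}")
    return int(f)


def _parse_real(value, *, row: int, what: str) -> Optional[float]:
    if value is None:
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"row {row}: non-numeric {what}: {value!r}")
    if np.isnan(f):
        return None
    return f


def read_dataset(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    delimiter: str = ",",
    quality_columns: Optional[Sequence[str]] = None,
    label: str = "",
    scale: str = "raw",
) -> Dataset:
    """Read a study-level dataset from a delimited text file.

    Parameters
    ----------
    path
        CSV file with one row per study.
    column_map
        Mapping role -> column name. Mandatory roles: study_id,
        mean_treatment, sd_treatment, n_treatment. Optional: the control
        triple and ``uncertainty_type`` (values ``"sd"``/``"se"``; when the
        column says ``"se"`` the stored uncertainty is converted to a
        standard deviation as se*sqrt(n)).
    delimiter
        Field separator (comma by default; period decimal separator only).
    quality_columns
        Names of the eight boolean quality-checklist columns, in order.

    Raises
    ------
    ValueError
        With row-indexed diagnostics if any row violates the record
        invariants (missing mandatory fields, partial control arm,
        non-numeric values, n < 1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=delimiter, dtype=object)

    for role in _MANDATORY:
        if cmap[role] not in df.columns:
            raise ValueError(f"mandatory column for role {role!r} "
                             f"({cmap[role]!r}) not found in {path.name}")

    has_unc = cmap.get("uncertainty_type") in df.columns
    if not has_unc:
        logger.warning(
            "%s: no uncertainty_type column mapped; uncertainty values are "
            "treated as standard deviations", path.name)

    consumed = {cmap[r] for r in cmap if cmap[r] in df.columns}
    if quality_columns:
        if len(quality_columns) != N_QUALITY_ITEMS:
            raise ValueError(f"quality_columns must list {N_QUALITY_ITEMS} columns")
        consumed |= set(quality_columns)
    covariate_cols = [c for c in df.columns if c not in consumed]

    records = []
    problems = []
    for idx, row in df.iterrows():
        rnum = int(idx) + 2  # 1-based file line, counting the header
        try:
            sid = row[cmap["study_id"]]
            if sid is None or (isinstance(sid, float) and np.isnan(sid)):
                raise ValueError(f"row {rnum}: missing study_id")
            sid = str(sid)
            mean_t = _parse_real(row[cmap["mean_treatment"]], row=rnum, what="mean_treatment")
            sd_t = _parse_real(row[cmap["sd_treatment"]], row=rnum, what="sd_treatment")
            n_t = _parse_n(row[cmap["n_treatment"]], row=rnum, what="n_treatment")
            missing = [name for name, v in
                       [("mean_treatment", mean_t), ("sd_treatment", sd_t), ("n_treatment", n_t)]
                       if v is None]
            if missing:
                raise ValueError(
                    f"row {rnum} (study {sid!r}): missing mandatory field(s) {missing}")

            def _opt(role, parser, what):
                col = cmap.get(role)
                if col is None or col not in df.columns:
                    return None
                return parser(row[col], row=rnum, what=what)

            mean_c = _opt("mean_control", _parse_real, "mean_control")
            sd_c = _opt("sd_control", _parse_real, "sd_control")
            n_c = _opt("n_control", _parse_n, "n_control")
            ctrl_present = [v is not None for v in (mean_c, sd_c, n_c)]
            if any(ctrl_present) and not all(ctrl_present):
                raise ValueError(
                    f"row {rnum} (study {sid!r}): partial control arm "
                    "(mean_control, sd_control, n_control must be all present or all absent)")

            if has_unc:
                unc = str(row[cmap["uncertainty_type"]]).strip().lower()
                if unc == "se":
                    sd_t = sd_t * np.sqrt(n_t)
                    if sd_c is not None:
                        sd_c = sd_c * np.sqrt(n_c)
                elif unc not in ("sd", "nan", ""):
                    raise ValueError(
                        f"row {rnum} (study {sid!r}): unknown uncertainty_type {unc!r}")

            covs = {c: row[c] for c in covariate_cols}
            for c, v in list(covs.items()):
                try:
                    covs[c] = float(v)
                except (TypeError, ValueError):
                    pass
            quality = [True] * N_QUALITY_ITEMS
            if quality_columns:
                quality = [_as_bool(row[c], rnum, c) for c in quality_columns]

            records.append(StudyRecord(
                study_id=sid, mean_treatment=mean_t, sd_treatment=sd_t,
                n_treatment=n_t, mean_control=mean_c, sd_control=sd_c,
                n_control=n_c, covariates=covs, quality=quality))
        except ValueError as exc:
            problems.append(str(exc))

    if problems:
        raise ValueError(
            f"{path.name}: {len(problems)} invalid row(s):\n" + "\n".join(problems))
    return Dataset(records=records, label=label or path.stem, scale=scale)


def _as_bool(value, rnum: int, col: str) -> bool:
    s = str(value).strip().lower()
    if s in ("1", "true", "yes", "y", "1.0"):
        return True
    if s in ("0", "false", "no", "n", "0.0"):
        return False
    raise ValueError(f"row {rnum}: non-boolean quality value {value!r} in column {col!r}")


def write_dataset(dataset: Dataset, path, delimiter: str = ",") -> None:
    """Write a Dataset back to CSV at full float precision (round-trip safe)."""
    rows = []
    cov_keys: list = []
    for r in dataset:
        for k in r.covariates:
            if k not in cov_keys:
                cov_keys.append(k)
    for r in dataset:
        row = {
            "study_id": r.study_id,
            "mean_treatment": repr(float(r.mean_treatment)),
            "sd_treatment": repr(float(r.sd_treatment)),
            "n_treatment": r.n_treatment,
            "mean_control": "" if r.mean_control is None else repr(float(r.mean_control)),
            "sd_control": "" if r.sd_control is None else repr(float(r.sd_control)),
            "n_control": "" if r.n_control is None else r.n_control,
        }
        for k in cov_keys:
            v = r.covariates.get(k, "")
            row[k] = repr(float(v)) if isinstance(v, float) else v
        for i, q in enumerate(r.quality):
            row[f"quality_{i + 1}"] = int(bool(q))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def quality_score(record: StudyRecord) -> QualityScore:
    """Aggregate quality score: the number of satisfied checklist items.

    All eight criteria are equally weighted; the checklist itself carries
    no prescribed ordering of importance.
    """
    if len(record.quality) != N_QUALITY_ITEMS:
        raise ValueError(
            f"quality checklist must have exactly {N_QUALITY_ITEMS} entries")
    return QualityScore(study_id=record.study_id,
                        score=int(sum(bool(q) for q in record.quality)))
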