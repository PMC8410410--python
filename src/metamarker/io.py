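"""Readers and writers for the tabular formats the pipeline touches.

Canonical dialect is TSV with a header row (comma-separated accepted via
``sep=","``).  Missing-value tokens ("NA", empty) are dropped with a
logged count and reported in the returned table's ``attrs["n_dropped"]``
— readers never silently discard rows.  GMT files follow the usual
set-name / description / tab-separated-members layout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .diagnostic import TwoByTwo
from .summary import ArmSummary

__all__ = [
    "StudyRecord",
    "Manifest",
    "ManifestStudy",
    "read_summary_table",
    "write_summary_table",
    "read_expression_table",
    "write_expression_table",
    "read_gmt",
    "read_gene_list",
    "read_deg_table",
    "read_survival_table",
    "load_manifest",
]

logger = logging.getLogger(__name__)

NA_TOKENS = {"", "NA", "NaN", "nan"}

SUMMARY_COLUMNS = ["Name", "Case_n", "Case_mean", "Case_sd", "Cont_n", "Cont_mean", "Cont_sd"]
COUNT_COLUMNS = ["TP", "FP", "FN", "TN"]


@dataclass(frozen=True)
class StudyRecord:
    """One dataset: id, optional provenance, both arm summaries, optional 2×2."""

    study_id: str
    case: ArmSummary
    control: ArmSummary
    country: str = ""
    year: int | None = None
    counts: TwoByTwo | None = None


@dataclass(frozen=True)
class ManifestStudy:
    study_id: str
    country: str = ""
    year: int | None = None
    path: str | None = None
    log2: bool = False


@dataclass(frozen=True)
class Manifest:
    """Dataset manifest: unique study ids plus analysis options."""

    studies: tuple[ManifestStudy, ...]
    options: dict

    def __post_init__(self) -> None:
        ids = [s.study_id for s in self.studies]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate study ids in manifest")
        for s in self.studies:
            if s.year is not None and not (1000 <= s.year <= 9999):
                raise ValueError(f"{s.study_id}: year must be a 4-digit integer")


def _read_table(path: str | Path, sep: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _to_float(value: str, path, line: int, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ValueError(
            f"{path}, line {line}: unparsable numeric field {value!r} in column {column}"
        ) from None


def _to_int(value: str, path, line: int, column: str) -> int:
    v = _to_float(value, path, line, column)
    if not float(v).is_integer():
        raise ValueError(f"{path}, line {line}: column {column} must be an integer, got {value!r}")
    return int(v)


def read_summary_table(path: str | Path, sep: str = "\t") -> list[StudyRecord]:
    """Load per-study arm summaries (and optional TP/FP/FN/TN counts).

    Required columns: Name, Case_n, Case_mean, Case_sd, Cont_n, Cont_mean,
    Cont_sd.  The four count columns are all-or-nothing per row; a partial
    2×2 is a validation error naming the study.
    """
    df = _read_table(path, sep)
    for col in SUMMARY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    has_count_cols = all(c in df.columns for c in COUNT_COLUMNS)
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        sid = getattr(row, "Name")
        try:
            arms = {}
            for prefix, label in (("Case", "case"), ("Cont", "control")):
                n = _to_int(getattr(row, f"{prefix}_n"), path, idx, f"{prefix}_n")
                mean = _to_float(getattr(row, f"{prefix}_mean"), path, idx, f"{prefix}_mean")
                sd = _to_float(getattr(row, f"{prefix}_sd"), path, idx, f"{prefix}_sd")
                if n < 1:
                    raise ValueError(f"study {sid}: {prefix}_n must be a positive integer")
                if sd < 0:
                    raise ValueError(f"study {sid}: negative SD")
                arms[label] = ArmSummary(n=n, mean=mean, sd=sd)
            counts = None
            if has_count_cols:
                raw = [getattr(row, c) for c in COUNT_COLUMNS]
                present = [v for v in raw if v not in NA_TOKENS]
                if len(present) == 4:
                    tp, fp, fn, tn = (_to_int(v, path, idx, c) for v, c in zip(raw, COUNT_COLUMNS))
                    counts = TwoByTwo(tp=tp, fp=fp, fn=fn, tn=tn)
                elif present:
                    raise ValueError(f"study {sid}: partial 2x2 counts (all of TP/FP/FN/TN or none)")
            records.append(StudyRecord(study_id=str(sid), case=arms["case"],
                                       control=arms["control"], counts=counts))
        except ValueError as err:
            raise ValueError(f"{path}, line {idx}: {err}") from None
    return records


def write_summary_table(records: Sequence[StudyRecord], path: str | Path, sep: str = "\t") -> None:
    rows = []
    any_counts = any(r.counts is not None for r in records)
    for r in records:
        row = {
            "Name": r.study_id,
            "Case_n": r.case.n, "Case_mean": r.case.mean, "Case_sd": r.case.sd,
            "Cont_n": r.control.n, "Cont_mean": r.control.mean, "Cont_sd": r.control.sd,
        }
        if any_counts:
            if r.counts is not None:
                row.update(TP=r.counts.tp, FP=r.counts.fp, FN=r.counts.fn, TN=r.counts.tn)
            else:
                row.update(TP="NA", FP="NA", FN="NA", TN="NA")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_expression_table(path: str | Path, sep: str = "\t", log2: bool = False) -> pd.DataFrame:
    """Load (sample_id, group, value) rows; drops NA values with a count.

    ``log2`` applies a log2 transform at load time (per-study manifest
    option for chips reported on a linear scale).  Values must be finite;
    group labels must be 'case' or 'control'.
    """
    df = _read_table(path, sep)
    for col in ("sample_id", "group", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    n0 = len(df)
    df = df[~df["value"].isin(NA_TOKENS)].copy()
    dropped = n0 - len(df)
    if dropped:
        logger.warning("%s: dropped %d rows with missing values", path, dropped)
    values = []
    for idx, v in zip(df.index, df["value"]):
        values.append(_to_float(v, path, idx + 2, "value"))
    df["value"] = values
    bad = set(df["group"]) - {"case", "control"}
    if bad:
        raise ValueError(f"{path}: unknown group labels {sorted(bad)}")
    if not all(math.isfinite(v) for v in df["value"]):
        raise ValueError(f"{path}: non-finite expression values")
    if log2:
        if (df["value"] <= 0).any():
            raise ValueError(f"{path}: log2 transform requires positive values")
        df["value"] = np.log2(df["value"])
    df = df.reset_index(drop=True)
    df.attrs["n_dropped"] = dropped
    return df


def write_expression_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df[["sample_id", "group", "value"]].to_csv(path, sep=sep, index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file into named gene sets (duplicates de-duplicated)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}, line {lineno}: GMT needs name, description, members")
            name = fields[0]
            members = {g for g in fields[2:] if g}
            if name in sets:
                raise ValueError(f"{path}, line {lineno}: duplicate set name {name!r}")
            sets[name] = members
    return sets


def read_gene_list(path: str | Path) -> set[str]:
    """Plain-text gene list, one symbol per line; blanks ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_deg_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Load (gene, logFC, P) rows with numeric validation."""
    df = _read_table(path, sep)
    for col in ("gene", "logFC", "P"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    n0 = len(df)
    df = df[~df["logFC"].isin(NA_TOKENS) & ~df["P"].isin(NA_TOKENS)].copy()
    dropped = n0 - len(df)
    if dropped:
        logger.warning("%s: dropped %d rows with missing values", path, dropped)
    df["logFC"] = [_to_float(v, path, i + 2, "logFC") for i, v in zip(df.index, df["logFC"])]
    df["P"] = [_to_float(v, path, i + 2, "P") for i, v in zip(df.index, df["P"])]
    df = df.reset_index(drop=True)
    df.attrs["n_dropped"] = dropped
    return df


def read_survival_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Load (sample_id, time, event, group) rows; event must be 0/1."""
    df = _read_table(path, sep)
    for col in ("sample_id", "time", "event", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df = df.copy()
    df["time"] = [_to_float(v, path, i + 2, "time") for i, v in zip(df.index, df["time"])]
    events = []
    for i, v in zip(df.index, df["event"]):
        e = _to_int(v, path, i + 2, "event")
        if e not in (0, 1):
            raise ValueError(f"{path}, line {i + 2}: event must be 0 or 1, got {v!r}")
        events.append(e)
    df["event"] = events
    return df.reset_index(drop=True)


def load_manifest(path: str | Path) -> Manifest:
    """Load a YAML dataset manifest and validate referenced paths."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = Path(path).parent
    studies = []
    for s in raw.get("studies", []):
        study = ManifestStudy(
            study_id=str(s["study_id"]),
            country=str(s.get("country", "")),
            year=int(s["year"]) if "year" in s and s["year"] is not None else None,
            path=s.get("path"),
            log2=bool(s.get("log2", False)),
        )
        if study.path is not None and not (base / study.path).exists():
            raise FileNotFoundError(f"manifest references missing path {study.path!r}")
        studies.append(study)
    return Manifest(studies=tuple(studies), options=dict(raw.get("options", {})))
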