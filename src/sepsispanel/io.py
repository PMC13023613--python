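"""Reading, validating and normalizing expression matrices and sample metadata.

Expression data travel as :class:`ExpressionMatrix` — a genes × samples
pandas frame plus a declared scale (``raw_counts`` or ``log2_normalized``).
The scale is carried explicitly so that downstream scoring can refuse raw
counts instead of silently averaging them.

Raw counts are normalized to log2(CPM + 1): counts-per-million within each
sample, a pseudocount of one, then log2. Pre-normalized matrices declared
``log2_normalized`` are accepted as-is and never re-normalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RAW_COUNTS = "raw_counts"
LOG2_NORMALIZED = "log2_normalized"
VALID_SCALES = (RAW_COUNTS, LOG2_NORMALIZED)

GENES_IN_ROWS = "genes_in_rows"
SAMPLES_IN_ROWS = "samples_in_rows"

#: column names recognized in metadata files (headers matched case-insensitively)
METADATA_COLUMNS = ("sample_id", "subject_id", "group", "timepoint", "sex", "sofa", "outcome")

SOFA_MIN, SOFA_MAX = 0, 24


class ExpressionError(ValueError):
    """Malformed or invalid expression input."""


class MetadataError(ValueError):
    """Malformed or invalid sample metadata."""


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with a declared scale.

    Parameters
    ----------
    values
        DataFrame indexed by uppercase, unique gene symbols; columns are
        sample identifiers.
    scale
        ``"raw_counts"`` (non-negative) or ``"log2_normalized"``.
    """

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ExpressionError(f"scale must be one of {VALID_SCALES}, got {self.scale!r}")
        if not self.values.index.is_unique:
            raise ExpressionError("gene symbols must be unique (deduplicate on read)")
        if not self.values.columns.is_unique:
            raise ExpressionError("sample ids must be unique")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ExpressionError("expression values must be finite")
        if self.scale == RAW_COUNTS and (arr < 0).any():
            raise ExpressionError("raw counts must be non-negative")

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SampleRecord:
    """Per-sample clinical metadata.

    ``subject_id`` links repeated measurements of one patient; it defaults
    to the sample id. ``sofa`` is the Sequential Organ Failure Assessment
    score (sum of six 0–4 organ sub-scores, range 0–24) or ``None``.
    """

    sample_id: str
    subject_id: str | None = None
    group: str = ""
    timepoint: str | None = None
    sex: str = "unknown"
    sofa: int | None = None
    outcome: str = "unknown"

    def __post_init__(self) -> None:
        if self.subject_id is None:
            self.subject_id = self.sample_id
        if self.sofa is not None:
            self.sofa = int(self.sofa)
            if not SOFA_MIN <= self.sofa <= SOFA_MAX:
                raise MetadataError(
                    f"sample {self.sample_id}: SOFA {self.sofa} outside [{SOFA_MIN}, {SOFA_MAX}]"
                )
        if self.sex not in ("F", "M", "unknown"):
            raise MetadataError(f"sample {self.sample_id}: sex must be F, M or unknown")


def _detect_sep(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).lower().endswith(".csv") else "\t"


def _dedupe_max(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse duplicate gene symbols by the per-sample maximum."""
    n_dup = int(df.index.duplicated().sum())
    if n_dup:
        df = df.groupby(level=0, sort=False).max()
    return df, n_dup


def read_expression(
    path: str | Path,
    orientation: str = GENES_IN_ROWS,
    scale: str = LOG2_NORMALIZED,
    sep: str | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression matrix into genes-in-rows orientation.

    The first column holds identifiers (genes or samples, per
    ``orientation``); the header row holds the other axis. Gene symbols are
    uppercased; duplicate symbols are collapsed by the per-sample maximum
    and the collapsed-row count is logged.
    """
    if orientation not in (GENES_IN_ROWS, SAMPLES_IN_ROWS):
        raise ExpressionError(f"unknown orientation {orientation!r}")
    try:
        df = pd.read_csv(path, sep=_detect_sep(path, sep), index_col=0)
    except pd.errors.ParserError as exc:
        raise ExpressionError(f"malformed expression file {path}: {exc}") from exc
    if orientation == SAMPLES_IN_ROWS:
        df = df.T
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ExpressionError(f"non-numeric expression values in {path}: {exc}") from exc
    df.index = df.index.astype(str).str.strip().str.upper()
    df.columns = df.columns.astype(str)
    df.index.name = "gene"
    df.columns.name = None
    df, n_dup = _dedupe_max(df)
    if n_dup:
        logger.info("collapsed %d duplicate gene rows in %s (per-sample max)", n_dup, path)
    return ExpressionMatrix(values=df, scale=scale)


def write_expression(matrix: ExpressionMatrix, path: str | Path, sep: str | None = None) -> None:
    matrix.values.to_csv(path, sep=_detect_sep(path, sep), index_label="gene")


def read_metadata(path: str | Path, sep: str | None = None) -> list[SampleRecord]:
    """Read per-sample metadata. ``sample_id`` is required and must be unique.

    Headers are matched case-insensitively; unrecognized columns are
    ignored. Missing optional fields take their missing markers
    (timepoint/sofa → None, sex/outcome → "unknown").
    """
    df = pd.read_csv(path, sep=_detect_sep(path, sep), dtype=str)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "sample_id" not in df.columns:
        raise MetadataError(f"{path}: metadata must contain a sample_id column")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise MetadataError(f"{path}: duplicate sample_id(s): {dups}")
    records = []
    for _, row in df.iterrows():
        def get(col: str) -> str | None:
            val = row.get(col)
            if val is None or (isinstance(val, float) and np.isnan(val)) or pd.isna(val):
                return None
            val = str(val).strip()
            return val or None

        sofa_raw = get("sofa")
        try:
            sofa = int(float(sofa_raw)) if sofa_raw is not None else None
        except ValueError as exc:
            raise MetadataError(f"sample {get('sample_id')}: non-integer SOFA {sofa_raw!r}") from exc
        records.append(
            SampleRecord(
                sample_id=get("sample_id"),
                subject_id=get("subject_id"),
                group=get("group") or "",
                timepoint=get("timepoint"),
                sex=get("sex") or "unknown",
                sofa=sofa,
                outcome=get("outcome") or "unknown",
            )
        )
    return records


def write_metadata(records: Sequence[SampleRecord], path: str | Path, sep: str | None = None) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "subject_id": r.subject_id,
                "group": r.group,
                "timepoint": r.timepoint if r.timepoint is not None else "",
                "sex": r.sex,
                "sofa": r.sofa if r.sofa is not None else "",
                "outcome": r.outcome,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=_detect_sep(path, sep), index=False)


def records_by_sample(records: Iterable[SampleRecord]) -> dict[str, SampleRecord]:
    out: dict[str, SampleRecord] = {}
    for r in records:
        if r.sample_id in out:
            raise MetadataError(f"duplicate sample_id {r.sample_id!r}")
        out[r.sample_id] = r
    return out


def normalize_log2(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert raw counts to log2(CPM + 1).

    CPM[g, s] = count[g, s] / total(s) × 10^6. Every sample must have a
    positive total count. The per-sample identity
    sum_g (2^value − 1) = 10^6 holds exactly up to floating error.
    """
    if matrix.scale != RAW_COUNTS:
        raise ExpressionError(
            f"normalize_log2 expects raw_counts input, got scale {matrix.scale!r}"
        )
    totals = matrix.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ExpressionError(f"zero total count in sample(s): {list(zero.index)}")
    cpm = matrix.values.div(totals, axis=1) * 1e6
    return ExpressionMatrix(values=np.log2(cpm + 1.0), scale=LOG2_NORMALIZED)
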