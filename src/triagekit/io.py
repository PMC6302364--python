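"""Reading score tables, serializing rules, and writing result tables.

Score tables are delimited text (comma or tab, auto-detected) with a header:
one item-id column first, one score column per class label, and optionally a
``truth`` column.  On-disk row sums are accepted within 1e-4 per score cell
of 1 — upstream exports round — and renormalized with a logged warning;
anything worse is rejected.  Rules persist as versioned JSON and round-trip losslessly.
All diagnostics go to the logger (standard error in the CLI); computation
results only ever go to standard output or the requested output files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import REFUSE, TriageResult, TriageRule
from .softmax import PrecisionCoverageCurve, ScoreMatrix

__all__ = [
    "ScoreTable",
    "read_scores",
    "save_rule",
    "load_rule",
    "write_decisions",
    "write_curve",
    "read_curve",
]

logger = logging.getLogger("triagekit")

RULE_FORMAT_VERSION = 1
TRUTH_COLUMN = "truth"
#: on-disk rounding allowance per score cell; a row of m scores each rounded
#: at the fourth decimal may be off by up to m * 1e-4 in total
DISK_CELL_TOL = 1e-4
#: fixed float format so identical inputs yield byte-identical outputs
_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class ScoreTable:
    """A parsed score file: matrix, item ids, and the truth column if present."""

    scores: ScoreMatrix
    ids: np.ndarray
    truth: np.ndarray | None = None


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_scores(path: str | Path) -> ScoreTable:
    """Parse a delimited score table into a validated :class:`ScoreMatrix`.

    The class-label order is taken from the header.  Rows whose scores sum
    to within ``DISK_ROW_TOL`` of 1 but not exactly are renormalized with a
    warning naming them; rows further off, non-numeric cells, duplicate
    label columns, or a missing header are parse errors.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\r\n")
    if not header_line:
        raise ValueError(f"{path}: empty file")
    sep = _sniff_delimiter(header_line)
    header = header_line.split(sep)
    if len(header) != len(set(header)):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ValueError(f"{path}: duplicate column(s) {dupes}")

    numeric_header = True
    for cell in header:
        try:
            float(cell)
        except ValueError:
            numeric_header = False
            break
    if numeric_header:
        raise ValueError(f"{path}: first line is numeric; a header row is required")

    frame = pd.read_csv(path, sep=sep, dtype=str)
    id_col = header[0]
    label_cols = [c for c in header[1:] if c != TRUTH_COLUMN]
    if not label_cols:
        raise ValueError(f"{path}: no score columns found after {id_col!r}")
    if REFUSE in label_cols:
        raise ValueError(
            f"{path}: column {REFUSE!r} collides with the refusal sentinel"
        )

    try:
        values = frame[label_cols].astype(float).to_numpy()
    except ValueError as exc:
        for col in label_cols:
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = coerced.isna() & frame[col].notna()
            if bad.any():
                row = int(np.argmax(bad.to_numpy()))
                raise ValueError(
                    f"{path}: non-numeric score at row {row}, column {col!r}"
                ) from exc
        raise
    if not np.all(np.isfinite(values)):
        row, col = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"{path}: non-finite score at row {int(row)}, "
            f"column {label_cols[int(col)]!r}"
        )

    sums = values.sum(axis=1)
    row_tol = DISK_CELL_TOL * len(label_cols)
    off = np.abs(sums - 1.0) > row_tol
    if np.any(off):
        row = int(np.argmax(off))
        raise ValueError(
            f"{path}: row {row} scores sum to {sums[row]!r}, "
            f"beyond the {row_tol:g} rounding tolerance"
        )
    needs_renorm = np.abs(sums - 1.0) > 1e-12
    if np.any(needs_renorm):
        rows = np.nonzero(needs_renorm)[0]
        logger.warning(
            "%s: renormalized %d row(s) whose scores did not sum to 1 "
            "(first: row %d, sum %.6g)",
            path,
            rows.size,
            int(rows[0]),
            sums[rows[0]],
        )
        values = values / sums[:, None]

    truth = None
    if TRUTH_COLUMN in header[1:]:
        truth = frame[TRUTH_COLUMN].astype(str).to_numpy(dtype=object)
        unknown = sorted(set(truth) - set(label_cols))
        if unknown:
            raise ValueError(
                f"{path}: truth value(s) {unknown} are not score columns"
            )
    scores = ScoreMatrix(values=values, labels=label_cols)
    return ScoreTable(
        scores=scores, ids=frame[id_col].to_numpy(dtype=object), truth=truth
    )


def save_rule(rule: TriageRule, path: str | Path) -> None:
    """Persist a rule as versioned JSON (lossless round-trip)."""
    payload = {
        "format_version": RULE_FORMAT_VERSION,
        "threshold_b": rule.threshold_b,
        "epsilon": rule.epsilon,
        "labels": list(rule.labels),
        "class_mask": [bool(v) for v in rule.class_mask],
        "tie_break": rule.tie_break,
    }
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def load_rule(path: str | Path) -> TriageRule:
    """Load a rule file, rejecting unknown format versions."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    version = payload.get("format_version")
    if version != RULE_FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported rule format version {version!r} "
            f"(expected {RULE_FORMAT_VERSION})"
        )
    return TriageRule(
        threshold_b=float(payload["threshold_b"]),
        labels=list(payload["labels"]),
        class_mask=np.asarray(payload["class_mask"], dtype=bool),
        epsilon=None if payload["epsilon"] is None else float(payload["epsilon"]),
        tie_break=payload.get("tie_break", "lowest-index"),
    )


def _fmt(value: float) -> str:
    return _FLOAT_FMT % value


def write_decisions(
    path: str | Path,
    ids: np.ndarray,
    result: TriageResult,
    max_scores: np.ndarray,
) -> None:
    """Write the per-item decision table: id, decision, max score, decided flag."""
    lines = ["item_id,decision,max_score,decided"]
    for i in range(result.n_items):
        lines.append(
            f"{ids[i]},{result.decisions[i]},"
            f"{_fmt(float(max_scores[i]))},{int(result.decided[i])}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_curve(path: str | Path, curve: PrecisionCoverageCurve) -> None:
    """Write curve points (threshold, coverage, precision, joint_loss) as CSV."""
    lines = ["threshold,coverage,precision,joint_loss"]
    for row in curve.points.itertuples(index=False):
        lines.append(
            f"{_fmt(row.threshold)},{_fmt(row.coverage)},"
            f"{_fmt(row.precision)},{_fmt(row.joint_loss)}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_curve(path: str | Path) -> PrecisionCoverageCurve:
    """Read back a curve file written by :func:`write_curve`."""
    frame = pd.read_csv(path)
    return PrecisionCoverageCurve(points=frame.astype(float))
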