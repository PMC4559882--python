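"""Cohort tables and analysis reports on disk.

The on-disk cohort format is a long, tab-separated, UTF-8 table with a
mandatory header::

    sample_id  class  session  assay  rep1  rep2  rep3

One row per (sample, assay) triplicate of cycle-threshold (Ct) values.
``NA`` is the sole missing token (empty cells are treated the same);
missing replicates are dropped from the replicate list, and rows left with
fewer than two usable replicates are rejected with a report entry rather
than silently discarded — a sample standard deviation needs at least two
points.

An alternate wide layout (one row per sample, replicate columns named
``<assay>.1``, ``<assay>.2``, ``<assay>.3``) is accepted via
``format_options={"layout": "wide"}``.

Class labels in files are free strings mapped onto the internal
``{target, versus}`` vocabulary through a mapping (default:
``ADC -> target``, ``SQC -> versus``); unmapped labels become ``unknown``.

Reports are written as machine-readable JSON documents built from plain
key/value structures; :func:`read_report` round-trips :func:`write_report`
exactly. Human-readable TSV companions are emitted by the CLI.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, IntegrityError, ParseError

MISSING_TOKEN = "NA"

CLASS_TARGET = "target"
CLASS_VERSUS = "versus"
CLASS_UNKNOWN = "unknown"

#: default free-string -> internal class mapping (lung-tumor study vocabulary)
DEFAULT_CLASS_MAP: dict[str, str] = {
    "ADC": CLASS_TARGET,
    "SQC": CLASS_VERSUS,
    CLASS_TARGET: CLASS_TARGET,
    CLASS_VERSUS: CLASS_VERSUS,
}

_COLUMNS = ("sample_id", "class", "session", "assay", "rep1", "rep2", "rep3")


@dataclass(frozen=True)
class TriplicateRecord:
    """One assay's technical replicates for one sample.

    ``replicates`` are Ct values (PCR cycles, log2-fluorescence scale); the
    triplicate is summarized by its sample mean ``x`` and sample SD ``s``
    (n-1 denominator).
    """

    sample_id: str
    assay: str
    replicates: tuple[float, ...]
    session: str | None = None
    class_label: str | None = None

    def __post_init__(self) -> None:
        if len(self.replicates) < 2:
            raise IntegrityError(
                f"triplicate ({self.sample_id}, {self.assay}) has "
                f"{len(self.replicates)} replicate(s); at least 2 required"
            )
        if not all(math.isfinite(v) for v in self.replicates):
            raise IntegrityError(
                f"triplicate ({self.sample_id}, {self.assay}) has non-finite replicates"
            )

    @property
    def mean(self) -> float:
        """Sample mean x of the replicates."""
        return float(np.mean(self.replicates))

    @property
    def sd(self) -> float:
        """Sample standard deviation s (n-1 denominator)."""
        return float(np.std(self.replicates, ddof=1))

    @property
    def variance(self) -> float:
        """Sample variance s**2 (n-1 denominator)."""
        return float(np.var(self.replicates, ddof=1))


@dataclass
class Cohort:
    """A collection of triplicate records plus class priors.

    ``priors`` is ``(p_T, p_V)``, the prior presentation probabilities of the
    target and versus class; they must be strictly positive and sum to 1.
    ``rejected`` carries human-readable entries for input rows that could not
    become records (e.g. fewer than two usable replicates).
    """

    records: list[TriplicateRecord]
    assays: list[str] = field(default_factory=list)
    priors: tuple[float, float] = (0.5, 0.5)
    rejected: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.assays:
            seen: dict[str, None] = {}
            for rec in self.records:
                seen.setdefault(rec.assay, None)
            self.assays = list(seen)
        p_t, p_v = self.priors
        if not (p_t > 0 and p_v > 0):
            raise ConfigurationError("class priors must be strictly positive")
        if abs(p_t + p_v - 1.0) > 1e-9:
            raise ConfigurationError("class priors must sum to 1")
        keys = [(r.sample_id, r.assay) for r in self.records]
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise IntegrityError(f"duplicate (sample_id, assay) pair {dup}")

    @property
    def prior_ratio(self) -> float:
        return self.priors[0] / self.priors[1]

    def by_assay(self, assay: str) -> list[TriplicateRecord]:
        return [r for r in self.records if r.assay == assay]

    def by_sample(self) -> dict[str, list[TriplicateRecord]]:
        out: dict[str, list[TriplicateRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.sample_id, []).append(rec)
        return out

    @property
    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.sample_id, None)
        return list(seen)


def _parse_cell(token: str, row_no: int, column: str) -> float | None:
    token = token.strip()
    if token in ("", MISSING_TOKEN):
        return None
    try:
        value = float(token)
    except ValueError:
        raise ParseError(
            f"malformed numeric cell {token!r} at row {row_no}, column {column!r}"
        ) from None
    if not math.isfinite(value):
        raise ParseError(f"non-finite value at row {row_no}, column {column!r}")
    return value


def _map_class(raw: str, class_map: Mapping[str, str]) -> str | None:
    raw = raw.strip()
    if raw in ("", MISSING_TOKEN):
        return None
    return class_map.get(raw, CLASS_UNKNOWN)


def read_cohort(
    path: str | Path,
    format_options: Mapping[str, Any] | None = None,
    class_map: Mapping[str, str] | None = None,
    priors: tuple[float, float] = (0.5, 0.5),
) -> Cohort:
    """Read a cohort TSV into a :class:`Cohort`.

    Parameters
    ----------
    path:
        TSV file in the long layout described in the module docstring, or the
        wide layout when ``format_options={"layout": "wide"}``.
    format_options:
        ``{"layout": "long" | "wide"}``; default long.
    class_map:
        Free-string -> ``{target, versus}`` mapping; defaults to the
        ADC/SQC vocabulary.
    priors:
        ``(p_T, p_V)`` prior class probabilities stored on the cohort.
    """
    path = Path(path)
    options = dict(format_options or {})
    layout = options.pop("layout", "long")
    if options:
        raise ConfigurationError(f"unknown format options: {sorted(options)}")
    cmap = dict(DEFAULT_CLASS_MAP if class_map is None else class_map)

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, header row required") from None
        rows = list(reader)

    if layout == "long":
        records, rejected = _parse_long(header, rows, cmap, path)
    elif layout == "wide":
        records, rejected = _parse_wide(header, rows, cmap, path)
    else:
        raise ConfigurationError(f"unknown layout {layout!r}")

    cohort = Cohort(records=records, priors=priors)
    cohort.rejected.extend(rejected)
    return cohort


def _parse_long(
    header: Sequence[str],
    rows: Iterable[Sequence[str]],
    cmap: Mapping[str, str],
    path: Path,
) -> tuple[list[TriplicateRecord], list[str]]:
    header = [h.strip() for h in header]
    if tuple(header[:4]) != _COLUMNS[:4] or not header[4:]:
        raise ParseError(
            f"{path}: header must start with {_COLUMNS[:4]} followed by replicate "
            f"columns, got {header}"
        )
    rep_cols = header[4:]
    records: list[TriplicateRecord] = []
    rejected: list[str] = []
    for row_no, row in enumerate(rows, start=2):
        if not any(cell.strip() for cell in row):
            continue
        row = list(row) + [""] * (len(header) - len(row))
        sample_id, raw_class, session, assay = (c.strip() for c in row[:4])
        reps = [
            v
            for col, cell in zip(rep_cols, row[4:])
            if (v := _parse_cell(cell, row_no, col)) is not None
        ]
        if len(reps) < 2:
            rejected.append(
                f"row {row_no}: ({sample_id}, {assay}) has {len(reps)} usable "
                "replicate(s) (<2), rejected"
            )
            continue
        records.append(
            TriplicateRecord(
                sample_id=sample_id,
                assay=assay,
                replicates=tuple(reps),
                session=session or None,
                class_label=_map_class(raw_class, cmap),
            )
        )
    return records, rejected


def _parse_wide(
    header: Sequence[str],
    rows: Iterable[Sequence[str]],
    cmap: Mapping[str, str],
    path: Path,
) -> tuple[list[TriplicateRecord], list[str]]:
    header = [h.strip() for h in header]
    if header[:3] != ["sample_id", "class", "session"]:
        raise ParseError(
            f"{path}: wide header must start with sample_id, class, session"
        )
    assay_cols: dict[str, list[int]] = {}
    for idx, name in enumerate(header[3:], start=3):
        assay, _, rep = name.rpartition(".")
        if not assay or not rep.isdigit():
            raise ParseError(
                f"{path}: wide replicate column {name!r} must be named <assay>.<k>"
            )
        assay_cols.setdefault(assay, []).append(idx)
    records: list[TriplicateRecord] = []
    rejected: list[str] = []
    for row_no, row in enumerate(rows, start=2):
        if not any(cell.strip() for cell in row):
            continue
        row = list(row) + [""] * (len(header) - len(row))
        sample_id, raw_class, session = (c.strip() for c in row[:3])
        for assay, idxs in assay_cols.items():
            cells = [(header[i], row[i]) for i in idxs]
            if all(c.strip() in ("", MISSING_TOKEN) for _, c in cells):
                continue  # assay not measured for this sample
            reps = [
                v
                for col, cell in cells
                if (v := _parse_cell(cell, row_no, col)) is not None
            ]
            if len(reps) < 2:
                rejected.append(
                    f"row {row_no}: ({sample_id}, {assay}) has {len(reps)} usable "
                    "replicate(s) (<2), rejected"
                )
                continue
            records.append(
                TriplicateRecord(
                    sample_id=sample_id,
                    assay=assay,
                    replicates=tuple(reps),
                    session=session or None,
                    class_label=_map_class(raw_class, cmap),
                )
            )
    return records, rejected


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort in the long TSV layout (inverse of :func:`read_cohort`)."""
    path = Path(path)
    inverse_class = {CLASS_TARGET: "ADC", CLASS_VERSUS: "SQC"}
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        for rec in cohort.records:
            reps = [f"{v:.6g}" for v in rec.replicates]
            reps += [MISSING_TOKEN] * (3 - len(reps))
            writer.writerow(
                [
                    rec.sample_id,
                    inverse_class.get(rec.class_label or "", rec.class_label or MISSING_TOKEN),
                    rec.session or MISSING_TOKEN,
                    rec.assay,
                    *reps,
                ]
            )


def to_document(obj: Any) -> Any:
    """Convert a result object into a JSON-safe nested key/value document."""
    if hasattr(obj, "to_dict"):
        return to_document(obj.to_dict())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_document(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, Mapping):
        return {str(k): to_document(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = sorted(obj) if isinstance(obj, (set, frozenset)) else obj
        return [to_document(v) for v in items]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [to_document(v) for v in obj.tolist()]
    if obj is None or isinstance(obj, (bool, int, float, str)):
        return obj
    raise TypeError(f"cannot serialize {type(obj).__name__} into a report document")


def write_report(obj: Any, path: str | Path) -> None:
    """Serialize a result object as a machine-readable JSON report."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = to_document(obj)
    with path.open("w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")


def read_report(path: str | Path) -> Any:
    """Read back a report written by :func:`write_report`."""
    with Path(path).open(encoding="utf-8") as fh:
        return json.load(fh)
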