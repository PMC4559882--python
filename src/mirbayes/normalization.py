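"""Reference normalization (delta-Ct) and cross-session accuracy audit.

Raw triplicate means drift between experimental sessions (different days,
reagent lots, instrument calibrations) by additive offsets of a few Ct.
Subtracting a stably expressed reference assay (here snRNA U6) cancels any
offset common to all assays of a session::

    dx_A = x_A - x_ref

Measure naming: for an assay named ``miR-205`` the raw measure is ``x_205``
and the normalized one ``dx_205`` (common prefixes ``miR-`` / ``snRNA `` are
stripped to form the suffix); the reference itself only contributes its raw
measure (``x_U6``).

The session audit quantifies the drift: per session and class it reports the
sample mean, SD and SE of a measure, and for each session pair the difference
of means with its standard error combined in quadrature
(``SE = sqrt(SE_1^2 + SE_2^2)``, sessions independent). A measure is declared
session-stable when ``|difference| < 2 SE`` (p > 0.05 under normality).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .data_io import Cohort
from .errors import AuditNotApplicableError, ConfigurationError


@dataclass
class MeasureVector:
    """All scalar measures derived for one sample (Ct units)."""

    sample_id: str
    class_label: str | None = None
    session: str | None = None
    values: dict[str, float] = field(default_factory=dict)


def measure_suffix(assay: str) -> str:
    """Short measure suffix for an assay name (``miR-205`` -> ``205``)."""
    for prefix in ("snRNA ", "miR-", "hsa-miR-"):
        if assay.startswith(prefix) and len(assay) > len(prefix):
            return assay[len(prefix):]
    return assay


def normalize(cohort: Cohort, reference_assay: str) -> tuple[list[MeasureVector], list[str]]:
    """Build per-sample measure vectors with reference-normalized deltas.

    Every triplicate contributes its raw mean ``x_<suffix>``; samples whose
    reference triplicate survived QC additionally get ``dx_<suffix>`` for each
    non-reference assay. Samples lacking the reference keep only raw values
    and are listed in the returned exclusions.
    """
    if reference_assay not in cohort.assays:
        raise ConfigurationError(
            f"reference assay {reference_assay!r} not present in cohort assays {cohort.assays}"
        )
    measures: list[MeasureVector] = []
    exclusions: list[str] = []
    for sample_id, records in cohort.by_sample().items():
        by_assay = {r.assay: r for r in records}
        first = records[0]
        mv = MeasureVector(
            sample_id=sample_id,
            class_label=first.class_label,
            session=first.session,
        )
        for assay, rec in by_assay.items():
            mv.values[f"x_{measure_suffix(assay)}"] = rec.mean
        ref = by_assay.get(reference_assay)
        if ref is None:
            exclusions.append(
                f"sample {sample_id}: no valid {reference_assay} triplicate; "
                "normalized measures unavailable"
            )
        else:
            for assay, rec in by_assay.items():
                if assay == reference_assay:
                    continue
                mv.values[f"dx_{measure_suffix(assay)}"] = rec.mean - ref.mean
        measures.append(mv)
    return measures, exclusions


@dataclass(frozen=True)
class SessionCell:
    """Summary of one measure within one (session, class) cell."""

    session: str
    class_label: str
    n: int
    mean: float
    sd: float
    se: float

    def to_dict(self) -> dict:
        return {
            "session": self.session,
            "class": self.class_label,
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "se": self.se,
        }


@dataclass(frozen=True)
class SessionDifference:
    """Between-session difference of means for one class, with combined SE."""

    session_a: str
    session_b: str
    class_label: str
    difference: float
    se: float
    stable: bool

    def to_dict(self) -> dict:
        return {
            "sessions": [self.session_a, self.session_b],
            "class": self.class_label,
            "difference": self.difference,
            "se": self.se,
            "stable": self.stable,
        }


@dataclass(frozen=True)
class SessionAudit:
    measure: str
    cells: tuple[SessionCell, ...]
    differences: tuple[SessionDifference, ...]

    @property
    def stable(self) -> bool:
        """True when every between-session difference is within 2 SE."""
        return all(d.stable for d in self.differences)

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "cells": [c.to_dict() for c in self.cells],
            "differences": [d.to_dict() for d in self.differences],
            "stable": self.stable,
        }


def session_bias_audit(measures: list[MeasureVector], measure_name: str) -> SessionAudit:
    """Audit the session stability of one measure, per class.

    Audits are per class only — pooling classes would confound class
    imbalance between sessions with genuine session bias. Requires at least
    two sessions with >= 2 samples each for some class.
    """
    grouped: dict[tuple[str, str], list[float]] = {}
    for mv in measures:
        if measure_name not in mv.values or not mv.session or not mv.class_label:
            continue
        grouped.setdefault((mv.session, mv.class_label), []).append(mv.values[measure_name])

    cells = []
    for (session, cls), vals in sorted(grouped.items()):
        if len(vals) < 2:
            continue
        arr = np.asarray(vals, dtype=float)
        sd = float(np.std(arr, ddof=1))
        cells.append(
            SessionCell(
                session=session,
                class_label=cls,
                n=arr.size,
                mean=float(np.mean(arr)),
                sd=sd,
                se=sd / np.sqrt(arr.size),
            )
        )

    sessions = sorted({c.session for c in cells})
    if len(sessions) < 2:
        raise AuditNotApplicableError(
            f"session audit of {measure_name!r} needs >= 2 sessions with >= 2 "
            f"samples; found sessions {sessions}"
        )

    by_key = {(c.session, c.class_label): c for c in cells}
    differences = []
    for cls in sorted({c.class_label for c in cells}):
        for sa, sb in combinations(sessions, 2):
            ca, cb = by_key.get((sa, cls)), by_key.get((sb, cls))
            if ca is None or cb is None:
                continue
            diff = cb.mean - ca.mean
            se = float(np.hypot(ca.se, cb.se))
            differences.append(
                SessionDifference(
                    session_a=sa,
                    session_b=sb,
                    class_label=cls,
                    difference=diff,
                    se=se,
                    stable=abs(diff) < 2.0 * se,
                )
            )
    return SessionAudit(measure=measure_name, cells=tuple(cells), differences=tuple(differences))
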