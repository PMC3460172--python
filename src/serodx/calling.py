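"""Per-antigen and panel-level positivity calling.

An antigen call is positive when (a) the titration series shows evidence of
a dose response — operationalized as Spearman rank correlation between RU
and coat level at or above a configurable threshold (default 0.8) — and (b)
the reference-level RU strictly exceeds the antigen's cutoff (ties at the
cutoff are negative).  Panel positivity is the any-positive OR rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from serodx.cohort import AntigenMeasurement, Cohort, CohortValidationError, PanelDefinition

DEFAULT_DOSE_RESPONSE_THRESHOLD = 0.8


@dataclass(frozen=True)
class AntigenCall:
    positive: bool
    ru_reference: float
    dose_response_ok: bool


@dataclass(frozen=True)
class CallResult:
    """One subject's per-antigen calls and panel outcome (OR rule)."""

    subject_id: str
    per_antigen: Mapping[str, AntigenCall]
    panel_positive: bool


def spearman_rows(ru: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Row-wise Spearman correlation of RU against coat level.

    ``ru`` is (n_series, k); ``levels`` is (k,).  Average ranks under ties;
    rows with zero RU variance get correlation 0 (a flat series carries no
    dose-response evidence).
    """
    ranks = sps.rankdata(ru, axis=1)
    level_ranks = sps.rankdata(levels)
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    lc = level_ranks - level_ranks.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (lc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rc @ lc) / denom
    return np.where(denom > 0, rho, 0.0)


def dose_response_ok(
    titration: Sequence[tuple[int, float]] | AntigenMeasurement,
    threshold: float = DEFAULT_DOSE_RESPONSE_THRESHOLD,
) -> bool:
    """True iff Spearman(RU, coat level) >= threshold over the series."""
    if isinstance(titration, AntigenMeasurement):
        titration = titration.titration
    if len(titration) < 3:
        raise CohortValidationError("dose-response check needs at least 3 titration points")
    levels = np.array([level for level, _ in titration], dtype=float)
    ru = np.array([[ru for _, ru in titration]], dtype=float)
    return bool(spearman_rows(ru, levels)[0] >= threshold)


def call_antigen(
    measurement: AntigenMeasurement,
    cutoff: float,
    dose_response_required: bool = True,
    dose_threshold: float = DEFAULT_DOSE_RESPONSE_THRESHOLD,
) -> AntigenCall:
    """Call one antigen: strict cutoff exceedance, gated on dose response."""
    dr_ok = dose_response_ok(measurement, dose_threshold)
    positive = measurement.ru_reference > cutoff and (dr_ok or not dose_response_required)
    return AntigenCall(positive=positive, ru_reference=measurement.ru_reference, dose_response_ok=dr_ok)


def _panel_matrices(
    cohort: Cohort, antigens: Sequence[str], dose_threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """(ru_reference, dose_response_ok) arrays of shape (n_subjects, n_antigens)."""
    sids = cohort.subject_ids()
    ru_ref = np.empty((len(sids), len(antigens)))
    dr_ok = np.empty((len(sids), len(antigens)), dtype=bool)
    # Series grouped by length so each group ranks in one vectorized pass.
    by_length: dict[int, tuple[list[tuple[int, int]], list[np.ndarray], list[np.ndarray]]] = {}
    for i, sid in enumerate(sids):
        for j, antigen in enumerate(antigens):
            m = cohort.measurement(sid, antigen)
            if len(m.titration) < 3:
                raise CohortValidationError(
                    f"{sid}/{antigen}: dose-response check needs at least 3 titration points"
                )
            ru_ref[i, j] = m.ru_reference
            positions, rows, level_rows = by_length.setdefault(len(m.titration), ([], [], []))
            positions.append((i, j))
            rows.append(np.fromiter((ru for _, ru in m.titration), dtype=float))
            level_rows.append(np.fromiter((level for level, _ in m.titration), dtype=float))
    for positions, rows, level_rows in by_length.values():
        stacked = np.vstack(rows)
        levels = np.vstack(level_rows)
        if np.ptp(levels, axis=0).max() == 0:
            rho = spearman_rows(stacked, levels[0])
        else:  # heterogeneous coat-level sets of equal length
            rho = np.array(
                [spearman_rows(row[None, :], lv)[0] for row, lv in zip(stacked, levels)]
            )
        ok = rho >= dose_threshold
        for (i, j), flag in zip(positions, ok):
            dr_ok[i, j] = bool(flag)
    return ru_ref, dr_ok


def call_panel(
    cohort: Cohort,
    panel: PanelDefinition,
    dose_threshold: float = DEFAULT_DOSE_RESPONSE_THRESHOLD,
) -> list[CallResult]:
    """Call every subject against the panel; OR rule across antigens."""
    antigens = panel.antigens
    ru_ref, dr_ok = _panel_matrices(cohort, antigens, dose_threshold)
    cutoffs = np.array([panel.cutoffs[a] for a in antigens])
    above = ru_ref > cutoffs
    positive = above & dr_ok if panel.dose_response_required else above
    results = []
    for i, sid in enumerate(cohort.subject_ids()):
        per_antigen = {
            antigen: AntigenCall(
                positive=bool(positive[i, j]),
                ru_reference=float(ru_ref[i, j]),
                dose_response_ok=bool(dr_ok[i, j]),
            )
            for j, antigen in enumerate(antigens)
        }
        results.append(
            CallResult(subject_id=sid, per_antigen=per_antigen, panel_positive=bool(positive[i].any()))
        )
    return results


def concordance(calls_a: Sequence[CallResult], calls_b: Sequence[CallResult]) -> float:
    """Percent of subjects with the same panel outcome in two call sets."""
    a = {c.subject_id: c.panel_positive for c in calls_a}
    b = {c.subject_id: c.panel_positive for c in calls_b}
    if set(a) != set(b):
        raise CohortValidationError("concordance requires identical subject sets")
    if not a:
        raise CohortValidationError("concordance undefined on an empty subject set")
    agree = sum(1 for sid in a if a[sid] == b[sid])
    return 100.0 * agree / len(a)
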