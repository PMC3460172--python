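"""Monte-Carlo direct search over per-antigen RU cutoff sets.

The search draws a fixed number of candidate cutoff vectors (default
10,000) uniformly, with replacement and independently per antigen, from
per-antigen grids anchored to percentiles of the control RU distribution.
Each candidate is scored by the any-positive panel rule; among candidates
whose constrained metric (specificity or sensitivity, optionally
occult-adjusted) lands within a tolerance band of the target, the one
maximizing the free metric wins.  Ties break deterministically: better
constrained metric, then lexicographically smallest cutoff vector.

The occult adjustment deflates observed false positives by the expected
number of undiagnosed cancers among controls, estimated from per-subject
absolute risks: E = sum(risk_i), adjusted FP = max(0, FP - sensitivity*E),
adjusted specificity = 100*(1 - adjusted FP / (N - E)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from serodx.calling import DEFAULT_DOSE_RESPONSE_THRESHOLD, CallResult, _panel_matrices, call_panel
from serodx.cohort import Cohort, CohortValidationError, PanelDefinition, SubjectRecord
from serodx.risk import RiskModelConfig, absolute_risk
from serodx.stats import OperatingPoint, operating_point


class SearchError(ValueError):
    pass


@dataclass(frozen=True)
class SearchConfig:
    """Parameters of the Monte-Carlo cutoff search.

    ``mode`` fixes one metric ("fix_specificity" or "fix_sensitivity") at
    ``target`` percent within ``tolerance`` percentage points while the
    other is maximized.  ``candidate_grid`` maps antigen to an ordered set
    of admissible cutoffs; antigens without an entry get the default grid:
    the empirical 80th-99.9th percentiles of control reference RU at
    0.1-percentile steps.  When ``adjust_occult`` the constrained/reported
    specificity is occult-adjusted using ``risk_config``.
    """

    mode: str
    target: float
    tolerance: float = 0.5
    n_candidates: int = 10_000
    candidate_grid: Mapping[str, Sequence[float]] = field(default_factory=dict)
    seed: int = 0
    adjust_occult: bool = False
    risk_config: RiskModelConfig | None = None
    dose_response_required: bool = True
    dose_threshold: float = DEFAULT_DOSE_RESPONSE_THRESHOLD
    audit_top_k: int = 10

    def __post_init__(self) -> None:
        if self.mode not in ("fix_specificity", "fix_sensitivity"):
            raise SearchError(f"unknown search mode {self.mode!r}")
        if not 0.0 < self.target < 100.0:
            raise SearchError("target must be in (0, 100) percent")
        if self.tolerance <= 0:
            raise SearchError("tolerance must be > 0")
        if self.n_candidates < 1:
            raise SearchError("n_candidates must be >= 1")
        if self.adjust_occult and self.risk_config is None:
            raise SearchError("adjust_occult requires a risk_config")
        grids = {}
        for antigen, grid in dict(self.candidate_grid).items():
            arr = np.asarray(grid, dtype=float)
            if arr.size == 0:
                raise SearchError(f"empty candidate grid for {antigen}")
            if np.any(np.diff(arr) < 0):
                raise SearchError(f"candidate grid for {antigen} must be sorted")
            grids[antigen] = arr
        object.__setattr__(self, "candidate_grid", grids)


@dataclass(frozen=True)
class SearchResult:
    best_cutoffs: dict[str, float]
    achieved: OperatingPoint
    n_feasible: int
    seed: int
    audit_log: tuple[dict, ...]


def label_truth(cohort: Cohort) -> dict[str, bool]:
    """Diseased-vs-not according to the cohort's recorded labels."""
    return {
        s.subject_id: (s.cohort == "cancer" or s.cancer_status == "confirmed")
        for s in cohort.subjects
    }


def adjusted_specificity(
    control_calls: Sequence[CallResult], risks: Sequence[float], sensitivity: float
) -> float:
    """Occult-adjusted specificity, percent.

    ``control_calls`` are panel calls for the nominal controls; ``risks``
    their absolute cancer risks in [0, 1]; ``sensitivity`` the panel's
    sensitivity as a fraction.  Expected occult cancers E = sum(risks) are
    assumed to test positive at the panel's sensitivity; those expected
    positives are removed from the false positives and E from the control
    denominator.
    """
    if len(control_calls) != len(risks):
        raise SearchError("one risk per control call required")
    if any(not 0.0 <= r <= 1.0 for r in risks):
        raise SearchError("risks must be in [0, 1]")
    if not 0.0 <= sensitivity <= 1.0:
        raise SearchError("sensitivity must be a fraction in [0, 1]")
    n = len(control_calls)
    expected_occult = float(sum(risks))
    if expected_occult >= n:
        raise SearchError("expected occult cancers exceed the control population")
    fp = sum(c.panel_positive for c in control_calls)
    adjusted_fp = max(0.0, fp - sensitivity * expected_occult)
    return 100.0 * (1.0 - adjusted_fp / (n - expected_occult))


def _control_risks(controls: Sequence[SubjectRecord], risk_config: RiskModelConfig) -> np.ndarray:
    """Per-control risks; unknown-smoking subjects get the evaluable mean."""
    evaluable = [absolute_risk(s, risk_config) for s in controls if s.smoking != "unknown"]
    if not evaluable:
        raise SearchError("no control subject has known smoking status; cannot adjust for occult cancers")
    mean_risk = float(np.mean(evaluable))
    return np.array(
        [absolute_risk(s, risk_config) if s.smoking != "unknown" else mean_risk for s in controls]
    )


def default_candidate_grid(control_ru: np.ndarray) -> np.ndarray:
    """80th-99.9th percentile grid of control RU at 0.1-percentile steps."""
    quantiles = np.arange(80.0, 100.0, 0.1)
    return np.percentile(control_ru, quantiles)


def _adjusted_spec_vector(fp: np.ndarray, sens: np.ndarray, n_controls: int, e_occult: float) -> np.ndarray:
    adj_fp = np.maximum(0.0, fp - (sens / 100.0) * e_occult)
    return 100.0 * (1.0 - adj_fp / (n_controls - e_occult))


def mc_search(cohort: Cohort, panel_antigens: Sequence[str], config: SearchConfig) -> SearchResult:
    """Monte-Carlo direct search for the best per-antigen cutoff set.

    Deterministic given the seed; the achieved operating point is
    recomputed from the winning cutoffs through the ordinary panel-calling
    path, so it is bit-identical to what evaluation of the returned panel
    would give.
    """
    antigens = tuple(panel_antigens)
    truth = label_truth(cohort)
    is_cancer = np.array([truth[sid] for sid in cohort.subject_ids()])
    if not is_cancer.any() or is_cancer.all():
        raise SearchError("search cohort must contain both cancer and control subjects")

    ru_ref, dr_ok = _panel_matrices(cohort, antigens, config.dose_threshold)
    # A measurement without dose response can never be positive: encode its
    # RU as -inf so every candidate cutoff excludes it.
    scored = np.where(dr_ok, ru_ref, -np.inf) if config.dose_response_required else ru_ref

    control_ru = ru_ref[~is_cancer, :]
    grids = [
        np.asarray(config.candidate_grid[a], dtype=float)
        if a in config.candidate_grid
        else default_candidate_grid(control_ru[:, j])
        for j, a in enumerate(antigens)
    ]

    e_occult = 0.0
    if config.adjust_occult:
        controls = [s for s in cohort.subjects if not truth[s.subject_id]]
        e_occult = float(_control_risks(controls, config.risk_config).sum())
        if e_occult >= len(controls):
            raise SearchError("expected occult cancers exceed the control population")

    rng = np.random.default_rng(config.seed)
    cut_idx = np.column_stack(
        [rng.integers(0, len(grid), size=config.n_candidates) for grid in grids]
    )
    cutoffs = np.column_stack([grid[cut_idx[:, j]] for j, grid in enumerate(grids)])

    n_cancer = int(is_cancer.sum())
    n_controls = int((~is_cancer).sum())
    cancer_ru = scored[is_cancer, :]
    ctrl_ru = scored[~is_cancer, :]

    sens = np.empty(config.n_candidates)
    fp = np.empty(config.n_candidates)
    chunk = max(1, int(2e7 // max(1, scored.shape[0] * len(antigens))))
    for start in range(0, config.n_candidates, chunk):
        sl = slice(start, min(start + chunk, config.n_candidates))
        c = cutoffs[sl][:, None, :]
        sens[sl] = 100.0 * (cancer_ru[None, :, :] > c).any(axis=2).sum(axis=1) / n_cancer
        fp[sl] = (ctrl_ru[None, :, :] > c).any(axis=2).sum(axis=1)
    spec_raw = 100.0 * (1.0 - fp / n_controls)
    spec = _adjusted_spec_vector(fp, sens, n_controls, e_occult) if config.adjust_occult else spec_raw

    constrained = spec if config.mode == "fix_specificity" else sens
    free = sens if config.mode == "fix_specificity" else spec
    feasible = np.abs(constrained - config.target) <= config.tolerance
    n_feasible = int(feasible.sum())
    if n_feasible == 0:
        nearest = int(np.argmin(np.abs(constrained - config.target)))
        raise SearchError(
            f"no candidate met {config.mode} target {config.target}+/-{config.tolerance}; "
            f"nearest miss: constrained={constrained[nearest]:.2f} at cutoffs "
            f"{dict(zip(antigens, np.round(cutoffs[nearest], 4)))}"
        )

    feasible_idx = np.flatnonzero(feasible)
    best_free = free[feasible_idx].max()
    tied = feasible_idx[free[feasible_idx] == best_free]
    best_constrained = constrained[tied].max()
    tied = tied[constrained[tied] == best_constrained]
    # Lexicographically smallest cutoff vector among remaining ties.
    order = np.lexsort(tuple(cutoffs[tied, j] for j in reversed(range(len(antigens)))))
    winner = int(tied[order[0]])

    best_cutoffs = {a: float(cutoffs[winner, j]) for j, a in enumerate(antigens)}
    panel = PanelDefinition(
        name=f"mc-search-{config.mode}",
        antigens=antigens,
        cutoffs=best_cutoffs,
        dose_response_required=config.dose_response_required,
    )
    achieved = validate_cutoffs(
        cohort,
        panel,
        adjust_occult=config.adjust_occult,
        risk_config=config.risk_config,
        dose_threshold=config.dose_threshold,
    )

    top = np.argsort(-free[feasible_idx], kind="stable")[: config.audit_top_k]
    audit = tuple(
        {
            "cutoffs": {a: float(cutoffs[i, j]) for j, a in enumerate(antigens)},
            "sensitivity": float(sens[i]),
            "specificity": float(spec_raw[i]),
            **({"adjusted_specificity": float(spec[i])} if config.adjust_occult else {}),
        }
        for i in feasible_idx[top]
    )
    return SearchResult(
        best_cutoffs=best_cutoffs,
        achieved=achieved,
        n_feasible=n_feasible,
        seed=config.seed,
        audit_log=audit,
    )


def validate_cutoffs(
    cohort: Cohort,
    panel: PanelDefinition,
    adjust_occult: bool = False,
    risk_config: RiskModelConfig | None = None,
    dose_threshold: float = DEFAULT_DOSE_RESPONSE_THRESHOLD,
    search_subject_ids: Sequence[str] | None = None,
) -> OperatingPoint:
    """Evaluate a fixed panel on a cohort: sensitivity/specificity with CIs.

    Held-out evaluation is the caller's responsibility; when the search
    cohort's subject ids are passed, any overlap with the evaluation cohort
    is reported as a warning.
    """
    if search_subject_ids is not None:
        overlap = set(search_subject_ids) & set(cohort.subject_ids())
        if overlap:
            warnings.warn(
                f"{len(overlap)} subjects overlap between search and validation cohorts",
                stacklevel=2,
            )
    truth = label_truth(cohort)
    calls = call_panel(cohort, panel, dose_threshold=dose_threshold)
    point = operating_point(calls, truth)
    if adjust_occult:
        if risk_config is None:
            raise SearchError("adjust_occult requires a risk_config")
        controls = [s for s in cohort.subjects if not truth[s.subject_id]]
        control_calls = [c for c in calls if not truth[c.subject_id]]
        risks = _control_risks(controls, risk_config)
        adjusted = adjusted_specificity(control_calls, risks.tolist(), point.sensitivity / 100.0)
        point = OperatingPoint(
            tp=point.tp, fn=point.fn, fp=point.fp, tn=point.tn, adjusted_specificity=adjusted
        )
    return point
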