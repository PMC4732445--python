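"""Diagnostic evaluation of an index against known 7-day outcomes.

Implements the full test-evaluation toolkit used to refine and assess the
mortality-prediction indices: ROC curves and AUC, AUC confidence intervals
(DeLong, Hanley-McNeil, stratified bootstrap), cutoff metric tables
(sensitivity, specificity, predictive values, likelihood ratios), optimal
cut-off selection, per-analyte AUC screening, and prevalence-adjusted
predictive values.

Orientation is fixed throughout: the positive class is death within 7 days,
and a test-positive animal is one whose score is **greater than or equal to**
the cut-off.  Percentages are carried as exact floating fractions internally
and rounded only for presentation (:func:`format_cutoff_row`).

The AUC is computed by the trapezoidal rule over the empirical ROC curve,
which is identical to the Mann-Whitney pair statistic with ties counted 1/2:
the probability that a random non-survivor outscores a random survivor.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import CohortError, ConfigurationError
from .panels import BloodPanel
from .scoring import BandTableSet, IndexDefinition, default_band_tables, get_index, score_analyte, score_index

AUC_RETENTION_THRESHOLD = 0.7


@dataclass(frozen=True)
class ScoredCohort:
    """Paired (score, outcome) data for one index over a cohort.

    ``outcomes`` is 1 for animals that died within 7 days, 0 for survivors.
    """

    scores: np.ndarray
    outcomes: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        outcomes = np.asarray(self.outcomes)
        if scores.shape != outcomes.shape or scores.ndim != 1:
            raise CohortError("scores and outcomes must be 1-d arrays of equal length")
        if not np.isin(outcomes, (0, 1)).all():
            raise CohortError("outcomes must be strictly binary (0 survived / 1 died)")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "outcomes", outcomes.astype(int))

    @property
    def n_pos(self) -> int:
        return int(self.outcomes.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self.outcomes) - self.outcomes.sum())

    @property
    def pos_scores(self) -> np.ndarray:
        return self.scores[self.outcomes == 1]

    @property
    def neg_scores(self) -> np.ndarray:
        return self.scores[self.outcomes == 0]

    def require_both_classes(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise CohortError(
                f"need at least one animal in each outcome class, got "
                f"{self.n_pos} died / {self.n_neg} survived"
            )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, int]]) -> "ScoredCohort":
        pairs = list(pairs)
        return cls(
            np.array([s for s, _ in pairs], dtype=float),
            np.array([o for _, o in pairs], dtype=int),
        )

    @classmethod
    def from_panels(
        cls,
        panels: Sequence[BloodPanel],
        index: IndexDefinition | str,
        tables: Optional[BandTableSet] = None,
    ) -> "ScoredCohort":
        """Score every panel with ``index``; panels need known outcomes."""
        if isinstance(index, str):
            index = get_index(index)
        missing = [p.animal_id for p in panels if p.outcome is None]
        if missing:
            raise CohortError(
                f"{len(missing)} panel(s) lack a 7-day outcome "
                f"(first: {missing[0]!r}); diagnostics need known outcomes"
            )
        scores = [score_index(index, p, tables) for p in panels]
        return cls(np.array(scores, dtype=float), np.array([p.outcome for p in panels]))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer counts at one cut-off (positive class = died within 7 days)."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise CohortError("confusion-matrix counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class CutoffRow:
    """One row of a cutoff metric table (Tables-4-to-6 shape).

    SE/SP/PPV/NPV are percentages in [0, 100]; likelihood ratios are
    unitless, possibly ``inf`` (LR+ with perfect specificity) or ``nan``
    (undefined, e.g. PPV with no test-positives).
    """

    cutoff: float
    se: float
    sp: float
    ppv: float
    npv: float
    lr_plus: float
    lr_minus: float


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve: operating points, trapezoidal AUC, CI if computed."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    ci_method: Optional[str] = None

    def accuracy_category(self) -> str:
        """Conventional qualitative reading of an AUC value."""
        a = self.auc
        if a == 1.0:
            return "perfect"
        if a > 0.9:
            return "highly accurate"
        if a > 0.7:
            return "moderately accurate"
        if a > 0.5:
            return "less accurate"
        return "non-informative"


def confusion_at_cutoff(cohort: ScoredCohort, cutoff: float) -> ConfusionMatrix:
    """Counts with test-positive defined as score >= cutoff."""
    positive = cohort.scores >= cutoff
    died = cohort.outcomes == 1
    return ConfusionMatrix(
        tp=int(np.sum(positive & died)),
        fn=int(np.sum(~positive & died)),
        tn=int(np.sum(~positive & ~died)),
        fp=int(np.sum(positive & ~died)),
    )


def _ratio(num: float, den: float) -> float:
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def test_metrics(cm: ConfusionMatrix, cutoff: float = math.nan) -> CutoffRow:
    """SE/SP/PPV/NPV and likelihood ratios from integer counts.

    SE and SP require a non-empty class each; PPV/NPV are ``nan`` when their
    denominator (test-positives / test-negatives) is zero; LR+ is ``inf``
    when SP = 100% and SE > 0.
    """
    if cm.n_pos == 0 or cm.n_neg == 0:
        raise CohortError("test_metrics needs at least one animal per outcome class")
    se = cm.tp / cm.n_pos
    sp = cm.tn / cm.n_neg
    ppv = math.nan if cm.tp + cm.fp == 0 else cm.tp / (cm.tp + cm.fp)
    npv = math.nan if cm.tn + cm.fn == 0 else cm.tn / (cm.tn + cm.fn)
    return CutoffRow(
        cutoff=cutoff,
        se=100.0 * se,
        sp=100.0 * sp,
        ppv=100.0 * ppv,
        npv=100.0 * npv,
        lr_plus=_ratio(se, 1.0 - sp),
        lr_minus=_ratio(1.0 - se, sp),
    )


def cutoff_table(
    cohort: ScoredCohort, cutoffs: Optional[Sequence[float]] = None
) -> list[CutoffRow]:
    """One metric row per cut-off, ascending.

    Defaults to every integer from the minimum to the maximum observed score.
    As the cut-off rises, SE is non-increasing and SP non-decreasing.
    """
    cohort.require_both_classes()
    if cutoffs is None:
        lo = math.floor(cohort.scores.min())
        hi = math.ceil(cohort.scores.max())
        cutoffs = list(range(lo, hi + 1))
    if len(cutoffs) == 0:
        raise CohortError("cutoff grid must be non-empty")
    return [
        test_metrics(confusion_at_cutoff(cohort, c), cutoff=float(c))
        for c in sorted(cutoffs)
    ]


def roc_curve(cohort: ScoredCohort) -> ROCResult:
    """Empirical ROC curve and trapezoidal AUC.

    Operating points are placed at every distinct observed score (threshold =
    "score >= t") plus the trivial (0,0) and (1,1) endpoints.  The
    trapezoidal area equals the Mann-Whitney statistic with ties counted 1/2.
    A cohort whose scores are all identical yields the degenerate two-point
    diagonal and AUC 0.5.
    """
    cohort.require_both_classes()
    thresholds = np.unique(cohort.scores)[::-1]
    pos = cohort.pos_scores
    neg = cohort.neg_scores
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        tpr.append(float(np.mean(pos >= t)))
        fpr.append(float(np.mean(neg >= t)))
    if tpr[-1] != 1.0 or fpr[-1] != 1.0:
        tpr.append(1.0)
        fpr.append(1.0)
    fpr_arr = np.array(fpr)
    tpr_arr = np.array(tpr)
    auc = float(np.trapezoid(tpr_arr, fpr_arr))
    return ROCResult(
        fpr=fpr_arr,
        tpr=tpr_arr,
        thresholds=np.concatenate(([math.inf], thresholds, [-math.inf]))[: len(fpr_arr)],
        auc=auc,
    )


def auc(cohort: ScoredCohort) -> float:
    """Trapezoidal/Mann-Whitney AUC (rank implementation, ties at 1/2)."""
    cohort.require_both_classes()
    ranks = stats.rankdata(cohort.scores)
    m = cohort.n_pos
    n = cohort.n_neg
    pos_rank_sum = float(ranks[cohort.outcomes == 1].sum())
    return (pos_rank_sum - m * (m + 1) / 2.0) / (m * n)


def _delong_ci(cohort: ScoredCohort, level: float) -> tuple[float, float]:
    pos = cohort.pos_scores[:, None]
    neg = cohort.neg_scores[None, :]
    # placement matrix: P(pos > neg) with ties at 1/2
    psi = (pos > neg).astype(float) + 0.5 * (pos == neg)
    a = float(psi.mean())
    v10 = psi.mean(axis=1)  # per-positive placements
    v01 = psi.mean(axis=0)  # per-negative placements
    m, n = len(v10), len(v01)
    var = 0.0
    if m > 1:
        var += float(np.var(v10, ddof=1)) / m
    if n > 1:
        var += float(np.var(v01, ddof=1)) / n
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = float(z) * math.sqrt(var)
    return max(0.0, a - half), min(1.0, a + half)


def _hanley_mcneil_ci(cohort: ScoredCohort, level: float) -> tuple[float, float]:
    a = auc(cohort)
    m = cohort.n_pos
    n = cohort.n_neg
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (m - 1) * (q1 - a * a) + (n - 1) * (q2 - a * a)) / (m * n)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = float(z) * math.sqrt(max(var, 0.0))
    return max(0.0, a - half), min(1.0, a + half)


def _bootstrap_ci(
    cohort: ScoredCohort, level: float, seed: Optional[int], n_boot: int
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    pos = cohort.pos_scores
    neg = cohort.neg_scores
    m, n = len(pos), len(neg)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        sample = ScoredCohort(
            np.concatenate(
                [rng.choice(pos, size=m, replace=True), rng.choice(neg, size=n, replace=True)]
            ),
            np.concatenate([np.ones(m, dtype=int), np.zeros(n, dtype=int)]),
        )
        aucs[b] = auc(sample)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


AUC_CI_METHODS = ("delong", "hanley-mcneil", "bootstrap")


def auc_ci(
    cohort: ScoredCohort,
    method: str = "delong",
    level: float = 0.95,
    seed: Optional[int] = None,
    n_boot: int = 2000,
) -> tuple[float, float]:
    """Two-sided AUC confidence interval.

    ``delong`` (default) uses the asymptotic placement-variance estimator;
    ``hanley-mcneil`` the classic binormal-free approximation; ``bootstrap``
    a stratified percentile bootstrap (reproducible under a fixed seed).
    Both outcome classes must have at least two members.
    """
    cohort.require_both_classes()
    if cohort.n_pos < 2 or cohort.n_neg < 2:
        raise CohortError("AUC confidence intervals need >= 2 animals per class")
    if not (0.0 < level < 1.0):
        raise CohortError(f"confidence level must be in (0, 1), got {level}")
    if method == "delong":
        return _delong_ci(cohort, level)
    if method == "hanley-mcneil":
        return _hanley_mcneil_ci(cohort, level)
    if method == "bootstrap":
        return _bootstrap_ci(cohort, level, seed, n_boot)
    raise ConfigurationError(
        f"unsupported AUC CI method {method!r}; expected one of {AUC_CI_METHODS}"
    )


def roc_with_ci(
    cohort: ScoredCohort,
    method: str = "delong",
    level: float = 0.95,
    seed: Optional[int] = None,
) -> ROCResult:
    base = roc_curve(cohort)
    lo, hi = auc_ci(cohort, method=method, level=level, seed=seed)
    return ROCResult(
        fpr=base.fpr,
        tpr=base.tpr,
        thresholds=base.thresholds,
        auc=base.auc,
        ci_low=lo,
        ci_high=hi,
        ci_method=method,
    )


def youden_j(row: CutoffRow) -> float:
    """Youden's J on the percentage scale: SE + SP - 100."""
    return row.se + row.sp - 100.0


def optimal_cutoff(rows: Sequence[CutoffRow], criterion: str = "youden") -> float:
    """Cut-off where sensitivity and specificity are jointly optimised.

    ``youden`` maximises J = SE + SP - 100; ``closest-topleft`` minimises the
    Euclidean distance to the perfect-test corner (0, 1) in ROC space.  Ties
    break toward the lower cut-off (favouring sensitivity).
    """
    if not rows:
        raise CohortError("optimal_cutoff needs at least one row")
    ordered = sorted(rows, key=lambda r: r.cutoff)
    if criterion == "youden":
        best = max(ordered, key=lambda r: (youden_j(r), -r.cutoff))
    elif criterion == "closest-topleft":
        best = min(
            ordered,
            key=lambda r: ((1 - r.se / 100.0) ** 2 + (1 - r.sp / 100.0) ** 2, r.cutoff),
        )
    else:
        raise ConfigurationError(
            f"unknown criterion {criterion!r}; expected 'youden' or 'closest-topleft'"
        )
    return best.cutoff


def analyte_retention(auc_value: float, threshold: float = AUC_RETENTION_THRESHOLD) -> bool:
    """Keep an analyte in a refined index iff its standalone AUC >= threshold."""
    return auc_value >= threshold


def per_analyte_auc(
    panels: Sequence[BloodPanel],
    table_id: str,
    analytes: Optional[Sequence[str]] = None,
    tables: Optional[BandTableSet] = None,
) -> dict[str, float]:
    """Standalone discrimination of each analyte's banded points.

    Scores every panel on one analyte at a time (its points from the given
    table) and computes the AUC of those single-analyte scores against the
    7-day outcome.  This is the screening step behind the refined indices.
    """
    tables = tables or default_band_tables()
    table = tables[table_id]
    names = tuple(analytes) if analytes is not None else table.analytes
    out: dict[str, float] = {}
    for analyte in names:
        pairs = [
            (float(score_analyte(table, analyte, p.get(analyte))), p.outcome)
            for p in panels
            if p.get(analyte) is not None and p.outcome is not None
        ]
        out[analyte] = auc(ScoredCohort.from_pairs(pairs))
    return out


def refine_index(
    panels: Sequence[BloodPanel],
    table_id: str,
    threshold: float = AUC_RETENTION_THRESHOLD,
    tables: Optional[BandTableSet] = None,
) -> dict[str, bool]:
    """Retention flags for every analyte of a table (AUC >= threshold)."""
    return {
        a: analyte_retention(v, threshold)
        for a, v in per_analyte_auc(panels, table_id, tables=tables).items()
    }


def predictive_values_at_prevalence(
    se: float, sp: float, prevalence: float
) -> tuple[float, float]:
    """Bayes' rule PPV/NPV (as fractions) at an assumed mortality proportion.

    PPV = SE*p / (SE*p + (1-SP)(1-p)); NPV = SP(1-p) / (SP(1-p) + (1-SE)p).
    PPV rises and NPV falls monotonically with prevalence.  An undefined
    value (zero denominator) is returned as ``nan``.
    """
    for label, v in (("se", se), ("sp", sp), ("prevalence", prevalence)):
        if not (0.0 <= v <= 1.0):
            raise CohortError(f"{label} must be a fraction in [0, 1], got {v}")
    ppv_den = se * prevalence + (1.0 - sp) * (1.0 - prevalence)
    npv_den = sp * (1.0 - prevalence) + (1.0 - se) * prevalence
    ppv = math.nan if ppv_den == 0 else se * prevalence / ppv_den
    npv = math.nan if npv_den == 0 else sp * (1.0 - prevalence) / npv_den
    return ppv, npv


def prevalence_curve(
    se: float, sp: float, p_min: float = 0.10, p_max: float = 0.40, step: float = 0.01
) -> list[tuple[float, float, float]]:
    """(prevalence, PPV, NPV) rows over a mortality-proportion sweep."""
    if step <= 0 or p_max < p_min:
        raise CohortError("need step > 0 and p_max >= p_min")
    n = int(round((p_max - p_min) / step))
    out = []
    for i in range(n + 1):
        p = min(p_min + i * step, p_max)
        ppv, npv = predictive_values_at_prevalence(se, sp, p)
        out.append((p, ppv, npv))
    return out


# -- reconstruction of printed rows and presentation rounding ---------------


def _round_half_up(x: float, digits: int) -> float:
    if not math.isfinite(x):
        return x
    q = Decimal("1." + "0" * digits) if digits else Decimal("1")
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def counts_from_rates(
    se_pct: float, sp_pct: float, n_pos: int, n_neg: int
) -> ConfusionMatrix:
    """Recover integer TP/FN/TN/FP from rounded SE/SP and the class sizes.

    Inverts the presentation rounding: TP is the integer nearest
    ``SE * n_pos / 100`` (half away from zero), likewise TN from SP.  With
    class sizes of 25 and 118 the published two-decimal rates identify the
    counts uniquely.
    """
    tp = math.floor(se_pct * n_pos / 100.0 + 0.5)
    tn = math.floor(sp_pct * n_neg / 100.0 + 0.5)
    return ConfusionMatrix(tp=tp, fn=n_pos - tp, tn=tn, fp=n_neg - tn)


def format_cutoff_row(row: CutoffRow) -> dict[str, str]:
    """Presentation rounding: SE/SP to 2 dp; PPV/NPV to 1 dp shown with a
    trailing zero; likelihood ratios to 2 dp."""

    def fmt(x: float, digits: int, pad_to: int) -> str:
        if math.isnan(x):
            return "undefined"
        if math.isinf(x):
            return "inf"
        return f"{_round_half_up(x, digits):.{pad_to}f}"

    return {
        "cutoff": f"{row.cutoff:g}",
        "se": fmt(row.se, 2, 2),
        "sp": fmt(row.sp, 2, 2),
        "ppv": fmt(row.ppv, 1, 2),
        "npv": fmt(row.npv, 1, 2),
        "lr_plus": fmt(row.lr_plus, 2, 2),
        "lr_minus": fmt(row.lr_minus, 2, 2),
    }


def load_reference_performance(path: str | Path | None = None) -> dict:
    """Published cutoff-performance rows for MPI4/5/6.

    The development cohort itself was never published, but its class sizes
    (25 died / 118 survived of 143 enrolled) and per-cutoff SE/SP/PPV/NPV/LR
    rows were; they are shipped as a data resource because the reconstruction
    and cut-off-recovery checks take them as *inputs*.
    """
    if path is None:
        text = (
            resources.files("coldstun_mpi.data")
            .joinpath("reference_performance.json")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    return json.loads(text)
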