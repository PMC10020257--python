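"""Model validation statistics for case-control risk-score data.

Implements the standard battery used to compare risk prediction models:

* odds ratio per control-standard-deviation of score (univariable logistic),
* AUC with a DeLong variance, and the DeLong test for the difference of two
  correlated AUCs via placement values,
* expected/observed calibration against population incidence, using the
  per-age-band median score (risk-score distributions are strongly
  right-skewed, so the mean would overstate expected counts),
* clinical risk categorization, reclassification tables, and the
  categorical net reclassification improvement (NRI) with the
  Pencina-Steyerberg standard error.
"""

from __future__ import annotations

import bisect
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import InputError, UndefinedStatisticError

__all__ = [
    "ScoredSubject",
    "CategoryScheme",
    "FIVE_YEAR_SCHEME",
    "LIFETIME_SCHEME",
    "ReclassificationTable",
    "NriResult",
    "ArmImprovement",
    "AucResult",
    "DelongResult",
    "OrPerSdResult",
    "CalibrationResult",
    "DEFAULT_AGE_BANDS",
    "categorize",
    "build_reclass_table",
    "nri",
    "arm_improvement",
    "auc",
    "delong_compare",
    "or_per_sd",
    "calibration_eo",
    "proportion_above",
    "assign_age_band",
]


# ---------------------------------------------------------------------------
# Subjects and category schemes
# ---------------------------------------------------------------------------


@dataclass
class ScoredSubject:
    """One woman with case status and one or more named risk scores."""

    id: str
    is_case: bool
    age: float
    scores: dict[str, float] = field(default_factory=dict)
    subgroups: dict[str, str] = field(default_factory=dict)

    def score(self, name: str) -> float:
        try:
            return self.scores[name]
        except KeyError:
            raise InputError(f"subject {self.id}: missing score {name!r}") from None


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered risk categories with left-closed, right-open intervals.

    ``edges`` are the interior cut points (strictly increasing probabilities);
    a risk equal to an edge belongs to the upper interval.
    """

    edges: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.edges) + 1:
            raise InputError("need exactly one more label than edges")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise InputError("category edges must be strictly increasing")

    @property
    def n_categories(self) -> int:
        return len(self.labels)

    def edge_index(self, threshold: float) -> int:
        """Category index whose lower edge equals ``threshold``."""
        for i, e in enumerate(self.edges):
            if math.isclose(e, threshold, rel_tol=0, abs_tol=1e-12):
                return i + 1
        raise InputError(
            f"threshold {threshold} is not a category edge of {self.edges}"
        )


#: 5-year risk categories around the chemoprevention thresholds
#: (1.67% NCCN, 3% USPSTF).
FIVE_YEAR_SCHEME = CategoryScheme(
    edges=(0.01, 0.0167, 0.03),
    labels=("< 1%", ">= 1 to < 1.67%", ">= 1.67 to < 3%", ">= 3%"),
)

#: Remaining-lifetime risk categories around the enhanced-screening
#: thresholds (20% US, 25% elsewhere).
LIFETIME_SCHEME = CategoryScheme(
    edges=(0.06, 0.12, 0.20, 0.25),
    labels=("< 6%", ">= 6 to < 12%", ">= 12 to < 20%", ">= 20 to < 25%", ">= 25%"),
)


def categorize(risk: float, scheme: CategoryScheme) -> int:
    """0-based index of the category containing ``risk`` (left-closed)."""
    if not 0.0 <= risk <= 1.0:
        raise InputError(f"risk {risk} outside [0, 1]")
    return bisect.bisect_right(scheme.edges, risk)


# ---------------------------------------------------------------------------
# Reclassification and NRI
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReclassificationTable:
    """K x K cross-classification counts (rows: old model, columns: new),
    tabulated separately for cases and controls."""

    cases: np.ndarray
    controls: np.ndarray
    scheme: CategoryScheme
    old_model: str = "old"
    new_model: str = "new"

    def __post_init__(self) -> None:
        k = self.scheme.n_categories
        for name, m in (("cases", self.cases), ("controls", self.controls)):
            if m.shape != (k, k):
                raise InputError(f"{name} matrix shape {m.shape} != ({k}, {k})")
            if (m < 0).any() or not np.issubdtype(m.dtype, np.integer):
                raise InputError(f"{name} matrix must hold non-negative integers")

    @property
    def n_cases(self) -> int:
        return int(self.cases.sum())

    @property
    def n_controls(self) -> int:
        return int(self.controls.sum())


def build_reclass_table(
    subjects: Sequence[ScoredSubject],
    old_model: str,
    new_model: str,
    scheme: CategoryScheme,
    drop_missing: bool = False,
) -> ReclassificationTable:
    """Cross-classify subjects by their old- and new-model risk categories.

    Subjects missing either score raise; with ``drop_missing`` they are
    excluded instead (the pairwise-complete convention used when one model
    is only available on a subset).
    """
    k = scheme.n_categories
    cases = np.zeros((k, k), dtype=np.int64)
    controls = np.zeros((k, k), dtype=np.int64)
    for s in subjects:
        if drop_missing and (old_model not in s.scores or new_model not in s.scores):
            continue
        i = categorize(s.score(old_model), scheme)
        j = categorize(s.score(new_model), scheme)
        (cases if s.is_case else controls)[i, j] += 1
    return ReclassificationTable(cases, controls, scheme, old_model, new_model)


@dataclass(frozen=True)
class ArmImprovement:
    """Net reclassification within one arm: (up - down) / n, with the
    Pencina-Steyerberg standard error."""

    improvement: float
    se: float
    n_up: int
    n_down: int
    n: int


def arm_improvement(matrix: np.ndarray) -> ArmImprovement:
    """Up/down mover tally for one arm's K x K count matrix."""
    n = int(matrix.sum())
    if n == 0:
        raise UndefinedStatisticError("empty arm: NRI undefined")
    up = int(np.triu(matrix, k=1).sum())
    down = int(np.tril(matrix, k=-1).sum())
    p_up = up / n
    p_down = down / n
    net = p_up - p_down
    se = math.sqrt((p_up + p_down - net**2) / n)
    return ArmImprovement(improvement=net, se=se, n_up=up, n_down=down, n=n)


@dataclass(frozen=True)
class NriResult:
    case_improvement: float
    control_improvement: float
    overall: float
    se_case: float
    se_control: float
    se_overall: float
    cases: ArmImprovement
    controls: ArmImprovement


def nri(table: ReclassificationTable) -> NriResult:
    """Categorical net reclassification improvement.

    Cases are credited for moving up, controls for moving down; the overall
    NRI is the sum of the two arm improvements and its standard error the
    root-sum-square of the independent arm standard errors.
    """
    case_arm = arm_improvement(table.cases)
    ctrl_arm = arm_improvement(table.controls)
    control_improvement = -ctrl_arm.improvement
    return NriResult(
        case_improvement=case_arm.improvement,
        control_improvement=control_improvement,
        overall=case_arm.improvement + control_improvement,
        se_case=case_arm.se,
        se_control=ctrl_arm.se,
        se_overall=math.hypot(case_arm.se, ctrl_arm.se),
        cases=case_arm,
        controls=ctrl_arm,
    )


def proportion_above(
    table: ReclassificationTable,
    threshold: float,
    arm: str = "case",
    model: str = "new",
) -> float:
    """Fraction of one arm at or above the category whose lower edge is
    ``threshold``, under the old (rows) or new (columns) model."""
    k = table.scheme.edge_index(threshold)
    m = table.cases if arm == "case" else table.controls
    total = m.sum()
    if total == 0:
        raise UndefinedStatisticError(f"empty {arm} arm")
    hits = m[:, k:].sum() if model == "new" else m[k:, :].sum()
    return float(hits / total)


# ---------------------------------------------------------------------------
# AUC and the DeLong machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AucResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int


def _placements(case_scores: np.ndarray, control_scores: np.ndarray):
    """Mann-Whitney placement values with midrank tie handling.

    Returns (auc, V10, V01): V10[i] is the fraction of controls below case i
    (ties half), V01[j] the fraction of cases above control j.
    """
    m = len(case_scores)
    n = len(control_scores)
    combined = np.concatenate([case_scores, control_scores])
    ranks = stats.rankdata(combined)  # midranks
    case_ranks = ranks[:m]
    control_ranks = ranks[m:]
    ranks_within_cases = stats.rankdata(case_scores)
    ranks_within_controls = stats.rankdata(control_scores)
    v10 = (case_ranks - ranks_within_cases) / n
    v01 = 1.0 - (control_ranks - ranks_within_controls) / m
    return float(v10.mean()), v10, v01


def auc(
    case_scores: Sequence[float], control_scores: Sequence[float], alpha: float = 0.05
) -> AucResult:
    """Mann-Whitney AUC (ties at half credit) with a DeLong Wald CI."""
    x = np.asarray(case_scores, dtype=float)
    y = np.asarray(control_scores, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise UndefinedStatisticError("AUC needs at least one case and one control")
    a, v10, v01 = _placements(x, y)
    var = 0.0
    if len(x) > 1:
        var += v10.var(ddof=1) / len(x)
    if len(y) > 1:
        var += v01.var(ddof=1) / len(y)
    se = math.sqrt(var)
    z = stats.norm.ppf(1 - alpha / 2)
    return AucResult(
        auc=a,
        se=se,
        ci_low=max(0.0, a - z * se),
        ci_high=min(1.0, a + z * se),
        n_cases=len(x),
        n_controls=len(y),
    )


@dataclass(frozen=True)
class DelongResult:
    auc_old: float
    auc_new: float
    delta: float
    var_delta: float
    chi2: float
    p_value: float


def delong_compare(
    case_scores_old: Sequence[float],
    case_scores_new: Sequence[float],
    control_scores_old: Sequence[float],
    control_scores_new: Sequence[float],
) -> DelongResult:
    """DeLong test for the difference of two correlated AUCs.

    Scores must be paired: the two models evaluated on the same cases and
    the same controls.  The statistic ``(dAUC)^2 / var(dAUC)`` is chi-square
    with 1 d.f.; the placement-value covariance accounts for the pairing.
    """
    xo = np.asarray(case_scores_old, dtype=float)
    xn = np.asarray(case_scores_new, dtype=float)
    yo = np.asarray(control_scores_old, dtype=float)
    yn = np.asarray(control_scores_new, dtype=float)
    if len(xo) != len(xn) or len(yo) != len(yn):
        raise InputError("DeLong comparison requires paired scores per subject")
    if len(xo) < 2 or len(yo) < 2:
        raise UndefinedStatisticError("DeLong test needs >= 2 subjects per arm")
    a_old, v10_o, v01_o = _placements(xo, yo)
    a_new, v10_n, v01_n = _placements(xn, yn)
    m, n = len(xo), len(yo)
    s10 = np.cov(np.vstack([v10_o, v10_n]), ddof=1)
    s01 = np.cov(np.vstack([v01_o, v01_n]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    delta = a_new - a_old
    if var <= 0:
        if abs(delta) < 1e-15:
            chi2, p = 0.0, 1.0
        else:
            warnings.warn("zero DeLong variance with nonzero AUC difference")
            chi2, p = math.inf, 0.0
    else:
        chi2 = delta**2 / var
        p = float(stats.chi2.sf(chi2, df=1))
    return DelongResult(
        auc_old=a_old, auc_new=a_new, delta=delta, var_delta=max(var, 0.0),
        chi2=chi2, p_value=p,
    )


# ---------------------------------------------------------------------------
# OR per SD
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrPerSdResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    control_sd: float


def or_per_sd(
    scores: Sequence[float], is_case: Sequence[bool], alpha: float = 0.05
) -> OrPerSdResult:
    """Odds ratio per control-arm standard deviation of score.

    Univariable logistic regression of case status on score / SD(controls),
    with the control SD computed with denominator n - 1.  The CI is Wald.
    """
    import statsmodels.api as sm

    x = np.asarray(scores, dtype=float)
    y = np.asarray(is_case, dtype=bool)
    if y.all() or not y.any():
        raise UndefinedStatisticError("OR per SD needs both cases and controls")
    sd = float(np.std(x[~y], ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise UndefinedStatisticError("control-arm SD is zero; OR per SD undefined")
    design = sm.add_constant(x / sd)
    fit = sm.Logit(y.astype(float), design).fit(disp=False)
    beta = fit.params[1]
    se = fit.bse[1]
    z = stats.norm.ppf(1 - alpha / 2)
    return OrPerSdResult(
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p_value=float(fit.pvalues[1]),
        control_sd=sd,
    )


# ---------------------------------------------------------------------------
# Expected/observed calibration
# ---------------------------------------------------------------------------

#: <45, then 5-year bands, then 75+ — the age grid used for calibration.
DEFAULT_AGE_BANDS: tuple[tuple[str, float, float], ...] = (
    ("< 45", 0.0, 45.0),
    ("45-49", 45.0, 50.0),
    ("50-54", 50.0, 55.0),
    ("55-59", 55.0, 60.0),
    ("60-64", 60.0, 65.0),
    ("65-69", 65.0, 70.0),
    ("70-74", 70.0, 75.0),
    ("75+", 75.0, math.inf),
)


def assign_age_band(
    age: float, bands: Sequence[tuple[str, float, float]] = DEFAULT_AGE_BANDS
) -> str:
    for label, lo, hi in bands:
        if lo <= age < hi:
            return label
    raise InputError(f"age {age} not covered by the age bands")


@dataclass(frozen=True)
class CalibrationBand:
    label: str
    n: int
    expected: float
    observed: float


@dataclass(frozen=True)
class CalibrationResult:
    bands: tuple[CalibrationBand, ...]
    expected: float
    observed: float
    ratio: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_bands(cls, bands: Sequence[CalibrationBand]) -> "CalibrationResult":
        e = sum(b.expected for b in bands)
        o = sum(b.observed for b in bands)
        if o <= 0 or e <= 0:
            raise UndefinedStatisticError("E/O ratio undefined for non-positive totals")
        ratio = e / o
        # Poisson-type log-scale interval on the expected count.
        halfwidth = 1.96 / math.sqrt(e)
        return cls(
            bands=tuple(bands),
            expected=e,
            observed=o,
            ratio=ratio,
            ci_low=ratio * math.exp(-halfwidth),
            ci_high=ratio * math.exp(halfwidth),
        )


def calibration_eo(
    controls: Sequence[ScoredSubject],
    score_name: str,
    population_risk: Mapping[str, float],
    age_bands: Sequence[tuple[str, float, float]] = DEFAULT_AGE_BANDS,
) -> CalibrationResult:
    """Expected/observed calibration on the control arm.

    Per age band, expected incident cases = median model risk x N women;
    observed = population risk x N.  Controls stand in for the general
    population; the median is used because risk-score distributions are
    strongly right-skewed.  Empty bands are skipped with a warning.
    """
    rows: list[CalibrationBand] = []
    for label, lo, hi in age_bands:
        members = [s for s in controls if lo <= s.age < hi]
        if not members:
            warnings.warn(f"age band {label!r} is empty; contributes zero")
            continue
        if label not in population_risk:
            raise InputError(f"no population risk supplied for band {label!r}")
        n = len(members)
        med = float(np.median([s.score(score_name) for s in members]))
        rows.append(
            CalibrationBand(
                label=label,
                n=n,
                expected=med * n,
                observed=population_risk[label] * n,
            )
        )
    return CalibrationResult.from_bands(rows)
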