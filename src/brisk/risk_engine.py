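"""Multiplicative relative-risk model and absolute-risk projection.

A woman's combined relative risk is the product of centered component
relative risks (family history, mammographic density, BMI by menopausal
status, and an optional polygenic risk score).  Each categorical component is
centered so that its population mean is 1 under the configured category
prevalences; continuous components are log-linear around a reference value.
Because every component averages to 1 in the population, the combined
relative risk multiplies the population baseline incidence directly, and
absolute risk over a horizon is the cumulative incidence of breast cancer in
the presence of competing (non-breast-cancer) mortality.

Hazards are modelled as piecewise-constant on one-year age intervals, for
which the cumulative-incidence integral has an exact closed form per year::

    P(a, tau) = sum_{t=a}^{a+tau-1}  h1*/(h1*+h2) * (1 - exp(-(h1*+h2)))
                                    * exp(-sum_{u<t} (h1*(u)+h2(u)))

with ``h1* = rr * h1(t)`` the woman's breast-cancer hazard and ``h2`` the
competing mortality hazard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, CoverageError, InputError

__all__ = [
    "RiskFactorProfile",
    "FamilyHistoryBand",
    "FamilyHistoryTable",
    "DensityParams",
    "DensityCategory",
    "BmiStratum",
    "BmiParams",
    "RelativeRiskParameterSet",
    "HazardTable",
    "RiskEstimate",
    "family_history_rr",
    "density_rr",
    "bmi_rr",
    "prs_rr",
    "combined_rr",
    "absolute_risk",
    "remaining_lifetime_risk",
    "score_cohort",
    "default_parameters",
]

_WEIGHT_TOL = 1e-9


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RiskFactorProfile:
    """Model inputs for a single woman.

    Parameters
    ----------
    age:
        Current age in years (20-89).  Real-valued ages are floored when
        indexing hazard tables.
    n_fdr:
        Number of first-degree relatives affected by breast cancer.
    age_youngest_fdr:
        Age at diagnosis of the youngest affected first-degree relative;
        must be absent when ``n_fdr`` is 0.
    n_sdr:
        Number of affected second-degree relatives.
    percent_density:
        Percent mammographic density (0-100), e.g. a Cumulus reading.
    density_category:
        Ordinal density band (1-based) under a categorical scheme, used when
        a continuous reading is unavailable.
    bmi:
        Body mass index in kg/m^2.
    menopausal_status:
        ``"pre"`` or ``"post"``.
    prs:
        Multiplicative polygenic risk score on the population-mean-1 scale.
    """

    age: float
    n_fdr: int = 0
    age_youngest_fdr: float | None = None
    n_sdr: int = 0
    percent_density: float | None = None
    density_category: int | None = None
    bmi: float | None = None
    menopausal_status: str | None = None
    prs: float | None = None

    def validate(self) -> None:
        if not 20 <= self.age <= 89:
            raise InputError(f"age {self.age} outside supported range 20-89")
        if self.n_fdr < 0 or self.n_sdr < 0:
            raise InputError("relative counts must be non-negative")
        if self.n_fdr == 0 and self.age_youngest_fdr is not None:
            raise InputError("age_youngest_fdr given but n_fdr is 0")
        if self.percent_density is not None and not 0 <= self.percent_density <= 100:
            raise InputError(
                f"percent density {self.percent_density} outside [0, 100]"
            )
        if self.density_category is not None and self.density_category < 1:
            raise InputError("density_category is 1-based")
        if self.bmi is not None and not 10 < self.bmi < 70:
            raise InputError(f"BMI {self.bmi} outside plausible range (10, 70)")
        if self.menopausal_status is not None and self.menopausal_status not in (
            "pre",
            "post",
        ):
            raise InputError(
                f"menopausal_status must be 'pre' or 'post', got {self.menopausal_status!r}"
            )
        if self.prs is not None and self.prs <= 0:
            raise InputError("PRS must be positive")


@dataclass(frozen=True)
class FamilyHistoryBand:
    """One category of the family-history table.

    A profile matches the band when every configured range contains the
    profile's value.  Ranges are inclusive; ``None`` bounds are open.
    ``weight`` is the category's population prevalence, used for centering.
    """

    name: str
    rr: float
    weight: float
    n_fdr_min: int = 0
    n_fdr_max: int | None = None
    n_sdr_min: int = 0
    n_sdr_max: int | None = None
    dx_age_max: float | None = None  # youngest FDR diagnosed before this age
    dx_age_min: float | None = None

    def matches(self, profile: RiskFactorProfile) -> bool:
        if profile.n_fdr < self.n_fdr_min:
            return False
        if self.n_fdr_max is not None and profile.n_fdr > self.n_fdr_max:
            return False
        if profile.n_sdr < self.n_sdr_min:
            return False
        if self.n_sdr_max is not None and profile.n_sdr > self.n_sdr_max:
            return False
        if self.dx_age_max is not None or self.dx_age_min is not None:
            dx = profile.age_youngest_fdr
            if dx is None:
                return False
            if self.dx_age_max is not None and dx >= self.dx_age_max:
                return False
            if self.dx_age_min is not None and dx < self.dx_age_min:
                return False
        return True


@dataclass(frozen=True)
class FamilyHistoryTable:
    bands: tuple[FamilyHistoryBand, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ConfigurationError("family-history table has no bands")
        for b in self.bands:
            if b.rr <= 0:
                raise ConfigurationError(f"band {b.name!r}: raw RR must be > 0")
            if b.weight < 0:
                raise ConfigurationError(f"band {b.name!r}: negative weight")
        total = sum(b.weight for b in self.bands)
        if abs(total - 1.0) > _WEIGHT_TOL:
            raise ConfigurationError(
                f"family-history prevalence weights sum to {total}, expected 1"
            )

    @property
    def centering_constant(self) -> float:
        return sum(b.weight * b.rr for b in self.bands)

    def lookup(self, profile: RiskFactorProfile) -> FamilyHistoryBand:
        for band in self.bands:
            if band.matches(profile):
                return band
        raise CoverageError(
            "no family-history band covers profile with "
            f"n_fdr={profile.n_fdr}, n_sdr={profile.n_sdr}, "
            f"age_youngest_fdr={profile.age_youngest_fdr}"
        )


@dataclass(frozen=True)
class DensityCategory:
    """One band of the categorical density scheme; ``upper`` is the exclusive
    percent-density upper edge (``None`` for the top band)."""

    name: str
    rr: float
    weight: float
    upper: float | None = None


@dataclass(frozen=True)
class DensityParams:
    """Mammographic density component, in ``continuous`` (log-linear in
    percent density) or ``categorical`` (centered band RRs) mode."""

    mode: str  # "continuous" | "categorical"
    slope: float | None = None  # log-RR per percent density
    reference: float | None = None  # percent
    categories: tuple[DensityCategory, ...] = ()

    def __post_init__(self) -> None:
        if self.mode == "continuous":
            if self.slope is None or self.reference is None:
                raise ConfigurationError(
                    "continuous density mode requires slope and reference"
                )
        elif self.mode == "categorical":
            if not self.categories:
                raise ConfigurationError("categorical density mode has no categories")
            for c in self.categories:
                if c.rr <= 0:
                    raise ConfigurationError(f"density category {c.name!r}: RR <= 0")
            total = sum(c.weight for c in self.categories)
            if abs(total - 1.0) > _WEIGHT_TOL:
                raise ConfigurationError(
                    f"density prevalence weights sum to {total}, expected 1"
                )
        else:
            raise ConfigurationError(
                f"density mode must be 'continuous' or 'categorical', got {self.mode!r}"
            )

    @property
    def centering_constant(self) -> float:
        if self.mode != "categorical":
            raise ConfigurationError("centering constant only defined in categorical mode")
        return sum(c.weight * c.rr for c in self.categories)

    def category_from_percent(self, percent: float) -> int:
        """1-based category index for a percent-density reading."""
        for i, c in enumerate(self.categories, start=1):
            if c.upper is None or percent < c.upper:
                return i
        return len(self.categories)


@dataclass(frozen=True)
class BmiStratum:
    slope: float  # log-RR per kg/m^2
    reference: float  # kg/m^2


@dataclass(frozen=True)
class BmiParams:
    pre: BmiStratum
    post: BmiStratum

    def stratum(self, status: str) -> BmiStratum:
        if status == "pre":
            return self.pre
        if status == "post":
            return self.post
        raise ConfigurationError(f"unknown menopause stratum {status!r}")


@dataclass(frozen=True)
class RelativeRiskParameterSet:
    """The model's configurable parameters: component relative-risk tables
    with their centering constants.

    Any component set to ``None`` is disabled and contributes a factor 1.
    ``rr_cap`` optionally truncates the combined relative risk.
    """

    fh_table: FamilyHistoryTable | None
    density_params: DensityParams | None
    bmi_params: BmiParams | None
    rr_cap: float | None = None

    def disable(self, *components: str) -> "RelativeRiskParameterSet":
        kwargs = {}
        for comp in components:
            if comp == "family_history":
                kwargs["fh_table"] = None
            elif comp == "density":
                kwargs["density_params"] = None
            elif comp == "bmi":
                kwargs["bmi_params"] = None
            else:
                raise ConfigurationError(f"unknown component {comp!r}")
        return replace(self, **kwargs)


class HazardTable:
    """Age-specific annual hazards: breast-cancer incidence ``h1`` and
    competing (non-breast-cancer) mortality ``h2``, per woman-year, on
    contiguous integer ages."""

    def __init__(self, ages: Sequence[int], incidence: Sequence[float], mortality: Sequence[float]):
        ages = np.asarray(ages, dtype=int)
        h1 = np.asarray(incidence, dtype=float)
        h2 = np.asarray(mortality, dtype=float)
        if not (len(ages) == len(h1) == len(h2)):
            raise ConfigurationError("hazard columns have unequal length")
        if len(ages) == 0:
            raise ConfigurationError("empty hazard table")
        if not np.array_equal(ages, np.arange(ages[0], ages[0] + len(ages))):
            raise ConfigurationError("hazard ages must be contiguous integers")
        if (h1 < 0).any() or (h2 < 0).any():
            raise ConfigurationError("hazard rates must be non-negative")
        self.age_min = int(ages[0])
        self.age_max = int(ages[-1])
        self._h1 = h1
        self._h2 = h2

    def h1(self, age: int) -> float:
        return float(self._h1[self._index(age)])

    def h2(self, age: int) -> float:
        return float(self._h2[self._index(age)])

    def _index(self, age: int) -> int:
        if not self.age_min <= age <= self.age_max:
            raise CoverageError(
                f"age {age} outside hazard coverage [{self.age_min}, {self.age_max}]"
            )
        return int(age) - self.age_min

    def slice_arrays(self, start: int, stop: int) -> tuple[np.ndarray, np.ndarray]:
        """Hazard vectors for integer ages ``start`` .. ``stop - 1``."""
        i = self._index(start)
        j = self._index(stop - 1) + 1 if stop > start else i
        return self._h1[i:j], self._h2[i:j]


@dataclass(frozen=True)
class RiskEstimate:
    """Scored output for one woman."""

    combined_rr: float
    five_year: float
    remaining_lifetime: float
    horizon_max_age: int


# ---------------------------------------------------------------------------
# Component relative risks
# ---------------------------------------------------------------------------


def family_history_rr(
    profile: RiskFactorProfile, params: RelativeRiskParameterSet
) -> float:
    """Centered family-history relative risk: raw band RR divided by the
    prevalence-weighted mean RR, so the population average is 1."""
    if params.fh_table is None:
        return 1.0
    band = params.fh_table.lookup(profile)
    return band.rr / params.fh_table.centering_constant


def density_rr(profile: RiskFactorProfile, params: RelativeRiskParameterSet) -> float:
    """Mammographic-density relative risk.

    Continuous mode: ``exp(slope * (percent_density - reference))``.
    Categorical mode: centered band RR; a percent reading is binned through
    the scheme's edges when no explicit category index is given.
    """
    dp = params.density_params
    if dp is None:
        return 1.0
    if dp.mode == "continuous":
        if profile.percent_density is None:
            raise InputError(
                "density component is in continuous mode but percent_density is absent"
            )
        return math.exp(dp.slope * (profile.percent_density - dp.reference))
    # categorical
    if profile.density_category is not None:
        idx = profile.density_category
    elif profile.percent_density is not None:
        idx = dp.category_from_percent(profile.percent_density)
    else:
        raise InputError("density enabled but neither percent nor category supplied")
    if not 1 <= idx <= len(dp.categories):
        raise InputError(
            f"density_category {idx} outside 1..{len(dp.categories)}"
        )
    return dp.categories[idx - 1].rr / dp.centering_constant


def bmi_rr(profile: RiskFactorProfile, params: RelativeRiskParameterSet) -> float:
    """Body-mass-index relative risk, log-linear within menopause stratum."""
    if params.bmi_params is None:
        return 1.0
    if profile.menopausal_status is None:
        raise InputError("BMI component enabled but menopausal_status absent")
    if profile.bmi is None:
        raise InputError("BMI component enabled but bmi absent")
    stratum = params.bmi_params.stratum(profile.menopausal_status)
    return math.exp(stratum.slope * (profile.bmi - stratum.reference))


def prs_rr(profile: RiskFactorProfile) -> float:
    """Polygenic component: the profile's mean-1 multiplicative score, or 1
    when absent."""
    return 1.0 if profile.prs is None else float(profile.prs)


def combined_rr(components: Iterable[float]) -> float:
    """Product of component relative risks (order-invariant)."""
    out = 1.0
    for c in components:
        if c <= 0:
            raise InputError(f"relative-risk component {c} must be positive")
        out *= c
    return out


# ---------------------------------------------------------------------------
# Absolute risk projection
# ---------------------------------------------------------------------------


def absolute_risk(age: float, horizon: int, rr: float, hazards: HazardTable) -> float:
    """Cumulative breast-cancer incidence over ``horizon`` years from ``age``
    under competing mortality, for a woman with combined relative risk ``rr``.

    Exact for piecewise-constant annual hazards; the cause-specific fraction
    is taken as 0 on years where both rates vanish.
    """
    if horizon < 0:
        raise InputError("horizon must be non-negative")
    if rr <= 0:
        raise InputError("relative risk must be positive")
    horizon = int(horizon)
    start = int(math.floor(age))
    if horizon == 0:
        return 0.0
    h1, h2 = hazards.slice_arrays(start, start + horizon)  # raises CoverageError
    h1 = rr * h1
    total = h1 + h2
    with np.errstate(invalid="ignore"):
        frac = np.where(total > 0, h1 / np.where(total > 0, total, 1.0), 0.0)
    cum = np.concatenate([[0.0], np.cumsum(total)[:-1]])
    contrib = frac * (1.0 - np.exp(-total)) * np.exp(-cum)
    return float(np.sum(contrib))


def remaining_lifetime_risk(
    age: float, rr: float, hazards: HazardTable, max_age: int = 85
) -> float:
    """Cumulative incidence from ``age`` to ``max_age`` (default 85)."""
    start = int(math.floor(age))
    if start > max_age:
        raise InputError(f"age {age} exceeds lifetime horizon {max_age}")
    return absolute_risk(age, max_age - start, rr, hazards)


# ---------------------------------------------------------------------------
# Cohort scoring
# ---------------------------------------------------------------------------


def profile_rr(profile: RiskFactorProfile, params: RelativeRiskParameterSet) -> float:
    """Combined relative risk for one profile under a parameter set."""
    rr = combined_rr(
        (
            family_history_rr(profile, params),
            density_rr(profile, params),
            bmi_rr(profile, params),
            prs_rr(profile),
        )
    )
    if params.rr_cap is not None and rr > params.rr_cap:
        rr = params.rr_cap
    return rr


def score_cohort(
    cohort: Sequence[RiskFactorProfile],
    params: RelativeRiskParameterSet,
    hazards: HazardTable,
    max_age: int = 85,
    skip_invalid: bool = False,
) -> list[RiskEstimate | None]:
    """Score every profile; deterministic and order-preserving.

    Invalid rows raise :class:`InputError` naming the row index, unless
    ``skip_invalid`` is set, in which case the corresponding output entry is
    ``None``.
    """
    out: list[RiskEstimate | None] = []
    errors: list[str] = []
    for i, profile in enumerate(cohort):
        try:
            profile.validate()
            rr = profile_rr(profile, params)
            five = absolute_risk(profile.age, 5, rr, hazards)
            lifetime = remaining_lifetime_risk(profile.age, rr, hazards, max_age)
            out.append(RiskEstimate(rr, five, lifetime, max_age))
        except (InputError, CoverageError) as exc:
            if skip_invalid:
                out.append(None)
            else:
                errors.append(f"row {i}: {exc}")
    if errors:
        raise InputError("; ".join(errors))
    return out


# ---------------------------------------------------------------------------
# Shipped default parameters
# ---------------------------------------------------------------------------


def default_parameters(density_mode: str = "continuous") -> RelativeRiskParameterSet:
    """Documented approximate defaults.

    The family-history raw risks follow the familiar pattern of the large
    collaborative reanalyses (risk rises with the number of affected
    first-degree relatives and with younger age at diagnosis; second-degree
    history carries a smaller risk); the density and BMI slopes are plausible
    log-linear summaries of the published literature.  They are deliberately
    round, clearly non-canonical values: any production deployment should
    drop in its own calibrated tables via the YAML config
    (:func:`brisk.io.load_parameter_yaml`).
    """
    fh = FamilyHistoryTable(
        bands=(
            FamilyHistoryBand(
                "2+ first-degree relatives", rr=2.9, weight=0.02, n_fdr_min=2
            ),
            FamilyHistoryBand(
                "1 first-degree relative, diagnosed before 50",
                rr=2.3,
                weight=0.05,
                n_fdr_min=1,
                n_fdr_max=1,
                dx_age_max=50.0,
            ),
            FamilyHistoryBand(
                "1 first-degree relative, diagnosed at 50+",
                rr=1.7,
                weight=0.08,
                n_fdr_min=1,
                n_fdr_max=1,
            ),
            FamilyHistoryBand(
                "second-degree relatives only",
                rr=1.3,
                weight=0.20,
                n_fdr_max=0,
                n_sdr_min=1,
            ),
            FamilyHistoryBand(
                "no affected relatives", rr=1.0, weight=0.65, n_fdr_max=0, n_sdr_max=0
            ),
        )
    )
    if density_mode == "continuous":
        density = DensityParams(mode="continuous", slope=0.02, reference=25.0)
    else:
        density = DensityParams(
            mode="categorical",
            categories=(
                DensityCategory("< 25%", rr=0.8, weight=0.6, upper=25.0),
                DensityCategory(">= 25%", rr=1.5, weight=0.4),
            ),
        )
    bmi = BmiParams(
        pre=BmiStratum(slope=-0.02, reference=25.0),
        post=BmiStratum(slope=0.03, reference=25.0),
    )
    return RelativeRiskParameterSet(fh_table=fh, density_params=density, bmi_params=bmi)


def default_hazards(age_min: int = 20, age_max: int = 89) -> HazardTable:
    """Synthetic baseline hazard table for demonstrations and simulation.

    Incidence follows the familiar age-incidence shape of breast cancer in
    high-income populations (steep rise through the 40s, plateau near
    4 per 1000 woman-years in the 70s); competing mortality is Gompertz.
    Values are round interpolations of public US surveillance-style rates,
    not an official life table — supply your own CSV for real projections.
    """
    anchor_age = np.array([20, 30, 40, 50, 60, 70, 80, 90], dtype=float)
    anchor_inc = np.array([1e-5, 2.5e-4, 1.2e-3, 2.2e-3, 3.3e-3, 4.0e-3, 4.1e-3, 3.8e-3])
    ages = np.arange(age_min, age_max + 1)
    incidence = np.interp(ages, anchor_age, anchor_inc)
    mortality = np.exp(-10.5 + 0.088 * ages)
    return HazardTable(ages, incidence, mortality)
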