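"""Synthetic nested case-control cohorts for end-to-end testing.

Real validation cohorts with linked questionnaire, mammographic-density and
genotype data are access-controlled, so this module generates cohorts whose
marginal risk-factor distributions emulate a typical mammography-screening
case-control study (control age ~ 59 (7.5), percent density ~ 25 (18),
BMI ~ 26 (4.7), ~14% of controls with an affected first-degree relative).

The generative model mirrors the risk model's own assumptions:

* controls are drawn from the population covariate model;
* cases are drawn from a large population pool by weighted sampling with
  probability proportional to the combined relative risk — the retrospective
  sampling scheme of a nested case-control design with a rare outcome;
* genotypes (optional) are Hardy-Weinberg with independent loci;
* the polygenic score, when not computed from genotypes, is log-normal with
  configurable log-SD and arithmetic mean 1.

Case-control differences in every covariate therefore arise solely through
the relative-risk model, which is exactly the structure the validation
statistics assume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from . import prs as prs_mod
from .errors import ConfigurationError, InputError
from .fixtures import FIXTURE_NAMES, load_fixture  # re-exported: packaged tables
from .risk_engine import (
    HazardTable,
    RelativeRiskParameterSet,
    RiskFactorProfile,
    default_hazards,
    default_parameters,
    profile_rr,
)

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "generate",
    "load_fixture",
    "FIXTURE_NAMES",
]


@dataclass(frozen=True)
class CohortSpec:
    """Distributional targets for one simulated cohort.

    Defaults reproduce the control-arm marginals of a screening-age nested
    case-control study; ``prs_log_sd`` defaults to ``ln(1.61)`` so the
    polygenic component alone has a design odds ratio per SD of 1.61, the
    published discrimination of the 313-SNP breast-cancer score.
    """

    n_cases: int
    n_controls: int
    seed: int
    age_mean: float = 59.3
    age_sd: float = 7.5
    age_range: tuple[float, float] = (40.0, 78.0)
    density_mean: float = 24.7
    density_sd: float = 18.1
    bmi_mean: float = 25.9
    bmi_sd: float = 4.7
    bmi_range: tuple[float, float] = (16.0, 55.0)
    menopause_midpoint: float = 50.0  # age at 50% postmenopausal
    menopause_scale: float = 2.0
    prs_log_sd: float | None = math.log(1.61)
    snp_weights: tuple[prs_mod.SnpWeight, ...] | None = None
    pool_factor: int = 50

    def validate(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise InputError("cohort arm sizes must be positive")
        for name, sd in (("age_sd", self.age_sd), ("density_sd", self.density_sd), ("bmi_sd", self.bmi_sd)):
            if sd <= 0:
                raise InputError(f"{name} must be positive")
        if self.prs_log_sd is not None and self.prs_log_sd < 0:
            raise InputError("prs_log_sd must be non-negative")
        if self.pool_factor < 2:
            raise InputError("pool_factor must be at least 2")


@dataclass
class SyntheticCohort:
    """Generated cohort: profiles with case status, the true combined
    relative risk each woman was sampled under, and optional genotypes."""

    profiles: list[RiskFactorProfile]
    is_case: np.ndarray
    true_rr: np.ndarray
    spec: CohortSpec
    genotypes: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (p, case, rr) in enumerate(zip(self.profiles, self.is_case, self.true_rr)):
            rows.append(
                {
                    "id": f"S{i:06d}",
                    "status": "case" if case else "control",
                    "age": round(p.age, 2),
                    "n_fdr": p.n_fdr,
                    "age_youngest_fdr": p.age_youngest_fdr,
                    "n_sdr": p.n_sdr,
                    "percent_density": None
                    if p.percent_density is None
                    else round(p.percent_density, 2),
                    "density_category": p.density_category,
                    "bmi": None if p.bmi is None else round(p.bmi, 2),
                    "menopausal_status": p.menopausal_status,
                    "prs": None if p.prs is None else round(p.prs, 6),
                    "true_rr": round(rr, 6),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Covariate sampling helpers
# ---------------------------------------------------------------------------


@lru_cache(maxsize=16)
def _logitnormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Parameters (mu, sigma) of 100*expit(mu + sigma*Z) matching the target
    mean and SD of percent density, by Gauss-Hermite moment matching."""
    nodes, wts = np.polynomial.hermite_e.hermegauss(81)
    w = wts / wts.sum()

    def resid(v):
        mu, log_s = v
        x = 100.0 * special.expit(mu + math.exp(log_s) * nodes)
        m1 = float(w @ x)
        m2 = float(w @ (x - m1) ** 2)
        return [m1 - mean, math.sqrt(m2) - sd]

    sol = optimize.root(resid, x0=[special.logit(mean / 100.0), 0.0], tol=1e-12)
    if not sol.success:  # pragma: no cover - solvable for any sane target
        raise ConfigurationError(
            f"no logit-normal matches density mean {mean}, sd {sd}"
        )
    return float(sol.x[0]), math.exp(float(sol.x[1]))


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _materialize_family_history(band, u: float):
    """Concrete (n_fdr, dx_age, n_sdr) consistent with one table band;
    ``u`` is a pre-drawn uniform deviate for the diagnosis age."""
    n_fdr = band.n_fdr_min
    n_sdr = band.n_sdr_min
    dx = None
    if n_fdr > 0:
        hi = band.dx_age_max if band.dx_age_max is not None else 70.0
        lo = band.dx_age_min if band.dx_age_min is not None else max(32.0, hi - 18.0)
        dx = lo + (hi - lo) * u
    return n_fdr, dx, n_sdr


def _draw_profiles(
    rng: np.random.Generator,
    n: int,
    spec: CohortSpec,
    params: RelativeRiskParameterSet,
) -> tuple[list[RiskFactorProfile], pd.DataFrame | None]:
    ages = _truncnorm(rng, spec.age_mean, spec.age_sd, *spec.age_range, size=n)

    if params.density_params is not None:
        mu, s = _logitnormal_params(spec.density_mean, spec.density_sd)
        density = 100.0 * special.expit(mu + s * rng.standard_normal(n))
        density = np.clip(density, 0.1, 99.9)
    else:
        density = None

    bmi = (
        _truncnorm(rng, spec.bmi_mean, spec.bmi_sd, *spec.bmi_range, size=n)
        if params.bmi_params is not None
        else None
    )
    post = rng.random(n) < special.expit(
        (ages - spec.menopause_midpoint) / spec.menopause_scale
    )

    if params.fh_table is not None:
        bands = params.fh_table.bands
        weights = np.array([b.weight for b in bands])
        band_idx = rng.choice(len(bands), size=n, p=weights / weights.sum())
        u_dx = rng.random(n)
    else:
        band_idx = None

    genotypes = None
    prs_scores = None
    if spec.snp_weights:
        mat = np.column_stack(
            [rng.binomial(2, w.p, size=n) for w in spec.snp_weights]
        )
        factors = np.column_stack(
            [
                w.r ** mat[:, j] / prs_mod.hwe_mean_factor(w.p, w.r)
                for j, w in enumerate(spec.snp_weights)
            ]
        )
        prs_scores = factors.prod(axis=1)
        genotypes = pd.DataFrame(
            mat, columns=[w.variant_id for w in spec.snp_weights]
        )
    elif spec.prs_log_sd is not None:
        sigma = spec.prs_log_sd
        # arithmetic mean 1 on the natural scale
        prs_scores = np.exp(sigma * rng.standard_normal(n) - sigma**2 / 2.0)

    profiles = []
    for i in range(n):
        n_fdr, dx, n_sdr = (0, None, 0)
        if band_idx is not None:
            n_fdr, dx, n_sdr = _materialize_family_history(bands[band_idx[i]], u_dx[i])
        profiles.append(
            RiskFactorProfile(
                age=float(ages[i]),
                n_fdr=n_fdr,
                age_youngest_fdr=dx,
                n_sdr=n_sdr,
                percent_density=None if density is None else float(density[i]),
                bmi=None if bmi is None else float(bmi[i]),
                menopausal_status="post" if post[i] else "pre",
                prs=None if prs_scores is None else float(prs_scores[i]),
            )
        )
    return profiles, genotypes


def _weighted_sample_without_replacement(
    rng: np.random.Generator, weights: np.ndarray, k: int
) -> np.ndarray:
    """Indices of a size-k weighted sample without replacement.

    Exponential-race construction: the k smallest Exp(1)/w arrival times are
    a draw from successive weighted sampling, in O(n log k).
    """
    arrivals = rng.exponential(size=len(weights)) / weights
    idx = np.argpartition(arrivals, k - 1)[:k]
    return idx[np.argsort(arrivals[idx])]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate(
    spec: CohortSpec,
    params: RelativeRiskParameterSet | None = None,
    hazards: HazardTable | None = None,
) -> SyntheticCohort:
    """Generate a case-control cohort under the multiplicative risk model.

    Controls are population draws; cases are sampled from a population pool
    of ``pool_factor * n_cases`` women with probability proportional to the
    combined relative risk.  Output is byte-identical for a fixed spec.
    """
    spec.validate()
    if params is None:
        params = default_parameters()
    if hazards is None:
        hazards = default_hazards()
    rng = np.random.default_rng(spec.seed)

    controls, geno_ctrl = _draw_profiles(rng, spec.n_controls, spec, params)
    pool, geno_pool = _draw_profiles(rng, spec.pool_factor * spec.n_cases, spec, params)

    rr_controls = np.array([profile_rr(p, params) for p in controls])
    rr_pool = np.array([profile_rr(p, params) for p in pool])
    if rr_pool.max() <= 0 or not np.isfinite(rr_pool).all():
        raise InputError("relative risks in the population pool are degenerate")

    case_idx = _weighted_sample_without_replacement(rng, rr_pool, spec.n_cases)
    cases = [pool[i] for i in case_idx]
    rr_cases = rr_pool[case_idx]

    profiles = cases + controls
    is_case = np.concatenate(
        [np.ones(spec.n_cases, dtype=bool), np.zeros(spec.n_controls, dtype=bool)]
    )
    true_rr = np.concatenate([rr_cases, rr_controls])

    genotypes = None
    if geno_pool is not None:
        genotypes = pd.concat(
            [geno_pool.iloc[case_idx].reset_index(drop=True), geno_ctrl],
            ignore_index=True,
        )

    return SyntheticCohort(
        profiles=profiles,
        is_case=is_case,
        true_rr=true_rr,
        spec=spec,
        genotypes=genotypes,
    )
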