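import numpy as np
import pytest

from brisk.risk_engine import (
    BmiParams,
    BmiStratum,
    DensityCategory,
    DensityParams,
    FamilyHistoryBand,
    FamilyHistoryTable,
    HazardTable,
    RelativeRiskParameterSet,
    default_hazards,
    default_parameters,
)


@pytest.fixture(scope="session")
def hazards() -> HazardTable:
    return default_hazards()


@pytest.fixture(scope="session")
def params() -> RelativeRiskParameterSet:
    return default_parameters()


@pytest.fixture(scope="session")
def demo_params() -> RelativeRiskParameterSet:
    """Small hand-checkable parameter set: a 4-band family-history table,
    continuous density slope 0.02 around 25%, BMI slopes +-0.03/0.02."""
    fh = FamilyHistoryTable(
        bands=(
            FamilyHistoryBand("2+ FDR", rr=2.9, weight=0.02, n_fdr_min=2),
            FamilyHistoryBand("1 FDR", rr=1.8, weight=0.13, n_fdr_min=1, n_fdr_max=1),
            FamilyHistoryBand("SDR only", rr=1.3, weight=0.20, n_fdr_max=0, n_sdr_min=1),
            FamilyHistoryBand("none", rr=1.0, weight=0.65, n_fdr_max=0, n_sdr_max=0),
        )
    )
    return RelativeRiskParameterSet(
        fh_table=fh,
        density_params=DensityParams(mode="continuous", slope=0.02, reference=25.0),
        bmi_params=BmiParams(
            pre=BmiStratum(slope=-0.02, reference=25.0),
            post=BmiStratum(slope=0.03, reference=25.0),
        ),
    )


@pytest.fixture(scope="session")
def categorical_density() -> DensityParams:
    return DensityParams(
        mode="categorical",
        categories=(
            DensityCategory("< 25%", rr=0.8, weight=0.6, upper=25.0),
            DensityCategory(">= 25%", rr=1.5, weight=0.4),
        ),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230207)
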