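"""Packaged reference tables from a published nested case-control validation
of breast-cancer risk models (1131 cases, 1700 controls; a 881/1327 subset
with remaining-lifetime comparator scores).

Two kinds of table are shipped as plain JSON:

* ``table4`` .. ``table11`` — reclassification count matrices (old-model
  rows by new-model columns, cases and, where published, controls), with the
  published summary statistics attached under ``printed``;
* ``table3_*`` — per-age-band expected/observed calibration columns for each
  model/horizon.

Every file embeds its row, column and grand totals; :func:`load_fixture`
re-derives the marginals from the raw cells and fails loudly on any
mismatch, so a corrupted transcription can never silently feed the
validation statistics.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from ..errors import FixtureError
from ..validation import (
    FIVE_YEAR_SCHEME,
    LIFETIME_SCHEME,
    CalibrationBand,
    CalibrationResult,
    ReclassificationTable,
)

__all__ = ["FIXTURE_NAMES", "load_fixture", "load_reclass_table", "load_calibration"]

FIXTURE_NAMES = (
    "table3_brisk5",
    "table3_gail5",
    "table3_brisklt",
    "table3_ibislt",
    "table4",
    "table5",
    "table6",
    "table7",
    "table8",
    "table9",
    "table10",
    "table11",
)

_SCHEMES = {"five_year": FIVE_YEAR_SCHEME, "lifetime": LIFETIME_SCHEME}

# Accumulated two-decimal rounding over eight printed cells.
_CALIB_TOTAL_TOL = 0.05


def _read(name: str) -> dict:
    if name not in FIXTURE_NAMES:
        raise FixtureError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    path = resources.files(__package__) / "data" / f"{name}.json"
    return json.loads(path.read_text())


def load_fixture(name: str) -> dict:
    """Load and self-validate one packaged table.

    Returns the raw document (matrices as nested lists / numeric columns)
    after checking every embedded marginal; use :func:`load_reclass_table`
    or :func:`load_calibration` for typed objects.
    """
    doc = _read(name)
    if doc["kind"] == "reclassification":
        for arm, block in doc["arms"].items():
            m = np.asarray(block["matrix"], dtype=np.int64)
            if (m < 0).any():
                raise FixtureError(f"{name}/{arm}: negative count")
            if list(m.sum(axis=1)) != block["row_totals"]:
                raise FixtureError(f"{name}/{arm}: row totals do not reproduce")
            if list(m.sum(axis=0)) != block["col_totals"]:
                raise FixtureError(f"{name}/{arm}: column totals do not reproduce")
            if int(m.sum()) != block["total"]:
                raise FixtureError(f"{name}/{arm}: grand total does not reproduce")
    elif doc["kind"] == "calibration":
        if len({len(doc["bands"]), len(doc["n"]), len(doc["expected"]), len(doc["observed"])}) != 1:
            raise FixtureError(f"{name}: ragged calibration columns")
        printed = doc["printed"]
        if abs(sum(doc["expected"]) - printed["total_expected"]) > _CALIB_TOTAL_TOL:
            raise FixtureError(f"{name}: expected column does not sum to printed total")
        if abs(sum(doc["observed"]) - printed["total_observed"]) > _CALIB_TOTAL_TOL:
            raise FixtureError(f"{name}: observed column does not sum to printed total")
    else:  # pragma: no cover - packaging error
        raise FixtureError(f"{name}: unknown fixture kind {doc['kind']!r}")
    return doc


def load_reclass_table(name: str) -> ReclassificationTable:
    """Typed reclassification table; subgroup tables (cases only) get an
    all-zero control matrix and must not be used for control-arm statistics."""
    doc = load_fixture(name)
    if doc["kind"] != "reclassification":
        raise FixtureError(f"{name} is not a reclassification fixture")
    scheme = _SCHEMES[doc["scheme"]]
    k = scheme.n_categories
    cases = np.asarray(doc["arms"]["cases"]["matrix"], dtype=np.int64)
    if "controls" in doc["arms"]:
        controls = np.asarray(doc["arms"]["controls"]["matrix"], dtype=np.int64)
    else:
        controls = np.zeros((k, k), dtype=np.int64)
    return ReclassificationTable(
        cases=cases,
        controls=controls,
        scheme=scheme,
        old_model=doc["old_model"],
        new_model=doc["new_model"],
    )


def load_calibration(name: str) -> CalibrationResult:
    """Typed calibration result recomputed from the fixture's per-band
    expected/observed columns (totals, E/O ratio, log-scale CI)."""
    doc = load_fixture(name)
    if doc["kind"] != "calibration":
        raise FixtureError(f"{name} is not a calibration fixture")
    bands = [
        CalibrationBand(label=lbl, n=n, expected=e, observed=o)
        for lbl, n, e, o in zip(doc["bands"], doc["n"], doc["expected"], doc["observed"])
    ]
    return CalibrationResult.from_bands(bands)
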