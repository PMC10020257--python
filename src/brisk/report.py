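"""Validation report assembly: binds the statistics in
:mod:`brisk.validation` into a serializable document.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import InputError, UndefinedStatisticError
from .validation import (
    CategoryScheme,
    ReclassificationTable,
    ScoredSubject,
    arm_improvement,
    auc,
    build_reclass_table,
    calibration_eo,
    delong_compare,
    nri,
    or_per_sd,
)

__all__ = ["build_validation_report", "report_to_text", "reclass_to_frame"]


def _paired_scores(subjects: Sequence[ScoredSubject], model: str, arm_case: bool):
    return [s.scores[model] for s in subjects if s.is_case == arm_case and model in s.scores]


def _model_block(subjects: Sequence[ScoredSubject], model: str) -> dict:
    scores = [s.scores[model] for s in subjects if model in s.scores]
    is_case = [s.is_case for s in subjects if model in s.scores]
    orsd = or_per_sd(scores, is_case)
    a = auc(_paired_scores(subjects, model, True), _paired_scores(subjects, model, False))
    return {
        "n": len(scores),
        "or_per_sd": orsd.odds_ratio,
        "or_per_sd_ci": [orsd.ci_low, orsd.ci_high],
        "or_per_sd_p": orsd.p_value,
        "control_sd": orsd.control_sd,
        "auc": a.auc,
        "auc_ci": [a.ci_low, a.ci_high],
    }


def _subgroup_tables(
    subjects: Sequence[ScoredSubject],
    old_model: str,
    new_model: str,
    scheme: CategoryScheme,
) -> dict:
    """Case-arm classification improvement for the standard subgroups
    (hormone-receptor status and stage), where labels are present."""

    def improvement(selector) -> dict | None:
        cases = [s for s in subjects if s.is_case and selector(s)
                 and old_model in s.scores and new_model in s.scores]
        if not cases:
            return None
        table = build_reclass_table(cases, old_model, new_model, scheme)
        arm = arm_improvement(table.cases)
        return {"n": arm.n, "case_improvement": arm.improvement, "se": arm.se}

    blocks = {}
    defs = {
        "er_pr_positive": lambda s: s.subgroups.get("er") == "pos" and s.subgroups.get("pr") == "pos",
        "er_pr_negative": lambda s: s.subgroups.get("er") == "neg" and s.subgroups.get("pr") == "neg",
        "stage_1": lambda s: s.subgroups.get("stage") == "1",
        "stage_2_plus": lambda s: s.subgroups.get("stage") not in (None, "1"),
    }
    for name, sel in defs.items():
        block = improvement(sel)
        if block is not None:
            blocks[name] = block
    return blocks


def build_validation_report(
    subjects: Sequence[ScoredSubject],
    old_model: str,
    new_model: str,
    scheme: CategoryScheme,
    population_risk: Mapping[str, float] | None = None,
    metadata: Mapping[str, object] | None = None,
) -> dict:
    """Full comparison of two risk models on one scored cohort.

    Subjects missing one model's score are dropped pairwise for the
    comparison statistics (the pairwise-complete convention); per-model
    blocks use all subjects carrying that model's score.
    """
    paired = [s for s in subjects if old_model in s.scores and new_model in s.scores]
    if not paired:
        raise InputError("no subjects carry both model scores")
    table = build_reclass_table(paired, old_model, new_model, scheme)
    nri_res = nri(table)
    dl = delong_compare(
        _paired_scores(paired, old_model, True),
        _paired_scores(paired, new_model, True),
        _paired_scores(paired, old_model, False),
        _paired_scores(paired, new_model, False),
    )
    report: dict = {
        "metadata": {"version": __version__, **(metadata or {})},
        "models": {
            old_model: _model_block(subjects, old_model),
            new_model: _model_block(subjects, new_model),
        },
        "delong": {
            "old": old_model,
            "new": new_model,
            "auc_old": dl.auc_old,
            "auc_new": dl.auc_new,
            "chi2": dl.chi2,
            "p_value": dl.p_value,
        },
        "reclassification": {
            "scheme_edges": list(table.scheme.edges),
            "labels": list(table.scheme.labels),
            "cases": table.cases.tolist(),
            "controls": table.controls.tolist(),
        },
        "nri": {
            "overall": nri_res.overall,
            "case_improvement": nri_res.case_improvement,
            "control_improvement": nri_res.control_improvement,
            "se_overall": nri_res.se_overall,
            "se_case": nri_res.se_case,
            "se_control": nri_res.se_control,
        },
        "subgroups": _subgroup_tables(subjects, old_model, new_model, scheme),
    }
    if population_risk is not None:
        cal = {}
        for model in (old_model, new_model):
            controls = [s for s in subjects if not s.is_case and model in s.scores]
            try:
                c = calibration_eo(controls, model, population_risk)
            except UndefinedStatisticError:
                continue
            cal[model] = {
                "expected": c.expected,
                "observed": c.observed,
                "ratio": c.ratio,
                "ci": [c.ci_low, c.ci_high],
                "bands": [asdict(b) for b in c.bands],
            }
        report["calibration"] = cal
    return report


def reclass_to_frame(table: ReclassificationTable, arm: str) -> pd.DataFrame:
    """One arm of a reclassification table in the published layout (old-model
    rows, new-model columns, with totals)."""
    m = table.cases if arm == "case" else table.controls
    labels = list(table.scheme.labels)
    df = pd.DataFrame(m, index=labels, columns=labels)
    df["Total"] = df.sum(axis=1)
    df.loc["Total"] = df.sum(axis=0)
    df.index.name = f"{table.old_model} \\ {table.new_model}"
    return df


def report_to_text(report: dict) -> str:
    """Human-readable rendering; risks formatted as percentages."""
    lines: list[str] = []
    for model, block in report["models"].items():
        lines.append(
            f"{model}: OR/SD {block['or_per_sd']:.2f} "
            f"(95% CI {block['or_per_sd_ci'][0]:.2f}, {block['or_per_sd_ci'][1]:.2f}); "
            f"AUC {block['auc']:.3f} "
            f"(95% CI {block['auc_ci'][0]:.3f}, {block['auc_ci'][1]:.3f}); n={block['n']}"
        )
    dl = report["delong"]
    chi = dl["chi2"]
    chi_txt = "inf" if math.isinf(chi) else f"{chi:.2f}"
    lines.append(
        f"DeLong {dl['new']} vs {dl['old']}: AUC {dl['auc_new']:.3f} vs "
        f"{dl['auc_old']:.3f}, chi2 = {chi_txt} (1 d.f.), P = {dl['p_value']:.3g}"
    )
    n = report["nri"]
    lines.append(
        f"NRI (SE): overall = {n['overall']:.3f} ({n['se_overall']:.3f}); "
        f"cases {n['case_improvement']:.3f} ({n['se_case']:.3f}), "
        f"controls {n['control_improvement']:.3f} ({n['se_control']:.3f})"
    )
    for name, sg in report.get("subgroups", {}).items():
        lines.append(
            f"  subgroup {name}: case improvement {sg['case_improvement']:.3f} "
            f"({sg['se']:.3f}), n={sg['n']}"
        )
    for model, cal in report.get("calibration", {}).items():
        lines.append(
            f"calibration {model}: E = {cal['expected']:.2f}, O = {cal['observed']:.2f}, "
            f"E/O = {cal['ratio']:.2f} (95% CI {cal['ci'][0]:.2f}, {cal['ci'][1]:.2f})"
        )
    return "\n".join(lines) + "\n"
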