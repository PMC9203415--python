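"""Detection-error computation, subgroup summaries and statistical tests.

Errors are Euclidean distances (mm) in the en face plane between a
detection and the manual (or ground-truth) annotation, with axis-wise
components reported separately.  Subgroup cells are summarised as
mean +/- sample SD; same-eye comparisons (horizontal vs vertical error,
method vs method) use a paired two-sided Student t test, while
between-group comparisons over different eyes (foveal vs extrafoveal
RORA, standard vs dense scans) necessarily fall back to Welch's
unpaired t test, which the report records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import FoveaAnnotation
from .detector import DetectionResult

__all__ = [
    "ErrorRecord",
    "TestResult",
    "EvaluationReport",
    "compute_errors",
    "paired_t",
    "summarize",
]


@dataclass(frozen=True)
class ErrorRecord:
    """Per-eye detection error for one method."""

    eye_id: str
    err_total: float
    err_x: float
    err_y: float
    method: str
    rora_location: str = "none"
    scan_density: str = "standard"
    reliability: float = math.nan


@dataclass(frozen=True)
class TestResult:
    name: str
    test: str  # "paired t" | "welch t" | "skipped"
    statistic: float
    p_value: float
    n: int
    note: str = ""


@dataclass
class EvaluationReport:
    """Per-subgroup error statistics plus pairwise comparisons."""

    cells: dict = field(default_factory=dict)  # name -> {mean, sd, n}
    comparisons: list = field(default_factory=list)
    outliers: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cell": name, "mean_mm": c["mean"], "sd_mm": c["sd"], "n": c["n"]}
            for name, c in self.cells.items()
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "cells": self.cells,
            "comparisons": [asdict(c) for c in self.comparisons],
            "outliers": self.outliers,
        }

    def comparison(self, name: str) -> TestResult:
        for c in self.comparisons:
            if c.name == name:
                return c
        raise KeyError(name)


def compute_errors(
    detections: Sequence[DetectionResult],
    annotations: Sequence[FoveaAnnotation],
) -> list:
    """Match detections to annotations by eye_id and compute errors."""
    ann_by_id = {a.eye_id: a for a in annotations}
    det_ids = [d.eye_id for d in detections]
    missing = sorted(set(det_ids) - set(ann_by_id))
    extra = sorted(set(ann_by_id) - set(det_ids))
    if missing or extra:
        raise ValueError(
            f"eye_id mismatch: detections without annotation {missing}, "
            f"annotations without detection {extra}"
        )
    records = []
    for det in detections:
        ann = ann_by_id[det.eye_id]
        err_x = abs(det.x_mm - ann.x_mm)
        err_y = abs(det.y_mm - ann.y_mm)
        records.append(
            ErrorRecord(
                eye_id=det.eye_id,
                err_total=math.hypot(err_x, err_y),
                err_x=err_x,
                err_y=err_y,
                method=det.method,
                rora_location=ann.rora_location,
                scan_density=ann.scan_density,
                reliability=det.reliability,
            )
        )
    return records


def paired_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided t test between two error samples.

    Equal-length inputs are treated as paired per eye (Student t on the
    difference vector); unequal lengths fall back to Welch's unpaired
    test with the fallback recorded in the result.  Zero-variance
    differences are handled as the degenerate limit (p -> 0 when the
    mean difference is nonzero, p = 1 when both samples are identical).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(a.size, b.size) < 2:
        raise ValueError("need at least 2 observations per sample")
    if a.size == b.size:
        d = a - b
        sd = d.std(ddof=1)
        n = d.size
        if sd == 0.0:
            if d.mean() == 0.0:
                return TestResult("", "paired t", 0.0, 1.0, n, note="all differences zero")
            return TestResult(
                "",
                "paired t",
                math.copysign(math.inf, d.mean()),
                0.0,
                n,
                note="degenerate zero-variance differences",
            )
        t = d.mean() / (sd / math.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t), df=n - 1)
        return TestResult("", "paired t", float(t), float(p), n)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(
        "",
        "welch t",
        float(t),
        float(p),
        int(a.size + b.size),
        note="unequal group sizes: unpaired Welch test used",
    )


def _cell(values: Sequence[float]) -> dict:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return {"mean": math.nan, "sd": math.nan, "n": 0}
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return {"mean": float(values.mean()), "sd": sd, "n": int(values.size)}


def _named(result: TestResult, name: str) -> TestResult:
    return TestResult(name, result.test, result.statistic, result.p_value, result.n, result.note)


def summarize(records: Sequence[ErrorRecord], outlier_quantile: float = 0.95) -> EvaluationReport:
    """Build the per-subgroup report with pairwise comparisons.

    The primary method for subgroup partitions is ``template``; baseline
    methods contribute their total-error cells and the paired
    method-vs-method comparisons.  Cells and comparisons do not depend
    on the input ordering.
    """
    if not records:
        raise ValueError("no error records")
    records = sorted(records, key=lambda r: (r.method, r.eye_id))
    by_method: dict = {}
    for r in records:
        by_method.setdefault(r.method, []).append(r)

    report = EvaluationReport()
    primary = by_method.get("template", [])

    def add_comparison(name, a, b):
        if len(a) < 2 or len(b) < 2:
            report.comparisons.append(
                TestResult(name, "skipped", math.nan, math.nan, len(a) + len(b),
                           note="a cell has fewer than 2 members")
            )
            return
        report.comparisons.append(_named(paired_t(a, b), name))

    if primary:
        report.cells["template/horizontal"] = _cell([r.err_x for r in primary])
        report.cells["template/vertical"] = _cell([r.err_y for r in primary])
        for density in ("standard", "dense"):
            sub = [r.err_total for r in primary if r.scan_density == density]
            report.cells[f"template/{density}"] = _cell(sub)
        for loc in ("foveal", "extrafoveal"):
            sub = [r.err_total for r in primary if r.rora_location == loc]
            report.cells[f"template/{loc}_rora"] = _cell(sub)
        report.cells["template/total"] = _cell([r.err_total for r in primary])

        add_comparison(
            "horizontal_vs_vertical",
            [r.err_x for r in primary],
            [r.err_y for r in primary],
        )
        add_comparison(
            "standard_vs_dense",
            [r.err_total for r in primary if r.scan_density == "standard"],
            [r.err_total for r in primary if r.scan_density == "dense"],
        )
        add_comparison(
            "foveal_vs_extrafoveal",
            [r.err_total for r in primary if r.rora_location == "foveal"],
            [r.err_total for r in primary if r.rora_location == "extrafoveal"],
        )

        # outliers of the primary method, flagged with reliability
        totals = np.array([r.err_total for r in primary])
        threshold = float(np.quantile(totals, outlier_quantile))
        for r in primary:
            if r.err_total > threshold:
                report.outliers.append(
                    {"eye_id": r.eye_id, "err_total": r.err_total, "reliability": r.reliability}
                )

    for method, recs in by_method.items():
        if method == "template":
            continue
        report.cells[f"{method}/total"] = _cell([r.err_total for r in recs])
        if primary:
            prim_ids = {r.eye_id: r for r in primary}
            other_ids = {r.eye_id: r for r in recs}
            shared = sorted(set(prim_ids) & set(other_ids))
            if len(shared) >= 2:
                report.comparisons.append(
                    _named(
                        paired_t(
                            [prim_ids[e].err_total for e in shared],
                            [other_ids[e].err_total for e in shared],
                        ),
                        f"template_vs_{method}",
                    )
                )
            else:
                report.comparisons.append(
                    TestResult(f"template_vs_{method}", "skipped", math.nan, math.nan,
                               len(shared), note="fewer than 2 shared eyes")
                )
    return report
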