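"""End-to-end helpers: phantom cohort -> detections -> evaluation report.

These functions wire the modules together the way the CLI and the
reproduction script use them: generate a synthetic eye, project and
resample its GCL-IPL map, run the template detector and both baselines,
and score everything against the ground-truth fovea.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .baselines import center_baseline, thinnest_point_baseline
from .data import FoveaAnnotation
from .detector import FoveaTemplate, build_template, detect
from .enface import layer_thickness_map, resample, total_thickness_map
from .evaluation import EvaluationReport, compute_errors, summarize
from .phantom import (
    CohortJitter,
    PhantomSpec,
    generate,
    make_degenerate,
    paper_like_base,
    paper_like_jitter,
    sample_cohort_specs,
    scan_density_of,
)

__all__ = [
    "CohortEvaluation",
    "evaluate_member",
    "run_cohort_evaluation",
    "paper_like_specs",
    "degenerate_cohort_specs",
]

GCLIPL_LAYERS = ("GCL", "IPL")


@dataclass
class CohortEvaluation:
    """Everything produced by a cohort run."""

    specs: list
    annotations: list
    detections: dict  # method -> list[DetectionResult]
    records: list  # ErrorRecord for every (eye, method)
    report: EvaluationReport

    def mean_error(self, method: str) -> float:
        cell = self.report.cells[f"{method}/total"]
        return cell["mean"]


def evaluate_member(
    spec: PhantomSpec, template: Optional[FoveaTemplate] = None, eye_id: str = "eye"
) -> tuple:
    """Run all three detectors on one phantom.

    Returns ``(detections_by_method, annotation)`` where the annotation
    carries the phantom's ground-truth fovea and subgroup labels.
    """
    vol, truth = generate(spec)
    iso = resample(layer_thickness_map(vol, GCLIPL_LAYERS))
    det_template = detect(iso, template, geometry=vol.geometry, eye_id=eye_id)
    det_center = center_baseline(vol.geometry, eye_id=eye_id)
    det_thinnest = thinnest_point_baseline(
        total_thickness_map(vol), vol.geometry, eye_id=eye_id
    )
    annotation = FoveaAnnotation(
        eye_id=eye_id,
        x_mm=truth.fovea_mm[0],
        y_mm=truth.fovea_mm[1],
        grader="truth",
        rora_location=truth.rora_location,
        scan_density=scan_density_of(vol.geometry),
    )
    return (
        {"template": det_template, "center": det_center, "thinnest": det_thinnest},
        annotation,
    )


def run_cohort_evaluation(
    specs: Sequence[PhantomSpec], template: Optional[FoveaTemplate] = None
) -> CohortEvaluation:
    """Detect + evaluate every member of a spec list."""
    if template is None:
        template = build_template()
    detections: dict = {"template": [], "center": [], "thinnest": []}
    annotations = []
    for k, spec in enumerate(specs):
        dets, ann = evaluate_member(spec, template, eye_id=f"eye{k:03d}")
        for method, det in dets.items():
            detections[method].append(det)
        annotations.append(ann)
    records = []
    for dets in detections.values():
        records.extend(compute_errors(dets, annotations))
    report = summarize(records)
    return CohortEvaluation(
        specs=list(specs),
        annotations=annotations,
        detections=detections,
        records=records,
        report=report,
    )


def paper_like_specs(n: int = 55, seed: int = 0) -> list:
    """The default GA-like cohort: mixed RORA, ~10% artifacts, noise on."""
    return sample_cohort_specs(n, paper_like_base(), paper_like_jitter(), seed)


def degenerate_cohort_specs(
    n_normal: int = 40, n_degenerate: int = 5, seed: int = 0
) -> list:
    """A cohort whose last members are advanced-degeneration failure cases."""
    base = paper_like_base()
    jitter = CohortJitter(artifact_prob=0.0)
    specs = sample_cohort_specs(n_normal + n_degenerate, base, jitter, seed)
    rng = np.random.default_rng([seed, 17])
    return specs[:n_normal] + [make_degenerate(s, rng) for s in specs[n_normal:]]
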