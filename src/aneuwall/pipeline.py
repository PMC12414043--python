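"""End-to-end orchestration: cohort -> metrics -> samples -> mixed models.

Ties the modules together the way the analysis is meant to run: generate (or
load) per-patient geometry and pulsatile surface fields, compute the six
haemodynamic metrics, label wall nodes thin/normal, sample fixed-size
patches around conservatively placed centre points, normalise, and fit the
nested mixed model per metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .fields import CohortConfig, GroundTruth, generate_patient_mesh, generate_wss_series
from .lmm import LMMResult, TransformSpec, apply_transform, fit_lmm
from .metrics import compute_all_metrics
from .sampling import (METRIC_COLUMNS, PatientData, build_sample_table,
                       labels_from_ground_truth, patient_maxima)


@dataclass
class CohortResult:
    config: CohortConfig
    patients: list[PatientData]
    truths: list[GroundTruth]
    table: pd.DataFrame
    maxima: pd.DataFrame


def generate_patient(config: CohortConfig, patient_index: int,
                     seed: int | None = None) -> tuple[PatientData, GroundTruth]:
    """One synthetic patient: mesh, fields, metrics and ground-truth labels."""
    mesh = generate_patient_mesh(config, patient_index, seed)
    series, truth = generate_wss_series(mesh, config, patient_index, seed)
    fields = compute_all_metrics(series, mesh)
    labels = labels_from_ground_truth(mesh, truth.thin_nodes)
    patient = PatientData(f"P{patient_index:02d}", mesh, labels, fields)
    return patient, truth


def run_cohort(config: CohortConfig, seed: int | None = None,
               k: int = 10, n_per_region: int = 2,
               margin_mm: float = 0.5) -> CohortResult:
    """Generate the cohort and build the long-format sample table."""
    patients, truths = [], []
    for i in range(config.n_patients):
        p, t = generate_patient(config, i, seed)
        patients.append(p)
        truths.append(t)
    table = build_sample_table(patients, k=k, n_per_region=n_per_region,
                               margin_mm=margin_mm,
                               seed=config.seed if seed is None else seed)
    maxima = patient_maxima(patients)
    return CohortResult(config, patients, truths, table, maxima)


def analyze_cohort(cohort: CohortResult,
                   model_spec: str = "model2") -> dict[str, LMMResult]:
    """Fit the per-metric mixed models with the reporting transforms.

    All metrics are normalised by the patient-specific maximum except OSI,
    which is analysed raw.
    """
    normed = apply_transform(cohort.table, TransformSpec("patient_max"),
                             patient_max=cohort.maxima)
    results = {}
    for metric in METRIC_COLUMNS:
        src = normed if metric not in ("osi",) else cohort.table
        results[metric] = fit_lmm(
            src, metric, model_spec=model_spec,
            transform="patient_max" if metric not in ("osi",) else "raw")
    return results


def run_full_analysis(config: CohortConfig | None = None,
                      seed: int | None = None) -> tuple[CohortResult, dict]:
    """Convenience wrapper: cohort generation plus the default analysis."""
    if config is None:
        config = CohortConfig(seed=0 if seed is None else seed)
    cohort = run_cohort(config, seed)
    return cohort, analyze_cohort(cohort)
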