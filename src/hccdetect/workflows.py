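"""Desk-scale benchmark workflows on synthetic cohorts.

These functions fix the synthetic study conditions used to characterise the
test end to end — null calibration, planted-signal recovery, confounder
mitigation — at sizes that run on one CPU in minutes.  The spectral geometry
is reduced (4 acquisitions per sample on a 3–10 kDa grid, 40 base peaks)
relative to the full acquisition protocol (189 acquisitions, 300 peaks,
3–30 kDa), and the training configuration is scaled accordingly (40
realizations, 300 dropout draws, top-20 features); the statistical structure
of the procedure — stratified splits, filtering, dropout averaging,
out-of-bag scoring — is unchanged.

The planted-signal effect size is calibrated analytically: with ``m``
informative peaks shifted by ``delta`` on the log scale against per-peak
log-variation ``sigma``, the two classes are Gaussian in log-amplitude space
at Mahalanobis distance Delta = delta*sqrt(m)/sigma, so the Bayes-optimal
sensitivity = specificity = Phi(Delta/2).  ``signal_class_effect`` inverts
this for a target of 0.90.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cortex_classifier import DevelopmentResult, TrainConfig, develop_test, ensemble_score
from .evaluation import confusion_metrics, roc_points
from .spectral_processing import PipelineConfig, QcCriteria, build_feature_table
from .synthetic_cohort import Cohort, CohortConfig, generate_cohort

__all__ = [
    "desk_pipeline_config",
    "desk_train_config",
    "null_cohort_config",
    "null_train_config",
    "signal_cohort_config",
    "confounded_cohort_config",
    "benchmark_cohort_config",
    "signal_class_effect",
    "cohort_feature_tables",
    "run_development",
    "run_null_calibration",
    "run_signal_recovery",
    "run_confounder_comparison",
    "run_validation_benchmark",
]

_DESK_SPECTRAL = dict(
    n_positions=4,
    n_spots=1,
    mz_range=(3000.0, 10000.0),
    mz_step=2.0,
    n_peaks=40,
    n_acute_phase=8,
    sample_log_sigma=0.3,
    shot_log_sigma=0.05,
)


def desk_pipeline_config() -> PipelineConfig:
    return PipelineConfig(
        n_select=4,
        n_features=40,
        background_half_widths=(100.0, 20.0),
        qc=QcCriteria(min_tic_frac_median=0.33, min_anchor_snr=2.0),
    )


def desk_train_config(seed: int, *, healthy_constraint: bool = True) -> TrainConfig:
    return TrainConfig(
        n_realizations=40,
        train_fraction=0.5,
        k_neighbors=7,
        max_subset_size=2,
        filter_min_accuracy=0.55,
        healthy_min_no_cancer_rate=0.60 if healthy_constraint else 0.0,
        dropout_leave_in=12,
        n_dropout_iterations=300,
        n_keep_features=20,
        seed=seed,
    )


def signal_class_effect(
    target: float = 0.90, sigma: float = 0.3, n_informative: int = 10
) -> float:
    """Log-fold peak shift giving Bayes sensitivity = specificity = target."""
    delta_mahalanobis = 2.0 * norm.ppf(target)
    return delta_mahalanobis * sigma / math.sqrt(n_informative)


def null_cohort_config(seed: int) -> CohortConfig:
    """No planted class effect, no confounding, no AFP signal."""
    return CohortConfig(
        n_hcc=160, n_no_hcc=160, n_healthy=16,
        n_informative=10, class_effect=0.0,
        confounder_effect=0.0, confounder_class_correlation=0.0,
        afp_hcc_signal=False, seed=seed, **_DESK_SPECTRAL,
    )


def null_train_config(seed: int) -> TrainConfig:
    """Desk config for null calibration.

    The full feature set is used (identity selection), isolating
    split/out-of-bag calibration from the upward bias that development-level
    univariate preselection induces under the null (see the methods note);
    the atomic enumeration is subsampled to 150 for runtime, and 60
    realizations tighten the out-of-bag average."""
    return replace(desk_train_config(seed), n_keep_features=10_000,
                   max_atomics=150, n_realizations=60)


def signal_cohort_config(seed: int) -> CohortConfig:
    """Planted MS effect calibrated to Bayes sens = spec = 0.90; AFP silent.

    The effect is concentrated in 6 of the 40 peaks, so single features
    classify only modestly while feature pairs do much better — the regime
    the pair-capable atomic classifiers are designed for.
    """
    return CohortConfig(
        n_hcc=100, n_no_hcc=100, n_healthy=16,
        n_informative=6, class_effect=signal_class_effect(0.90, 0.3, 6),
        confounder_effect=0.0, confounder_class_correlation=0.0,
        afp_hcc_signal=False, seed=seed, **_DESK_SPECTRAL,
    )


def confounded_cohort_config(seed: int, *, n_extra_healthy: int = 80) -> CohortConfig:
    """Transplant-like confounding: liver function anticorrelated with HCC.

    The acute-phase peak block tracks the liver-function score, which is
    negatively correlated with HCC among the patient cohorts; healthy
    volunteers sit at the population baseline.  The first 16 healthy samples
    serve as the filtering reference, the rest as an independent healthy-like
    validation set for false-positive-rate measurement.
    """
    return CohortConfig(
        n_hcc=40, n_no_hcc=40, n_healthy=16 + n_extra_healthy,
        n_informative=6, class_effect=signal_class_effect(0.80, 0.3, 6),
        confounder_effect=0.8, confounder_class_correlation=-0.7,
        afp_hcc_signal=False, seed=seed, **_DESK_SPECTRAL,
    )


# ---------------------------------------------------------------------------
# cohort -> feature tables -> development
# ---------------------------------------------------------------------------

def cohort_feature_tables(
    cohort: Cohort,
    pipeline: Optional[PipelineConfig] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run the spectral chain over a cohort.

    Returns (patient table with ``label``, healthy table).  Feature windows
    are defined on the patient (development) samples' mean spectrum; batch
    correction runs against the cohort's reference spectra.
    """
    pipeline = pipeline or desk_pipeline_config()
    afp = {r.sample_id: r.afp for r in cohort.records}
    labels = {r.sample_id: r.hcc for r in cohort.records}
    patient_ids = [r.sample_id for r in cohort.records if r.cohort != "Healthy"]
    healthy_ids = [r.sample_id for r in cohort.records if r.cohort == "Healthy"]
    table, defs, qc_failures = build_feature_table(
        cohort.spectra,
        afp,
        pipeline,
        labels=labels,
        batches=cohort.batches,
        reference_spectra=cohort.reference_spectra,
        dev_ids=patient_ids,
        seed=cohort.config.seed + 1,
    )
    patients = table.loc[[i for i in patient_ids if i in table.index]]
    healthy = table.loc[[i for i in healthy_ids if i in table.index]].drop(
        columns=["label"]
    )
    patients.attrs.update(table.attrs)
    return patients, healthy


def run_development(
    cohort_config: CohortConfig,
    train_config: TrainConfig,
    *,
    n_filter_healthy: int = 16,
    threshold_criterion: str = "youden",
) -> Tuple[DevelopmentResult, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a cohort, extract features, and run the development procedure.

    Returns (development result, patient table, filtering-healthy table,
    extra-healthy table for independent validation; empty when the cohort has
    no extra healthy samples).
    """
    cohort = generate_cohort(cohort_config)
    patients, healthy = cohort_feature_tables(cohort)
    healthy_filter = healthy.iloc[:n_filter_healthy]
    healthy_extra = healthy.iloc[n_filter_healthy:]
    result = develop_test(patients, healthy_filter, train_config,
                          threshold_criterion=threshold_criterion)
    return result, patients, healthy_filter, healthy_extra


# ---------------------------------------------------------------------------
# benchmark runs
# ---------------------------------------------------------------------------

def run_null_calibration(n_runs: int, seed: int) -> List[float]:
    """Development OOB AUC over repeated seeded runs with no planted effect."""
    aucs = []
    for i in range(n_runs):
        run_seed = seed + 1000 * i
        result, patients, _, _ = run_development(
            null_cohort_config(run_seed), null_train_config(run_seed)
        )
        y = patients.loc[result.oob.index, "label"].astype(bool).to_numpy()
        aucs.append(roc_points(result.oob.to_numpy(), y).auc)
    return aucs


def run_signal_recovery(seed: int) -> Dict[str, float]:
    """OOB sensitivity/specificity at the chosen threshold under the planted
    signal calibrated to Bayes sens = spec = 0.90."""
    result, patients, _, _ = run_development(
        signal_cohort_config(seed), desk_train_config(seed),
        threshold_criterion="balanced",
    )
    y = patients.loc[result.oob.index, "label"].astype(bool).to_numpy()
    calls = result.oob.to_numpy() >= result.model.threshold
    cm = confusion_metrics(y, calls)
    return {
        "oob_sensitivity": cm.sensitivity,
        "oob_specificity": cm.specificity,
        "oob_auc": roc_points(result.oob.to_numpy(), y).auc,
        "threshold": result.model.threshold,
        "n": len(y),
    }


def benchmark_cohort_config(seed: int) -> CohortConfig:
    """Development + blinded-validation cohort with MS signal and an AFP
    class difference (HCC median 10 ng/mL vs non-HCC 2 ng/mL)."""
    return CohortConfig(
        n_hcc=80 + 60, n_no_hcc=80 + 60, n_healthy=16,
        n_informative=6, class_effect=signal_class_effect(0.90, 0.3, 6),
        confounder_effect=0.0, confounder_class_correlation=0.0,
        afp_hcc_signal=True, seed=seed, **_DESK_SPECTRAL,
    )


def run_validation_benchmark(seed: int) -> Dict[str, float]:
    """Develop on one stratified half, lock, classify the held-out half
    through the hierarchical rules, and compare the test's AUC with AFP
    alone by the DeLong method.

    High-AFP rule-assigned samples enter the ROC with effective score 1.0
    (they are Cancer at every classifier cutoff).
    """
    from .evaluation import confusion_metrics as _cm, delong_compare

    cohort = generate_cohort(benchmark_cohort_config(seed))
    patients, healthy = cohort_feature_tables(cohort)
    afp = {r.sample_id: r.afp for r in cohort.records}
    hcc_ids = [r.sample_id for r in cohort.records if r.hcc]
    no_ids = [r.sample_id for r in cohort.records
              if not r.hcc and r.cohort != "Healthy"]
    dev_ids = hcc_ids[:80] + no_ids[:80]
    val_ids = hcc_ids[80:] + no_ids[80:]

    dev = patients.loc[[i for i in dev_ids if i in patients.index]].copy()
    dev["afp"] = [str(afp[i]) for i in dev.index]
    dev["pre_label"] = "Good"
    result = develop_test(dev, healthy.iloc[:16], desk_train_config(seed),
                          threshold_criterion="balanced")

    val = patients.loc[[i for i in val_ids if i in patients.index]]
    y = val["label"].astype(bool).to_numpy()
    ml_scores = ensemble_score(
        result.model, val.loc[:, list(result.model.feature_subset)]
    )
    high_afp = np.array([afp[i].geq(result.model.afp_assign_cutoff) for i in val.index])
    eff_scores = np.where(high_afp, 1.0, ml_scores)
    calls = high_afp | (ml_scores >= result.model.threshold)
    afp_scores = np.array([afp[i].point_estimate() for i in val.index])

    cm = _cm(y, calls)
    auc_test, auc_afp, var_diff, p = delong_compare(eff_scores, afp_scores, y)
    return {
        "val_sensitivity": cm.sensitivity,
        "val_specificity": cm.specificity,
        "auc_test": auc_test,
        "auc_afp": auc_afp,
        "delong_p": p,
        "n": len(y),
    }


def run_confounder_comparison(n_pairs: int, seed: int) -> List[Tuple[float, float]]:
    """False-positive rate on an independent healthy-like validation set,
    with the healthy-sample filtering constraint ON vs OFF.

    Each pair shares a cohort seed, so the comparison is paired in every
    source of randomness except the constraint itself.
    """
    out = []
    for i in range(n_pairs):
        run_seed = seed + 1000 * i
        cohort = generate_cohort(confounded_cohort_config(run_seed))
        patients, healthy = cohort_feature_tables(cohort)
        healthy_filter = healthy.iloc[:16]
        healthy_extra = healthy.iloc[16:]
        fprs = []
        for constraint in (True, False):
            result = develop_test(
                patients, healthy_filter,
                desk_train_config(run_seed, healthy_constraint=constraint),
                threshold_criterion="balanced",
            )
            scores = ensemble_score(
                result.model, healthy_extra.loc[:, list(result.model.feature_subset)]
            )
            fprs.append(float((scores >= result.model.threshold).mean()))
        out.append((fprs[0], fprs[1]))  # (constraint ON, constraint OFF)
    return out
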