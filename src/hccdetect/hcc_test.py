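"""The locked hierarchical HCC detection test.

A new sample is evaluated strictly in order:

1. spectral quality control — a valid averaged spectrum must be obtainable
   and must not show evidence of contamination or degradation, else the
   sample receives no valid classification (``QCFail``);
2. a Poor call from the serum-proteomic pre-classifier assigns "Cancer";
3. serum AFP at or above 100 ng/mL assigns "Cancer";
4. otherwise the ensemble classifier score against the locked threshold
   decides "Cancer" vs "No Cancer".

The proprietary pre-classifier is a plug-in point: any deterministic
callable mapping a processed spectrum to Good/Poor satisfies the interface.
A documented surrogate trained on the synthetic acute-phase peak block is
provided so the full decision flow is exercisable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Mapping, Optional, Protocol, Sequence, Tuple

import numpy as np
import pandas as pd

from .afp import CensoredAfp, parse_afp
from .cortex_classifier import ContractError, CortexModel, ensemble_score
from .spectral_processing import (
    FeatureDefinition,
    PipelineConfig,
    ProcessedSpectrum,
    QcFailure,
    extract_features,
    normalize_spectrum,
    process_sample,
    window_integral,
)
from .synthetic_cohort import ShotSpectrum

__all__ = [
    "PreClassifier",
    "SurrogatePreClassifier",
    "TestClassification",
    "LockedHccTest",
    "QcLimits",
    "apply_test",
    "surrogate_pre_classifier",
]

ROUTES = ("QC", "PRECLASSIFIER_POOR", "HIGH_AFP", "ML_SCORE")


class PreClassifier(Protocol):
    """Contract for the Good/Poor serum-proteomic pre-classifier."""

    identifier: str
    version: str

    def __call__(self, spectrum: ProcessedSpectrum) -> str: ...


@dataclass(frozen=True)
class TestClassification:
    __test__ = False  # a domain type, not a pytest suite

    sample_id: str
    label: str                       # Cancer | NoCancer | QCFail
    route: str                       # one of ROUTES
    score: Optional[float] = None
    threshold_used: Optional[float] = None
    detail: str = ""

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}")
        if (self.route == "ML_SCORE") != (self.score is not None and self.threshold_used is not None):
            raise ValueError("score and threshold are present iff route is ML_SCORE")
        if (self.label == "QCFail") != (self.route == "QC"):
            raise ValueError("QCFail label iff QC route")


# ---------------------------------------------------------------------------
# surrogate pre-classifier
# ---------------------------------------------------------------------------

@dataclass
class SurrogatePreClassifier:
    """Thresholded linear score on the acute-phase window block.

    Stands in for the proprietary pre-classifier.  The score is the summed
    normalized intensity over windows covering acute-phase peaks; the Poor
    threshold is calibrated on healthy-donor spectra so that healthy Poor
    calls are rare (target rate at most ``target_poor_rate``).
    """

    windows: Tuple[FeatureDefinition, ...]
    threshold: float
    identifier: str = "surrogate-acute-phase"
    version: str = "1"

    def score(self, spectrum: ProcessedSpectrum) -> float:
        total = window_integral(spectrum.mz, spectrum.intensity,
                                spectrum.mz[0], spectrum.mz[-1])
        if total <= 0:
            return 0.0
        return sum(
            window_integral(spectrum.mz, spectrum.intensity, w.mz_left, w.mz_right)
            for w in self.windows
        ) / total

    def __call__(self, spectrum: ProcessedSpectrum) -> str:
        return "Poor" if self.score(spectrum) > self.threshold else "Good"


def surrogate_pre_classifier(
    healthy_spectra: Sequence[ProcessedSpectrum],
    acute_phase_windows: Sequence[FeatureDefinition],
    *,
    target_poor_rate: float = 0.02,
) -> SurrogatePreClassifier:
    """Calibrate the surrogate so the healthy Poor rate is at most the target."""
    if not healthy_spectra:
        raise ValueError("healthy calibration spectra required")
    stub = SurrogatePreClassifier(tuple(acute_phase_windows), threshold=np.inf)
    scores = np.array([stub.score(s) for s in healthy_spectra])
    if np.unique(scores).size < 2 and len(scores) > 1:
        threshold = float(scores[0]) + abs(float(scores[0])) * 0.5 + 1e-9
    else:
        threshold = float(np.quantile(scores, 1.0 - target_poor_rate,
                                      method="higher"))
    return SurrogatePreClassifier(tuple(acute_phase_windows), threshold)


# ---------------------------------------------------------------------------
# the locked test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QcLimits:
    """Contamination/degradation heuristics applied before classification."""

    max_zero_fraction: float = 0.5          # fraction of zero-intensity grid points
    norm_factor_range: Tuple[float, float] = (0.0, np.inf)


@dataclass
class LockedHccTest:
    """Everything needed to classify a new serum sample."""

    model: CortexModel
    feature_defs: Tuple[FeatureDefinition, ...]
    pipeline: PipelineConfig
    anchors: Tuple[float, ...]
    pre_classifier: PreClassifier
    qc_limits: QcLimits = field(default_factory=QcLimits)
    batch_factors: Optional[pd.DataFrame] = None   # per-batch feature factors


def _spectral_qc(spectrum: ProcessedSpectrum, norm_factor: float,
                 limits: QcLimits) -> Optional[str]:
    zero_frac = float((spectrum.intensity == 0).mean())
    if zero_frac > limits.max_zero_fraction:
        return f"degraded spectrum: {zero_frac:.0%} of grid points empty"
    lo, hi = limits.norm_factor_range
    if not lo <= norm_factor <= hi:
        return f"normalization factor {norm_factor:.3g} outside [{lo:.3g}, {hi:.3g}]"
    return None


def apply_test(
    spectra: Sequence[ShotSpectrum],
    afp,
    test: LockedHccTest,
    *,
    sample_id: str = "",
    batch: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
) -> TestClassification:
    """Classify one sample through the locked hierarchical flow.

    ``afp`` may be a number, a censored report string ("<0.8", ">=10,000"),
    a :class:`CensoredAfp`, or None (missing AFP fails QC: both spectral
    data and AFP are required inputs of the test).  The true label is never
    an input.
    """
    if not test.model.locked:
        raise ContractError("the model must be locked before application")
    sid = sample_id or (spectra[0].sample_id if spectra else "")
    rng = rng or np.random.default_rng(0)

    # (1) spectral QC gate
    try:
        processed = process_sample(spectra, test.pipeline, test.anchors, rng)
        normed = normalize_spectrum(processed, test.feature_defs)
    except QcFailure as e:
        return TestClassification(sid, "QCFail", "QC", detail=str(e))
    reason = _spectral_qc(normed, normed.normalization_factor, test.qc_limits)
    if reason is not None:
        return TestClassification(sid, "QCFail", "QC", detail=reason)
    if afp is None:
        return TestClassification(sid, "QCFail", "QC", detail="missing AFP measurement")
    afp_value = parse_afp(afp)

    # (2) pre-classifier Poor -> Cancer
    if test.pre_classifier(normed) == "Poor":
        return TestClassification(sid, "Cancer", "PRECLASSIFIER_POOR")

    # (3) AFP >= cutoff -> Cancer (inclusive; ">=10,000" qualifies)
    if afp_value.geq(test.model.afp_assign_cutoff):
        return TestClassification(sid, "Cancer", "HIGH_AFP")

    # (4) ensemble score vs locked threshold
    fv = extract_features(normed, test.feature_defs, afp_value)
    row = dict(fv.ms_features)
    if test.batch_factors is not None and batch is not None:
        factors = test.batch_factors.loc[batch]
        for k in row:
            if k in factors.index:
                row[k] *= float(factors[k])
    row["ln_afp"] = fv.ln_afp
    score = float(ensemble_score(test.model, row)[0])
    label = "Cancer" if score >= test.model.threshold else "NoCancer"
    return TestClassification(sid, label, "ML_SCORE", score=score,
                              threshold_used=test.model.threshold)


def classify_feature_rows(
    table: pd.DataFrame,
    test: LockedHccTest,
    afp_by_sample: Mapping[str, CensoredAfp],
    pre_labels: Mapping[str, str],
) -> List[TestClassification]:
    """Apply rules (2)-(4) to already-extracted, QC-passing feature rows.

    Convenience path for cohort-scale evaluation where the spectral stage has
    already run through :func:`~hccdetect.spectral_processing.build_feature_table`.
    """
    if not test.model.locked:
        raise ContractError("the model must be locked before application")
    out: List[TestClassification] = []
    scores = ensemble_score(test.model, table.loc[:, list(test.model.feature_subset)])
    for (sid, _), score in zip(table.iterrows(), scores):
        sid = str(sid)
        if pre_labels.get(sid) == "Poor":
            out.append(TestClassification(sid, "Cancer", "PRECLASSIFIER_POOR"))
            continue
        if parse_afp(afp_by_sample[sid]).geq(test.model.afp_assign_cutoff):
            out.append(TestClassification(sid, "Cancer", "HIGH_AFP"))
            continue
        label = "Cancer" if score >= test.model.threshold else "NoCancer"
        out.append(TestClassification(sid, label, "ML_SCORE", score=float(score),
                                      threshold_used=test.model.threshold))
    return out
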