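"""Spectral processing: alignment, QC, averaging, background subtraction,
normalization, batch correction, feature definition and extraction.

The chain turns raw per-position acquisitions into one processed average
spectrum per sample and then into a feature table whose columns are
integrated intensities over fixed m/z windows plus ln(AFP).  Every step a
spectrum passes through is recorded in its provenance so downstream code can
verify the full chain ran exactly once and in order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, minimum_filter1d, uniform_filter1d
from scipy.signal import find_peaks, peak_widths
from scipy.stats import mannwhitneyu

from .afp import CensoredAfp, parse_afp
from .synthetic_cohort import ShotSpectrum

__all__ = [
    "ProcessedSpectrum",
    "FeatureDefinition",
    "FeatureVector",
    "QcCriteria",
    "QcFailure",
    "InputError",
    "align_spectra",
    "qc_filter",
    "select_and_average",
    "subtract_background",
    "normalize_spectrum",
    "batch_correct",
    "define_features",
    "extract_features",
    "select_top_features",
    "window_integral",
    "PipelineConfig",
    "build_feature_table",
    "process_sample",
]


class QcFailure(RuntimeError):
    """A sample failed spectral quality control; no valid test classification."""


class InputError(ValueError):
    """Invalid input to a processing operation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProcessedSpectrum:
    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str
    provenance: Tuple[Tuple[str, dict], ...] = ()
    normalization_factor: float = 1.0

    def with_step(self, step: str, params: dict, intensity: np.ndarray,
                  **changes) -> "ProcessedSpectrum":
        return replace(
            self,
            intensity=intensity,
            provenance=self.provenance + ((step, params),),
            **changes,
        )

    @property
    def steps(self) -> Tuple[str, ...]:
        return tuple(s for s, _ in self.provenance)


@dataclass(frozen=True)
class FeatureDefinition:
    """A half-open m/z window [mz_left, mz_right); its value is the
    integrated intensity of the processed average spectrum over the window."""

    feature_id: str
    mz_left: float
    mz_right: float

    def __post_init__(self) -> None:
        if not self.mz_left < self.mz_right:
            raise InputError(f"feature {self.feature_id}: mz_left must be < mz_right")

    @property
    def width(self) -> float:
        return self.mz_right - self.mz_left


@dataclass(frozen=True)
class FeatureVector:
    sample_id: str
    ms_features: Dict[str, float]
    ln_afp: float
    label: Optional[bool] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.ln_afp):
            raise InputError("ln_afp must be finite")


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _detect_peaks(mz: np.ndarray, intensity: np.ndarray) -> np.ndarray:
    if intensity.size < 3:
        return np.array([])
    prom = 0.05 * float(intensity.max() - intensity.min()) or None
    idx, _ = find_peaks(intensity, prominence=prom)
    return mz[idx]


def align_spectra(
    spectra: Sequence[ShotSpectrum],
    reference_points: Sequence[float],
    *,
    tolerance: float = 30.0,
) -> Tuple[List[ShotSpectrum], List[bool]]:
    """Warp each spectrum so peaks near the reference anchors land on them.

    A piecewise-linear m/z map is built from (detected peak -> anchor) pairs
    and the intensity is resampled back onto the original grid.  Spectra with
    no detectable peak within ``tolerance`` Da of any anchor are returned
    unchanged; the second return value flags them.

    Returns (aligned spectra, unaligned flags).
    """
    anchors = np.sort(np.asarray(reference_points, dtype=float))
    if anchors.size == 0:
        raise InputError("at least one reference point is required")
    if len(spectra) == 0:
        raise InputError("no spectra to align")

    aligned: List[ShotSpectrum] = []
    flags: List[bool] = []
    for s in spectra:
        if s.mz.size == 0:
            raise InputError("empty spectrum")
        peaks = _detect_peaks(s.mz, s.intensity)
        src, dst = [], []
        for a in anchors:
            if peaks.size == 0:
                continue
            j = int(np.argmin(np.abs(peaks - a)))
            if abs(peaks[j] - a) <= tolerance:
                src.append(peaks[j])
                dst.append(a)
        if not src:
            aligned.append(s)
            flags.append(True)
            continue
        src_a, dst_a = np.asarray(src), np.asarray(dst)
        # piecewise-linear warp of the m/z axis; constant offset beyond the
        # outermost matched anchors
        offset = np.interp(s.mz, src_a, dst_a - src_a)
        warped_mz = s.mz + offset
        new_int = np.interp(s.mz, warped_mz, s.intensity)
        aligned.append(replace(s, intensity=np.maximum(new_int, 0.0)))
        flags.append(False)
    return aligned, flags


# ---------------------------------------------------------------------------
# QC and averaging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QcCriteria:
    """Shot-spectrum quality thresholds.

    ``min_tic_frac_median`` rejects spectra whose total ion current falls
    below that fraction of the per-sample median TIC; ``min_anchor_snr``
    requires at least that signal-to-noise at one anchor peak.  Zeros make
    every check vacuous.
    """

    min_tic: float = 0.0
    min_tic_frac_median: float = 0.33
    min_anchor_snr: float = 2.0
    anchors: Tuple[float, ...] = ()
    anchor_window: float = 30.0


def _noise_estimate(intensity: np.ndarray) -> float:
    # robust noise from the differenced signal (peaks contribute little)
    if intensity.size < 3:
        return 0.0
    d = np.diff(intensity)
    return float(np.median(np.abs(d - np.median(d))) / 0.6745 / math.sqrt(2)) or 1e-12


def qc_filter(
    spectra: Sequence[ShotSpectrum],
    criteria: QcCriteria = QcCriteria(),
) -> Tuple[List[ShotSpectrum], List[Tuple[int, str]]]:
    """Discard spectra failing quality control; log each rejection."""
    tics = np.array([float(np.sum(s.intensity)) for s in spectra])
    median_tic = float(np.median(tics)) if len(spectra) else 0.0
    passing: List[ShotSpectrum] = []
    rejections: List[Tuple[int, str]] = []
    for i, s in enumerate(spectra):
        if tics[i] < criteria.min_tic:
            rejections.append((i, f"total ion current {tics[i]:.3g} below floor"))
            continue
        if criteria.min_tic_frac_median > 0 and tics[i] < criteria.min_tic_frac_median * median_tic:
            rejections.append((i, "total ion current below fraction of sample median"))
            continue
        if criteria.min_anchor_snr > 0 and criteria.anchors:
            noise = _noise_estimate(s.intensity)
            snrs = []
            for a in criteria.anchors:
                m = (s.mz >= a - criteria.anchor_window) & (s.mz <= a + criteria.anchor_window)
                if m.any():
                    snrs.append(float(s.intensity[m].max()) / noise)
            if snrs and max(snrs) < criteria.min_anchor_snr:
                rejections.append((i, "anchor-peak signal-to-noise below threshold"))
                continue
        passing.append(s)
    return passing, rejections


def select_and_average(
    spectra: Sequence[ShotSpectrum],
    n_select: int = 140,
    rng: Optional[np.random.Generator] = None,
) -> ProcessedSpectrum:
    """Randomly select ``n_select`` passing spectra and average them.

    Fewer than ``n_select`` passing spectra is a sample-level QC failure: the
    sample gets no valid test classification.
    """
    if len(spectra) < n_select:
        raise QcFailure(
            f"only {len(spectra)} passing spectra; {n_select} required for averaging"
        )
    rng = rng or np.random.default_rng()
    idx = np.sort(rng.choice(len(spectra), size=n_select, replace=False))
    grid = spectra[idx[0]].mz
    acc = np.zeros_like(grid, dtype=float)
    for i in idx:
        s = spectra[i]
        acc += s.intensity if s.mz.shape == grid.shape and np.allclose(s.mz, grid) \
            else np.interp(grid, s.mz, s.intensity)
    avg = acc / n_select
    sid = spectra[idx[0]].sample_id
    return ProcessedSpectrum(
        grid, avg, sid,
        provenance=(("average", {"n_select": int(n_select), "selected": idx.tolist()}),),
    )


# ---------------------------------------------------------------------------
# background, normalization, batch correction
# ---------------------------------------------------------------------------

def subtract_background(
    spectrum: ProcessedSpectrum,
    half_widths: Tuple[float, float] = (250.0, 50.0),
) -> ProcessedSpectrum:
    """Estimate and remove the smooth baseline.

    The baseline is a morphological opening (moving minimum then moving
    maximum over the first half-width, which erases peaks while preserving
    slowly varying background, including linear ramps) smoothed by a moving
    average over the second half-width.  Negative residuals are clipped to 0.
    """
    w_open, w_smooth = half_widths
    if w_open <= 0 or w_smooth <= 0:
        raise InputError("half_widths must be positive")
    dm = float(np.median(np.diff(spectrum.mz)))
    span = spectrum.mz[-1] - spectrum.mz[0]
    if 2 * w_open > span:
        raise InputError("background window exceeds the m/z span")
    k_open = max(1, int(round(w_open / dm))) * 2 + 1
    k_smooth = max(1, int(round(w_smooth / dm))) * 2 + 1
    baseline = minimum_filter1d(spectrum.intensity, size=k_open, mode="nearest")
    baseline = maximum_filter1d(baseline, size=k_open, mode="nearest")
    baseline = uniform_filter1d(baseline, size=k_smooth, mode="nearest")
    residual = np.maximum(spectrum.intensity - baseline, 0.0)
    return spectrum.with_step(
        "background", {"half_widths": tuple(half_widths), "baseline": baseline}, residual
    )


def window_integral(mz: np.ndarray, intensity: np.ndarray, left: float, right: float) -> float:
    """Trapezoidal integral over [left, right) with interpolated endpoints.

    Endpoint interpolation makes the integral exactly additive over adjacent
    windows sharing a boundary.
    """
    if left < mz[0] or right > mz[-1]:
        raise InputError(f"window [{left}, {right}) outside spectrum span")
    i0, i1 = np.searchsorted(mz, [left, right])
    xs = np.concatenate(([left], mz[i0:i1], [right]))
    ys = np.concatenate((
        [np.interp(left, mz, intensity)],
        intensity[i0:i1],
        [np.interp(right, mz, intensity)],
    ))
    # drop duplicated abscissae at exact grid hits
    keep = np.concatenate(([True], np.diff(xs) > 0))
    return float(np.trapezoid(ys[keep], xs[keep]))


def normalize_spectrum(
    spectrum: ProcessedSpectrum,
    windows: Sequence[FeatureDefinition],
) -> ProcessedSpectrum:
    """Divide by the partial ion current over the given windows.

    After normalization the summed window integral is exactly 1, so samples
    become comparable regardless of overall intensity scale.
    """
    if not windows:
        raise InputError("normalization requires at least one window")
    pic = sum(window_integral(spectrum.mz, spectrum.intensity, w.mz_left, w.mz_right)
              for w in windows)
    if pic <= 0:
        raise QcFailure("zero partial ion current over normalization windows")
    return spectrum.with_step(
        "normalize",
        {"n_windows": len(windows), "factor": pic},
        spectrum.intensity / pic,
        normalization_factor=pic,
    )


def batch_correct(
    table: pd.DataFrame,
    batches: Mapping[str, str],
    reference_ids: Mapping[str, Sequence[str]],
    *,
    feature_columns: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Equalize per-feature reference means across batches.

    ``table`` holds one row per sample (index = sample_id, including the
    reference samples); ``batches`` maps sample_id -> batch; ``reference_ids``
    maps batch -> its reference sample ids.  Each batch's features are scaled
    by (cross-batch mean of reference means) / (this batch's reference mean),
    which is exactly idempotent.  Returns (corrected table, factors table).
    """
    cols = list(feature_columns) if feature_columns is not None else [
        c for c in table.columns if c not in ("ln_afp", "label")
    ]
    batch_of = pd.Series({sid: batches[sid] for sid in table.index})
    batch_names = sorted(set(batch_of))
    ref_means = {}
    for b in batch_names:
        rids = [r for r in reference_ids.get(b, []) if r in table.index]
        if not rids:
            raise InputError(f"batch {b!r} has no reference samples")
        ref_means[b] = table.loc[rids, cols].mean(axis=0)
    target = pd.concat(ref_means, axis=1).mean(axis=1)
    factors = pd.DataFrame(
        {b: target / ref_means[b].replace(0.0, np.nan) for b in batch_names}
    ).T.fillna(1.0)
    corrected = table.copy()
    for b in batch_names:
        rows = batch_of[batch_of == b].index
        corrected.loc[rows, cols] = table.loc[rows, cols].mul(factors.loc[b], axis=1)
    return corrected, factors


# ---------------------------------------------------------------------------
# feature definition / extraction / selection
# ---------------------------------------------------------------------------

def define_features(
    mean_dev_spectrum: ProcessedSpectrum,
    n_features: int = 300,
    *,
    min_prominence_frac: float = 0.001,
) -> List[FeatureDefinition]:
    """Define m/z windows around the most prominent peaks of the mean
    development spectrum.

    Windows are [peak - w, peak + w) with w set from the local peak width
    (FWHM), trimmed to disjointness at the intensity minimum between
    neighbouring peaks.  If fewer peaks than requested are detectable, all
    available windows are returned with a warning.
    """
    mz, inten = mean_dev_spectrum.mz, mean_dev_spectrum.intensity
    prom = min_prominence_frac * float(inten.max()) if inten.size else 0.0
    idx, props = find_peaks(inten, prominence=prom or None)
    if idx.size == 0:
        warnings.warn("no detectable peaks; returning no feature definitions")
        return []
    order = np.argsort(props["prominences"])[::-1][:n_features]
    kept = np.sort(idx[order])
    widths, _, _, _ = peak_widths(inten, kept, rel_height=0.5)
    dm = float(np.median(np.diff(mz)))
    w = widths * dm  # full width at half max, in Da -> generous half-window

    lefts = mz[kept] - w
    rights = mz[kept] + w
    # trim overlapping neighbours at the intensity minimum between the peaks
    for i in range(len(kept) - 1):
        if rights[i] > lefts[i + 1]:
            lo, hi = kept[i], kept[i + 1]
            jmin = lo + int(np.argmin(inten[lo:hi + 1]))
            boundary = mz[jmin]
            rights[i] = boundary
            lefts[i + 1] = boundary
    lefts = np.maximum(lefts, mz[0])
    rights = np.minimum(rights, mz[-1])
    defs = [
        FeatureDefinition(f"F{i + 1:03d}", float(l), float(r))
        for i, (l, r) in enumerate(zip(lefts, rights))
        if r > l
    ]
    if len(defs) < n_features:
        warnings.warn(
            f"only {len(defs)} of the requested {n_features} features definable"
        )
    return defs


def extract_features(
    spectrum: ProcessedSpectrum,
    defs: Sequence[FeatureDefinition],
    afp: CensoredAfp,
    *,
    label: Optional[bool] = None,
) -> FeatureVector:
    """Integrate the processed spectrum over each window and append ln(AFP)."""
    if not defs:
        raise InputError("no feature definitions")
    values = {
        d.feature_id: window_integral(spectrum.mz, spectrum.intensity, d.mz_left, d.mz_right)
        for d in defs
    }
    return FeatureVector(spectrum.sample_id, values, parse_afp(afp).ln(), label)


def select_top_features(
    dev_table: pd.DataFrame,
    n_keep: int = 100,
    *,
    label_column: str = "label",
) -> List[str]:
    """Rank MS features by two-sided Mann-Whitney p (HCC vs non-HCC).

    Ties broken by absolute rank-biserial effect size, then feature id.
    ``ln_afp`` is not ranked; it always accompanies the selected features.
    """
    y = dev_table[label_column].astype(bool)
    if y.all() or not y.any():
        raise InputError("feature ranking requires both classes")
    cols = [c for c in dev_table.columns if c not in (label_column, "ln_afp")]
    n1, n0 = int(y.sum()), int((~y).sum())
    rows = []
    for c in cols:
        a, b = dev_table.loc[y, c], dev_table.loc[~y, c]
        try:
            u, p = mannwhitneyu(a, b, alternative="two-sided")
        except ValueError:  # all values identical
            u, p = n1 * n0 / 2.0, 1.0
        rank_biserial = 2.0 * u / (n1 * n0) - 1.0
        rows.append((p, -abs(rank_biserial), c))
    rows.sort()
    return [c for _, _, c in rows[:n_keep]]


# ---------------------------------------------------------------------------
# sample-level pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of the full per-sample processing chain."""

    anchors: Optional[Tuple[float, ...]] = None  # auto-detected if None
    n_anchors_auto: int = 5
    qc: QcCriteria = field(default_factory=QcCriteria)
    n_select: int = 140
    background_half_widths: Tuple[float, float] = (250.0, 50.0)
    n_features: int = 300
    align_tolerance: float = 30.0


def _auto_anchors(spectra_by_sample: Mapping[str, Sequence[ShotSpectrum]],
                  n_anchors: int) -> Tuple[float, ...]:
    # pooled quick mean over the first acquisition of each sample
    first = [specs[0] for specs in spectra_by_sample.values() if specs]
    grid = first[0].mz
    acc = np.zeros_like(grid)
    for s in first:
        acc += s.intensity if s.mz.shape == grid.shape else np.interp(grid, s.mz, s.intensity)
    acc /= len(first)
    idx, props = find_peaks(acc, prominence=0.01 * float(acc.max()))
    if idx.size == 0:
        raise InputError("could not auto-detect alignment anchors")
    top = idx[np.argsort(props["prominences"])[::-1][:n_anchors]]
    return tuple(sorted(float(grid[i]) for i in top))


def process_sample(
    spectra: Sequence[ShotSpectrum],
    cfg: PipelineConfig,
    anchors: Sequence[float],
    rng: np.random.Generator,
) -> ProcessedSpectrum:
    """Align, QC-filter, select-and-average, and background-subtract one sample.

    Normalization happens later, once feature windows exist.  Raises
    :class:`QcFailure` when too few spectra survive QC.
    """
    aligned, flags = align_spectra(spectra, anchors, tolerance=cfg.align_tolerance)
    qc = replace(cfg.qc, anchors=tuple(anchors)) if not cfg.qc.anchors else cfg.qc
    passing, rejections = qc_filter(aligned, qc)
    avg = select_and_average(passing, cfg.n_select, rng)
    avg = replace(
        avg,
        provenance=(
            ("align", {"anchors": tuple(anchors), "n_unaligned": int(sum(flags))}),
            ("qc", {"n_rejected": len(rejections)}),
        ) + avg.provenance,
    )
    return subtract_background(avg, cfg.background_half_widths)


def build_feature_table(
    spectra_by_sample: Mapping[str, Sequence[ShotSpectrum]],
    afp_by_sample: Mapping[str, CensoredAfp],
    cfg: PipelineConfig,
    *,
    labels: Optional[Mapping[str, bool]] = None,
    batches: Optional[Mapping[str, str]] = None,
    reference_spectra: Optional[Mapping[str, Mapping[str, Sequence[ShotSpectrum]]]] = None,
    feature_defs: Optional[Sequence[FeatureDefinition]] = None,
    dev_ids: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> Tuple[pd.DataFrame, List[FeatureDefinition], List[str]]:
    """Run the full chain over a cohort and return (table, feature defs, qc failures).

    Feature windows are defined on the mean of the development samples'
    background-subtracted spectra (``dev_ids``; all samples if omitted)
    unless ``feature_defs`` is given (the locked-test path).  The returned
    table has one row per sample (plus reference samples when batch
    correction applies), columns = feature ids + ``ln_afp`` (+ ``label``).
    """
    rng = np.random.default_rng(seed)
    anchors = cfg.anchors or _auto_anchors(spectra_by_sample, cfg.n_anchors_auto)

    processed: Dict[str, ProcessedSpectrum] = {}
    qc_failures: List[str] = []
    for sid, specs in spectra_by_sample.items():
        try:
            processed[sid] = process_sample(specs, cfg, anchors, rng)
        except QcFailure:
            qc_failures.append(sid)

    ref_processed: Dict[str, ProcessedSpectrum] = {}
    ref_batches: Dict[str, str] = {}
    if reference_spectra:
        for batch, refs in reference_spectra.items():
            for rid, specs in refs.items():
                ref_processed[rid] = process_sample(specs, cfg, anchors, rng)
                ref_batches[rid] = batch

    if feature_defs is None:
        ids = list(dev_ids) if dev_ids is not None else list(processed)
        ids = [i for i in ids if i in processed]
        if not ids:
            raise QcFailure("no processed development spectra to define features on")
        grid = processed[ids[0]].mz
        mean_int = np.mean([processed[i].intensity for i in ids], axis=0)
        mean_spec = ProcessedSpectrum(grid, mean_int, "dev_mean",
                                      provenance=(("background", {}),))
        feature_defs = define_features(mean_spec, cfg.n_features)
    defs = list(feature_defs)

    rows = {}
    for sid, spec in {**processed, **ref_processed}.items():
        normed = normalize_spectrum(spec, defs)
        afp = afp_by_sample.get(sid, CensoredAfp(1.0))
        fv = extract_features(normed, defs, afp)
        row = dict(fv.ms_features)
        row["ln_afp"] = fv.ln_afp
        row["_norm_factor"] = normed.normalization_factor
        row["_steps"] = ",".join(normed.steps)
        rows[sid] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    meta = table[["_norm_factor", "_steps"]]
    table = table.drop(columns=["_norm_factor", "_steps"])

    if batches and ref_processed:
        all_batches = {**dict(batches), **ref_batches}
        by_batch: Dict[str, List[str]] = {}
        for rid, b in ref_batches.items():
            by_batch.setdefault(b, []).append(rid)
        feature_cols = [d.feature_id for d in defs]
        table, factors = batch_correct(
            table, all_batches, by_batch, feature_columns=feature_cols
        )
        table.attrs["batch_factors"] = factors
        meta = meta.copy()
        meta["_steps"] = meta["_steps"] + ",batch_correct"
    table = table.drop(index=[r for r in ref_processed if r in table.index])

    if labels is not None:
        table["label"] = pd.Series({s: bool(labels[s]) for s in table.index if s in labels})
    table.attrs["provenance"] = meta
    table.attrs["qc_failures"] = qc_failures
    table.attrs["anchors"] = tuple(anchors)
    return table, defs, qc_failures
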