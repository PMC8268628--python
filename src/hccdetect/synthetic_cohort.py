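"""Synthetic Deep-MALDI serum cohorts.

The real serum cohorts behind the HCC detection test are not public, so this
module generates virtual cohorts with the statistical structure the analysis
assumes: Gaussian peaks on a decaying baseline, a block of "informative"
peaks whose intensities differ between HCC and non-HCC samples, an
"acute-phase" peak block driven by a latent liver-function score that can be
correlated with disease status (the confounding present in transplant
cohorts, where non-HCC transplant candidates have far worse liver function
than early-HCC patients), per-batch gain and m/z-offset shifts, and
class-conditional log-normal AFP with assay censoring.

Shot-level acquisition is collapsed: the instrument collects 800 laser shots
at each of 63 raster positions on each of 3 spots (151,200 shots/sample);
here each 800-shot aggregate is simulated directly as one ``ShotSpectrum``
(189 per sample at defaults), which preserves all downstream averaging
behaviour at desk-scale runtime.
"""

from __future__ import annotations

import csv
import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
from scipy.stats import norm

from .afp import CensoredAfp, DEFAULT_LOWER_BOUND, DEFAULT_UPPER_BOUND

__all__ = [
    "AfpParams",
    "BatchShift",
    "CohortConfig",
    "SampleRecord",
    "ShotSpectrum",
    "Cohort",
    "ConfigurationError",
    "generate_cohort",
    "simulate_afp",
    "render_shot_spectrum",
    "write_cohort",
    "read_spectrum_csv",
    "read_spectra_mzml",
]


class ConfigurationError(ValueError):
    """Raised for invalid simulator configuration."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _default_hcc_sigma(median: float = 10.0, frac_over_100: float = 0.25) -> float:
    # log-normal scale such that P(AFP > 100) = frac_over_100 given the median
    z = norm.ppf(1.0 - frac_over_100)
    return math.log(100.0 / median) / z


@dataclass(frozen=True)
class AfpParams:
    """Class-conditional log-normal AFP (ng/mL) with assay censoring.

    Defaults put the No-HCC median at 2.0 ng/mL and the HCC median at
    10 ng/mL with 25% of HCC draws exceeding 100 ng/mL.  Healthy subjects
    use the No-HCC parameters.
    """

    no_hcc_mu: float = math.log(2.0)
    no_hcc_sigma: float = 1.2
    hcc_mu: float = math.log(10.0)
    hcc_sigma: float = field(default_factory=_default_hcc_sigma)
    # healthy volunteers (no liver disease) have a much tighter AFP
    # distribution than cirrhotic non-HCC patients
    healthy_mu: float = math.log(2.6)
    healthy_sigma: float = 0.65
    lower_bound: float = DEFAULT_LOWER_BOUND
    upper_bound: float = DEFAULT_UPPER_BOUND

    def frac_hcc_over(self, cutoff: float) -> float:
        """Closed-form fraction of HCC draws above ``cutoff`` ng/mL."""
        if self.hcc_sigma == 0:
            return float(math.exp(self.hcc_mu) > cutoff)
        return float(norm.sf((math.log(cutoff) - self.hcc_mu) / self.hcc_sigma))


@dataclass(frozen=True)
class BatchShift:
    """Multiplicative intensity gain and additive m/z offset for one batch."""

    gain: float = 1.0
    mz_offset: float = 0.0


@dataclass(frozen=True)
class CohortConfig:
    n_hcc: int = 0
    n_no_hcc: int = 0
    n_healthy: int = 0
    n_positions: int = 63
    shots_per_position: int = 800
    n_spots: int = 3
    mz_range: Tuple[float, float] = (3000.0, 30000.0)
    mz_step: float = 1.0
    n_peaks: int = 300
    n_informative: int = 30
    n_acute_phase: int = 20
    class_effect: float = 0.0            # log-fold shift of informative peaks in HCC
    confounder_effect: float = 0.0       # log-fold shift of acute-phase peaks per unit score
    confounder_class_correlation: float = 0.0
    sample_log_sigma: float = 0.3        # between-sample biological variation (log scale)
    shot_log_sigma: float = 0.05         # residual variation of an 800-shot aggregate
    noise_floor: float = 0.5             # additive noise sd (arbitrary units)
    noise_rel: float = 0.02              # heteroscedastic component: sd += rel*sqrt(signal)
    baseline_amp: float = 20.0
    baseline_decay: float = 5000.0       # Da
    peak_resolution: float = 2000.0      # sigma = mz / resolution
    batch_shifts: Mapping[str, BatchShift] = field(
        default_factory=lambda: {"batch0": BatchShift()}
    )
    n_reference_per_batch: int = 2
    afp_params: AfpParams = field(default_factory=AfpParams)
    afp_hcc_signal: bool = True          # False -> HCC draws use No-HCC parameters
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hcc, self.n_no_hcc, self.n_healthy) < 0:
            raise ConfigurationError("cohort counts must be nonnegative")
        if not self.mz_range[0] < self.mz_range[1]:
            raise ConfigurationError("mz_range lower bound must be below upper bound")
        if not -1.0 <= self.confounder_class_correlation <= 1.0:
            raise ConfigurationError("confounder_class_correlation must lie in [-1, 1]")
        if self.n_informative + self.n_acute_phase > self.n_peaks:
            raise ConfigurationError("informative + acute-phase peaks exceed n_peaks")

    @property
    def spectra_per_sample(self) -> int:
        return self.n_positions * self.n_spots

    @property
    def shots_per_sample(self) -> int:
        return self.n_positions * self.shots_per_position * self.n_spots

    @property
    def mz_grid(self) -> np.ndarray:
        lo, hi = self.mz_range
        n = int(round((hi - lo) / self.mz_step)) + 1
        return lo + self.mz_step * np.arange(n)


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    cohort: str
    batch: str
    hcc: bool
    afp: CensoredAfp
    lesion_size_cm: Optional[float] = None
    bclc: Optional[str] = None
    child_pugh: Optional[str] = None
    meld: Optional[float] = None
    etiology: str = "other/NA"
    liver_function_score: Optional[float] = None  # latent; synthetic only

    def __post_init__(self) -> None:
        if self.lesion_size_cm is not None and not self.hcc:
            raise ValueError("lesion_size_cm only applies to HCC samples")


@dataclass(frozen=True)
class ShotSpectrum:
    """One acquisition aggregate: m/z and intensity arrays with position metadata."""

    mz: np.ndarray
    intensity: np.ndarray
    position_index: int
    spot_index: int
    sample_id: str
    n_shots: int = 800

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.shape != inten.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if mz.size >= 2 and not np.all(np.diff(mz) > 0):
            raise ValueError("mz must be strictly increasing")
        if not np.all(np.isfinite(inten)) or np.any(inten < 0):
            raise ValueError("intensities must be finite and nonnegative")


@dataclass(frozen=True)
class PeakGroundTruth:
    """What the generator planted; consumed by tests and the surrogate pre-classifier."""

    centers: np.ndarray           # m/z of every base peak
    base_log_amp: np.ndarray
    sigmas: np.ndarray
    informative: np.ndarray       # indices of class-effect peaks
    acute_phase: np.ndarray       # indices of liver-function peaks


@dataclass
class Cohort:
    records: List[SampleRecord]
    spectra: Dict[str, List[ShotSpectrum]]
    reference_spectra: Dict[str, Dict[str, List[ShotSpectrum]]]  # batch -> ref id -> spectra
    ground_truth: PeakGroundTruth
    config: CohortConfig

    @property
    def batches(self) -> Dict[str, str]:
        return {r.sample_id: r.batch for r in self.records}


# ---------------------------------------------------------------------------
# spectrum rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrumParams:
    """Noise/baseline/grid parameters passed to :func:`render_shot_spectrum`."""

    mz_grid: np.ndarray
    baseline_amp: float = 0.0
    baseline_decay: float = 5000.0
    noise_floor: float = 0.0
    noise_rel: float = 0.0
    mz_offset: float = 0.0
    gain: float = 1.0


def render_shot_spectrum(
    peaks: Tuple[np.ndarray, np.ndarray, np.ndarray],
    params: SpectrumParams,
    rng: np.random.Generator,
    *,
    position_index: int = 0,
    spot_index: int = 0,
    sample_id: str = "",
    n_shots: int = 800,
) -> ShotSpectrum:
    """Render one acquisition: Gaussian peaks + exponential baseline + noise.

    ``peaks`` is (centers, amplitudes, sigmas); amplitudes are peak *areas*
    so a window integral over a well-isolated peak recovers the amplitude.
    The batch m/z offset shifts peak centers relative to the fixed grid.
    """
    centers, amps, sigmas = (np.asarray(a, dtype=float) for a in peaks)
    grid = np.asarray(params.mz_grid, dtype=float)
    lo, hi = grid[0], grid[-1]
    if centers.size and (centers.min() < lo or centers.max() > hi):
        raise ConfigurationError("peak centre outside the configured m/z range")

    intensity = np.zeros_like(grid)
    shifted = centers + params.mz_offset
    for c, a, s in zip(shifted, amps, sigmas):
        i0, i1 = np.searchsorted(grid, [c - 6 * s, c + 6 * s])
        if i0 >= i1:
            continue
        g = grid[i0:i1]
        intensity[i0:i1] += a / (s * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((g - c) / s) ** 2
        )
    if params.baseline_amp:
        intensity += params.baseline_amp * np.exp(-(grid - lo) / params.baseline_decay)
    intensity *= params.gain
    if params.noise_floor or params.noise_rel:
        sd = params.noise_floor + params.noise_rel * np.sqrt(np.maximum(intensity, 0.0))
        intensity = intensity + rng.normal(0.0, 1.0, size=grid.size) * sd
    intensity = np.maximum(intensity, 0.0)
    return ShotSpectrum(grid, intensity, position_index, spot_index, sample_id, n_shots)


# ---------------------------------------------------------------------------
# AFP
# ---------------------------------------------------------------------------

def simulate_afp(
    hcc: bool,
    liver_function_score: float,
    rng: np.random.Generator,
    params: Optional[AfpParams] = None,
    *,
    hcc_signal: bool = True,
    healthy: bool = False,
) -> CensoredAfp:
    """Draw a censored AFP value from the class-conditional log-normal.

    ``liver_function_score`` is accepted for interface symmetry with the rest
    of the generator; AFP is class-conditional only by default.
    """
    p = params or AfpParams()
    if hcc and hcc_signal:
        mu, sigma = p.hcc_mu, p.hcc_sigma
    elif healthy:
        mu, sigma = p.healthy_mu, p.healthy_sigma
    else:
        mu, sigma = p.no_hcc_mu, p.no_hcc_sigma
    value = math.exp(mu + sigma * rng.standard_normal())
    if value < p.lower_bound:
        return CensoredAfp(p.lower_bound, "lt")
    if value >= p.upper_bound:
        return CensoredAfp(p.upper_bound, "ge")
    return CensoredAfp(value)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _draw_peak_ground_truth(cfg: CohortConfig, rng: np.random.Generator) -> PeakGroundTruth:
    lo, hi = cfg.mz_range
    # keep peaks 6 sigma clear of the grid edges so rendering never truncates
    margin = 6.0 * hi / cfg.peak_resolution
    # jittered stratified placement: one peak per equal-width slot with the
    # jitter bounded so neighbouring peaks stay resolvable (feature windows
    # would otherwise merge and silently dilute planted effects)
    slot = (hi - lo - 2 * margin) / cfg.n_peaks
    jitter = rng.uniform(0.15, 0.85, size=cfg.n_peaks)
    centers = lo + margin + (np.arange(cfg.n_peaks) + jitter) * slot
    base_log_amp = rng.normal(math.log(300.0), 0.8, size=cfg.n_peaks)
    sigmas = centers / cfg.peak_resolution
    order = rng.permutation(cfg.n_peaks)
    informative = np.sort(order[: cfg.n_informative])
    acute = np.sort(order[cfg.n_informative : cfg.n_informative + cfg.n_acute_phase])
    return PeakGroundTruth(centers, base_log_amp, sigmas, informative, acute)


def _liver_function_scores(
    hcc_flags: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Latent liver-function score with point-biserial correlation ``rho`` to HCC.

    Higher score = worse liver function. Negative rho reproduces transplant-like
    cohorts where non-HCC patients are sicker than early-HCC patients.
    """
    x = hcc_flags.astype(float)
    p = x.mean()
    n = x.size
    z = rng.standard_normal(n)
    if n == 0 or p in (0.0, 1.0) or rho == 0.0:
        return z
    centered = (x - p) / math.sqrt(p * (1 - p))
    return rho * centered + math.sqrt(max(1 - rho**2, 0.0)) * z


def _clinical_covariates(
    hcc: bool, lfs: float, rng: np.random.Generator
) -> Dict[str, object]:
    meld = float(np.clip(14.0 + 6.0 * lfs + rng.normal(0, 3), 6, 47))
    if lfs < 0.2:
        cp = "A"
    elif lfs < 1.0:
        cp = "B"
    else:
        cp = "C"
    etiology = rng.choice(["HBV", "HCV", "other/NA"], p=[0.40, 0.27, 0.33])
    out: Dict[str, object] = {"meld": meld, "child_pugh": cp, "etiology": str(etiology)}
    if hcc:
        size = float(np.clip(math.exp(rng.normal(math.log(5.0), 0.6)), 0.5, 25.0))
        out["lesion_size_cm"] = size if rng.random() > 0.2 else None
        out["bclc"] = str(rng.choice(["A", "B", "C", "D"], p=[0.32, 0.10, 0.45, 0.13]))
    return out


def _sample_log_amplitudes(
    cfg: CohortConfig,
    truth: PeakGroundTruth,
    hcc: bool,
    lfs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    log_amp = truth.base_log_amp + rng.normal(0.0, cfg.sample_log_sigma, cfg.n_peaks)
    if hcc and cfg.class_effect:
        log_amp[truth.informative] += cfg.class_effect
    if cfg.confounder_effect:
        log_amp[truth.acute_phase] += cfg.confounder_effect * lfs
    return log_amp


def _render_sample_spectra(
    cfg: CohortConfig,
    truth: PeakGroundTruth,
    log_amp: np.ndarray,
    batch: BatchShift,
    sample_id: str,
    rng: np.random.Generator,
    grid: np.ndarray,
) -> List[ShotSpectrum]:
    spectra = []
    for pos in range(cfg.n_positions):
        for spot in range(cfg.n_spots):
            amps = np.exp(log_amp + rng.normal(0.0, cfg.shot_log_sigma, cfg.n_peaks))
            params = SpectrumParams(
                mz_grid=grid,
                baseline_amp=cfg.baseline_amp,
                baseline_decay=cfg.baseline_decay,
                noise_floor=cfg.noise_floor,
                noise_rel=cfg.noise_rel,
                mz_offset=batch.mz_offset,
                gain=batch.gain,
            )
            spectra.append(
                render_shot_spectrum(
                    (truth.centers, amps, truth.sigmas),
                    params,
                    rng,
                    position_index=pos,
                    spot_index=spot,
                    sample_id=sample_id,
                    n_shots=cfg.shots_per_position,
                )
            )
    return spectra


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a reproducible virtual cohort of clinical records and spectra."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    truth = _draw_peak_ground_truth(cfg, rng)
    grid = cfg.mz_grid
    batch_names = list(cfg.batch_shifts)

    groups = (
        [("HCC", True)] * cfg.n_hcc
        + [("NoHCC", False)] * cfg.n_no_hcc
        + [("Healthy", False)] * cfg.n_healthy
    )
    n = len(groups)
    # confounder applies to the patient cohorts; healthy volunteers sit at the
    # population baseline (mean-zero liver function, uncorrelated with class)
    patient_mask = np.array([g != "Healthy" for g, _ in groups], dtype=bool)
    hcc_flags = np.array([h for _, h in groups], dtype=bool)
    lfs = np.empty(n)
    lfs[patient_mask] = _liver_function_scores(
        hcc_flags[patient_mask], cfg.confounder_class_correlation, rng
    )
    lfs[~patient_mask] = rng.standard_normal((~patient_mask).sum()) - 0.5

    records: List[SampleRecord] = []
    spectra: Dict[str, List[ShotSpectrum]] = {}
    for i, (cohort_name, hcc) in enumerate(groups):
        sid = f"S{i:04d}"
        batch_name = batch_names[i % len(batch_names)]
        batch = cfg.batch_shifts[batch_name]
        afp = simulate_afp(hcc, lfs[i], rng, cfg.afp_params,
                           hcc_signal=cfg.afp_hcc_signal,
                           healthy=cohort_name == "Healthy")
        cov = _clinical_covariates(hcc, lfs[i], rng) if cohort_name != "Healthy" else {}
        records.append(
            SampleRecord(
                sample_id=sid,
                cohort=cohort_name,
                batch=batch_name,
                hcc=hcc,
                afp=afp,
                liver_function_score=float(lfs[i]),
                **cov,
            )
        )
        log_amp = _sample_log_amplitudes(cfg, truth, hcc, lfs[i], rng)
        spectra[sid] = _render_sample_spectra(cfg, truth, log_amp, batch, sid, rng, grid)

    # reference material: one shared aliquot pool rendered in every batch
    ref_log_amp = truth.base_log_amp.copy()
    reference: Dict[str, Dict[str, List[ShotSpectrum]]] = {}
    for batch_name in batch_names:
        batch = cfg.batch_shifts[batch_name]
        reference[batch_name] = {}
        for j in range(cfg.n_reference_per_batch):
            rid = f"REF_{batch_name}_{j}"
            noisy = ref_log_amp + rng.normal(0.0, cfg.sample_log_sigma / 4, cfg.n_peaks)
            reference[batch_name][rid] = _render_sample_spectra(
                cfg, truth, noisy, batch, rid, rng, grid
            )

    return Cohort(records, spectra, reference, truth, cfg)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MANIFEST_FIELDS = [
    "sample_id", "cohort", "batch", "hcc", "afp_ng_ml", "lesion_size_cm",
    "bclc", "child_pugh", "meld", "etiology", "liver_function_score",
]


def write_cohort(cohort: Cohort, out_dir: Path, *, gzip_spectra: bool = True) -> None:
    """Write the manifest CSV and per-sample two-column spectrum CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.csv", "w", newline="") as fh:
        fh.write(f"# seed={cohort.config.seed}\n")
        w = csv.DictWriter(fh, fieldnames=_MANIFEST_FIELDS)
        w.writeheader()
        for r in cohort.records:
            w.writerow(
                {
                    "sample_id": r.sample_id,
                    "cohort": r.cohort,
                    "batch": r.batch,
                    "hcc": int(r.hcc),
                    "afp_ng_ml": str(r.afp),
                    "lesion_size_cm": "" if r.lesion_size_cm is None else f"{r.lesion_size_cm:.2f}",
                    "bclc": r.bclc or "",
                    "child_pugh": r.child_pugh or "",
                    "meld": "" if r.meld is None else f"{r.meld:.1f}",
                    "etiology": r.etiology,
                    "liver_function_score": "" if r.liver_function_score is None
                    else f"{r.liver_function_score:.4f}",
                }
            )
    for sid, specs in cohort.spectra.items():
        sdir = out / sid
        sdir.mkdir(exist_ok=True)
        for s in specs:
            name = f"pos{s.position_index:03d}_spot{s.spot_index}.csv"
            write_spectrum_csv(s, sdir / (name + (".gz" if gzip_spectra else "")))


def write_spectrum_csv(spectrum: ShotSpectrum, path: Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["mz", "intensity"])
        for m, i in zip(spectrum.mz, spectrum.intensity):
            w.writerow([f"{m:.6g}", f"{i:.6g}"])


def read_spectrum_csv(path: Path, *, sample_id: str = "", position_index: int = 0,
                      spot_index: int = 0) -> ShotSpectrum:
    """Read a two-column (mz, intensity) CSV, optionally gzipped."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    mz, inten = [], []
    with opener(path, "rt") as fh:
        for row in csv.reader(fh):
            if not row or not row[0] or row[0].startswith("#"):
                continue
            try:
                m = float(row[0])
            except ValueError:
                continue  # header line
            mz.append(m)
            inten.append(float(row[1]))
    return ShotSpectrum(np.array(mz), np.array(inten), position_index, spot_index, sample_id)


def read_spectra_mzml(path: Path, *, sample_id: str = "") -> List[ShotSpectrum]:
    """Read all spectra from an mzML file via pyteomics."""
    from pyteomics import mzml as _mzml

    out: List[ShotSpectrum] = []
    with _mzml.read(str(path)) as reader:
        for k, entry in enumerate(reader):
            out.append(
                ShotSpectrum(
                    np.asarray(entry["m/z array"], dtype=float),
                    np.maximum(np.asarray(entry["intensity array"], dtype=float), 0.0),
                    position_index=k,
                    spot_index=0,
                    sample_id=sample_id or entry.get("id", f"scan{k}"),
                )
            )
    return out
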