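import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from hccdetect.afp import CensoredAfp, parse_afp
from hccdetect.spectral_processing import (
    FeatureDefinition,
    InputError,
    PipelineConfig,
    ProcessedSpectrum,
    QcCriteria,
    QcFailure,
    align_spectra,
    batch_correct,
    build_feature_table,
    define_features,
    extract_features,
    normalize_spectrum,
    qc_filter,
    select_and_average,
    select_top_features,
    subtract_background,
    window_integral,
)
from hccdetect.synthetic_cohort import ShotSpectrum, generate_cohort

from conftest import gaussian_spectrum, tiny_cohort_config


def shift_spectrum(s: ShotSpectrum, delta: float) -> ShotSpectrum:
    """A copy of s with every structure moved by delta Da (same grid)."""
    return ShotSpectrum(
        s.mz, np.interp(s.mz, s.mz + delta, s.intensity),
        s.position_index, s.spot_index, s.sample_id,
    )


def peak_position(s, near: float, window: float = 100.0) -> float:
    m = (s.mz >= near - window) & (s.mz <= near + window)
    return float(s.mz[m][np.argmax(s.intensity[m])])


class TestAlign:
    anchors = (4000.0, 6000.0)

    def fixture_spectrum(self, **kw):
        return gaussian_spectrum(
            [4000.0, 5000.0, 6000.0], [100.0, 80.0, 90.0], [4.0, 4.0, 4.0], **kw
        )

    def test_already_aligned_identity(self):
        s = self.fixture_spectrum()
        (out,), flags = align_spectra([s], self.anchors)
        assert flags == [False]
        assert np.max(np.abs(out.intensity - s.intensity)) < 1e-9 * s.intensity.max()

    def test_uniform_offset_removed(self):
        s = shift_spectrum(self.fixture_spectrum(), 6.0)
        assert peak_position(s, 4000) == pytest.approx(4006.0, abs=1.5)
        (out,), flags = align_spectra([s], self.anchors)
        assert flags == [False]
        for a in self.anchors:
            assert peak_position(out, a) == pytest.approx(a, abs=0.5)

    def test_two_anchor_linear_interpolation(self):
        # anchors moved by +8 and +2; the midpoint peak at 5000 should come
        # back by the interpolated offset (8+2)/2 = 5
        s = self.fixture_spectrum()
        warped = ShotSpectrum(
            s.mz,
            np.interp(s.mz, np.interp(s.mz, [3000, 4000, 6000, 8000],
                                      [3008, 4008, 6002, 8002]), s.intensity),
            0, 0, s.sample_id,
        )
        (out,), _ = align_spectra([warped], self.anchors)
        assert peak_position(out, 4000) == pytest.approx(4000, abs=1.0)
        assert peak_position(out, 6000) == pytest.approx(6000, abs=1.0)
        assert peak_position(out, 5000) == pytest.approx(5000, abs=1.5)

    def test_anchorless_spectrum_flagged_unchanged(self):
        flat = ShotSpectrum(np.arange(3000.0, 8000.0), np.ones(5000), 0, 0, "flat")
        (out,), flags = align_spectra([flat], self.anchors)
        assert flags == [True]
        assert np.array_equal(out.intensity, flat.intensity)

    def test_empty_inputs_rejected(self):
        with pytest.raises(InputError):
            align_spectra([], self.anchors)
        with pytest.raises(InputError):
            align_spectra([self.fixture_spectrum()], [])


class TestQcFilter:
    def test_all_zero_spectrum_rejected(self):
        good = gaussian_spectrum([5000.0], [100.0], [4.0])
        zero = ShotSpectrum(good.mz, np.zeros_like(good.intensity), 1, 0, "z")
        passing, log = qc_filter([good, good, good, zero], QcCriteria())
        assert len(passing) == 3
        assert log[0][0] == 3 and "ion current" in log[0][1]

    def test_vacuous_thresholds_pass_everything(self):
        good = gaussian_spectrum([5000.0], [100.0], [4.0])
        zero = ShotSpectrum(good.mz, np.zeros_like(good.intensity), 1, 0, "z")
        passing, log = qc_filter(
            [good, zero], QcCriteria(min_tic=0, min_tic_frac_median=0, min_anchor_snr=0)
        )
        assert len(passing) == 2 and log == []

    def test_attenuated_spectra_exactly_rejected(self):
        rng = np.random.default_rng(0)
        spectra = []
        weak = set()
        for i in range(20):
            scale = 0.01 if i % 10 == 9 else 1.0
            if scale < 1:
                weak.add(i)
            s = gaussian_spectrum([5000.0], [100.0 * scale], [4.0],
                                  noise=0.0, seed=i)
            spectra.append(ShotSpectrum(s.mz, s.intensity, i, 0, "s"))
        passing, log = qc_filter(spectra, QcCriteria())
        assert {i for i, _ in log} == weak
        assert len(passing) == 18


class TestSelectAndAverage:
    def test_mean_of_identical_is_identity(self, rng):
        s = gaussian_spectrum([5000.0], [100.0], [4.0])
        avg = select_and_average([s] * 140, 140, rng)
        assert np.allclose(avg.intensity, s.intensity)
        assert avg.steps == ("average",)

    def test_insufficient_spectra_is_sample_qc_failure(self, rng):
        s = gaussian_spectrum([5000.0], [100.0], [4.0])
        with pytest.raises(QcFailure):
            select_and_average([s] * 139, 140, rng)

    def test_two_spectrum_mean(self, rng):
        a = gaussian_spectrum([5000.0], [100.0], [4.0])
        b = ShotSpectrum(a.mz, a.intensity * 3.0, 1, 0, "b")
        avg = select_and_average([a, b], 2, rng)
        assert np.allclose(avg.intensity, 2.0 * a.intensity)


class TestBackground:
    def base(self, intensity, mz=None):
        mz = np.arange(3000.0, 8000.0) if mz is None else mz
        return ProcessedSpectrum(mz, intensity, "s")

    def test_flat_spectrum_fully_removed(self):
        s = self.base(np.full(5000, 7.0))
        out = subtract_background(s, (250.0, 50.0))
        assert np.allclose(out.intensity, 0.0)

    def test_gaussian_area_preserved(self):
        g = gaussian_spectrum([5000.0], [120.0], [4.0])
        s = self.base(g.intensity, g.mz)
        out = subtract_background(s, (100.0, 20.0))  # window 25x peak sigma
        before = window_integral(g.mz, g.intensity, 4960, 5040)
        after = window_integral(out.mz, out.intensity, 4960, 5040)
        assert after == pytest.approx(before, rel=0.01)

    def test_gaussian_on_ramp_recovered(self):
        g = gaussian_spectrum([5000.0], [120.0], [4.0])
        ramp = 5.0 + (g.mz - g.mz[0]) * 2e-3
        s = self.base(g.intensity + ramp, g.mz)
        out = subtract_background(s, (100.0, 20.0))
        pure = window_integral(g.mz, g.intensity, 4960, 5040)
        corrected = window_integral(out.mz, out.intensity, 4960, 5040)
        assert corrected == pytest.approx(pure, rel=0.02)

    def test_oversized_window_rejected(self):
        s = self.base(np.ones(100), np.arange(3000.0, 3100.0))
        with pytest.raises(InputError):
            subtract_background(s, (500.0, 50.0))


class TestNormalize:
    windows = [FeatureDefinition("a", 4900.0, 5100.0),
               FeatureDefinition("b", 6000.0, 6100.0)]

    def test_partial_ion_current_becomes_one(self):
        g = gaussian_spectrum([5000.0, 6050.0], [100.0, 40.0], [4.0, 4.0])
        out = normalize_spectrum(ProcessedSpectrum(g.mz, g.intensity, "s"), self.windows)
        total = sum(window_integral(out.mz, out.intensity, w.mz_left, w.mz_right)
                    for w in self.windows)
        assert total == pytest.approx(1.0, abs=1e-12)
        assert out.normalization_factor > 0

    def test_scale_invariance(self):
        g = gaussian_spectrum([5000.0, 6050.0], [100.0, 40.0], [4.0, 4.0])
        a = normalize_spectrum(ProcessedSpectrum(g.mz, g.intensity, "s"), self.windows)
        b = normalize_spectrum(ProcessedSpectrum(g.mz, 7.0 * g.intensity, "s"), self.windows)
        assert np.allclose(a.intensity, b.intensity)

    def test_factor_blind_to_outside_windows(self):
        g = gaussian_spectrum([5000.0, 6050.0], [100.0, 40.0], [4.0, 4.0])
        extra = gaussian_spectrum([7000.0], [55.0], [4.0])
        a = normalize_spectrum(ProcessedSpectrum(g.mz, g.intensity, "s"), self.windows)
        b = normalize_spectrum(
            ProcessedSpectrum(g.mz, g.intensity + extra.intensity, "s"), self.windows
        )
        assert a.normalization_factor == pytest.approx(b.normalization_factor, rel=1e-9)

    def test_zero_signal_is_qc_failure(self):
        s = ProcessedSpectrum(np.arange(3000.0, 8000.0), np.zeros(5000), "s")
        with pytest.raises(QcFailure):
            normalize_spectrum(s, self.windows)


class TestBatchCorrect:
    def table(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(
            rng.uniform(1, 2, size=(8, 3)),
            index=[f"S{i}" for i in range(6)] + ["REF_A", "REF_B"],
            columns=["F1", "F2", "F3"],
        )
        data.loc["REF_B"] = data.loc["REF_A"] * 2.0  # batch B doubles everything
        data.loc[["S3", "S4", "S5"]] *= 2.0
        batches = {f"S{i}": ("A" if i < 3 else "B") for i in range(6)}
        batches.update({"REF_A": "A", "REF_B": "B"})
        refs = {"A": ["REF_A"], "B": ["REF_B"]}
        return data, batches, refs

    def test_single_batch_identity(self):
        data, _, _ = self.table()
        corrected, factors = batch_correct(
            data, {i: "A" for i in data.index}, {"A": ["REF_A", "REF_B"]}
        )
        assert np.allclose(factors.to_numpy(), 1.0)
        assert np.allclose(corrected.to_numpy(), data.to_numpy())

    def test_double_intensity_batch_halved(self):
        data, batches, refs = self.table()
        corrected, factors = batch_correct(data, batches, refs)
        # B's factor relative to A's is exactly 1/2
        assert np.allclose(factors.loc["B"] / factors.loc["A"], 0.5)
        assert np.allclose(corrected.loc["REF_A"], corrected.loc["REF_B"])

    def test_idempotent(self):
        data, batches, refs = self.table()
        once, _ = batch_correct(data, batches, refs)
        twice, factors2 = batch_correct(once, batches, refs)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), rtol=1e-12)
        assert np.allclose(factors2.to_numpy(), 1.0, rtol=1e-10)

    def test_reference_means_equalized(self):
        data, batches, refs = self.table()
        corrected, _ = batch_correct(data, batches, refs)
        a = corrected.loc[refs["A"]].mean()
        b = corrected.loc[refs["B"]].mean()
        assert np.allclose(a, b, rtol=1e-10)

    def test_missing_references_rejected(self):
        data, batches, _ = self.table()
        with pytest.raises(InputError):
            batch_correct(data, batches, {"A": ["REF_A"]})


class TestDefineFeatures:
    def test_separated_peaks_one_window_each(self):
        centers = np.linspace(3500, 7500, 25)
        g = gaussian_spectrum(centers, np.full(25, 100.0), np.full(25, 4.0))
        defs = define_features(ProcessedSpectrum(g.mz, g.intensity, "m"), 25)
        assert len(defs) == 25
        for d, c in zip(defs, centers):
            assert d.mz_left < c < d.mz_right

    def test_close_peaks_share_boundary_at_minimum(self):
        g = gaussian_spectrum([5000.0, 5012.0], [100.0, 80.0], [4.0, 4.0])
        defs = define_features(ProcessedSpectrum(g.mz, g.intensity, "m"), 2)
        left, right = sorted(defs, key=lambda d: d.mz_left)
        assert left.mz_right == right.mz_left  # disjoint, shared boundary
        between = (g.mz >= 5000) & (g.mz <= 5012)
        valley = g.mz[between][np.argmin(g.intensity[between])]
        assert left.mz_right == pytest.approx(valley, abs=1.0)

    def test_too_few_peaks_warns(self):
        centers = np.linspace(3500, 7500, 10)
        g = gaussian_spectrum(centers, np.full(10, 100.0), np.full(10, 4.0))
        with pytest.warns(UserWarning, match="10 of the requested 300"):
            defs = define_features(ProcessedSpectrum(g.mz, g.intensity, "m"), 300)
        assert len(defs) == 10


class TestExtractFeatures:
    def test_unit_intensity_rectangle(self):
        mz = np.arange(3000.0, 3100.0)
        s = ProcessedSpectrum(mz, np.ones_like(mz), "s")
        fv = extract_features(s, [FeatureDefinition("w", 3010.0, 3015.0)],
                              CensoredAfp(2.0))
        assert fv.ms_features["w"] == pytest.approx(5.0)

    @given(split=st.floats(3020.0, 3080.0))
    @settings(max_examples=30, deadline=None)
    def test_additive_over_adjacent_windows(self, split):
        rng = np.random.default_rng(7)
        mz = np.arange(3000.0, 3101.0)
        s = ProcessedSpectrum(mz, rng.uniform(0, 5, mz.size), "s")
        merged = window_integral(mz, s.intensity, 3010.0, 3090.0)
        parts = (window_integral(mz, s.intensity, 3010.0, split)
                 + window_integral(mz, s.intensity, split, 3090.0))
        assert parts == pytest.approx(merged, rel=1e-9)

    def test_censored_afp_mappings(self):
        mz = np.arange(3000.0, 3100.0)
        s = ProcessedSpectrum(mz, np.ones_like(mz), "s")
        defs = [FeatureDefinition("w", 3010.0, 3015.0)]
        assert extract_features(s, defs, parse_afp(">=10000")).ln_afp == pytest.approx(
            np.log(10_000.0))
        assert extract_features(s, defs, parse_afp("<0.8")).ln_afp == pytest.approx(
            np.log(0.4))

    def test_window_outside_span_rejected(self):
        mz = np.arange(3000.0, 3100.0)
        s = ProcessedSpectrum(mz, np.ones_like(mz), "s")
        with pytest.raises(InputError):
            extract_features(s, [FeatureDefinition("w", 2000.0, 2005.0)],
                             CensoredAfp(2.0))


class TestSelectTopFeatures:
    def make_table(self, rng, n=40, p=12):
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"F{i:02d}" for i in range(p)])
        X["label"] = np.arange(n) % 2 == 0
        return X

    def test_perfect_separator_ranked_first(self, rng):
        t = self.make_table(rng)
        t["F05"] = t["label"].astype(float) * 10 + rng.normal(scale=0.01, size=len(t))
        assert select_top_features(t, 3)[0] == "F05"

    def test_identity_when_keeping_all(self, rng):
        t = self.make_table(rng)
        assert set(select_top_features(t, 12)) == {f"F{i:02d}" for i in range(12)}

    def test_ranking_matches_direct_recomputation(self, rng):
        t = self.make_table(rng)
        got = select_top_features(t, 5)
        y = t["label"]
        expected = sorted(
            (c for c in t.columns if c != "label"),
            key=lambda c: (
                mannwhitneyu(t.loc[y, c], t.loc[~y, c], alternative="two-sided").pvalue,
                -abs(2 * mannwhitneyu(t.loc[y, c], t.loc[~y, c],
                                      alternative="two-sided").statistic
                     / (y.sum() * (~y).sum()) + 1) + 2,
                c,
            ),
        )[:5]
        assert got == expected

    def test_single_class_rejected(self, rng):
        t = self.make_table(rng)
        t["label"] = True
        with pytest.raises(InputError):
            select_top_features(t, 3)


class TestEndToEnd:
    def build(self, cohort, scale_sample=None, factor=7.0, feature_defs=None,
              anchors=None):
        spectra = {
            sid: [
                ShotSpectrum(s.mz,
                             s.intensity * (factor if sid == scale_sample else 1.0),
                             s.position_index, s.spot_index, sid)
                for s in specs
            ]
            for sid, specs in cohort.spectra.items()
        }
        afp = {r.sample_id: r.afp for r in cohort.records}
        labels = {r.sample_id: r.hcc for r in cohort.records}
        cfg = PipelineConfig(n_select=3, n_features=20,
                             background_half_widths=(100.0, 20.0),
                             anchors=anchors)
        return build_feature_table(
            spectra, afp, cfg, labels=labels, batches=cohort.batches,
            reference_spectra=cohort.reference_spectra, seed=5,
            feature_defs=feature_defs,
        )

    def test_scale_invariance_of_feature_vectors(self, tiny_cohort):
        # with the processing chain locked (fixed anchors and windows, the
        # situation of an applied test), rescaling one sample's raw
        # intensities leaves every feature vector untouched
        sid = tiny_cohort.records[0].sample_id
        base, defs, _ = self.build(tiny_cohort)
        anchors = base.attrs["anchors"]
        locked, _, _ = self.build(tiny_cohort, feature_defs=defs, anchors=anchors)
        scaled, _, _ = self.build(tiny_cohort, scale_sample=sid,
                                  feature_defs=defs, anchors=anchors)
        pd.testing.assert_frame_equal(locked, scaled, rtol=1e-9)

    def test_provenance_complete_and_ordered(self, tiny_cohort):
        table, defs, fails = self.build(tiny_cohort)
        prov = table.attrs["provenance"]
        for steps in prov["_steps"]:
            assert steps.split(",") == [
                "align", "qc", "average", "background", "normalize", "batch_correct"
            ]
        assert fails == []
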