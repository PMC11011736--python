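import numpy as np
import pytest

from craterspec import (
    CD_LINES,
    CPRCModel,
    EmissionLine,
    ReferenceValues,
    SpectrumSet,
    SyntheticConfig,
    apply_cprc,
    fit_cprc,
    fit_curve,
    generate,
    peak_intensities,
    r2,
    ratio_candidates,
    select_matrix_variables,
    split_by_group,
)
from craterspec.errors import CorrectionError, SelectionError

LINE = EmissionLine("Cd", "I", 228.80)


def _ratio_set(peak_values, background=1.0, p=21):
    """Spectra whose peak bin carries the given values over a flat background."""
    wl = 228.60 + 0.02 * np.arange(p)
    X = np.full((len(peak_values), p), float(background))
    peak_bin = int(np.argmin(np.abs(wl - 228.80)))
    X[:, peak_bin] = peak_values
    return SpectrumSet(X, wl, [f"s{i}" for i in range(len(peak_values))]), peak_bin


def _pearson_loop(b, y):
    bm, ym = b.mean(), y.mean()
    num = sum((bi - bm) * (yi - ym) for bi, yi in zip(b, y))
    den = np.sqrt(sum((bi - bm) ** 2 for bi in b) * sum((yi - ym) ** 2 for yi in y))
    return num / den


class TestRatioCandidates:
    @pytest.mark.parametrize(
        "peaks, refs, expected_r",
        [
            ([1.0, 2.0, 3.0], [10.0, 20.0, 30.0], 1.0),
            ([1.0, 2.0, 3.0], [30.0, 20.0, 10.0], -1.0),
            ([1.0, 2.0, 4.0], [1.0, 2.0, 3.0], 3.0 / np.sqrt(28.0 / 3.0)),
        ],
    )
    def test_correlation_oracle(self, peaks, refs, expected_r):
        ss, peak_bin = _ratio_set(peaks)
        rv = ReferenceValues(np.array(refs), ss.sample_ids)
        cands = ratio_candidates(ss, rv, LINE)
        background_bin = 0  # flat background: B equals the peak intensity there
        assert cands[background_bin].valid
        assert cands[background_bin].r == pytest.approx(expected_r, abs=1e-12)

    def test_matches_bruteforce_pearson(self, rng):
        wl = 228.60 + 0.02 * np.arange(21)
        X = rng.uniform(0.5, 10.0, size=(6, 21))
        ss = SpectrumSet(X, wl, [f"s{i}" for i in range(6)])
        refs = ReferenceValues(rng.uniform(1, 50, 6), ss.sample_ids)
        x_peak = peak_intensities(ss, LINE)
        for c in ratio_candidates(ss, refs, LINE):
            if not c.valid:
                continue
            expected = _pearson_loop(x_peak / X[:, c.j], refs.values)
            assert c.r == pytest.approx(expected, abs=1e-12)

    def test_peak_own_bin_is_invalid(self):
        ss, peak_bin = _ratio_set([5.0, 7.0, 9.0])
        refs = ReferenceValues(np.array([1.0, 2.0, 3.0]), ss.sample_ids)
        cands = ratio_candidates(ss, refs, LINE)
        assert not cands[peak_bin].valid  # B identically 1 there

    def test_constant_references_rejected(self):
        ss, _ = _ratio_set([1.0, 2.0, 3.0])
        refs = ReferenceValues(np.full(3, 5.0), ss.sample_ids)
        with pytest.raises(SelectionError):
            ratio_candidates(ss, refs, LINE)

    def test_two_samples_rejected(self):
        ss, _ = _ratio_set([1.0, 2.0])
        refs = ReferenceValues(np.array([1.0, 2.0]), ss.sample_ids)
        with pytest.raises(SelectionError):
            ratio_candidates(ss, refs, LINE)


class TestApply:
    def test_forced_division(self):
        wl = np.array([228.78, 228.80])
        ss = SpectrumSet(np.array([[2.0, 4.0]]), wl, ["s0"])
        model = CPRCModel(
            peak=LINE, peak_window_nm=0.1,
            selected_wavelengths=[228.80], selected_bins=[1],
            r_values=[1.0], cv_rmse_path=[0.0], m=1,
        )
        out = apply_cprc(model, ss)
        np.testing.assert_allclose(out.X, [[0.5, 1.0]])

    def test_multiplicative_factor_removed(self, rng):
        wl = 228.60 + 0.02 * np.arange(25)
        row = rng.uniform(1, 10, 25)
        ss = SpectrumSet(np.vstack([row, 2.0 * row]), wl, ["a", "b"])
        model = CPRCModel(
            peak=LINE, peak_window_nm=0.1,
            selected_wavelengths=[wl[3]], selected_bins=[3],
            r_values=[1.0], cv_rmse_path=[0.0], m=1,
        )
        out = apply_cprc(model, ss)
        np.testing.assert_allclose(out.X[0], out.X[1], rtol=1e-12)

    def test_selected_bin_mean_is_one(self, benchmark_split, cd_line):
        cal, pred = benchmark_split
        model = fit_cprc(cal.spectra, cal.references, cd_line, seed=0)
        out = apply_cprc(model, pred.spectra)
        means = out.X[:, model.selected_bins].mean(axis=1)
        np.testing.assert_allclose(means, 1.0, rtol=1e-12)

    def test_scale_invariance(self, rng):
        wl = 228.60 + 0.02 * np.arange(30)
        X = rng.uniform(1, 100, size=(8, 30))
        ss = SpectrumSet(X, wl, [f"s{i}" for i in range(8)])
        model = CPRCModel(
            peak=LINE, peak_window_nm=0.1,
            selected_wavelengths=[wl[2], wl[20]], selected_bins=[2, 20],
            r_values=[0.9, 0.8], cv_rmse_path=[1.0, 0.5], m=2,
        )
        c = rng.uniform(0.1, 10.0, 8)
        base = apply_cprc(model, ss)
        scaled = apply_cprc(model, ss.with_X(c[:, None] * X))
        np.testing.assert_allclose(scaled.X, base.X, atol=1e-10)

    def test_nonpositive_mean_names_sample(self):
        wl = np.array([228.78, 228.80, 228.82])
        ss = SpectrumSet(np.array([[0.0, 4.0, 1.0]]), wl, ["bad-sample"])
        model = CPRCModel(
            peak=LINE, peak_window_nm=0.1,
            selected_wavelengths=[228.78], selected_bins=[0],
            r_values=[1.0], cv_rmse_path=[0.0], m=1,
        )
        with pytest.raises(CorrectionError, match="bad-sample"):
            apply_cprc(model, ss)


class TestSelection:
    def test_max_m_one_forces_top_candidate(self, benchmark_split, cd_line):
        cal, _ = benchmark_split
        cands = ratio_candidates(cal.spectra, cal.references, cd_line)
        model = select_matrix_variables(cands, cal.spectra, cal.references, cd_line, max_m=1)
        assert model.m == 1
        best = max((c for c in cands if c.valid), key=lambda c: (c.r, -c.wavelength))
        assert model.selected_bins == [best.j]

    def test_all_invalid_rejected(self, cd_line):
        wl = 228.60 + 0.02 * np.arange(21)
        ss = SpectrumSet(np.ones((4, 21)), wl, list("abcd"))
        refs = ReferenceValues(np.arange(4, dtype=float), ss.sample_ids)
        cands = ratio_candidates(ss, refs, cd_line)
        with pytest.raises(SelectionError):
            select_matrix_variables(cands, ss, refs, cd_line)

    def test_too_many_folds_rejected(self, cd_line, rng):
        wl = 228.60 + 0.02 * np.arange(21)
        ss = SpectrumSet(rng.uniform(1, 5, (4, 21)), wl, list("abcd"))
        refs = ReferenceValues(np.arange(4, dtype=float), ss.sample_ids)
        cands = ratio_candidates(ss, refs, cd_line)
        with pytest.raises(SelectionError):
            select_matrix_variables(cands, ss, refs, cd_line, cv=10)


class TestFitOnBenchmark:
    def test_noiseless_single_bin_correction_is_exact(self, cd_line):
        cfg = SyntheticConfig(seed=3, noise_cv=0.0, ref_cv=0.0)
        ds = generate(cfg)
        cal, _ = split_by_group(ds, ["Group1", "Group2", "Group3"], ["Group4"])
        model = fit_cprc(cal.spectra, cal.references, cd_line, seed=0)
        assert model.m == 1
        # the whole CV path sits at machine noise: any prefix corrects exactly
        assert model.cv_rmse_path[0] == pytest.approx(min(model.cv_rmse_path), abs=1e-12)
        assert model.r_values[0] == pytest.approx(1.0, abs=1e-9)

    def test_correction_improves_held_out_linearity(self, benchmark_split, cd_line):
        cal, pred = benchmark_split
        model = fit_cprc(cal.spectra, cal.references, cd_line, seed=0)
        assert 1 <= model.m <= 10
        raw = peak_intensities(pred.spectra, cd_line)
        corr = peak_intensities(apply_cprc(model, pred.spectra), cd_line)
        y = pred.references.values
        r2_raw = r2(y, fit_curve(raw, y).predict(raw))
        r2_corr = r2(y, fit_curve(corr, y).predict(corr))
        assert r2_corr > r2_raw

    def test_model_json_round_trip(self, benchmark_split, cd_line, tmp_path):
        cal, _ = benchmark_split
        model = fit_cprc(cal.spectra, cal.references, cd_line, seed=0)
        path = model.save(tmp_path / "cprc.json")
        back = CPRCModel.load(path)
        assert back.selected_bins == model.selected_bins
        assert back.m == model.m
        np.testing.assert_allclose(back.r_values, model.r_values)
        out_a = apply_cprc(model, cal.spectra)
        out_b = apply_cprc(back, cal.spectra)
        np.testing.assert_array_equal(out_a.X, out_b.X)
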