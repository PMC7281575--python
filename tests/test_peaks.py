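import numpy as np
import pytest
from dataclasses import replace
from scipy.optimize import curve_fit

from metaboflow import (
    CentroidScan,
    NoiseModel,
    PickerParams,
    PlantedPeak,
    SpectraRun,
    detect_isotopes,
    estimate_noise_and_ppm,
    group_and_align,
    pick_peaks,
    score_gaussian,
    simulate_run,
)
from metaboflow.peaks import ChromPeak, Feature, FeatureSet, lip_threshold


def single_peak_run(sigma=4.0, height=5e4, seed=0, shift=0.0):
    return simulate_run(
        [PlantedPeak(mz=250.0, rt_apex=100.0 + shift, rt_sigma=sigma, height=height)],
        NoiseModel(baseline=50, sd=20, spike_rate=3),
        rt_grid=(0, 200, 1),
        mz_jitter_ppm=2,
        seed=seed,
    )


class TestPickPeaks:
    def test_single_gaussian_recovered_at_apex(self, permissive_params):
        run = single_peak_run(sigma=4.0)
        peaks = [p for p in pick_peaks(run, permissive_params) if abs(p.mz - 250) < 0.1]
        assert len(peaks) == 1
        assert abs(peaks[0].rt - 100.0) < 1.0  # within one scan step
        assert peaks[0].gauss_cor > 0.99

    def test_width_filter_rejects_narrow_peaks(self, permissive_params):
        run = single_peak_run(sigma=4.0)
        strict = replace(permissive_params, peakwidth_min=25.0, peakwidth_max=60.0)
        assert not [p for p in pick_peaks(run, strict) if abs(p.mz - 250) < 0.1]

    def test_mzdiff_merging(self):
        # two co-eluting plants 0.005 Th apart
        scans = []
        for i in range(60):
            h = 1e4 * np.exp(-((i - 30) ** 2) / 32.0)
            if h < 1:
                scans.append(CentroidScan(rt=float(i), mz=np.empty(0), intensity=np.empty(0)))
            else:
                scans.append(
                    CentroidScan(rt=float(i), mz=[200.000, 200.005], intensity=[h, 0.8 * h])
                )
        run = SpectraRun(scans=scans)
        base = PickerParams(ppm=10, peakwidth_min=5, peakwidth_max=40, snthresh=2,
                            noise=10, prefilter_k=3, prefilter_i=10, bw=5)
        merged = pick_peaks(run, replace(base, mzdiff=0.01))
        split = pick_peaks(run, replace(base, mzdiff=0.001))
        assert len(merged) == 1
        assert len(split) == 2

    def test_raising_snthresh_never_adds_peaks(self, noisy_run, permissive_params):
        counts = [
            len(pick_peaks(noisy_run, replace(permissive_params, snthresh=s)))
            for s in (2, 5, 10, 30, 100)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_deterministic(self, noisy_run, permissive_params):
        a = pick_peaks(noisy_run, permissive_params)
        b = pick_peaks(noisy_run, permissive_params)
        assert [(p.mz, p.rt, p.area) for p in a] == [(p.mz, p.rt, p.area) for p in b]

    def test_area_approaches_closed_form_with_fine_sampling(self, permissive_params):
        h, sigma = 5e4, 5.0
        run = simulate_run(
            [PlantedPeak(mz=250.0, rt_apex=100.0, rt_sigma=sigma, height=h)],
            rt_grid=(0, 200, 0.25),
            seed=0,
        )
        peaks = pick_peaks(run, permissive_params)
        assert len(peaks) == 1
        expected = h * sigma * np.sqrt(2 * np.pi)
        # bounds at 5% of apex clip the outer tails (~2.5% of the mass)
        assert peaks[0].area == pytest.approx(expected, rel=0.08)


class TestScoreGaussian:
    def test_noiseless_gaussian(self):
        t = np.arange(0, 40.0)
        y = 100 * np.exp(-((t - 20) ** 2) / 18.0)
        cor, p = score_gaussian(list(zip(t, y)))
        assert cor > 0.9999
        assert p < 1e-6

    def test_flat_eic_returns_failure(self):
        cor, p = score_gaussian([(0, 5.0), (1, 5.0), (2, 5.0), (3, 5.0)])
        assert (cor, p) == (0.0, 1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            score_gaussian([(0, 1.0), (1, 2.0), (2, 1.0)])

    def test_cor_matches_independent_pearson(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 19, 20)
        y = 100 * np.exp(-((t - 10) ** 2) / 8.0) * (1 + 0.2 * rng.normal(size=20))
        y = np.abs(y)
        cor, _ = score_gaussian(list(zip(t, y)))

        def g(x, h, mu, s):
            return h * np.exp(-((x - mu) ** 2) / (2 * s**2))

        popt, _ = curve_fit(g, t, y, p0=(y.max(), t[np.argmax(y)], np.ptp(t) / 4), maxfev=400)
        fitted = g(t, *popt)
        # closed-form Pearson
        fx, fy = fitted - fitted.mean(), y - y.mean()
        expected = float(np.sum(fx * fy) / np.sqrt(np.sum(fx**2) * np.sum(fy**2)))
        assert cor == pytest.approx(expected, abs=1e-6)


class TestGroupAndAlign:
    def test_identical_peak_in_three_samples_forms_one_feature(self, permissive_params):
        runs = [single_peak_run(seed=s) for s in (1, 2, 3)]
        by_sample = [
            [p for p in pick_peaks(r, permissive_params) if abs(p.mz - 250) < 0.1]
            for r in runs
        ]
        fs = group_and_align(by_sample, permissive_params)
        assert len(fs.features) == 1
        assert len(fs.features[0].members) == 3

    def test_no_shared_peaks_gives_zero_grouping_score(self, permissive_params):
        p1 = ChromPeak(mz=100, mzmin=0, mzmax=0, rt=50, rtmin=40, rtmax=60,
                       area=1, apex_height=1, sn=5)
        p2 = ChromPeak(mz=500, mzmin=0, mzmax=0, rt=150, rtmin=140, rtmax=160,
                       area=1, apex_height=1, sn=5)
        fs = group_and_align([[p1], [p2]], permissive_params)
        assert fs.gs == 0.0

    def test_single_sample_one_feature_per_peak_max_rcs(self, noisy_run, permissive_params):
        peaks = pick_peaks(noisy_run, permissive_params)
        fs = group_and_align([peaks], permissive_params)
        assert len(fs.features) == len(peaks)
        assert fs.rcs == 1.0

    def test_alignment_shrinks_planted_rt_shift(self, planted_peaks, permissive_params):
        run_a = simulate_run(planted_peaks, rt_grid=(0, 240, 1), seed=1)
        shifted = [replace(p, rt_apex=p.rt_apex + 5.0) for p in planted_peaks]
        run_b = simulate_run(shifted, rt_grid=(0, 240, 1), seed=2)
        params = replace(permissive_params, bw=8.0)
        by_sample = [pick_peaks(run_a, params), pick_peaks(run_b, params)]
        pre = np.mean(
            [abs(p.rt - np.mean([q.rt for q in by_sample[0]])) for p in by_sample[1]]
        )
        fs = group_and_align(by_sample, params)
        post = [
            abs(f.members[1].rt - f.members[0].rt)
            for f in fs.features
            if 0 in f.members and 1 in f.members
        ]
        assert np.mean(post) < 0.2 * 5.0  # residual under 20% of the planted shift


class TestIsotopes:
    def _feature(self, mz, rt, area, sample=0):
        peak = ChromPeak(mz=mz, mzmin=mz, mzmax=mz, rt=rt, rtmin=rt - 5, rtmax=rt + 5,
                         area=area, apex_height=area, sn=10)
        return Feature(mz=mz, rt=rt, members={sample: peak})

    def test_coeluting_partner_flagged(self):
        feats = [
            self._feature(200.0, 100.0, 1000.0),
            self._feature(200.0 + 1.003355, 100.5, 200.0),
        ]
        fs = FeatureSet(features=feats, n_samples=1)
        detect_isotopes(fs, ppm=10)
        assert feats[0].has_isotope
        assert not feats[1].has_isotope

    def test_distant_rt_partner_not_flagged(self):
        feats = [
            self._feature(200.0, 100.0, 1000.0),
            self._feature(200.0 + 1.003355, 130.0, 200.0),
        ]
        fs = FeatureSet(features=feats, n_samples=1)
        detect_isotopes(fs, ppm=10)
        assert not feats[0].has_isotope

    def test_charge_two_spacing_detected(self):
        feats = [
            self._feature(400.0, 100.0, 1000.0),
            self._feature(400.0 + 1.003355 / 2, 100.0, 300.0),
        ]
        fs = FeatureSet(features=feats, n_samples=1)
        detect_isotopes(fs, ppm=10)
        assert feats[0].has_isotope

    def test_lip_threshold_three_percent_rule(self):
        # 1000 intensities 1..1000: lowest 3% are 1..30, mean 15.5
        assert lip_threshold(np.arange(1, 1001)) == pytest.approx(15.5)

    def test_low_intensity_isotope_flag(self):
        feats = [self._feature(100.0 + 5 * i, 50.0, float(i + 1)) for i in range(100)]
        # partner below threshold mean(1, 2, 3) = 2.0
        feats.append(self._feature(1000.0, 80.0, 500.0))
        feats.append(self._feature(1000.0 + 1.003355, 80.0, 1.5))
        fs = FeatureSet(features=feats, n_samples=1)
        detect_isotopes(fs, ppm=10)
        target = feats[-2]
        assert target.has_isotope
        assert target.low_intensity_isotope


class TestNoiseEstimation:
    def _bimodal_run(self):
        rng = np.random.default_rng(0)
        scans = []
        for i in range(100):
            noise_mz = rng.uniform(100, 900, 20)
            noise_int = rng.lognormal(np.log(100), 0.25, 20)
            sig_mz = 950.0 + np.arange(5) * 2.0
            sig_int = rng.lognormal(np.log(1e5), 0.3, 5)
            mz = np.concatenate([noise_mz, sig_mz])
            inten = np.concatenate([noise_int, sig_int])
            order = np.argsort(mz)
            scans.append(CentroidScan(rt=float(i), mz=mz[order], intensity=inten[order]))
        return SpectraRun(scans=scans)

    def test_antimode_sits_between_populations(self):
        noise, k, prefilter_i, ppm = estimate_noise_and_ppm(self._bimodal_run())
        assert 300 < noise < 3e4  # between the ~100 and ~1e5 modes
        assert prefilter_i == noise
        assert 2 <= k <= 10

    def test_zero_jitter_gives_floor_ppm(self, planted_peaks):
        run = simulate_run(planted_peaks, NoiseModel(50, 20, 5), mz_jitter_ppm=0.0, seed=1)
        assert estimate_noise_and_ppm(run)[3] == pytest.approx(1.0)

    def test_unimodal_run_falls_back_with_warning(self):
        rng = np.random.default_rng(1)
        scans = [
            CentroidScan(
                rt=float(i),
                mz=np.sort(rng.uniform(100, 900, 30)),
                intensity=rng.lognormal(np.log(100), 0.1, 30),
            )
            for i in range(50)
        ]
        run = SpectraRun(scans=scans)
        with pytest.warns(UserWarning, match="unimodal"):
            noise, *_ = estimate_noise_and_ppm(run)
        assert noise > 0
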