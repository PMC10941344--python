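import numpy as np
import pytest
from scipy import stats

from hralab import (
    CONDITIONS,
    CohortModel,
    GenerationError,
    TECHNICAL_ARTIFACT,
    TachogramModel,
    asymmetry_descriptors,
    assess_stationarity,
    condition_preset,
    detect_artifacts,
    generate_cohort,
    generate_rr,
    inject_artifacts,
    time_domain_summary,
)
from hralab.synthetic import dominant_frequency


class TestGenerateRR:
    def test_constant_model_beat_count(self):
        model = TachogramModel(m=936.0, a_resp=0, a_lf=0, sigma_n=0, duration_s=300)
        series = generate_rr(model)
        assert len(series) == 300_000 // 936  # 320 beats fill 300 s
        assert np.allclose(series.values, 936.0)

    def test_seed_determinism(self):
        model = TachogramModel(seed=5)
        a, b = generate_rr(model), generate_rr(model)
        assert np.array_equal(a.values, b.values)

    def test_respiratory_peak_recoverable(self):
        model = TachogramModel(m=900, a_resp=40, f_resp=0.2, a_lf=0, sigma_n=0, kappa=0)
        f = dominant_frequency(generate_rr(model))
        assert f == pytest.approx(0.2, abs=0.01)

    def test_impossible_parameters_raise_generation_error(self):
        with pytest.raises(GenerationError, match="beat"):
            generate_rr(TachogramModel(m=400.0, trend=-5.0, sigma_n=0, duration_s=300))


class TestPresets:
    def test_presets_are_valid_models(self):
        for name in CONDITIONS:
            preset = condition_preset(name)
            assert isinstance(preset, TachogramModel)

    def test_rest_baseline_and_breathing_order(self):
        rest, stim = condition_preset("rest"), condition_preset("snsa_stim")
        assert rest.m == pytest.approx(936.0)
        assert stim.f_resp > rest.f_resp
        assert stim.trend < 0 < condition_preset("recovery").trend

    def test_unknown_name(self):
        with pytest.raises(KeyError):
            condition_preset("exercise")

    def test_stimulation_raises_heart_rate(self):
        hr = {}
        for name in ("rest", "snsa_stim"):
            model = condition_preset(name)
            series = generate_rr(TachogramModel(**{**model.__dict__, "seed": 3}))
            hr[name] = time_domain_summary(series).hr_mean
        assert hr["snsa_stim"] > hr["rest"] + 5


class TestInjectArtifacts:
    def test_zero_rate_is_identity(self, random_series):
        s = random_series(1)
        out, idx = inject_artifacts(s, 0.0, seed=1)
        assert out is s and idx.size == 0

    def test_rate_controls_count(self):
        s = generate_rr(TachogramModel(seed=2, duration_s=280))
        out, idx = inject_artifacts(s, 0.02, seed=2)
        assert idx.size == round(0.02 * len(s))
        assert np.min(np.diff(idx)) >= 2

    def test_detection_recovers_injected_artifacts(self):
        hits = total = 0
        for seed in range(1, 21):
            s = generate_rr(TachogramModel(seed=seed, duration_s=280))
            perturbed, idx = inject_artifacts(s, 0.02, seed=seed)
            flagged = set(
                np.flatnonzero(detect_artifacts(perturbed).labels == TECHNICAL_ARTIFACT)
            )
            hits += len(flagged & set(idx.tolist()))
            total += idx.size
        assert hits / total >= 5 / 6

    def test_rate_cap(self, random_series):
        with pytest.raises(ValueError):
            inject_artifacts(random_series(1), 0.2, seed=1)

    def test_seed_determinism(self, random_series):
        s = random_series(9)
        a, _ = inject_artifacts(s, 0.03, seed=4)
        b, _ = inject_artifacts(s, 0.03, seed=4)
        assert np.array_equal(a.values, b.values)


class TestEstimatorResponses:
    """Monotone response of estimators to generator knobs (medians over seeds)."""

    @staticmethod
    def median_over_seeds(fn, n_seeds=20, **model_kwargs):
        out = []
        for seed in range(n_seeds):
            series = generate_rr(TachogramModel(seed=seed, **model_kwargs))
            out.append(fn(series))
        return float(np.median(out))

    def test_noise_increases_rmssd_and_sd1(self):
        rmssd = lambda s: time_domain_summary(s).rmssd
        sd1 = lambda s: asymmetry_descriptors(s).sd1
        assert self.median_over_seeds(rmssd, sigma_n=4.0) < self.median_over_seeds(rmssd, sigma_n=16.0)
        assert self.median_over_seeds(sd1, sigma_n=4.0) < self.median_over_seeds(sd1, sigma_n=16.0)

    def test_shorter_baseline_raises_heart_rate(self):
        hr = lambda s: time_domain_summary(s).hr_mean
        assert self.median_over_seeds(hr, m=800.0) > self.median_over_seeds(hr, m=950.0)

    def test_trend_induces_non_stationarity(self):
        def nonstat_rate(trend):
            calls = [
                not assess_stationarity(generate_rr(TachogramModel(seed=s, trend=trend))).stationary
                for s in range(20)
            ]
            return np.mean(calls)

        assert nonstat_rate(0.6) > nonstat_rate(0.0)

    def test_kappa_sweep_moves_guzik_index_monotonically(self):
        gi = lambda s: asymmetry_descriptors(s).gi
        medians = [
            self.median_over_seeds(gi, kappa=kappa)
            for kappa in (-0.5, -0.25, 0.0, 0.25, 0.5)
        ]
        assert medians == sorted(medians)
        assert medians[0] < 0.5 < medians[-1]

    def test_porta_index_symmetric_at_null(self):
        pi = lambda s: asymmetry_descriptors(s).pi
        median_pi = self.median_over_seeds(pi, n_seeds=50, kappa=0.0, trend=0.0)
        assert 45.0 <= median_pi <= 55.0


class TestGenerateCohort:
    def test_cohort_is_complete_and_deterministic(self):
        model = CohortModel(n_subjects=5, seed=3)
        a, b = generate_cohort(model), generate_cohort(model)
        assert len(a) == 5
        for subj_a, subj_b in zip(a, b):
            assert subj_a.career_duration == subj_b.career_duration
            for cond in CONDITIONS:
                rec = subj_a.recording(cond)
                assert rec.resp_rate is not None and len(rec.series) > 100
                assert np.array_equal(
                    rec.series.values, subj_b.recording(cond).series.values
                )

    def test_null_coupling_leaves_career_uninformative(self):
        # Under the exact Spearman null at n=9, P(|rho| < 0.5) ~ 0.85;
        # over 30 cohorts the observed fraction should stay comfortably
        # inside the binomial band around that value.
        from hralab.hra import run_distribution
        from hralab.pipeline import AnalysisConfig, extract_window, short_term_window

        cfg = AnalysisConfig()
        ok = 0
        for seed in range(30):
            cohort = generate_cohort(CohortModel(n_subjects=9, coupling=0.0, seed=seed))
            deltas, careers = [], []
            for subj in cohort:
                ar1 = {}
                for cond in ("rest", "snsa_stim"):
                    rec = subj.recording(cond)
                    w = extract_window(rec, short_term_window(rec, cfg))
                    ar1[cond] = run_distribution(w).ar.get(1, 0)
                deltas.append(ar1["snsa_stim"] - ar1["rest"])
                careers.append(subj.career_duration)
            if abs(stats.spearmanr(careers, deltas).statistic) < 0.5:
                ok += 1
        assert ok >= 21  # >= 70% of 30, binomial-compatible with p ~ 0.85
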