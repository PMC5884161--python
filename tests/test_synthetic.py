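"""Calibrated cohort generator and its exact-posterior Bayes oracle."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import chisquare

from prostage.data import CLINICAL_T_CATEGORIES, GLEASON_CATEGORIES, Label, derive_label
from prostage.synthetic import (
    ClassConditionalTables,
    GeneratorConfig,
    PsaParams,
    bayes_predict,
    default_tables,
    generate_cohort,
    sample_patient,
    sample_psa,
    solve_log_mean,
)


class TestDefaultTables:
    def test_published_count_spot_checks(self):
        t = default_tables()
        assert t.gleason_counts[Label.OCD][GLEASON_CATEGORIES.index("6")] == 1342
        assert t.clinical_t_counts[Label.NOCD][CLINICAL_T_CATEGORIES.index("T3b")] == 104
        assert t.psa_params[Label.NOCD].target_mean == 18.606

    def test_counts_sum_to_group_sizes(self):
        t = default_tables()
        assert t.gleason_counts[Label.OCD].sum() == 2478
        assert t.gleason_counts[Label.NOCD].sum() == 1561
        assert t.clinical_t_counts[Label.OCD].sum() == 2478
        assert t.clinical_t_counts[Label.NOCD].sum() == 1561
        assert t.prevalence_nocd == pytest.approx(1561 / 4039)


class TestSamplePsa:
    def test_infeasible_target_rejected(self):
        with pytest.raises(ValueError):
            PsaParams(target_mean=200.0, minimum=4.0, maximum=160.0, log_sd=0.5)

    def test_draws_respect_published_bounds(self, rng):
        params = default_tables().psa_params[Label.OCD]
        mu = solve_log_mean(params)
        draws = [sample_psa(Label.OCD, params, rng, log_mean=mu) for _ in range(2000)]
        assert min(draws) >= 4.0 and max(draws) <= 160.0

    def test_same_seed_identical_stream(self):
        params = default_tables().psa_params[Label.NOCD]
        mu = solve_log_mean(params)
        a = [sample_psa(Label.NOCD, params, np.random.default_rng(3), log_mean=mu) for _ in range(5)]
        b = [sample_psa(Label.NOCD, params, np.random.default_rng(3), log_mean=mu) for _ in range(5)]
        assert a == b

    def test_calibrated_mean_hits_target(self):
        """Monte-Carlo check of the truncated-mean calibration solve."""
        rng = np.random.default_rng(42)
        for cls, target in ((Label.OCD, 9.535), (Label.NOCD, 18.606)):
            params = default_tables().psa_params[cls]
            mu = solve_log_mean(params)
            draws = [sample_psa(cls, params, rng, log_mean=mu) for _ in range(30000)]
            assert np.mean(draws) == pytest.approx(target, rel=0.02)


class TestSamplePatient:
    def test_degenerate_prevalence_forces_class(self, rng):
        t = replace(default_tables(), prevalence_nocd=1.0 - 1e-12)
        for _ in range(20):
            assert sample_patient(t, rng).label == Label.NOCD

    def test_degenerate_categorical_forces_category(self, rng):
        t = default_tables()
        g = {k: v.copy() for k, v in t.gleason_counts.items()}
        g[Label.OCD] = np.zeros(9)
        g[Label.OCD][GLEASON_CATEGORIES.index("6")] = 1.0
        t = replace(t, gleason_counts=g)
        for _ in range(50):
            r = sample_patient(t, rng)
            if r.label == Label.OCD:
                assert r.gleason == "6"

    def test_pathologic_fields_rederive_the_sampled_label(self, rng):
        t = default_tables()
        for _ in range(50):
            r = sample_patient(t, rng)
            assert derive_label(r.path_t, r.path_n) == r.label


class TestGenerateCohort:
    def test_zero_size_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n=0, seed=1, tables=default_tables())

    def test_deterministic_under_seed(self):
        cfg = GeneratorConfig(n=40, seed=8, tables=default_tables())
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert [(r.psa, r.gleason, r.clinical_t, r.label) for r in a] == [
            (r.psa, r.gleason, r.clinical_t, r.label) for r in b
        ]

    def test_training_scale_marginals_near_published_shares(self):
        """At the published training size the OCD Gleason-6 share should sit
        within binomial noise of 1342/2478 = 54.16%."""
        cohort = generate_cohort(GeneratorConfig(n=4039, seed=5, tables=default_tables()))
        ocd = [r for r in cohort if r.label == Label.OCD]
        share = sum(r.gleason == "6" for r in ocd) / len(ocd)
        assert share == pytest.approx(0.5416, abs=0.02)

    def test_different_seeds_same_calibration(self):
        shares = []
        for seed in (1, 2):
            cohort = generate_cohort(GeneratorConfig(n=4039, seed=seed, tables=default_tables()))
            ocd = [r for r in cohort if r.label == Label.OCD]
            shares.append(sum(r.gleason == "6" for r in ocd) / len(ocd))
        assert shares[0] != shares[1]  # different draws...
        assert abs(shares[0] - 0.5416) < 0.03 and abs(shares[1] - 0.5416) < 0.03

    def test_categorical_marginals_pass_goodness_of_fit(self):
        """Chi-square GOF against the target categoricals at n=10^5 (alpha 0.01)."""
        cohort = generate_cohort(GeneratorConfig(n=100_000, seed=17, tables=default_tables()))
        t = default_tables()
        for cls in (Label.OCD, Label.NOCD):
            members = [r for r in cohort if r.label == cls]
            observed = np.array(
                [sum(r.gleason == g for r in members) for g in GLEASON_CATEGORIES]
            )
            expected = t.gleason_probs(cls) * len(members)
            keep = expected > 0
            stat, p = chisquare(observed[keep], expected[keep])
            assert p > 0.01


class TestBayesPredict:
    def _uniform_tables(self):
        return ClassConditionalTables(
            prevalence_nocd=0.5,
            gleason_counts={Label.OCD: np.ones(9), Label.NOCD: np.ones(9)},
            clinical_t_counts={Label.OCD: np.ones(8), Label.NOCD: np.ones(8)},
            psa_params={
                Label.OCD: PsaParams(10.0, 4.0, 160.0, 0.5),
                Label.NOCD: PsaParams(10.0, 4.0, 160.0, 0.5),
            },
        )

    def test_symmetric_model_gives_half(self, small_cohort):
        t = self._uniform_tables()
        post, _ = bayes_predict(t, small_cohort[0])
        assert post == pytest.approx(0.5)

    def test_disjoint_supports_give_certainty(self, rng):
        t = self._uniform_tables()
        g = {
            Label.OCD: np.array([1.0] * 4 + [0.0] * 5),
            Label.NOCD: np.array([0.0] * 4 + [1.0] * 5),
        }
        t = replace(t, gleason_counts=g)
        r = sample_patient(t, rng)
        post, label = bayes_predict(t, r)
        assert post in (0.0, 1.0) and label == r.label

    def test_invariant_to_count_rescaling(self, small_cohort):
        t = default_tables()
        scaled = replace(
            t,
            gleason_counts={
                Label.OCD: t.gleason_counts[Label.OCD] * 37.0,
                Label.NOCD: t.gleason_counts[Label.NOCD],
            },
        )
        for r in small_cohort:
            assert bayes_predict(t, r)[0] == pytest.approx(bayes_predict(scaled, r)[0], abs=1e-12)

    def test_beats_a_coarsened_classifier_within_sampling_error(self):
        """The exact posterior is Bayes-optimal under the generator: a
        PSA-only posterior rule cannot beat it by more than 2 SE."""
        t = default_tables()
        cohort = generate_cohort(GeneratorConfig(n=10_000, seed=23, tables=t))
        log_means = {c: t.psa_log_mean(c) for c in (Label.OCD, Label.NOCD)}
        uniform = replace(
            t,
            gleason_counts={Label.OCD: np.ones(9), Label.NOCD: np.ones(9)},
            clinical_t_counts={Label.OCD: np.ones(8), Label.NOCD: np.ones(8)},
        )
        full = np.mean([bayes_predict(t, r, _log_means=log_means)[1] == r.label for r in cohort])
        psa_only = np.mean(
            [bayes_predict(uniform, r, _log_means=log_means)[1] == r.label for r in cohort]
        )
        se = np.sqrt(full * (1 - full) / len(cohort))
        assert psa_only <= full + 2 * se
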