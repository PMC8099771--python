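"""Phasing, paternal bias, upscaling, age regressions, transmission."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pedmut.parental import (
    ORIGIN_MATERNAL,
    ORIGIN_PATERNAL,
    ORIGIN_UNPHASED,
    fit_parent_count_regressions,
    fit_rate_age_regressions,
    paternal_fraction,
    phase_mutations,
    predict_counts,
    transmission_test,
    upscale_phased,
    upscaled_table,
)
from pedmut.reference import COUNT_MODEL
from pedmut.simulate import SimulationConfig, simulate_dataset


def _mut(trio, pos):
    return {"trio": trio, "pos": pos, "chrom": "chr1", "ref": "C", "alt": "T"}


class TestPhasing:
    def test_father_carried_same_haplotype_informant_gives_paternal(self):
        muts = pd.DataFrame([_mut("T1", 1000)])
        inf = pd.DataFrame(
            [{"trio": "T1", "pos": 1000, "informant_pos": 1100,
              "carrier": "father", "same_haplotype": True}]
        )
        out = phase_mutations(muts, inf, window=230)
        assert out["origin"].iloc[0] == ORIGIN_PATERNAL

    def test_opposite_haplotype_implies_other_parent(self):
        muts = pd.DataFrame([_mut("T1", 1000)])
        inf = pd.DataFrame(
            [{"trio": "T1", "pos": 1000, "informant_pos": 900,
              "carrier": "father", "same_haplotype": False}]
        )
        out = phase_mutations(muts, inf, window=230)
        assert out["origin"].iloc[0] == ORIGIN_MATERNAL

    def test_no_informant_in_window_stays_unphased(self):
        muts = pd.DataFrame([_mut("T1", 1000)])
        inf = pd.DataFrame(
            [{"trio": "T1", "pos": 1000, "informant_pos": 5000,
              "carrier": "mother", "same_haplotype": True}]
        )
        out = phase_mutations(muts, inf, window=230)
        assert out["origin"].iloc[0] == ORIGIN_UNPHASED

    def test_conflicting_informants_stay_unphased(self):
        muts = pd.DataFrame([_mut("T1", 1000)])
        inf = pd.DataFrame(
            [
                {"trio": "T1", "pos": 1000, "informant_pos": 1050,
                 "carrier": "father", "same_haplotype": True},
                {"trio": "T1", "pos": 1000, "informant_pos": 950,
                 "carrier": "father", "same_haplotype": False},
            ]
        )
        out = phase_mutations(muts, inf, window=230)
        assert out["origin"].iloc[0] == ORIGIN_UNPHASED

    def test_simulated_truth_phasing_is_accurate(self, small_cohort):
        """Phased assignments match truth; phased fraction tracks informant rate."""
        truth = small_cohort.truth
        germ = truth[truth["kind"].str.startswith("germline")].copy()
        phased = phase_mutations(
            germ, small_cohort.informants, window=small_cohort.config.phase_window
        )
        assigned = phased[phased["origin"] != ORIGIN_UNPHASED]
        merged = assigned.merge(
            germ, on=["trio", "pos"], suffixes=("_hat", "_true")
        )
        assert (merged["origin_hat"] == merged["origin_true"]).mean() >= 0.99
        frac = len(assigned) / len(germ)
        rate = small_cohort.config.phase_informative_rate
        se = np.sqrt(rate * (1 - rate) / len(germ))
        assert abs(frac - rate) <= 3 * se


class TestPaternalFraction:
    def test_all_paternal_gives_one(self):
        muts = pd.DataFrame([{**_mut("T1", i), "origin": ORIGIN_PATERNAL}
                             for i in range(5)])
        assert paternal_fraction(muts).fraction == 1.0

    def test_balanced_counts_give_half_and_zero_t(self):
        rows = []
        for trio in ("T1", "T2"):
            rows += [{**_mut(trio, i), "origin": ORIGIN_PATERNAL} for i in range(5)]
            rows += [{**_mut(trio, 100 + i), "origin": ORIGIN_MATERNAL}
                     for i in range(5)]
        result = paternal_fraction(pd.DataFrame(rows))
        assert result.fraction == 0.5
        assert np.isnan(result.t_statistic)  # zero variance across trios

    def test_no_phased_mutations_raise(self):
        muts = pd.DataFrame([{**_mut("T1", 1), "origin": ORIGIN_UNPHASED}])
        with pytest.raises(ValueError, match="no phased"):
            paternal_fraction(muts)

    def test_invariant_to_order_and_chromosome_labels(self):
        rng = np.random.default_rng(0)
        rows = [
            {**_mut(f"T{i % 3}", i), "origin":
             ORIGIN_PATERNAL if i % 4 else ORIGIN_MATERNAL}
            for i in range(60)
        ]
        muts = pd.DataFrame(rows)
        shuffled = muts.sample(frac=1, random_state=1).reset_index(drop=True)
        relabeled = shuffled.assign(chrom="chrX")
        assert (
            paternal_fraction(muts).fraction
            == paternal_fraction(shuffled).fraction
            == paternal_fraction(relabeled).fraction
        )

    def test_four_to_one_truth_recovered(self, study_pedigree):
        """Phasing a 4:1 simulated cohort recovers the planted paternal share."""
        config = SimulationConfig(
            genome_length=40_000, seed=71, error_mv_rate=0.0,
            mosaic_sharing_rate=0.0, heterozygosity=1e-4,
            maternal_intercept=8.0, maternal_slope=0.0,
            paternal_intercept=32.0, paternal_slope=0.0,
        )
        fractions = []
        for rep in range(10):
            cohort = simulate_dataset(
                SimulationConfig(**{**config.__dict__, "seed": config.seed + rep}),
                study_pedigree,
            )
            germ = cohort.truth[cohort.truth["kind"].str.startswith("germline")]
            phased = phase_mutations(
                germ.copy(), cohort.informants, window=config.phase_window
            )
            fractions.append(paternal_fraction(phased).fraction)
        mean = np.mean(fractions)
        se = np.std(fractions, ddof=1) / np.sqrt(len(fractions))
        assert abs(mean - 0.8) <= 2 * se + 0.01


class TestUpscaling:
    def test_worked_example_forty_mutations(self):
        """m=40 with 16/20 phased paternal upscales to 32 paternal, 8 maternal."""
        paternal, maternal = upscale_phased(40, 16, 4)
        assert paternal == pytest.approx(32.0)
        assert maternal == pytest.approx(8.0)

    def test_fully_phased_totals_equal_phased_counts(self):
        paternal, maternal = upscale_phased(10, 7, 3)
        assert paternal == pytest.approx(7.0) and maternal == pytest.approx(3.0)

    def test_zero_phased_raises(self):
        with pytest.raises(ValueError, match="no phased"):
            upscale_phased(10, 0, 0)

    def test_denominator_normalization(self):
        # equal denominators match the simple ratio
        assert upscale_phased(30, 10, 5, 100, 100) == pytest.approx(
            upscale_phased(30, 10, 5)
        )
        # halving the paternal denominator doubles the paternal weight
        paternal, _ = upscale_phased(30, 10, 5, 50, 100)
        assert paternal == pytest.approx(30 * 20 / 25)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        m=st.integers(1, 200),
        data=st.data(),
    )
    def test_conservation_of_total(self, m, data):
        phased_p = data.draw(st.integers(0, m))
        phased_m = data.draw(st.integers(0, m - phased_p))
        if phased_p + phased_m == 0:
            return
        paternal, maternal = upscale_phased(m, phased_p, phased_m)
        assert paternal + maternal == pytest.approx(m)
        assert 0 <= paternal <= m


class TestRegressions:
    def _exact_table(self):
        ages_m = np.array([4.0, 6.0, 8.0, 10.0, 12.0])
        ages_p = np.array([10.0, 11.0, 12.0, 13.0, 14.0])
        return pd.DataFrame(
            {
                "age_maternal": ages_m,
                "age_paternal": ages_p,
                "maternal_count": 4.6497 + 0.3042 * ages_m,
                "paternal_count": 4.8399 + 1.8364 * ages_p,
            }
        )

    def test_exact_linear_data_recovers_coefficients(self):
        model = fit_parent_count_regressions(self._exact_table())
        assert model.maternal_intercept == pytest.approx(4.6497, abs=1e-8)
        assert model.maternal_slope == pytest.approx(0.3042, abs=1e-8)
        assert model.paternal_intercept == pytest.approx(4.8399, abs=1e-8)
        assert model.paternal_slope == pytest.approx(1.8364, abs=1e-8)

    def test_ols_matches_lstsq_oracle(self):
        """statsmodels coefficients equal a direct least-squares solve."""
        rng = np.random.default_rng(8)
        table = self._exact_table()
        table["paternal_count"] += rng.normal(0, 2, len(table))
        model = fit_parent_count_regressions(table)
        X = np.column_stack([np.ones(len(table)), table["age_paternal"]])
        beta, *_ = np.linalg.lstsq(X, table["paternal_count"], rcond=None)
        assert model.paternal_intercept == pytest.approx(beta[0])
        assert model.paternal_slope == pytest.approx(beta[1])

    def test_slope_recovery_from_poisson_counts(self, study_pedigree):
        """Counts drawn from the printed truth model refit to the same slopes."""
        rng = np.random.default_rng(99)
        ages_m = np.array([t.age_maternal for t in study_pedigree.trios])
        ages_p = np.array([t.age_paternal for t in study_pedigree.trios])
        slopes_m, slopes_p = [], []
        for _ in range(300):
            table = pd.DataFrame(
                {
                    "age_maternal": ages_m,
                    "age_paternal": ages_p,
                    "maternal_count": rng.poisson(4.6497 + 0.3042 * ages_m),
                    "paternal_count": rng.poisson(4.8399 + 1.8364 * ages_p),
                }
            )
            model = fit_parent_count_regressions(table)
            slopes_m.append(model.maternal_slope)
            slopes_p.append(model.paternal_slope)
        for observed, truth in ((slopes_m, 0.3042), (slopes_p, 1.8364)):
            mean = np.mean(observed)
            se = np.std(observed, ddof=1) / np.sqrt(len(observed))
            assert abs(mean - truth) <= 2 * se

    def test_poisson_link_fits_log_linear_truth(self):
        ages = np.arange(3.0, 16.0)
        table = pd.DataFrame(
            {
                "age_maternal": ages,
                "age_paternal": ages,
                "maternal_count": np.exp(1.62 + 0.04 * ages),
                "paternal_count": np.exp(2.48 + 0.07 * ages),
            }
        )
        model = fit_parent_count_regressions(table, link="log")
        assert model.link == "log"
        assert model.paternal_intercept == pytest.approx(2.48, abs=1e-6)
        assert model.paternal_slope == pytest.approx(0.07, abs=1e-6)

    def test_rate_regressions_recover_exact_plane(self):
        ages_m = np.array([4.0, 5.0, 7.0, 9.0, 11.0, 13.0])
        ages_p = np.array([10.0, 12.0, 11.0, 13.0, 14.0, 10.5])
        mu = 1.355e-9 + 7.936e-11 * ages_m + 4.588e-10 * ages_p
        model = fit_rate_age_regressions(
            pd.DataFrame({"mu": mu, "age_maternal": ages_m, "age_paternal": ages_p})
        )
        assert model.joint_intercept == pytest.approx(1.355e-9, rel=1e-6)
        assert model.joint_maternal_slope == pytest.approx(7.936e-11, rel=1e-6)
        assert model.joint_paternal_slope == pytest.approx(4.588e-10, rel=1e-6)

    def test_constant_ages_raise(self):
        table = pd.DataFrame(
            {"mu": [1e-9, 2e-9, 3e-9], "age_maternal": [5.0, 5.0, 5.0],
             "age_paternal": [10.0, 11.0, 12.0]}
        )
        with pytest.raises(ValueError, match="constant"):
            fit_rate_age_regressions(table)


class TestPredictions:
    def test_published_model_at_age_five(self):
        maternal, paternal, ratio = predict_counts(COUNT_MODEL, 5.0, 5.0)
        assert round(paternal) == 14
        assert round(maternal, 1) == 6.2
        assert round(ratio, 1) == 2.3

    def test_published_model_at_age_fifteen(self):
        # the coefficient arithmetic gives a paternal:maternal ratio of ~3.5
        _, paternal, ratio = predict_counts(COUNT_MODEL, 15.0, 15.0)
        assert round(paternal) == 32
        assert ratio == pytest.approx(3.52, abs=0.01)

    def test_zero_paternal_slope_makes_ratio_age_free(self):
        from pedmut.parental import ParentAgeModel

        model = ParentAgeModel(5.0, 0.5, 10.0, 0.0)
        _, _, r1 = predict_counts(model, 7.0, 5.0)
        _, _, r2 = predict_counts(model, 7.0, 15.0)
        assert r1 == r2

    def test_negative_prediction_raises(self):
        from pedmut.parental import ParentAgeModel

        model = ParentAgeModel(-10.0, 0.1, 5.0, 1.0)
        with pytest.raises(ValueError, match="negative"):
            predict_counts(model, 1.0, 10.0)


class TestTransmission:
    def test_even_split_gives_p_one(self):
        result = transmission_test(10, 20)
        assert result.fraction == 0.5
        assert result.p_value == 1.0

    def test_all_transmitted_matches_exact_binomial(self):
        result = transmission_test(20, 20)
        assert result.p_value == pytest.approx(2 * 0.5**20)
        assert result.p_value == pytest.approx(1.9073e-6, rel=1e-3)

    def test_no_sites_raise(self):
        with pytest.raises(ValueError):
            transmission_test(0, 0)

    def test_rejection_rate_under_mendelian_null(self):
        """Under true 50% transmission the test rejects at <= nominal alpha."""
        rng = np.random.default_rng(5)
        n_rep, n_sites = 2000, 30
        rejections = sum(
            transmission_test(int(rng.binomial(n_sites, 0.5)), n_sites).p_value < 0.05
            for _ in range(n_rep)
        )
        assert rejections / n_rep <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)


def test_upscaled_table_excludes_unphased_trios(halfsib_pedigree):
    rows = [
        {**_mut("C1", 10), "origin": ORIGIN_PATERNAL},
        {**_mut("C1", 20), "origin": ORIGIN_UNPHASED},
        {**_mut("C2", 30), "origin": ORIGIN_UNPHASED},  # C2 has nothing phased
    ]
    table = upscaled_table(pd.DataFrame(rows), halfsib_pedigree)
    assert table["trio"].tolist() == ["C1"]
    assert table["paternal_count"].iloc[0] == pytest.approx(2.0)
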