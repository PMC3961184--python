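"""Bioassay, LC50, exact Mann-Whitney and depletion statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resistscope import phenotypes, synthetic


def reps(n_dead_list, n=25, **cond):
    base = {"insecticide": "bendiocarb", "season": "dry", "pbo": False}
    base.update(cond)
    return pd.DataFrame(
        [{**base, "replicate": i + 1, "n_exposed": n, "n_dead": d}
         for i, d in enumerate(n_dead_list)]
    )


class TestMortalitySummary:
    def test_wilson_interval_hand_value(self):
        out = phenotypes.mortality_summary(reps([20, 20, 20, 20]))
        assert out["mortality"].iloc[0] == pytest.approx(0.80)
        assert out["ci_low"].iloc[0] == pytest.approx(0.711, abs=0.001)
        assert out["ci_high"].iloc[0] == pytest.approx(0.867, abs=0.001)

    def test_all_dead_upper_limit_one(self):
        out = phenotypes.mortality_summary(reps([25, 25]))
        assert out["mortality"].iloc[0] == 1.0
        assert out["ci_high"].iloc[0] == pytest.approx(1.0)

    def test_none_dead_lower_limit_zero(self):
        out = phenotypes.mortality_summary(reps([0, 0]))
        assert out["mortality"].iloc[0] == 0.0
        assert out["ci_low"].iloc[0] == pytest.approx(0.0)

    def test_wilson_interval_covers_truth_at_nominal_rate(self):
        rng = np.random.default_rng(0)
        for p in (0.1, 0.5, 0.8):
            dead = rng.binomial(100, p, size=10000)
            # one draw per condition group, so each row gets its own CI
            out = phenotypes.mortality_summary(
                pd.DataFrame(
                    {"draw": np.arange(dead.size), "n_exposed": 100, "n_dead": dead}
                ),
                by=("draw",),
            )
            cover = ((out["ci_low"] <= p) & (p <= out["ci_high"])).mean()
            assert 0.93 <= cover <= 0.97


class TestSynergism:
    def test_identical_mortality_null(self):
        res = phenotypes.synergism_test((40, 100), (40, 100))
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_example(self):
        res = phenotypes.synergism_test((80, 100), (17, 100))
        assert res["odds_ratio"] == pytest.approx(19.53, abs=0.01)
        assert res["chi2"] == pytest.approx(79.45, abs=0.01)
        assert res["p"] < 1e-3

    def test_complete_mortality_uses_haldane(self):
        res = phenotypes.synergism_test((100, 100), (99, 100))
        assert res["haldane"]
        assert np.isfinite(res["odds_ratio"])

    def test_or_above_one_iff_pbo_mortality_higher(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            d1, d0 = rng.integers(1, 99, size=2)
            res = phenotypes.synergism_test((int(d1), 100), (int(d0), 100))
            assert (res["odds_ratio"] > 1) == (d1 > d0)


def dose_df(doses, survival, n=10):
    return pd.DataFrame(
        {
            "line_id": "l",
            "dose_ug": doses,
            "n": n,
            "n_survived": np.asarray(survival) * n,
        }
    )


class TestLC50:
    def test_symmetric_profile_gives_unit_lc50(self):
        fit = phenotypes.fit_lc50(
            dose_df([0.25, 0.5, 1.0, 2.0, 4.0], [0.9, 0.7, 0.5, 0.3, 0.1])
        )
        assert fit["lc50"] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("planted", [0.11, 0.94, 5.56, 18.37])
    def test_noise_free_recovery_is_exact(self, planted):
        doses = planted * 10.0 ** np.linspace(-1.4, 1.4, 6)
        obs = synthetic.generate_dose_response(
            [("l", planted, 0.3)], list(doses), noise="none"
        )
        fit = phenotypes.fit_lc50(obs)
        assert fit["lc50"] == pytest.approx(planted, rel=1e-9)
        assert fit["ci"][0] == pytest.approx(fit["ci"][1], rel=1e-6)

    def test_sharp_inflection_refused_with_guidance(self):
        df = dose_df([0.1, 0.2, 0.4, 0.8], [1.0, 1.0, 0.0, 0.0])
        with pytest.raises(phenotypes.SharpInflectionError, match="discriminating"):
            phenotypes.fit_lc50(df)

    def test_dose_scale_equivariance(self):
        df = dose_df([0.5, 1.0, 2.0, 4.0], [0.8, 0.6, 0.4, 0.2])
        base = phenotypes.fit_lc50(df)["lc50"]
        scaled = df.assign(dose_ug=df["dose_ug"] * 7.0)
        assert phenotypes.fit_lc50(scaled)["lc50"] == pytest.approx(7.0 * base, rel=1e-9)

    def test_fieller_interval_contains_estimate_under_noise(self):
        obs = synthetic.generate_dose_response(
            [("l", 1.0, 0.3)],
            list(10.0 ** np.linspace(-1.2, 1.2, 8)),
            n_per_vial=50,
            seed=5,
        )
        fit = phenotypes.fit_lc50(obs)
        assert fit["ci"][0] < fit["lc50"] < fit["ci"][1]


def brute_force_mw_p(x, y):
    """Independent oracle: permutation distribution of U computed by
    pairwise comparison counting (not rank sums)."""

    def u_stat(a, b):
        return sum(
            1.0 if ai > bi else 0.5 if ai == bi else 0.0
            for ai in a for bi in b
        )

    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = u_stat(x, y)
    n_le = n_ge = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(a, b)
        total += 1
        if u <= u_obs + 1e-9:
            n_le += 1
        if u >= u_obs - 1e-9:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


class TestExactMannWhitney:
    def test_complete_separation_8v8_minimum_p(self):
        res = phenotypes.exact_mannwhitney(np.arange(8) + 100, np.arange(8))
        assert res["p"] == pytest.approx(2 / 12870)

    def test_identical_groups_give_p_one(self):
        res = phenotypes.exact_mannwhitney([1, 1, 1], [1, 1, 1])
        assert res["p"] == 1.0

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(7)
        x, y = rng.integers(0, 5, 6), rng.integers(0, 5, 5)
        assert phenotypes.exact_mannwhitney(x, y)["p"] == pytest.approx(
            phenotypes.exact_mannwhitney(y, x)["p"]
        )

    def test_matches_scipy_exact_without_ties(self):
        from scipy import stats

        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(size=rng.integers(3, 7))
            y = rng.normal(size=rng.integers(3, 7))
            ours = phenotypes.exact_mannwhitney(x, y)["p"]
            _, ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours == pytest.approx(ref, rel=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.integers(0, 3), min_size=2, max_size=6),
        st.lists(st.integers(0, 3), min_size=2, max_size=6),
    )
    def test_matches_brute_force_oracle_with_ties(self, x, y):
        assert phenotypes.exact_mannwhitney(x, y)["p"] == pytest.approx(
            brute_force_mw_p(x, y)
        )


class TestDiscriminatingDose:
    def test_resistance_ratio_and_p(self):
        test = [0.7, 0.8, 0.7, 0.6, 0.7, 0.8, 0.6, 0.7]
        control = [0.1, 0.0, 0.1, 0.2, 0.1, 0.0, 0.1, 0.2]
        res = phenotypes.discriminating_dose_test(test, control)
        assert res["resistance_ratio"] == pytest.approx(7.0, rel=0.1)
        assert res["p"] == pytest.approx(2 / 12870)

    def test_zero_control_survival_ratio_undefined_p_reported(self):
        res = phenotypes.discriminating_dose_test([0.5, 0.6, 0.7], [0.0, 0.0, 0.0])
        assert np.isnan(res["resistance_ratio"])
        assert 0.0 < res["p"] <= 1.0


class TestDepletion:
    def test_no_depletion_when_means_equal(self):
        res = phenotypes.substrate_depletion([500, 500], [500, 500])
        assert res["mean_depletion"] == 0.0

    def test_constructed_peak_areas(self):
        res = phenotypes.substrate_depletion([358, 358, 358], [1000, 1000, 1000])
        assert res["mean_depletion"] == pytest.approx(64.2)

    def test_negative_raw_value_clamped_and_flagged(self):
        res = phenotypes.substrate_depletion([1100, 1120], [1000, 1000])
        assert res["mean_depletion"] == 0.0
        assert res["clamped"]
        assert res["raw_depletion"] < 0.0

    def test_nonpositive_control_rejected(self):
        with pytest.raises(phenotypes.PhenotypeError):
            phenotypes.substrate_depletion([1.0], [0.0])
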