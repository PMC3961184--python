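"""Genotype calling and population/association statistics."""

import numpy as np
import pandas as pd
import pytest

from resistscope import genotyping, synthetic


def plate_df(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "fam_dR", "vic_dR", "control_type", "phenotype"]
    )


BASE_CONTROLS = [
    ("cSS", np.sin(np.deg2rad(75)), np.cos(np.deg2rad(75)), "SS", "untested"),
    ("cGG", np.sin(np.deg2rad(15)), np.cos(np.deg2rad(15)), "GG", "untested"),
]


class TestCallGenotypes:
    def test_sample_at_control_angle_called_homozygote(self):
        plate = plate_df(
            BASE_CONTROLS
            + [("s1", np.sin(np.deg2rad(75)), np.cos(np.deg2rad(75)), "none", "alive")]
        )
        calls = genotyping.call_genotypes(plate)
        assert calls.set_index("sample_id").loc["s1", "call"] == "SS"

    def test_equal_dyes_called_heterozygote(self):
        plate = plate_df(BASE_CONTROLS + [("s1", 0.7, 0.7, "none", "dead")])
        calls = genotyping.call_genotypes(plate)
        assert calls.set_index("sample_id").loc["s1", "call"] == "GS"

    def test_dim_well_and_ambiguous_angle_no_called(self):
        # controls at 80/10 degrees leave a gap > 15 degrees from every
        # reference around 27.5 degrees
        controls = [
            ("cSS", np.sin(np.deg2rad(80)), np.cos(np.deg2rad(80)), "SS", "untested"),
            ("cGG", np.sin(np.deg2rad(10)), np.cos(np.deg2rad(10)), "GG", "untested"),
        ]
        plate = plate_df(
            controls
            + [
                ("dim", 0.05, 0.05, "none", "dead"),
                ("ambig", np.sin(np.deg2rad(27.5)), np.cos(np.deg2rad(27.5)), "none", "dead"),
            ]
        )
        calls = genotyping.call_genotypes(plate).set_index("sample_id")
        assert calls.loc["dim", "call"] == "NC"
        assert calls.loc["ambig", "call"] == "NC"

    def test_scale_invariance_of_calls(self):
        plate, _ = synthetic.generate_taqman_plate(
            {"SS": 5, "GS": 5, "GG": 5}, angular_sd=2.0, seed=8
        )
        scaled = plate.copy()
        scaled[["fam_dR", "vic_dR"]] *= 37.5
        a = genotyping.call_genotypes(plate)["call"]
        b = genotyping.call_genotypes(scaled)["call"]
        assert (a == b).all()

    def test_missing_controls_rejected(self):
        plate = plate_df([("s1", 0.7, 0.7, "none", "dead")])
        with pytest.raises(genotyping.GenotypingError):
            genotyping.call_genotypes(plate)

    def test_synthetic_plate_concordance_at_wide_separation(self):
        plate, labels = synthetic.generate_taqman_plate(
            {"SS": 100, "GS": 100, "GG": 100}, angular_sd=5.0, seed=21
        )
        calls = genotyping.call_genotypes(plate).set_index("sample_id")
        truth = labels[~labels.index.str.startswith("CTRL")]
        called = calls.loc[truth.index, "call"]
        ok = called != "NC"
        assert (called[ok] == truth[ok]).mean() >= 0.99
        assert (~ok).mean() < 0.02


class TestDyeBalance:
    def test_planted_duplication_shift_detected(self):
        plate, _ = synthetic.generate_taqman_plate(
            {"GS": 20, "DUP_GS": 20},
            angular_sd=1.0,
            alive_prob={"GS": 0.0, "DUP_GS": 1.0},
            seed=5,
        )
        calls = genotyping.call_genotypes(plate)
        res = genotyping.het_dye_balance_contrast(calls)
        assert res["p"] < 1e-6
        assert res["mean_alive"] > res["mean_dead"]

    def test_identical_groups_give_p_one(self):
        calls = pd.DataFrame(
            {
                "call": ["GS"] * 4,
                "dye_ratio": [1.0, 1.0, 1.0, 1.0],
                "phenotype": ["alive", "alive", "dead", "dead"],
            }
        )
        assert genotyping.het_dye_balance_contrast(calls)["p"] == 1.0

    def test_insufficient_heterozygotes_rejected(self):
        calls = pd.DataFrame(
            {"call": ["GS", "GS"], "dye_ratio": [1.0, 1.2], "phenotype": ["alive", "dead"]}
        )
        with pytest.raises(genotyping.GenotypingError):
            genotyping.het_dye_balance_contrast(calls)


class TestAlleleFrequency:
    def test_field_counts_reproduce_reported_frequency(self):
        # all serine alleles in heterozygotes: 141 GS, 12 GG among 153
        res = genotyping.allele_frequency(0, 141, 12)
        assert res["freq_S"] == pytest.approx(141 / 306)
        assert res["het_frequency"] == pytest.approx(141 / 153)
        lo, hi = res["het_frequency_ci"]
        assert lo < 141 / 153 < hi

    def test_monomorphic_sample(self):
        res = genotyping.allele_frequency(10, 0, 0)
        assert res["freq_S"] == 1.0
        assert res["het_frequency"] == 0.0

    def test_small_mixed_sample(self):
        res = genotyping.allele_frequency(0, 2, 2)
        assert res["freq_S"] == 0.25
        assert res["het_frequency"] == 0.5


class TestHWE:
    def test_exact_hw_proportions_give_zero(self):
        chi2, p = genotyping.hwe_test(25, 50, 25)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_two_heterozygotes_only(self):
        chi2, _ = genotyping.hwe_test(0, 2, 0)
        assert chi2 == pytest.approx(2.0)

    def test_all_serine_in_heterozygotes_hand_value(self):
        chi2, p = genotyping.hwe_test(0, 141, 12)
        assert chi2 == pytest.approx(111.73, abs=0.01)
        assert p < 1e-20


class TestAssociation:
    def test_worked_odds_ratio(self):
        res = genotyping.association_test([[50, 50], [2, 48]])
        assert res["odds_ratio"] == pytest.approx(24.0)

    def test_equal_rows_null(self):
        res = genotyping.association_test([[30, 70], [30, 70]])
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_cell_triggers_haldane(self):
        res = genotyping.association_test([[10, 0], [5, 5]])
        assert res["haldane"]
        assert np.isfinite(res["odds_ratio"])

    def test_zero_margin_rejected(self):
        with pytest.raises(genotyping.GenotypingError):
            genotyping.association_test([[0, 10], [0, 5]])

    def test_or_invariant_to_double_swap_chi2_to_any_permutation(self):
        t = np.array([[13, 7], [4, 21]])
        base = genotyping.association_test(t)
        swapped = genotyping.association_test(t[::-1, ::-1])
        assert swapped["odds_ratio"] == pytest.approx(base["odds_ratio"])
        rowswap = genotyping.association_test(t[::-1, :])
        assert rowswap["chi2"] == pytest.approx(base["chi2"])


class TestHomogeneity:
    def test_identical_strata_zero(self):
        chi2, p, df = genotyping.homogeneity_test(
            [[[20, 10], [10, 20]]] * 2
        )
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1

    def test_hand_woolf_value(self):
        chi2, _, _ = genotyping.homogeneity_test(
            [[[90, 10], [50, 50]], [[50, 50], [50, 50]]]
        )
        assert chi2 == pytest.approx(20.89, abs=0.01)

    def test_three_identical_strata_df_two(self):
        chi2, _, df = genotyping.homogeneity_test([[[20, 10], [10, 20]]] * 3)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 2

    def test_single_stratum_rejected(self):
        with pytest.raises(genotyping.GenotypingError):
            genotyping.homogeneity_test([[[20, 10], [10, 20]]])
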