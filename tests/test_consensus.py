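"""Consensus filtering rules and gene aggregation."""

import numpy as np
import pandas as pd
import pytest

from resistscope import consensus

SUS = ("NGousso", "MaliNIH", "Okyereko")
EXP1_COMPS = [(res, sus) for res in ("TiaSel", "Tia") for sus in SUS]
EXP1_PLAN = consensus.ComparisonPlan(
    "exp1",
    tuple(EXP1_COMPS),
    tuple((f"TiaSel_vs_{s}", f"Tia_vs_{s}") for s in SUS),
)
EXP2_PLAN = consensus.ComparisonPlan(
    "exp2", (("Kovie", "Okyereko"), ("Kovie", "Malanville"))
)


def contrast_table(probe_values: dict, comps) -> pd.DataFrame:
    """probe -> {comparison_id: (log2FC, q)}."""
    rows = []
    for probe, per_comp in probe_values.items():
        for (res, sus) in comps:
            cid = consensus.comparison_id(res, sus)
            if cid in per_comp:
                fc, q = per_comp[cid]
                rows.append((probe, cid, fc, q))
    return pd.DataFrame(rows, columns=["probe_id", "comparison_id", "log2FC", "q"])


def exp1_probe(sel_fcs, une_fcs, qs):
    vals = {}
    for s, fc, q in zip(SUS, sel_fcs, qs[:3]):
        vals[f"TiaSel_vs_{s}"] = (fc, q)
    for s, fc, q in zip(SUS, une_fcs, qs[3:]):
        vals[f"Tia_vs_{s}"] = (fc, q)
    return vals


class TestExp1Criteria:
    def test_all_criteria_met_is_significant(self):
        tab = contrast_table(
            {"p": exp1_probe([2.0, 2.1, 1.9], [1.5, 1.6, 1.4], [0.01] * 6)},
            EXP1_COMPS,
        )
        v = consensus.evaluate_exp1(tab, EXP1_PLAN)
        assert v["significant"].iloc[0]

    def test_single_q_above_threshold_vetoes(self):
        # mirrors a gene marginally non-significant with five of six
        # comparisons below the q threshold
        qs = [0.01] * 5 + [0.06]
        tab = contrast_table(
            {"p": exp1_probe([2.0, 2.1, 1.9], [1.5, 1.6, 1.4], qs)}, EXP1_COMPS
        )
        v = consensus.evaluate_exp1(tab, EXP1_PLAN)
        assert not v["significant"].iloc[0]
        assert v["crit_direction"].iloc[0] and v["crit_escalation"].iloc[0]

    def test_all_q_one_not_significant(self):
        tab = contrast_table(
            {"p": exp1_probe([2.0, 2.1, 1.9], [1.5, 1.6, 1.4], [1.0] * 6)},
            EXP1_COMPS,
        )
        assert not consensus.evaluate_exp1(tab, EXP1_PLAN)["significant"].iloc[0]

    def test_escalation_requires_selected_more_extreme(self):
        tab = contrast_table(
            {"p": exp1_probe([1.4, 2.1, 1.9], [1.5, 1.6, 1.4], [0.01] * 6)},
            EXP1_COMPS,
        )
        v = consensus.evaluate_exp1(tab, EXP1_PLAN)
        assert not v["crit_escalation"].iloc[0]
        assert not v["significant"].iloc[0]

    def test_consistent_under_expression_allowed(self):
        tab = contrast_table(
            {"p": exp1_probe([-2.0, -2.1, -1.9], [-1.5, -1.6, -1.4], [0.01] * 6)},
            EXP1_COMPS,
        )
        assert consensus.evaluate_exp1(tab, EXP1_PLAN)["significant"].iloc[0]

    def test_probe_missing_a_comparison_is_unevaluable_not_failed(self):
        vals = exp1_probe([2.0, 2.1, 1.9], [1.5, 1.6, 1.4], [0.01] * 6)
        del vals["Tia_vs_Okyereko"]
        v = consensus.evaluate_exp1(contrast_table({"p": vals}, EXP1_COMPS), EXP1_PLAN)
        assert not v["evaluable"].iloc[0]
        assert not v["significant"].iloc[0]


class TestExp2Criteria:
    def make(self, fc_q_pairs):
        vals = {
            "Kovie_vs_Okyereko": fc_q_pairs[0],
            "Kovie_vs_Malanville": fc_q_pairs[1],
        }
        return contrast_table({"p": vals}, EXP2_PLAN.comparisons)

    def test_both_significant_same_sign(self):
        v = consensus.evaluate_exp2(self.make([(1.0, 0.03), (0.8, 0.04)]), EXP2_PLAN)
        assert v["significant"].iloc[0]

    def test_discordant_signs_vetoed_despite_tiny_q(self):
        v = consensus.evaluate_exp2(
            self.make([(1.0, 1e-8), (-0.8, 1e-8)]), EXP2_PLAN
        )
        assert not v["significant"].iloc[0]

    def test_threshold_is_strict_in_every_comparison(self):
        v = consensus.evaluate_exp2(
            self.make([(1.0, 0.049), (0.8, 0.051)]), EXP2_PLAN
        )
        assert not v["significant"].iloc[0]


class TestCombine:
    def verdict(self, probe, sig, fc=1.0):
        return pd.DataFrame(
            {"probe_id": [probe], "significant": [sig], "mean_log2FC": [fc]}
        )

    def test_significant_in_one_experiment_only_is_not_overall(self):
        probes, genes = consensus.combine_experiments(
            self.verdict("p1", True), self.verdict("p1", False), {"p1": "g1"}
        )
        assert not probes["overall_significant"].iloc[0]
        assert genes["n_probes_significant"].iloc[0] == 0

    def test_probe_in_single_experiment_marked_untested(self):
        v1 = self.verdict("p1", True)
        v2 = pd.concat([self.verdict("p1", True), self.verdict("p2", True)])
        probes, _ = consensus.combine_experiments(v1, v2, {"p1": "g", "p2": "g"})
        row = probes.set_index("probe_id").loc["p2"]
        assert row["status"] == "untested"
        assert not row["overall_significant"]

    def test_gene_annotation_counts_significant_over_total(self):
        v1 = pd.concat([self.verdict(f"p{i}", True) for i in range(4)])
        v2 = pd.concat([self.verdict(f"p{i}", True) for i in range(4)])
        _, genes = consensus.combine_experiments(
            v1, v2, {f"p{i}": "g" for i in range(4)}
        )
        assert genes["annotation"].iloc[0] == "4/4"


class TestProperties:
    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(0)
        tab = contrast_table(
            {
                f"p{i}": exp1_probe(
                    rng.normal(1, 1, 3), rng.normal(0.7, 1, 3), rng.uniform(0, 0.1, 6)
                )
                for i in range(200)
            },
            EXP1_COMPS,
        )
        strict = consensus.ComparisonPlan(
            "exp1", EXP1_PLAN.comparisons, EXP1_PLAN.selected_unexposed_pairs,
            alpha=0.01,
        )
        s_strict = set(
            consensus.evaluate_exp1(tab, strict).query("significant")["probe_id"]
        )
        s_loose = set(
            consensus.evaluate_exp1(tab, EXP1_PLAN).query("significant")["probe_id"]
        )
        assert s_strict <= s_loose

    def test_adding_a_comparison_never_rescues_a_probe(self):
        rng = np.random.default_rng(1)
        partial_comps = EXP1_COMPS[:4]
        partial_plan = consensus.ComparisonPlan("exp1", tuple(partial_comps))
        values = {
            f"p{i}": exp1_probe(
                rng.normal(1, 1, 3), rng.normal(0.7, 1, 3), rng.uniform(0, 0.1, 6)
            )
            for i in range(200)
        }
        tab_full = contrast_table(values, EXP1_COMPS)
        tab_part = contrast_table(
            {p: {k: v for k, v in vals.items()
                 if k in {consensus.comparison_id(*c) for c in partial_comps}}
             for p, vals in values.items()},
            partial_comps,
        )
        full_plan = consensus.ComparisonPlan("exp1", tuple(EXP1_COMPS))
        sig_full = set(
            consensus.evaluate_exp1(tab_full, full_plan).query("significant")["probe_id"]
        )
        sig_part = set(
            consensus.evaluate_exp1(tab_part, partial_plan).query("significant")["probe_id"]
        )
        assert sig_full <= sig_part
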