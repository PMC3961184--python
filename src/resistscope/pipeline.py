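"""End-to-end orchestration: simulate a full study, run every stage,
and write a traceable report.

``simulate_all`` writes a complete synthetic study — two array
experiments, qPCR expression and copy-number Ct tables, a TaqMan
genotyping plate, WHO-bioassay counts, dose-response and
discriminating-dose survival, and HPLC peak areas — with a
``truth.json`` sidecar of planted parameters.  ``run_pipeline`` chains
differential expression, consensus filtering, qPCR quantitation,
genotype/copy-number association and phenotype statistics over such a
directory and writes a report whose every number traces to a stage
output file.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from resistscope import __version__, consensus, diffexpr, genotyping, phenotypes, qpcr
from resistscope.io import load_and_validate, write_json, write_table
from resistscope.synthetic import (
    EXP1_RESISTANT,
    EXP1_SUSCEPTIBLE,
    SimConfig,
    exp1_scheme,
    exp2_scheme,
    generate_bioassay_counts,
    generate_ct_table,
    generate_dose_response,
    generate_expression_experiment,
    generate_taqman_plate,
    make_probe_map,
    make_truth,
)

__all__ = ["simulate_all", "run_pipeline", "write_report", "default_config"]

CANDIDATE_GENES = ("ACE1", "CYP6M2", "CYP6P1", "CYP6P2", "CYP6P3", "CYP6P4", "CYB5")
REFERENCE_GENES = ("Rsp7", "EF")
ACE1_AMPLICONS = ("ACE1_ex2", "ACE1_ex5", "ACE1_ex7")
CN_REFERENCES = ("CYP4G16", "EF_gdna")
INSECTICIDES = ("bendiocarb", "permethrin", "deltamethrin", "DDT", "fenitrothion")

# planted bioassay mortalities (insecticide -> (without PBO, with PBO));
# bendiocarb shows the strongest synergism, DDT essentially none
BIOASSAY_TRUTH = {
    "bendiocarb": (0.17, 0.80),
    "permethrin": (0.30, 0.75),
    "deltamethrin": (0.35, 0.78),
    "DDT": (0.25, 0.30),
    "fenitrothion": (0.55, 0.95),
}

# planted dose-response LC50s (µg) for transgenic lines, slope per log10 dose
DOSE_LINES = {
    "CYP6M2_Act5C_perm": 18.37,
    "CYP6M2_CyO_perm": 4.97,
    "CYP6P3_Act5C_perm": 13.74,
    "CYP6P3_CyO_perm": 5.56,
    "CYP6M2_Act5C_delta": 0.94,
    "CYP6M2_CyO_delta": 0.11,
    "CYP6P3_Act5C_delta": 0.72,
    "CYP6P3_CyO_delta": 0.09,
}
DOSE_SLOPE = 0.3


def _scheme_tables(scheme):
    arrays = pd.DataFrame(
        scheme.arrays, columns=["array_id", "cy3_sample", "cy5_sample"]
    )
    samples = pd.DataFrame(scheme.samples, columns=["sample_id", "group"])
    return arrays, samples


def simulate_all(
    out_dir: str | Path,
    seed: int = 0,
    n_genes: int = 400,
    probes_per_gene: int = 4,
    array_noise_sd: float = 0.25,
    ct_noise_sd: float = 0.15,
) -> dict:
    """Write a complete synthetic study under ``out_dir``.

    Seven planted resistance genes (named for the field's candidate
    loci) are over-expressed in every resistant group with the
    bendiocarb-selected group most extreme; a handful of decoy genes
    are perturbed in only one experiment to exercise the cross-
    experiment intersection.  Returns the truth dictionary (also
    written to ``truth.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # --- expression truth -------------------------------------------------
    probe_map = make_probe_map(n_genes, probes_per_gene)
    extra = {
        f"{g}_{i}": g
        for g in CANDIDATE_GENES
        for i in range(probes_per_gene)
    }
    decoys_exp1 = [f"DECOY1_{i}" for i in range(3)]
    decoys_exp2 = [f"DECOY2_{i}" for i in range(3)]
    for g in decoys_exp1 + decoys_exp2:
        for i in range(probes_per_gene):
            extra[f"{g}_{i}"] = g
    probe_map.update(extra)

    flagged: dict[str, dict[str, float]] = {}
    for g in CANDIDATE_GENES:
        hi = float(rng.uniform(1.6, 2.4))
        flagged[g] = {"TiaSel": hi, "Tia": hi - 0.5, "Kovie": hi - 0.6}
    for g in decoys_exp1:
        flagged[g] = {"TiaSel": 1.8, "Tia": 1.2}           # absent in Exp2
    for g in decoys_exp2:
        flagged[g] = {"Kovie": 1.8}                        # absent in Exp1
    truth = make_truth(probe_map, flagged)

    scheme1, scheme2 = exp1_scheme(), exp2_scheme()
    for name, scheme in (("exp1", scheme1), ("exp2", scheme2)):
        cfg = SimConfig(
            n_probes=len(probe_map),
            n_genes=n_genes,
            probes_per_gene=probes_per_gene,
            array_noise_sd=array_noise_sd,
            dye_bias_sd=0.1,
            seed=int(rng.integers(2**31)),
        )
        m, _ = generate_expression_experiment(scheme, truth, cfg)
        arrays, samples = _scheme_tables(scheme)
        write_table(m, out / name / "mvalues.tsv")
        write_table(arrays, out / name / "scheme.tsv")
        write_table(samples, out / name / "samples.tsv")
    write_table(
        pd.DataFrame(sorted(probe_map.items()), columns=["probe_id", "gene_id"]),
        out / "probe2gene.tsv",
    )

    # --- qPCR expression --------------------------------------------------
    qpcr_groups = {"TiaSel": 3, "Tia": 5, "Kovie": 5, "Okyereko": 5}
    planted_folds = {
        g: {
            "TiaSel": 2.0 ** flagged[g]["TiaSel"],
            "Tia": 2.0 ** flagged[g]["Tia"],
            "Kovie": 2.0 ** flagged[g]["Kovie"],
            "Okyereko": 1.0,
        }
        for g in CANDIDATE_GENES
    }
    samples_ct, groups_map = [], {}
    for grp, n in qpcr_groups.items():
        for i in range(n):
            sid = f"{grp}_r{i + 1}"
            groups_map[sid] = grp
            quantities = {"Rsp7": 1.0, "EF": 1.0}
            for g in CANDIDATE_GENES:
                quantities[g] = planted_folds[g][grp]
            samples_ct.append((sid, quantities))
    efficiencies = {a: 1.0 for a in CANDIDATE_GENES + REFERENCE_GENES}
    for a in CANDIDATE_GENES:
        efficiencies[a] = float(rng.uniform(0.85, 1.0))
    ct_expr, _ = generate_ct_table(
        samples_ct, efficiencies, replicates=3, ct_noise_sd=ct_noise_sd,
        seed=int(rng.integers(2**31)),
    )
    write_table(ct_expr, out / "ct_expression.tsv")
    write_table(
        pd.DataFrame(sorted(efficiencies.items()), columns=["amplicon", "efficiency"]),
        out / "efficiencies_expression.tsv",
    )
    write_table(
        pd.DataFrame(sorted(groups_map.items()), columns=["sample_id", "group"]),
        out / "groups_expression.tsv",
    )

    # --- ACE-1 copy number ------------------------------------------------
    # calibrator strain carries two copies; ratio 1.5 == one extra allele
    cn_truth: dict[str, int] = {}
    cn_samples = []
    survivors = [f"SURV_{i + 1:02d}" for i in range(16)]
    dead = [f"DEAD_{i + 1:02d}" for i in range(16)]
    # carriers planted at 4 copies: 3 copies sits exactly on the 1.5
    # threshold, which the strict "in excess of" rule treats as below
    for i, sid in enumerate(survivors):
        cn_truth[sid] = 4 if i < 15 else 2          # 15/16 with extra copies
    for i, sid in enumerate(dead):
        cn_truth[sid] = 4 if i < 5 else 2           # 5/16 with extra copies
    for sid, copies in cn_truth.items():
        q = {a: copies / 2.0 for a in ACE1_AMPLICONS}
        q.update({r: 1.0 for r in CN_REFERENCES})
        cn_samples.append((sid, q))
    for pool in ("KisumuPool_1", "KisumuPool_2"):
        q = {a: 1.0 for a in ACE1_AMPLICONS}
        q.update({r: 1.0 for r in CN_REFERENCES})
        cn_samples.append((pool, q))
    cn_eff = {a: 1.0 for a in ACE1_AMPLICONS + CN_REFERENCES}
    ct_cn, _ = generate_ct_table(
        cn_samples, cn_eff, replicates=3, ct_noise_sd=0.10,
        seed=int(rng.integers(2**31)),
    )
    write_table(ct_cn, out / "ct_copynumber.tsv")
    write_table(
        pd.DataFrame(sorted(cn_eff.items()), columns=["amplicon", "efficiency"]),
        out / "efficiencies_copynumber.tsv",
    )

    # --- TaqMan plate -----------------------------------------------------
    taqman_counts = {"SS": 0, "GS": 120, "DUP_GS": 40, "GG": 12}
    alive_prob = {"GG": 0.05, "GS": 0.30, "DUP_GS": 0.90}
    plate, labels = generate_taqman_plate(
        taqman_counts, angular_sd=3.0, alive_prob=alive_prob,
        seed=int(rng.integers(2**31)),
    )
    write_table(plate, out / "taqman.tsv")

    # --- bioassays --------------------------------------------------------
    conditions = []
    for ins in INSECTICIDES:
        p0, p1 = BIOASSAY_TRUTH[ins]
        for season in ("dry", "wet"):
            conditions.append((ins, season, False, p0, 4, 25))
            conditions.append((ins, season, True, p1, 4, 25))
    bio = generate_bioassay_counts(conditions, seed=int(rng.integers(2**31)))
    write_table(bio, out / "bioassay.tsv")

    # --- dose-response ----------------------------------------------------
    frames = []
    for line_id, lc50 in DOSE_LINES.items():
        doses = lc50 * 10.0 ** np.linspace(-1.3, 1.3, 6)
        frames.append(
            generate_dose_response(
                [(line_id, lc50, DOSE_SLOPE)], list(doses), n_per_vial=50,
                noise="binomial", seed=int(rng.integers(2**31)),
            )
        )
    dose = pd.concat(frames, ignore_index=True)
    write_table(dose.drop(columns=["survival"]), out / "dose.tsv")

    # bendiocarb discriminating dose, 8 vials per line at 0.1 µg
    disc_truth = {"CYP6M2_Act5C_bendio": 0.70, "CYP6M2_CyO_bendio": 0.10,
                  "CYP6P3_Act5C_bendio": 0.28, "CYP6P3_CyO_bendio": 0.20}
    rows = []
    for line_id, p in disc_truth.items():
        surv = rng.binomial(10, p, size=8)
        for s in surv:
            rows.append((line_id, 0.1, 10, int(s)))
    write_table(
        pd.DataFrame(rows, columns=["line_id", "dose_ug", "n", "n_survived"]),
        out / "disc.tsv",
    )

    # --- HPLC depletion ---------------------------------------------------
    hplc_rows = []
    for i in range(3):
        hplc_rows.append(("CYP6P3", True, i + 1, float(rng.normal(358, 15))))
        hplc_rows.append(("CYP6P3", False, i + 1, float(rng.normal(1000, 20))))
        hplc_rows.append(("CYP6M2", True, i + 1, float(rng.normal(1000, 40))))
        hplc_rows.append(("CYP6M2", False, i + 1, float(rng.normal(1000, 40))))
    write_table(
        pd.DataFrame(
            hplc_rows, columns=["condition", "nadph", "replicate", "peak_area"]
        ),
        out / "hplc.tsv",
    )

    truth_doc = {
        "seed": seed,
        "flagged_offsets": flagged,
        "consensus_genes": sorted(CANDIDATE_GENES),
        "planted_folds": planted_folds,
        "copy_number": cn_truth,
        "taqman_classes": labels.to_dict(),
        "bioassay_mortality": {k: list(v) for k, v in BIOASSAY_TRUTH.items()},
        "dose_lc50": DOSE_LINES,
        "dose_slope": DOSE_SLOPE,
        "disc_survival": disc_truth,
    }
    write_json(truth_doc, out / "truth.json")
    return truth_doc


def default_config(data_dir: str | Path) -> dict:
    """Configuration mapping for a ``simulate_all`` directory layout."""
    d = Path(data_dir)
    return {
        "alpha": 0.05,
        "copy_ratio_threshold": 1.5,
        "diagnostic_dose_ug": 0.1,
        "exp1": {
            "mvalues": str(d / "exp1" / "mvalues.tsv"),
            "scheme": str(d / "exp1" / "scheme.tsv"),
            "samples": str(d / "exp1" / "samples.tsv"),
            "comparisons": [
                [res, sus]
                for res in EXP1_RESISTANT
                for sus in EXP1_SUSCEPTIBLE
            ],
            "selected_unexposed_pairs": [
                [f"TiaSel_vs_{sus}", f"Tia_vs_{sus}"] for sus in EXP1_SUSCEPTIBLE
            ],
        },
        "exp2": {
            "mvalues": str(d / "exp2" / "mvalues.tsv"),
            "scheme": str(d / "exp2" / "scheme.tsv"),
            "samples": str(d / "exp2" / "samples.tsv"),
            "comparisons": [["Kovie", "Okyereko"], ["Kovie", "Malanville"]],
        },
        "probe2gene": str(d / "probe2gene.tsv"),
        "qpcr": {
            "ct": str(d / "ct_expression.tsv"),
            "efficiencies": str(d / "efficiencies_expression.tsv"),
            "groups": str(d / "groups_expression.tsv"),
            "targets": list(CANDIDATE_GENES),
            "references": list(REFERENCE_GENES),
            "calibrator_group": "Okyereko",
            "ordering": ["TiaSel", "Tia", "Kovie"],
        },
        "copynumber": {
            "ct": str(d / "ct_copynumber.tsv"),
            "efficiencies": str(d / "efficiencies_copynumber.tsv"),
            "ace1_amplicons": list(ACE1_AMPLICONS),
            "reference_genes": list(CN_REFERENCES),
            "calibrators": ["KisumuPool_1", "KisumuPool_2"],
        },
        "taqman": str(d / "taqman.tsv"),
        "bioassay": str(d / "bioassay.tsv"),
        "dose": str(d / "dose.tsv"),
        "disc": str(d / "disc.tsv"),
        "hplc": str(d / "hplc.tsv"),
    }


def _load_scheme(cfg_block) -> "HybridizationScheme":
    from resistscope.synthetic import HybridizationScheme

    arrays = load_and_validate(cfg_block["scheme"], "scheme")
    samples = load_and_validate(cfg_block["samples"], "samples")
    return HybridizationScheme(
        [tuple(r) for r in arrays.itertuples(index=False)],
        [tuple(r) for r in samples.itertuples(index=False)],
    )


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute every stage on the configured inputs and write outputs.

    Stage order: differential expression for both experiments, the
    consensus filter, qPCR expression (with the fold-change ordering
    hypothesis check and per-group over-expression tests), copy-number
    calling with survivor-vs-dead contrast, TaqMan genotyping with
    allele/HWE/association statistics, and bioassay, dose-response and
    depletion statistics.  Returns the report dictionary (also written
    by :func:`write_report`).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    alpha = float(config.get("alpha", 0.05))
    report: dict = {}

    # --- differential expression + consensus ------------------------------
    verdicts = {}
    for exp in ("exp1", "exp2"):
        block = config[exp]
        scheme = _load_scheme(block)
        m = load_and_validate(block["mvalues"], "mvalues")
        comparisons = [tuple(c) for c in block["comparisons"]]
        res = diffexpr.run_differential_expression(m, scheme, comparisons)
        write_table(res, out / f"contrasts_{exp}.tsv")
        plan = consensus.ComparisonPlan(
            experiment_id=exp,
            comparisons=tuple(comparisons),
            selected_unexposed_pairs=tuple(
                tuple(p) for p in block.get("selected_unexposed_pairs", [])
            ),
            alpha=alpha,
        )
        verdicts[exp] = (
            consensus.evaluate_exp1(res, plan)
            if exp == "exp1"
            else consensus.evaluate_exp2(res, plan)
        )
        write_table(verdicts[exp], out / f"verdicts_{exp}.tsv")

    p2g = load_and_validate(config["probe2gene"], "probe2gene")
    probe_map = dict(zip(p2g["probe_id"], p2g["gene_id"]))
    probes, genes = consensus.combine_experiments(
        verdicts["exp1"], verdicts["exp2"], probe_map
    )
    write_table(probes, out / "probes_combined.tsv")
    write_table(genes, out / "genes.tsv")
    sig_genes = genes.loc[genes["n_probes_significant"] > 0, "gene_id"]
    report["consensus"] = {
        "n_probes_significant": int(probes["overall_significant"].sum()),
        "significant_genes": sorted(sig_genes),
    }

    # --- qPCR expression --------------------------------------------------
    qc = config["qpcr"]
    ct = load_and_validate(qc["ct"], "ct")
    eff_tab = load_and_validate(qc["efficiencies"], "efficiencies")
    eff = dict(zip(eff_tab["amplicon"], eff_tab["efficiency"]))
    grp_tab = load_and_validate(qc["groups"], "samples")
    groups = dict(zip(grp_tab["sample_id"], grp_tab["group"]))
    cal = qc["calibrator_group"]
    order = qc.get("ordering", [])
    fold_rows, qpcr_report = [], {}
    for target in qc["targets"]:
        table, norm = qpcr.relative_expression(
            ct, target, qc["references"], groups, cal, eff
        )
        table.insert(0, "gene_id", target)
        fold_rows.append(table)
        folds = dict(zip(table["group_id"], table["fold"]))
        ordering_ok = all(
            folds[a] > folds[b] for a, b in zip(order, order[1:]) if a in folds and b in folds
        )
        tests = {}
        grp_series = pd.Series({s: groups[s] for s in norm.index})
        cal_vals = norm[grp_series == cal]
        for g in sorted(set(grp_series) - {cal}):
            p, used = qpcr.overexpression_test(norm[grp_series == g], cal_vals)
            tests[g] = {"p": p, "test": used}
        qpcr_report[target] = {
            "folds": folds,
            "ordering_hypothesis_met": bool(ordering_ok),
            "overexpression_tests": tests,
        }
    write_table(pd.concat(fold_rows, ignore_index=True), out / "foldchanges.tsv")
    report["qpcr_expression"] = qpcr_report

    # --- copy number ------------------------------------------------------
    cc = config["copynumber"]
    ct_cn = load_and_validate(cc["ct"], "ct")
    eff_cn = dict(
        zip(
            *load_and_validate(cc["efficiencies"], "efficiencies")[
                ["amplicon", "efficiency"]
            ].T.values
        )
    )
    calls = qpcr.copy_number_ratio(
        ct_cn,
        cc["ace1_amplicons"],
        cc["reference_genes"],
        cc["calibrators"],
        eff_cn,
        threshold=float(config.get("copy_ratio_threshold", 1.5)),
    )
    write_table(calls, out / "copynumber.tsv")
    surv = calls[calls["sample_id"].str.startswith("SURV")]
    dead = calls[calls["sample_id"].str.startswith("DEAD")]
    cn_report = {
        "n_extra_copy": int(calls["extra_copy"].sum()),
        "n_samples": len(calls),
    }
    if len(surv) >= 2 and len(dead) >= 2:
        t, p = qpcr.copy_number_contrast(surv["ratio"], dead["ratio"])
        cn_report.update(
            {
                "survivor_extra": f"{int(surv['extra_copy'].sum())}/{len(surv)}",
                "dead_extra": f"{int(dead['extra_copy'].sum())}/{len(dead)}",
                "welch_t": t,
                "p": p,
            }
        )
    report["copy_number"] = cn_report

    # --- genotyping -------------------------------------------------------
    plate = load_and_validate(config["taqman"], "taqman")
    calls = genotyping.call_genotypes(plate)
    write_table(calls, out / "genotypes.tsv")
    n = calls["call"].value_counts()
    counts = {k: int(n.get(k, 0)) for k in ("SS", "GS", "GG", "NC")}
    freq = genotyping.allele_frequency(counts["SS"], counts["GS"], counts["GG"])
    chi2, p_hwe = genotyping.hwe_test(counts["SS"], counts["GS"], counts["GG"])
    geno_report = {
        "genotype_counts": counts,
        "allele_frequency": freq,
        "hwe": {"chi2": chi2, "p": p_hwe},
    }
    tested = calls[calls["phenotype"].isin(["alive", "dead"])]
    if not tested.empty:
        has_serine = tested["call"].isin(["SS", "GS"])
        alive = tested["phenotype"] == "alive"
        table = np.array(
            [
                [int((has_serine & alive).sum()), int((has_serine & ~alive).sum())],
                [int((~has_serine & alive).sum()), int((~has_serine & ~alive).sum())],
            ]
        )
        try:
            geno_report["serine_survival_association"] = genotyping.association_test(
                table
            )
        except genotyping.GenotypingError as exc:
            geno_report["serine_survival_association"] = {"error": str(exc)}
        try:
            geno_report["het_dye_balance"] = genotyping.het_dye_balance_contrast(calls)
        except genotyping.GenotypingError as exc:
            geno_report["het_dye_balance"] = {"error": str(exc)}
    report["genotyping"] = geno_report

    # --- bioassays and synergism -----------------------------------------
    bio = load_and_validate(config["bioassay"], "bioassay")
    mort = phenotypes.mortality_summary(bio)
    write_table(mort, out / "mortality.tsv")
    synergy = {}
    for ins, grp in bio.groupby("insecticide"):
        with_pbo = grp[grp["pbo"]][["n_dead", "n_exposed"]].sum()
        without = grp[~grp["pbo"]][["n_dead", "n_exposed"]].sum()
        synergy[ins] = phenotypes.synergism_test(
            (int(with_pbo["n_dead"]), int(with_pbo["n_exposed"])),
            (int(without["n_dead"]), int(without["n_exposed"])),
        )
    write_json(synergy, out / "synergism.json")
    report["synergism"] = synergy

    # --- dose-response ----------------------------------------------------
    dose = load_and_validate(config["dose"], "dose")
    lc50_rows, lc50_report = [], {}
    for line, grp in dose.groupby("line_id"):
        try:
            fit = phenotypes.fit_lc50(grp)
            lc50_rows.append(
                (line, fit["lc50"], fit["ci"][0], fit["ci"][1], fit["slope"])
            )
            lc50_report[line] = {"lc50": fit["lc50"], "ci": fit["ci"]}
        except phenotypes.SharpInflectionError as exc:
            lc50_report[line] = {"error": str(exc)}
    write_table(
        pd.DataFrame(
            lc50_rows, columns=["line_id", "lc50", "ci_low", "ci_high", "slope"]
        ),
        out / "lc50.tsv",
    )
    report["lc50"] = lc50_report

    disc = load_and_validate(config["disc"], "dose")
    disc_report = {}
    props = {
        line: (grp["n_survived"] / grp["n"]).to_numpy()
        for line, grp in disc.groupby("line_id")
    }
    for gene in ("CYP6M2", "CYP6P3"):
        test = props.get(f"{gene}_Act5C_bendio")
        ctrl = props.get(f"{gene}_CyO_bendio")
        if test is not None and ctrl is not None:
            disc_report[gene] = phenotypes.discriminating_dose_test(test, ctrl)
    report["discriminating_dose"] = disc_report

    # --- depletion --------------------------------------------------------
    hplc = load_and_validate(config["hplc"], "hplc")
    depl_rows, depl_report = [], {}
    for cond, grp in hplc.groupby("condition"):
        res = phenotypes.substrate_depletion(
            grp.loc[grp["nadph"], "peak_area"],
            grp.loc[~grp["nadph"], "peak_area"],
        )
        depl_rows.append((cond, res["mean_depletion"], res["sd"], res["clamped"]))
        depl_report[cond] = res
    write_table(
        pd.DataFrame(
            depl_rows, columns=["condition", "mean_depletion", "sd", "clamped"]
        ),
        out / "depletion.tsv",
    )
    report["depletion"] = depl_report

    # --- provenance -------------------------------------------------------
    cfg_json = json.dumps(config, sort_keys=True)
    report["provenance"] = {
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "resistscope_version": __version__,
        "alpha": alpha,
        "copy_ratio_threshold": float(config.get("copy_ratio_threshold", 1.5)),
    }
    write_report(report, out)
    return report


def write_report(report: dict, out_dir: str | Path, fmt: str = "json") -> Path:
    """Serialize the run report; the provenance block is mandatory."""
    if "provenance" not in report:
        raise ValueError("report must carry a provenance block")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        path = out / "report.json"
        write_json(report, path)
        return path
    raise ValueError(f"unknown report format {fmt!r}")
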