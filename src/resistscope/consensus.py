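"""Consensus significance filtering across array experiments.

A probe counts as resistance-associated only if every pairwise
resistant-vs-susceptible comparison in an experiment agrees: consistent
direction of differential expression, FDR-corrected significance in
each comparison, and (for the design with a bendiocarb-selected group)
an escalation requirement that the selected-vs-susceptible fold-change
be more extreme than the matching unexposed-vs-susceptible one.
Probes significant in both experiments are aggregated to genes with
significant/total probe counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ComparisonPlan",
    "comparison_id",
    "evaluate_exp1",
    "evaluate_exp2",
    "combine_experiments",
]


def comparison_id(res: str, sus: str) -> str:
    return f"{res}_vs_{sus}"


@dataclass(frozen=True)
class ComparisonPlan:
    """Filtering plan for one experiment.

    ``comparisons`` are (resistant_group, susceptible_group) pairs, each
    predicted resistant-higher (under-expression is allowed as long as
    the sign is consistent across all comparisons).
    ``selected_unexposed_pairs`` names (selected, unexposed) comparison
    pairs sharing a susceptible partner, used by the escalation
    criterion; leave empty for designs without a selected group.
    """

    experiment_id: str
    comparisons: tuple[tuple[str, str], ...]
    selected_unexposed_pairs: tuple[tuple[str, str], ...] = ()
    alpha: float = 0.05

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        object.__setattr__(self, "comparisons", tuple(map(tuple, self.comparisons)))
        object.__setattr__(
            self,
            "selected_unexposed_pairs",
            tuple(map(tuple, self.selected_unexposed_pairs)),
        )
        ids = {comparison_id(r, s) for r, s in self.comparisons}
        for sel, unexp in self.selected_unexposed_pairs:
            if sel not in ids or unexp not in ids:
                raise ValueError(
                    f"escalation pair ({sel}, {unexp}) references comparisons "
                    "absent from the plan"
                )

    @property
    def comparison_ids(self) -> list[str]:
        return [comparison_id(r, s) for r, s in self.comparisons]


def _pivot(contrasts: pd.DataFrame, plan: ComparisonPlan):
    need = plan.comparison_ids
    sub = contrasts[contrasts["comparison_id"].isin(need)]
    fc = sub.pivot(index="probe_id", columns="comparison_id", values="log2FC")
    q = sub.pivot(index="probe_id", columns="comparison_id", values="q")
    for cid in need:
        if cid not in fc.columns:
            fc[cid] = np.nan
            q[cid] = np.nan
    return fc[need], q[need]


def _evaluate(
    contrasts: pd.DataFrame, plan: ComparisonPlan, escalation: bool
) -> pd.DataFrame:
    fc, q = _pivot(contrasts, plan)
    fcv = fc.to_numpy(dtype=float)
    qv = q.to_numpy(dtype=float)

    evaluable = np.isfinite(fcv).all(axis=1) & np.isfinite(qv).all(axis=1)
    sign = np.sign(fcv)
    crit_direction = (
        (sign != 0).all(axis=1)
        & (np.abs(sign.sum(axis=1)) == sign.shape[1])
    )
    crit_q = (qv < plan.alpha).all(axis=1)

    if escalation and plan.selected_unexposed_pairs:
        crit_esc = np.ones(len(fc), dtype=bool)
        cols = {c: i for i, c in enumerate(fc.columns)}
        for sel, unexp in plan.selected_unexposed_pairs:
            a, b = fcv[:, cols[sel]], fcv[:, cols[unexp]]
            crit_esc &= (np.sign(a) == np.sign(b)) & (np.abs(a) > np.abs(b))
    else:
        crit_esc = np.ones(len(fc), dtype=bool)

    out = pd.DataFrame(
        {
            "probe_id": fc.index,
            "evaluable": evaluable,
            "crit_direction": crit_direction & evaluable,
            "crit_q": crit_q & evaluable,
            "mean_log2FC": np.nanmean(fcv, axis=1),
        }
    )
    if escalation:
        out["crit_escalation"] = crit_esc & evaluable
        out["significant"] = (
            out["crit_direction"] & out["crit_q"] & out["crit_escalation"]
        )
    else:
        out["significant"] = out["crit_direction"] & out["crit_q"]
    return out.reset_index(drop=True)


def evaluate_exp1(contrasts: pd.DataFrame, plan: ComparisonPlan) -> pd.DataFrame:
    """Apply all three criteria (direction, per-comparison q < alpha,
    selected-vs-unexposed escalation) to every probe.

    Probes missing any plan comparison are returned with
    ``evaluable = False`` and never significant.
    """
    return _evaluate(contrasts, plan, escalation=True)


def evaluate_exp2(contrasts: pd.DataFrame, plan: ComparisonPlan) -> pd.DataFrame:
    """As :func:`evaluate_exp1` without the escalation criterion."""
    return _evaluate(contrasts, plan, escalation=False)


def combine_experiments(
    v1: pd.DataFrame,
    v2: pd.DataFrame,
    probe_to_gene: dict[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intersect per-experiment verdicts and aggregate probes to genes.

    A probe is overall-significant only if significant in both
    experiments; probes present in a single experiment get status
    ``"untested"`` and are excluded from overall significance.  Gene
    summaries count significant/total probes (the "n/m" annotation
    convention) with the representative log2FC taken as the median of
    the first experiment's mean fold-change over significant probes.

    Returns ``(probe_table, gene_table)``.
    """
    missing = (set(v1["probe_id"]) | set(v2["probe_id"])) - set(probe_to_gene)
    if missing:
        raise ValueError(f"probes absent from probe-gene map: {sorted(missing)[:5]}")

    m = v1.set_index("probe_id")[["significant", "mean_log2FC"]].join(
        v2.set_index("probe_id")[["significant"]],
        how="outer",
        lsuffix="_exp1",
        rsuffix="_exp2",
    )
    in_both = m["significant_exp1"].notna() & m["significant_exp2"].notna()
    m["status"] = np.where(in_both, "tested", "untested")
    sig1 = m["significant_exp1"].astype("boolean").fillna(False).astype(bool)
    sig2 = m["significant_exp2"].astype("boolean").fillna(False).astype(bool)
    m["overall_significant"] = in_both & sig1 & sig2
    probes = m.reset_index().rename(columns={"index": "probe_id"})
    probes["gene_id"] = probes["probe_id"].map(probe_to_gene)

    rows = []
    for gene, grp in probes.groupby("gene_id"):
        sig = grp["overall_significant"]
        rep = grp.loc[sig, "mean_log2FC"].median() if sig.any() else np.nan
        rows.append(
            (gene, int(sig.sum()), len(grp), f"{int(sig.sum())}/{len(grp)}", rep)
        )
    genes = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "n_probes_significant",
            "n_probes_total",
            "annotation",
            "representative_log2FC",
        ],
    ).sort_values("gene_id", ignore_index=True)
    return probes, genes
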