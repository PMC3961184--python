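"""Efficiency-corrected relative quantification and copy-number ratios.

Relative expression follows the comparative-Ct method generalised for
per-amplicon PCR efficiency: each amplicon's quantity is
``(1+E)**(-Ct)`` (technical replicates averaged on the Ct scale first),
the target is normalised by the geometric mean of the reference-gene
quantities, and fold-changes are expressed against a calibrator group.
With every efficiency equal to 1 this reduces exactly to the textbook
2^-ddCt form.

Gene copy number uses the same arithmetic on genomic DNA: three target
amplicons are each normalised against two single-copy reference genes
and against the mean of calibrator-strain pools, and the six
amplicon-by-reference contributions are averaged (ratio scale by
default).  A ratio strictly above 1.5 is read as carrying at least one
extra gene copy.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "amplicon_quantities",
    "relative_expression",
    "overexpression_test",
    "copy_number_ratio",
    "copy_number_contrast",
]


class QpcrError(ValueError):
    pass


def _check_ct(ct: pd.DataFrame) -> None:
    required = {"sample_id", "amplicon", "replicate", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise QpcrError(f"Ct table missing columns: {sorted(missing)}")
    if (ct["ct"] <= 0).any():
        raise QpcrError("Ct values must be positive")


def _check_efficiencies(eff: dict[str, float], amplicons) -> None:
    for a in amplicons:
        if a not in eff:
            raise QpcrError(f"no efficiency for amplicon {a!r}")
        if not 0.5 < eff[a] <= 1.2:
            raise QpcrError(f"efficiency for {a!r} must be in (0.5, 1.2]")


def amplicon_quantities(
    ct: pd.DataFrame, efficiencies: dict[str, float]
) -> pd.DataFrame:
    """Per-(sample, amplicon) relative quantities ``(1+E)**(-mean Ct)``,
    technical replicates averaged on the Ct scale."""
    _check_ct(ct)
    mean_ct = (
        ct.groupby(["sample_id", "amplicon"])["ct"].mean().reset_index()
    )
    _check_efficiencies(efficiencies, mean_ct["amplicon"].unique())
    e = mean_ct["amplicon"].map(efficiencies).to_numpy(dtype=float)
    mean_ct["quantity"] = (1.0 + e) ** (-mean_ct["ct"].to_numpy(dtype=float))
    return mean_ct


def _normalized_expression(
    ct: pd.DataFrame,
    target: str,
    references: list[str],
    efficiencies: dict[str, float],
) -> pd.Series:
    """Target quantity over the geometric mean of reference quantities,
    per sample (biological replicate).  Samples lacking the target or
    any reference amplicon are dropped with a warning."""
    if not references:
        raise QpcrError("at least one reference amplicon is required")
    q = amplicon_quantities(ct, efficiencies)
    wide = q.pivot(index="sample_id", columns="amplicon", values="quantity")
    needed = [target] + list(references)
    for a in needed:
        if a not in wide.columns:
            raise QpcrError(f"amplicon {a!r} absent from Ct table")
    ok = wide[needed].notna().all(axis=1)
    if (~ok).any():
        warnings.warn(
            f"dropping {int((~ok).sum())} sample(s) missing target/reference Cts",
            stacklevel=2,
        )
    wide = wide.loc[ok]
    if wide.empty:
        raise QpcrError("no sample has complete target and reference Cts")
    ref_geomean = np.exp(np.log(wide[list(references)]).mean(axis=1))
    return wide[target] / ref_geomean


def relative_expression(
    ct: pd.DataFrame,
    target: str,
    references: list[str],
    groups: dict[str, str],
    calibrator_group: str,
    efficiencies: dict[str, float],
) -> tuple[pd.DataFrame, pd.Series]:
    """Fold-change of ``target`` per group relative to the calibrator
    group, with a 95% t interval over biological replicates.

    Returns ``(per_group_table, per_sample_normalized_expression)``.
    The interval is computed on the log2 normalised-expression scale
    within each group (calibrator mean treated as the fixed
    denominator) and back-transformed.
    """
    norm = _normalized_expression(ct, target, references, efficiencies)
    unknown = set(norm.index) - set(groups)
    if unknown:
        raise QpcrError(f"samples without group assignment: {sorted(unknown)}")
    grp = pd.Series({s: groups[s] for s in norm.index})
    if calibrator_group not in set(grp):
        raise QpcrError(f"calibrator group {calibrator_group!r} has no samples")
    cal_mean = norm[grp == calibrator_group].mean()
    rows = []
    for g, vals in norm.groupby(grp):
        fold = vals.mean() / cal_mean
        n = len(vals)
        if n >= 2 and (vals > 0).all():
            logv = np.log2(vals / cal_mean)
            half = stats.t.ppf(0.975, n - 1) * logv.std(ddof=1) / np.sqrt(n)
            lo, hi = 2.0 ** (logv.mean() - half), 2.0 ** (logv.mean() + half)
        else:
            lo = hi = np.nan
        rows.append((g, fold, lo, hi, n))
    table = pd.DataFrame(
        rows, columns=["group_id", "fold", "ci_low", "ci_high", "n"]
    ).sort_values("group_id", ignore_index=True)
    return table, norm


def overexpression_test(
    test_values, calibrator_values, alpha: float = 0.05
) -> tuple[float, str]:
    """Two-sample t-test of log2 normalised expression, pooled or Welch
    according to a two-sided F-test for homoscedasticity at ``alpha``.

    Returns ``(two-sided p, test_used)`` where ``test_used`` is
    ``"pooled"`` or ``"welch"``.
    """
    x = np.log2(np.asarray(test_values, dtype=float))
    y = np.log2(np.asarray(calibrator_values, dtype=float))
    if len(x) < 2 or len(y) < 2:
        raise QpcrError("need >= 2 replicates per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return 1.0, "pooled"
        return 0.0, "pooled"
    f = vx / vy if vy > 0 else np.inf
    if np.isinf(f):
        p_f = 0.0
    else:
        cdf = stats.f.cdf(f, len(x) - 1, len(y) - 1)
        p_f = 2.0 * min(cdf, 1.0 - cdf)
    if p_f < alpha:
        t, p = stats.ttest_ind(x, y, equal_var=False)
        return float(p), "welch"
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(p), "pooled"


def copy_number_ratio(
    ct: pd.DataFrame,
    ace1_amplicons: list[str],
    reference_genes: list[str],
    calibrator_samples: list[str],
    efficiencies: dict[str, float],
    threshold: float = 1.5,
    scale: str = "ratio",
) -> pd.DataFrame:
    """Per-sample copy-number ratio against calibrator-strain pools.

    For each (target amplicon, reference gene) pair the efficiency-
    corrected quantity ratio of the sample is divided by the geometric
    mean of the calibrator pools' ratios (averaging the calibrator on
    the dCt scale); the sample's ratio is the mean of the six resulting
    contributions, arithmetic on the ratio scale (``scale="ratio"``,
    default) or geometric, i.e. dCt-scale, with ``scale="ddct"``.
    ``extra_copy`` is True strictly above ``threshold``.
    """
    if scale not in ("ratio", "ddct"):
        raise QpcrError(f"unknown averaging scale {scale!r}")
    q = amplicon_quantities(ct, efficiencies)
    wide = q.pivot(index="sample_id", columns="amplicon", values="quantity")
    absent = [
        a for a in list(ace1_amplicons) + list(reference_genes)
        if a not in wide.columns
    ]
    if absent:
        raise QpcrError(f"missing assays: {absent}")
    for s in calibrator_samples:
        if s not in wide.index:
            raise QpcrError(f"calibrator sample {s!r} absent from Ct table")
    need = list(ace1_amplicons) + list(reference_genes)
    incomplete = wide.index[wide[need].isna().any(axis=1)]
    if len(incomplete):
        raise QpcrError(
            f"samples with missing assays: {list(incomplete)[:5]}"
        )

    rows = []
    test_samples = [s for s in wide.index if s not in set(calibrator_samples)]
    for sample in test_samples:
        contribs = {}
        for tgt in ace1_amplicons:
            for ref in reference_genes:
                sample_ratio = wide.loc[sample, tgt] / wide.loc[sample, ref]
                cal = np.exp(
                    np.mean(
                        [
                            np.log(wide.loc[c, tgt] / wide.loc[c, ref])
                            for c in calibrator_samples
                        ]
                    )
                )
                contribs[(tgt, ref)] = sample_ratio / cal
        vals = np.array(list(contribs.values()))
        ratio = (
            float(vals.mean()) if scale == "ratio"
            else float(np.exp(np.log(vals).mean()))
        )
        # strict ">": a ratio exactly at threshold is below it, with a
        # relative guard so float round-trip error cannot flip the call
        extra = ratio > threshold * (1.0 + 1e-9)
        rows.append(
            {
                "sample_id": sample,
                "ratio": ratio,
                "extra_copy": extra,
                **{
                    f"ratio_{t}_{r}": v for (t, r), v in contribs.items()
                },
            }
        )
    return pd.DataFrame(rows)


def copy_number_contrast(survivor_ratios, dead_ratios) -> tuple[float, float]:
    """Welch two-sample t comparing copy-number ratios of bioassay
    survivors against dead individuals; returns ``(t, two-sided p)``."""
    x = np.asarray(survivor_ratios, dtype=float)
    y = np.asarray(dead_ratios, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise QpcrError("need >= 2 ratios per group")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)
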