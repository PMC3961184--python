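"""Bioassay, dose-response and metabolism statistics.

Covers the phenotype arm of the pipeline: pooled WHO-bioassay mortality
with Wilson binomial intervals, synergism odds ratios (mortality with
vs without PBO pre-exposure), linear survival-on-log10-dose LC50
estimation with Fieller confidence limits, an exact tie-aware two-sided
Mann-Whitney test for discriminating-dose comparisons, and percent
substrate depletion from HPLC peak areas against no-NADPH controls.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from resistscope.genotyping import _haldane, _pearson_chi2

__all__ = [
    "mortality_summary",
    "synergism_test",
    "fit_lc50",
    "exact_mannwhitney",
    "discriminating_dose_test",
    "substrate_depletion",
    "SharpInflectionError",
]


class PhenotypeError(ValueError):
    pass


class SharpInflectionError(PhenotypeError):
    """Too few partial-response doses for a dose-response regression;
    use the discriminating-dose test instead."""


# --------------------------------------------------------------------------
# WHO bioassays and synergism
# --------------------------------------------------------------------------

def mortality_summary(
    reps: pd.DataFrame,
    by: tuple[str, ...] = ("insecticide", "season", "pbo"),
    ci_method: str = "wilson",
) -> pd.DataFrame:
    """Pooled mortality with a 95% binomial interval per condition.

    Replicate counts are pooled within each ``by`` group; the interval
    is Wilson by default (``ci_method="beta"`` gives Clopper-Pearson).
    """
    required = {"n_exposed", "n_dead"}
    if required - set(reps.columns):
        raise PhenotypeError("replicate table needs n_exposed and n_dead")
    if (reps["n_exposed"] <= 0).any():
        raise PhenotypeError("n_exposed must be positive")
    if ((reps["n_dead"] < 0) | (reps["n_dead"] > reps["n_exposed"])).any():
        raise PhenotypeError("n_dead must lie in [0, n_exposed]")
    keys = [k for k in by if k in reps.columns]
    grouped = (
        reps.groupby(keys, as_index=False)[["n_exposed", "n_dead"]].sum()
        if keys
        else reps[["n_exposed", "n_dead"]].sum().to_frame().T
    )
    lo, hi = proportion_confint(
        grouped["n_dead"], grouped["n_exposed"], method=ci_method
    )
    grouped["mortality"] = grouped["n_dead"] / grouped["n_exposed"]
    grouped["ci_low"] = lo
    grouped["ci_high"] = hi
    return grouped


def synergism_test(
    with_pbo: tuple[int, int], without_pbo: tuple[int, int]
) -> dict:
    """Odds ratio of mortality with PBO pre-exposure versus insecticide
    alone, with a Woolf 95% interval and a Pearson chi-square.

    Each argument is pooled ``(n_dead, n_exposed)``.  The
    Haldane-Anscombe correction is applied to the OR when any cell is
    zero; the chi-square uses the raw counts.
    """
    d1, n1 = with_pbo
    d0, n0 = without_pbo
    if not (0 <= d1 <= n1 and 0 <= d0 <= n0) or n1 == 0 or n0 == 0:
        raise PhenotypeError("invalid pooled counts")
    table = np.array([[d1, n1 - d1], [d0, n0 - d0]], dtype=float)
    if (table.sum(axis=0) == 0).any():
        raise PhenotypeError("zero margin: odds ratio undefined")
    chi2, p = _pearson_chi2(table)
    tc, haldane = _haldane(table)
    a, b = tc[0]
    c, d = tc[1]
    or_ = (a * d) / (b * c)
    z = stats.norm.ppf(0.975)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return {
        "odds_ratio": float(or_),
        "or_ci": (float(np.exp(np.log(or_) - z * se)),
                  float(np.exp(np.log(or_) + z * se))),
        "chi2": chi2,
        "p": p,
        "haldane": haldane,
        "mortality_with_pbo": d1 / n1,
        "mortality_without_pbo": d0 / n0,
    }


# --------------------------------------------------------------------------
# dose-response LC50
# --------------------------------------------------------------------------

def fit_lc50(obs: pd.DataFrame) -> dict:
    """LC50 from a linear fit of survival proportion on log10 dose.

    Only partial-response doses (0 < survival < 1) enter the
    regression; at least three are required, otherwise the profile is
    too sharp for a regression and :class:`SharpInflectionError` is
    raised (use :func:`discriminating_dose_test` at a fixed dose
    instead).  The LC50 is the dose where fitted survival crosses 0.5,
    with a 95% interval on the log10-dose scale by Fieller's theorem,
    back-transformed.
    """
    required = {"dose_ug", "n", "n_survived"}
    if required - set(obs.columns):
        raise PhenotypeError("dose table needs dose_ug, n, n_survived")
    if (obs["dose_ug"] <= 0).any():
        raise PhenotypeError("doses must be positive")
    prop = obs["n_survived"].to_numpy(float) / obs["n"].to_numpy(float)
    x_all = np.log10(obs["dose_ug"].to_numpy(float))
    partial = (prop > 0.0) & (prop < 1.0)
    if np.unique(x_all[partial]).size < 3:
        raise SharpInflectionError(
            "fewer than 3 partial-response doses (sharp inflection); "
            "use the discriminating-dose test"
        )
    x, y = x_all[partial], prop[partial]
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b = beta
    if b == 0:
        raise PhenotypeError("zero slope: LC50 undefined")
    fitted = X @ beta
    dof = n - 2
    s2 = float(((y - fitted) ** 2).sum() / dof) if dof > 0 else 0.0
    cov = s2 * np.linalg.inv(X.T @ X)

    nu = 0.5 - a               # numerator of the log10 LC50 ratio
    rho = nu / b
    s_nn = cov[0, 0]           # var(nu) = var(a)
    s_bb = cov[1, 1]
    s_nb = -cov[0, 1]          # cov(nu, b) = -cov(a, b)
    tcrit = stats.t.ppf(0.975, dof) if dof > 0 else 0.0
    g = tcrit**2 * s_bb / b**2 if s_bb > 0 else 0.0
    if g >= 1.0:
        ci_log = (-np.inf, np.inf)
    else:
        center = (rho - g * s_nb / s_bb) / (1 - g) if s_bb > 0 else rho
        inner = s_nn - 2 * rho * s_nb + rho**2 * s_bb
        if s_bb > 0:
            inner -= g * (s_nn - s_nb**2 / s_bb)
        half = (
            tcrit / (abs(b) * (1 - g)) * math.sqrt(max(inner, 0.0))
            if dof > 0
            else 0.0
        )
        ci_log = (center - half, center + half)
    return {
        "lc50": float(10.0**rho),
        "ci": (float(10.0 ** ci_log[0]), float(10.0 ** ci_log[1])),
        "slope": float(-b),          # mortality increase per log10 dose
        "intercept": float(a),
        "residual_s2": s2,
        "n_doses": n,
    }


# --------------------------------------------------------------------------
# exact Mann-Whitney
# --------------------------------------------------------------------------

def exact_mannwhitney(x, y, exact_limit: int = 20) -> dict:
    """Two-sided Mann-Whitney U test, exact for small samples.

    When ``n1 + n2 <= exact_limit`` the permutation distribution of U
    is enumerated over all assignments of the pooled observations to
    the two groups (average ranks, so ties are handled exactly);
    the two-sided p is ``min(1, 2*min(P(U <= u), P(U >= u)))``.
    Larger samples fall back to the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise PhenotypeError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0

    if n1 + n2 <= exact_limit:
        base = n1 * (n1 + 1) / 2.0
        n_le = n_ge = 0
        total = 0
        eps = 1e-9
        for comb in itertools.combinations(range(n1 + n2), n1):
            u = sum(ranks[i] for i in comb) - base
            total += 1
            if u <= u_obs + eps:
                n_le += 1
            if u >= u_obs - eps:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
        method = "exact"
    else:
        _, p = stats.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic")
        method = "normal"
    return {"u": float(u_obs), "p": float(p), "method": method,
            "n1": n1, "n2": n2}


def discriminating_dose_test(test_reps, control_reps) -> dict:
    """Resistance ratio and exact Mann-Whitney p at a fixed
    discriminating dose.

    ``test_reps`` and ``control_reps`` are per-vial survival
    proportions (vials are the experimental replicates).  The ratio is
    mean test survival over mean control survival; it is undefined
    (NaN) when the control mean is zero, but the test p is still
    reported.
    """
    test = np.asarray(test_reps, dtype=float)
    control = np.asarray(control_reps, dtype=float)
    if len(test) < 2 or len(control) < 2:
        raise PhenotypeError("need >= 2 vials per group")
    mw = exact_mannwhitney(test, control)
    cmean = control.mean()
    ratio = float(test.mean() / cmean) if cmean > 0 else float("nan")
    return {
        "resistance_ratio": ratio,
        "mean_test": float(test.mean()),
        "mean_control": float(cmean),
        **mw,
    }


# --------------------------------------------------------------------------
# substrate depletion
# --------------------------------------------------------------------------

def substrate_depletion(
    test_areas, control_areas, method: str = "ratio_of_means"
) -> dict:
    """Percent substrate depletion from HPLC peak areas.

    Depletion is ``100 * (1 - mean(test)/mean(control))`` where test
    reactions contain the NADPH regenerating system and controls do
    not; the standard deviation comes from the per-replicate ratios
    ``test_i / mean(control)``.  A negative raw value (test above
    control) is reported as 0% with ``clamped = True`` and the raw
    value retained.  ``method="mean_of_ratios"`` averages per-replicate
    depletion instead.
    """
    test = np.asarray(test_areas, dtype=float)
    control = np.asarray(control_areas, dtype=float)
    if len(test) < 1 or len(control) < 1:
        raise PhenotypeError("need >= 1 replicate in each condition")
    cmean = control.mean()
    if cmean <= 0:
        raise PhenotypeError("control mean peak area must be positive")
    per_rep = 100.0 * (1.0 - test / cmean)
    if method == "ratio_of_means":
        raw = 100.0 * (1.0 - test.mean() / cmean)
    elif method == "mean_of_ratios":
        raw = float(per_rep.mean())
    else:
        raise PhenotypeError(f"unknown method {method!r}")
    sd = float(per_rep.std(ddof=1)) if len(test) > 1 else 0.0
    clamped = raw < 0.0
    return {
        "mean_depletion": max(raw, 0.0),
        "raw_depletion": float(raw),
        "sd": sd,
        "clamped": bool(clamped),
        "n": len(test),
    }
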