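"""Per-probe contrast estimation for two-colour array designs.

A single least-squares group-offset model serves both the pairwise
dye-swap design and the interwoven loop: each array contributes one
equation ``M = offset[cy5 group] - offset[cy3 group] + error`` and any
requested resistant-vs-susceptible contrast is a linear combination of
the fitted offsets.  Variance moderation (empirical Bayes shrinkage of
per-probe residual variances toward a common value) and Benjamini-
Hochberg q-values complete the significance machinery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from resistscope.synthetic import HybridizationScheme, SchemaError

__all__ = [
    "normalize_arrays",
    "fit_contrasts",
    "moderate_and_test",
    "bh_qvalues",
    "add_qvalues",
    "run_differential_expression",
]


class DesignError(ValueError):
    """The hybridization design cannot support the requested contrasts."""


def _check_mvalue_table(m: pd.DataFrame) -> None:
    required = {"probe_id", "array_id", "M"}
    missing = required - set(m.columns)
    if missing:
        raise SchemaError(f"M-value table missing columns: {sorted(missing)}")
    if not np.isfinite(m["M"].to_numpy(dtype=float)).all():
        raise SchemaError("non-finite M values")
    if m.duplicated(["probe_id", "array_id"]).any():
        raise SchemaError("duplicate (probe_id, array_id) pairs")


def normalize_arrays(m: pd.DataFrame, method: str = "median") -> pd.DataFrame:
    """Per-array location normalization of M values.

    ``"median"`` subtracts each array's median M; ``"none"`` returns the
    input unchanged.
    """
    _check_mvalue_table(m)
    if method == "none":
        return m
    if method != "median":
        raise ValueError(f"unknown normalization method {method!r}")
    if m.empty:
        raise SchemaError("cannot normalize an empty M-value table")
    out = m.copy()
    out["M"] = out["M"] - out.groupby("array_id")["M"].transform("median")
    return out


def _design_matrix(
    scheme: HybridizationScheme, comparisons: list[tuple[str, str]]
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Group-offset design matrix (baseline = first group, fixed at 0)
    and the contrast matrix for the requested comparisons.
    """
    groups = scheme.groups
    for res, sus in comparisons:
        for g in (res, sus):
            if g not in groups:
                raise DesignError(f"comparison references unknown group {g!r}")

    # connectivity check on the group graph induced by the arrays
    gidx = {g: i for i, g in enumerate(groups)}
    group_of = scheme.sample_group
    edges = [
        (gidx[group_of[cy3]], gidx[group_of[cy5]])
        for _, cy3, cy5 in scheme.arrays
    ]
    n_g = len(groups)
    if edges:
        r, c = zip(*edges)
        adj = coo_matrix((np.ones(len(edges)), (r, c)), shape=(n_g, n_g))
    else:
        adj = coo_matrix((n_g, n_g))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        comps = [
            [g for g in groups if labels[gidx[g]] == k] for k in range(n_comp)
        ]
        raise DesignError(
            "design is disconnected; group components: "
            + "; ".join(",".join(c) for c in comps)
        )

    # parameters: offsets of groups[1:] relative to groups[0]
    params = groups[1:]
    pidx = {g: i for i, g in enumerate(params)}
    X = np.zeros((len(scheme.arrays), len(params)))
    for a, (_, cy3, cy5) in enumerate(scheme.arrays):
        g5, g3 = group_of[cy5], group_of[cy3]
        if g5 in pidx:
            X[a, pidx[g5]] += 1.0
        if g3 in pidx:
            X[a, pidx[g3]] -= 1.0
    C = np.zeros((len(comparisons), len(params)))
    for k, (res, sus) in enumerate(comparisons):
        if res in pidx:
            C[k, pidx[res]] += 1.0
        if sus in pidx:
            C[k, pidx[sus]] -= 1.0
    return X, [f"{res}_vs_{sus}" for res, sus in comparisons], C


def fit_contrasts(
    m: pd.DataFrame,
    scheme: HybridizationScheme,
    comparisons: list[tuple[str, str]],
) -> pd.DataFrame:
    """Least-squares group-offset fit per probe; one row per probe and
    requested (resistant, susceptible) comparison.

    Output columns: ``probe_id, comparison_id, log2FC, unit_se, s2, df,
    se, direction``.  ``unit_se`` is the contrast standard error for
    unit residual variance, so moderated tests can rescale it; ``se`` is
    the plain (unmoderated) standard error.  Probes observed on only a
    subset of arrays are fit on their available equations; estimates
    with zero residual degrees of freedom are returned with ``df = 0``
    (tests downstream flag them as undefined).
    """
    _check_mvalue_table(m)
    X, comp_ids, C = _design_matrix(scheme, comparisons)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise DesignError("design matrix is rank deficient")

    arrays = scheme.array_ids()
    unknown = set(m["array_id"]) - set(arrays)
    if unknown:
        raise SchemaError(f"M-value table references unknown arrays: {sorted(unknown)}")
    wide = m.pivot(index="array_id", columns="probe_id", values="M").reindex(arrays)
    probes = list(wide.columns)
    Y = wide.to_numpy(dtype=float)

    full = ~np.isnan(Y).any(axis=0)
    n_arrays = X.shape[0]

    est = np.full((len(probes), len(comp_ids)), np.nan)
    unit = np.full((len(probes), len(comp_ids)), np.nan)
    s2 = np.full(len(probes), np.nan)
    dfs = np.zeros(len(probes))

    def solve_block(Xb: np.ndarray, Yb: np.ndarray, cols: np.ndarray) -> None:
        rk = np.linalg.matrix_rank(Xb)
        if rk < Xb.shape[1]:
            return  # contrasts not estimable for these probes
        XtX_inv = np.linalg.inv(Xb.T @ Xb)
        beta = XtX_inv @ Xb.T @ Yb
        resid = Yb - Xb @ beta
        df = Xb.shape[0] - rk
        rss = (resid**2).sum(axis=0)
        s2[cols] = rss / df if df > 0 else np.nan
        dfs[cols] = df
        est[cols] = (C @ beta).T
        unit[cols] = np.sqrt(np.einsum("ki,ij,kj->k", C, XtX_inv, C))

    if full.any():
        solve_block(X, Y[:, full], np.flatnonzero(full))
    for j in np.flatnonzero(~full):
        obs = ~np.isnan(Y[:, j])
        if obs.sum() == 0:
            continue
        solve_block(X[obs], Y[obs, j][:, None], np.array([j]))

    long = []
    for k, cid in enumerate(comp_ids):
        long.append(
            pd.DataFrame(
                {
                    "probe_id": probes,
                    "comparison_id": cid,
                    "log2FC": est[:, k],
                    "unit_se": unit[:, k],
                    "s2": s2,
                    "df": dfs,
                }
            )
        )
    out = pd.concat(long, ignore_index=True)
    with np.errstate(invalid="ignore"):
        out["se"] = np.sqrt(out["s2"]) * out["unit_se"]
    out["direction"] = np.sign(out["log2FC"])
    del n_arrays
    return out


def _moments_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments prior (s0^2, d0) for variance shrinkage.

    Matches the marginal mean and variance of the observed residual
    variances: any spread of the s^2 beyond the chi-square scatter
    expected at the probes' residual df is attributed to true variance
    heterogeneity, and d0 is the pseudo-df at which a variance estimate
    would show that much spread.  No heterogeneity (or fewer than two
    usable probes) yields d0 = inf, i.e. complete shrinkage to s0^2.
    """
    ok = df > 0
    s2, df = s2[ok], df[ok]
    if s2.size == 0:
        raise DesignError("all residual degrees of freedom are zero")
    s0sq = float(np.mean(s2))
    if s2.size < 2 or s0sq == 0.0:
        return s0sq, np.inf
    var_obs = float(np.var(s2, ddof=1))
    inv_d = float(np.mean(1.0 / df))
    v = (var_obs - 2.0 * s0sq**2 * inv_d) / (1.0 + 2.0 * inv_d)
    if v <= 0:
        return s0sq, np.inf
    return s0sq, 2.0 * s0sq**2 / v


def moderate_and_test(
    contrasts: pd.DataFrame, moderation: str = "eb"
) -> pd.DataFrame:
    """Attach t statistics and two-sided p-values to fitted contrasts.

    ``"plain"`` uses each probe's own residual variance with its
    residual df.  ``"eb"`` shrinks per-probe variances toward the
    across-probe mean (posterior variance ``(d0*s0^2 + d*s^2)/(d0+d)``)
    and tests on ``d0 + d`` degrees of freedom.  Probes with zero
    residual df get NaN t and p and ``tested = False``.
    """
    if moderation not in ("eb", "plain"):
        raise ValueError(f"unknown moderation {moderation!r}")
    out = contrasts.copy()
    df = out["df"].to_numpy(dtype=float)
    s2 = out["s2"].to_numpy(dtype=float)
    if not (df > 0).any():
        raise DesignError("all residual degrees of freedom are zero")

    if moderation == "plain":
        post_s2, post_df = s2, df
    else:
        per_probe = out.drop_duplicates("probe_id")
        s0sq, d0 = _moments_prior(
            per_probe["s2"].to_numpy(dtype=float),
            per_probe["df"].to_numpy(dtype=float),
        )
        if np.isinf(d0):
            post_s2 = np.full_like(s2, s0sq)
            post_df = np.full_like(df, np.inf)
        else:
            post_s2 = (d0 * s0sq + df * s2) / (d0 + df)
            post_df = d0 + df
        post_df = np.where(df > 0, post_df, 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(post_s2) * out["unit_se"].to_numpy(dtype=float)
        t = out["log2FC"].to_numpy(dtype=float) / se
    tested = (df > 0) & np.isfinite(t)
    t = np.where(tested, t, np.nan)
    p = np.full_like(t, np.nan)
    finite_df = np.where(np.isinf(post_df), 1e12, post_df)
    p[tested] = 2.0 * stats.t.sf(np.abs(t[tested]), finite_df[tested])
    out["t"] = t
    out["p"] = p
    out["tested"] = tested
    out["moderated_se"] = se
    return out


def bh_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone,
    order-preserving with the input)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def add_qvalues(tested: pd.DataFrame, within: str = "comparison_id") -> pd.DataFrame:
    """BH q-values computed separately within each comparison (each
    pairwise comparison is its own multiple-testing family)."""
    out = tested.copy()
    out["q"] = np.nan
    for _, idx in out.groupby(within).groups.items():
        sub = out.loc[idx]
        ok = sub["tested"] & sub["p"].notna()
        if ok.any():
            out.loc[sub.index[ok], "q"] = bh_qvalues(sub.loc[ok, "p"].to_numpy())
    return out


def run_differential_expression(
    m: pd.DataFrame,
    scheme: HybridizationScheme,
    comparisons: list[tuple[str, str]],
    normalize: str = "median",
    moderation: str = "eb",
) -> pd.DataFrame:
    """Normalize, fit contrasts, test, and attach per-comparison
    q-values in one call."""
    normed = normalize_arrays(m, method=normalize)
    fitted = fit_contrasts(normed, scheme, comparisons)
    tested = moderate_and_test(fitted, moderation=moderation)
    return add_qvalues(tested)
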