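"""TaqMan endpoint genotype calling and population statistics.

G119S genotypes are called from endpoint FAM (serine, mutant) and VIC
(glycine, wild-type) fluorescence by angular position in the
scatterplot: homozygote reference angles are anchored on the plate's
SS and GG control wells, heterozygotes on the 45-degree 1:1 allele-
balance line, and samples are assigned to the nearest reference unless
they are too dim or angularly ambiguous (no-call).  Heterozygote
FAM/VIC dye ratios carry copy-number information: an extra serine
allele shifts the cluster toward FAM, which the dye-balance contrast
tests between bioassay survivors and dead.

Population statistics: allele/heterozygote frequencies with Wilson
intervals, a one-df Hardy-Weinberg chi-square, Pearson association
chi-square with Woolf odds-ratio intervals (Haldane-Anscombe corrected
when a cell is empty), and Woolf's homogeneity-of-odds-ratios test
across strata.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "call_genotypes",
    "het_dye_balance_contrast",
    "allele_frequency",
    "hwe_test",
    "association_test",
    "homogeneity_test",
]


class GenotypingError(ValueError):
    pass


def _angles_deg(fam: np.ndarray, vic: np.ndarray) -> np.ndarray:
    return np.rad2deg(np.arctan2(fam, vic))


def call_genotypes(
    records: pd.DataFrame,
    min_signal_frac: float = 0.2,
    max_angle_dist: float = 15.0,
    het_angle: float = 45.0,
) -> pd.DataFrame:
    """Call SS/GS/GG genotypes from endpoint fluorescence.

    Reference angles are the mean angle of the SS controls, the mean of
    the GG controls, and ``het_angle`` (45 degrees, the 1:1 dye-balance
    line) for heterozygotes; the GS reference is fixed rather than
    estimated because duplication skews the empirical heterozygote
    cluster toward FAM.  A sample is no-called (``NC``) when its total
    signal falls below ``min_signal_frac`` of the mean control total or
    its angular distance to the nearest reference exceeds
    ``max_angle_dist``.  Calls are scale-invariant in fluorescence.

    Returns one row per non-control record: ``sample_id, call, angle,
    total_signal, dye_ratio, phenotype``.
    """
    required = {"sample_id", "fam_dR", "vic_dR", "control_type"}
    missing = required - set(records.columns)
    if missing:
        raise GenotypingError(f"plate missing columns: {sorted(missing)}")
    if (records["fam_dR"] < 0).any() or (records["vic_dR"] < 0).any():
        raise GenotypingError("fluorescence must be non-negative")

    ss = records[records["control_type"] == "SS"]
    gg = records[records["control_type"] == "GG"]
    if ss.empty or gg.empty:
        raise GenotypingError("need at least one SS and one GG control well")

    ref = {
        "SS": float(
            _angles_deg(ss["fam_dR"].to_numpy(), ss["vic_dR"].to_numpy()).mean()
        ),
        "GS": float(het_angle),
        "GG": float(
            _angles_deg(gg["fam_dR"].to_numpy(), gg["vic_dR"].to_numpy()).mean()
        ),
    }
    controls = pd.concat([ss, gg])
    mean_control_total = float(
        (controls["fam_dR"] + controls["vic_dR"]).mean()
    )

    samples = records[records["control_type"] == "none"]
    fam = samples["fam_dR"].to_numpy(dtype=float)
    vic = samples["vic_dR"].to_numpy(dtype=float)
    angle = _angles_deg(fam, vic)
    total = fam + vic

    names = list(ref)
    dist = np.abs(angle[:, None] - np.array([ref[k] for k in names])[None, :])
    nearest = np.argmin(dist, axis=1)
    call = np.array(names, dtype=object)[nearest]
    ambiguous = dist[np.arange(len(samples)), nearest] > max_angle_dist
    dim = total < min_signal_frac * mean_control_total
    call[ambiguous | dim] = "NC"

    with np.errstate(divide="ignore", invalid="ignore"):
        dye_ratio = np.where(vic > 0, fam / vic, np.inf)
    out = pd.DataFrame(
        {
            "sample_id": samples["sample_id"].to_numpy(),
            "call": call,
            "angle": angle,
            "total_signal": total,
            "dye_ratio": dye_ratio,
        }
    )
    if "phenotype" in samples.columns:
        out["phenotype"] = samples["phenotype"].to_numpy()
    return out


def het_dye_balance_contrast(
    calls: pd.DataFrame, log_scale: bool = False
) -> dict:
    """Welch t-test of heterozygote FAM/VIC dye ratios between bioassay
    survivors and dead.

    Tests whether surviving G119S heterozygotes carry a higher
    serine:glycine dye balance (the signature of extra serine copies).
    Raw ratios by default (``log_scale=True`` tests log ratios).
    """
    het = calls[calls["call"] == "GS"]
    alive = het.loc[het["phenotype"] == "alive", "dye_ratio"].to_numpy(float)
    dead = het.loc[het["phenotype"] == "dead", "dye_ratio"].to_numpy(float)
    if len(alive) < 2 or len(dead) < 2:
        raise GenotypingError("need >= 2 alive and >= 2 dead heterozygotes")
    x, y = (np.log(alive), np.log(dead)) if log_scale else (alive, dead)
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0 and x.mean() == y.mean():
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(x, y, equal_var=False)
    return {
        "mean_alive": float(alive.mean()),
        "mean_dead": float(dead.mean()),
        "n_alive": len(alive),
        "n_dead": len(dead),
        "t": float(t),
        "p": float(p),
    }


def allele_frequency(n_SS: int, n_GS: int, n_GG: int) -> dict:
    """Serine (resistant) allele frequency and heterozygote frequency
    with Wilson 95% intervals from genotype counts."""
    counts = (n_SS, n_GS, n_GG)
    if any(c < 0 for c in counts):
        raise GenotypingError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise GenotypingError("no individuals")
    s_alleles = 2 * n_SS + n_GS
    freq_s = s_alleles / (2 * n)
    s_lo, s_hi = proportion_confint(s_alleles, 2 * n, method="wilson")
    h_lo, h_hi = proportion_confint(n_GS, n, method="wilson")
    return {
        "freq_S": freq_s,
        "freq_S_ci": (float(s_lo), float(s_hi)),
        "het_frequency": n_GS / n,
        "het_frequency_ci": (float(h_lo), float(h_hi)),
        "n": n,
    }


def hwe_test(n_SS: int, n_GS: int, n_GG: int) -> tuple[float, float]:
    """One-df chi-square goodness of fit of genotype counts to
    Hardy-Weinberg proportions computed from the observed allele
    frequencies; returns ``(chi2, p)``.  A monomorphic sample gives
    chi2 = 0 by convention."""
    counts = np.array([n_SS, n_GS, n_GG], dtype=float)
    if (counts < 0).any():
        raise GenotypingError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise GenotypingError("no individuals")
    p = (2 * n_SS + n_GS) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 0.0, 1.0
    expected = n * np.array([p**2, 2 * p * q, q**2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _haldane(table: np.ndarray) -> tuple[np.ndarray, bool]:
    if (table == 0).any():
        return table + 0.5, True
    return table.astype(float), False


def _pearson_chi2(table: np.ndarray) -> tuple[float, float]:
    t = table.astype(float)
    n = t.sum()
    a, b = t[0]
    c, d = t[1]
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def association_test(table) -> dict:
    """Pearson chi-square (df 1, no continuity correction) and odds
    ratio with Woolf 95% interval for a 2x2 genotype-by-outcome table.

    The Haldane-Anscombe +0.5 correction is applied to all cells of the
    OR computation when any cell is zero (``haldane`` flags it); the
    chi-square uses the raw counts.  A zero margin makes association
    undefined and raises.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise GenotypingError("expected a 2x2 table")
    if (t < 0).any():
        raise GenotypingError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise GenotypingError("zero margin: association undefined")
    chi2, p = _pearson_chi2(t)
    tc, haldane = _haldane(t)
    a, b = tc[0]
    c, d = tc[1]
    or_ = (a * d) / (b * c)
    se_ln = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    ci = (float(np.exp(np.log(or_) - z * se_ln)), float(np.exp(np.log(or_) + z * se_ln)))
    return {
        "chi2": chi2,
        "p": p,
        "odds_ratio": float(or_),
        "or_ci": ci,
        "haldane": haldane,
    }


def homogeneity_test(strata) -> tuple[float, float, int]:
    """Woolf's test of homogeneity of odds ratios across 2x2 strata.

    Each stratum's log odds ratio is weighted by the inverse of the sum
    of reciprocal cell counts; the statistic is the weighted sum of
    squared deviations from the pooled log odds ratio, chi-square on
    k-1 df.  Returns ``(chi2, p, df)``.
    """
    tables = [np.asarray(t, dtype=float) for t in strata]
    if len(tables) < 2:
        raise GenotypingError("need >= 2 strata")
    lnors, weights = [], []
    for t in tables:
        if t.shape != (2, 2) or (t < 0).any():
            raise GenotypingError("each stratum must be a non-negative 2x2 table")
        tc, _ = _haldane(t)
        if (tc.sum(axis=0) == 0).any() or (tc.sum(axis=1) == 0).any():
            raise GenotypingError("zero margin in a stratum")
        a, b = tc[0]
        c, d = tc[1]
        lnors.append(np.log((a * d) / (b * c)))
        weights.append(1.0 / (1 / a + 1 / b + 1 / c + 1 / d))
    lnors = np.array(lnors)
    w = np.array(weights)
    pooled = float((w * lnors).sum() / w.sum())
    chi2 = float((w * (lnors - pooled) ** 2).sum())
    df = len(tables) - 1
    return chi2, float(stats.chi2.sf(chi2, df=df)), df
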