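"""Synthetic assay data with planted ground truth.

Every downstream stage of the pipeline (microarray contrasts, consensus
filtering, qPCR quantitation, TaqMan genotype calling, bioassay and
dose-response statistics) can be exercised against data generated here,
with the planted parameters returned alongside so recovery is checkable.

The generators mirror the structure of the study designs they emulate:

* Expression: two-colour arrays simulated on the M (log2 cy5/cy3 ratio)
  scale.  Exp1-style pairwise full dye-swap designs comparing two
  resistant Tiassale groups against three susceptible populations, and
  an Exp2-style 18-array fully interwoven loop over three populations.
* TaqMan plates: endpoint FAM/VIC fluorescence clusters on rays from the
  origin, including duplication-carrying heterozygotes shifted toward
  the FAM (serine) axis.
* qPCR Ct tables: Ct = base - log(quantity)/log(1+E) plus noise, so the
  efficiency-corrected closed forms in :mod:`resistscope.qpcr` invert
  them exactly at zero noise.
* WHO-bioassay mortality counts (binomial) and dose-response survival
  under a linear-in-log10-dose model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HybridizationScheme",
    "PlantedTruth",
    "SimConfig",
    "exp1_scheme",
    "exp2_scheme",
    "make_probe_map",
    "make_truth",
    "generate_expression_experiment",
    "generate_taqman_plate",
    "generate_ct_table",
    "generate_bioassay_counts",
    "generate_dose_response",
]


class SchemaError(ValueError):
    """A generated or supplied table violates its schema contract."""


class ConfigError(ValueError):
    """A simulation configuration value is out of its valid range."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HybridizationScheme:
    """Two-colour hybridization design.

    Parameters
    ----------
    arrays
        ``(array_id, cy3_sample_id, cy5_sample_id)`` per array.
    samples
        ``(sample_id, group_id)`` per biological sample.
    """

    arrays: tuple[tuple[str, str, str], ...]
    samples: tuple[tuple[str, str], ...]

    def __init__(self, arrays, samples):
        object.__setattr__(self, "arrays", tuple(tuple(a) for a in arrays))
        object.__setattr__(self, "samples", tuple(tuple(s) for s in samples))
        self._validate()

    def _validate(self) -> None:
        sample_ids = [s for s, _ in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise SchemaError("duplicate sample_id in scheme")
        known = set(sample_ids)
        seen_arrays = set()
        for array_id, cy3, cy5 in self.arrays:
            if array_id in seen_arrays:
                raise SchemaError(f"duplicate array_id {array_id!r}")
            seen_arrays.add(array_id)
            if cy3 == cy5:
                raise SchemaError(
                    f"array {array_id!r} hybridizes sample {cy3!r} against itself"
                )
            for s in (cy3, cy5):
                if s not in known:
                    raise SchemaError(
                        f"array {array_id!r} references unknown sample {s!r}"
                    )

    @property
    def sample_group(self) -> dict[str, str]:
        return dict(self.samples)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, g in self.samples:
            seen.setdefault(g)
        return list(seen)

    def array_ids(self) -> list[str]:
        return [a for a, _, _ in self.arrays]


@dataclass(frozen=True)
class PlantedTruth:
    """Per-gene planted expression offsets and resistance flags.

    ``offsets[gene][group]`` is the true log2 expression offset of the
    group relative to the (implicit, zero) baseline; genes not flagged
    as resistance-associated have all offsets zero.  ``probe_to_gene``
    maps every probe on the array to its gene.
    """

    offsets: dict[str, dict[str, float]]
    resistance_flag: dict[str, bool]
    probe_to_gene: dict[str, str]

    def gene_offset(self, gene: str, group: str) -> float:
        return self.offsets.get(gene, {}).get(group, 0.0)

    def flagged_genes(self) -> list[str]:
        return sorted(g for g, f in self.resistance_flag.items() if f)


@dataclass(frozen=True)
class SimConfig:
    """Expression-simulation configuration.

    All standard deviations are on the log2 scale; ``seed`` makes every
    generator deterministic.
    """

    n_probes: int = 15000
    n_genes: int = 3000
    probes_per_gene: int = 5
    array_noise_sd: float = 0.25
    dye_bias_sd: float = 0.0
    array_effect_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("array_noise_sd", "dye_bias_sd", "array_effect_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("n_probes", "n_genes", "probes_per_gene"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")


# --------------------------------------------------------------------------
# scheme builders
# --------------------------------------------------------------------------

EXP1_RESISTANT = ("TiaSel", "Tia")
EXP1_SUSCEPTIBLE = ("NGousso", "MaliNIH", "Okyereko")
EXP2_POPULATIONS = ("Kovie", "Malanville", "Okyereko")


def exp1_scheme(n_reps: dict[str, int] | None = None) -> HybridizationScheme:
    """Pairwise full dye-swap design: two resistant Tiassale groups
    (bendiocarb-selected and unexposed) each compared against three
    susceptible populations, every pairing hybridized in both dye
    orientations.  Default replication: three biological replicates per
    group except NGousso with two.
    """
    reps = {g: 3 for g in EXP1_RESISTANT + EXP1_SUSCEPTIBLE}
    reps["NGousso"] = 2
    if n_reps:
        reps.update(n_reps)
    samples = [
        (f"{g}_{i + 1}", g)
        for g in EXP1_RESISTANT + EXP1_SUSCEPTIBLE
        for i in range(reps[g])
    ]
    arrays = []
    for res, sus in itertools.product(EXP1_RESISTANT, EXP1_SUSCEPTIBLE):
        for i in range(reps[res]):
            r = f"{res}_{i + 1}"
            s = f"{sus}_{(i % reps[sus]) + 1}"
            tag = f"{res}v{sus}_{i + 1}"
            arrays.append((f"A1_{tag}_fwd", s, r))  # resistant in cy5
            arrays.append((f"A1_{tag}_rev", r, s))  # dye swap
    return HybridizationScheme(arrays, samples)


def exp2_scheme(n_reps: int = 3) -> HybridizationScheme:
    """18-array fully interwoven loop over three populations (Kovie,
    Malanville, Okyereko), biological replicates interleaved so
    adjacent loop positions belong to different populations.
    """
    samples = [
        (f"{p}_{i + 1}", p)
        for i in range(n_reps)
        for p in EXP2_POPULATIONS
    ]
    ids = [s for s, _ in samples]
    n = len(ids)
    arrays = []
    for k, step in enumerate((1, 2), start=1):
        for i in range(n):
            j = (i + step) % n
            arrays.append((f"A2_loop{k}_{i + 1}", ids[i], ids[j]))
    return HybridizationScheme(arrays, samples)


def make_probe_map(
    n_genes: int, probes_per_gene: int, prefix: str = ""
) -> dict[str, str]:
    """Probe -> gene map with a fixed number of probes per gene."""
    return {
        f"{prefix}P{g:05d}_{p}": f"{prefix}G{g:05d}"
        for g in range(n_genes)
        for p in range(probes_per_gene)
    }


def make_truth(
    probe_to_gene: dict[str, str],
    flagged_offsets: dict[str, dict[str, float]] | None = None,
) -> PlantedTruth:
    """Build a :class:`PlantedTruth` where genes in ``flagged_offsets``
    carry the given per-group log2 offsets and every other gene is null.
    """
    flagged_offsets = flagged_offsets or {}
    genes = sorted(set(probe_to_gene.values()))
    unknown = set(flagged_offsets) - set(genes)
    if unknown:
        raise SchemaError(f"flagged genes not in probe map: {sorted(unknown)}")
    offsets = {g: dict(flagged_offsets.get(g, {})) for g in genes}
    flags = {g: g in flagged_offsets for g in genes}
    return PlantedTruth(offsets=offsets, resistance_flag=flags,
                        probe_to_gene=dict(probe_to_gene))


# --------------------------------------------------------------------------
# expression generator
# --------------------------------------------------------------------------

def generate_expression_experiment(
    scheme: HybridizationScheme,
    truth: PlantedTruth,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Simulate per-probe M values (log2 cy5/cy3) for every array.

    For each probe and array::

        M = offset[cy5 group] - offset[cy3 group]
            + array effect + probe dye bias + Normal(0, array_noise_sd)

    The dye bias is a per-probe constant on the M scale (a cy5-vs-cy3
    labelling effect), so it changes sign relative to sample orientation
    and cancels exactly in dye-swap least-squares contrasts.  The array
    effect is drawn once per array.

    Returns the long-format M-value table (probe_id, array_id, M) and
    the truth object unchanged.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    group_of = scheme.sample_group
    probes = sorted(truth.probe_to_gene)
    genes = [truth.probe_to_gene[p] for p in probes]

    groups = scheme.groups
    gidx = {g: i for i, g in enumerate(groups)}
    gene_ids = sorted(set(genes))
    offmat = np.zeros((len(gene_ids), len(groups)))
    for i, g in enumerate(gene_ids):
        for grp, off in truth.offsets.get(g, {}).items():
            # a truth shared across designs may carry groups absent here
            if grp in gidx:
                offmat[i, gidx[grp]] = off
    gene_row = {g: i for i, g in enumerate(gene_ids)}
    probe_rows = np.array([gene_row[g] for g in genes])

    n_arrays = len(scheme.arrays)
    n_probes = len(probes)
    dye_bias = (
        rng.normal(0.0, cfg.dye_bias_sd, size=n_probes)
        if cfg.dye_bias_sd > 0
        else np.zeros(n_probes)
    )
    array_eff = (
        rng.normal(0.0, cfg.array_effect_sd, size=n_arrays)
        if cfg.array_effect_sd > 0
        else np.zeros(n_arrays)
    )

    frames = []
    for a, (array_id, cy3, cy5) in enumerate(scheme.arrays):
        for s in (cy3, cy5):
            if s not in group_of:
                raise SchemaError(f"array {array_id!r} references unknown sample {s!r}")
        signal = offmat[probe_rows, gidx[group_of[cy5]]] - offmat[
            probe_rows, gidx[group_of[cy3]]
        ]
        noise = (
            rng.normal(0.0, cfg.array_noise_sd, size=n_probes)
            if cfg.array_noise_sd > 0
            else 0.0
        )
        m = signal + array_eff[a] + dye_bias + noise
        frames.append(
            pd.DataFrame({"probe_id": probes, "array_id": array_id, "M": m})
        )
    table = pd.concat(frames, ignore_index=True)
    return table, truth


# --------------------------------------------------------------------------
# TaqMan plate generator
# --------------------------------------------------------------------------

DEFAULT_CLUSTER_ANGLES = {"GG": 15.0, "GS": 45.0, "DUP_GS": 56.31, "SS": 75.0}
GENOTYPE_OF_CLASS = {"SS": "SS", "GS": "GS", "GG": "GG", "DUP_GS": "GS"}


def generate_taqman_plate(
    n_per_class: dict[str, int],
    cluster_angles: dict[str, float] | None = None,
    angular_sd: float = 3.0,
    signal_mean: float = 1.0,
    signal_sd: float = 0.1,
    n_controls: int = 3,
    alive_prob: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate endpoint TaqMan fluorescence for G119S genotyping.

    Each well lies on a ray from the origin: ``FAM = r*sin(theta)``,
    ``VIC = r*cos(theta)`` with ``r ~ Normal(signal_mean, signal_sd)``
    truncated positive and ``theta ~ Normal(class angle, angular_sd)``.
    FAM labels the mutant serine allele, VIC the wild-type glycine, so
    true heterozygotes sit on the 45-degree 1:1 balance line while
    duplication-carrying heterozygotes (class ``DUP_GS``, extra serine
    copy) sit at an angle shifted toward FAM (default 56.31 degrees,
    i.e. a 1.5:1 dye ratio).  SS and GG control wells are appended.

    ``alive_prob`` optionally assigns survival phenotypes per class
    (probability of "alive"; classes absent default to "untested").

    Returns the plate table (sample_id, fam_dR, vic_dR, control_type,
    phenotype) and a Series of true class labels indexed by sample_id.
    """
    if signal_mean <= 0:
        raise ConfigError("signal_mean must be positive")
    if angular_sd < 0 or signal_sd < 0:
        raise ConfigError("standard deviations must be >= 0")
    angles = dict(DEFAULT_CLUSTER_ANGLES)
    if cluster_angles:
        angles.update(cluster_angles)
    used = {k: angles[k] for k in set(n_per_class) | {"SS", "GG"}}
    for cls, ang in used.items():
        if not 0.0 < ang < 90.0:
            raise ConfigError(f"cluster angle for {cls} must be in (0, 90) degrees")
    if len(set(used.values())) != len(used):
        raise ConfigError("cluster angles must be distinct")
    for cls, n in n_per_class.items():
        if n < 0:
            raise ConfigError(f"count for class {cls} must be >= 0")
        if cls not in GENOTYPE_OF_CLASS:
            raise ConfigError(f"unknown class {cls!r}")

    rng = np.random.default_rng(seed)
    alive_prob = alive_prob or {}

    def draw(cls: str, n: int) -> tuple[np.ndarray, np.ndarray]:
        theta = np.deg2rad(rng.normal(angles[cls], angular_sd, size=n))
        if signal_sd > 0:
            a = (0.0 - signal_mean) / signal_sd
            r = stats.truncnorm.rvs(
                a, np.inf, loc=signal_mean, scale=signal_sd,
                size=n, random_state=rng,
            )
        else:
            r = np.full(n, signal_mean)
        return r * np.sin(theta), r * np.cos(theta)

    rows = []
    labels = {}
    for cls in sorted(n_per_class):
        n = n_per_class[cls]
        fam, vic = draw(cls, n)
        p_alive = alive_prob.get(cls)
        alive = (
            rng.random(n) < p_alive if p_alive is not None else np.zeros(n, bool)
        )
        for i in range(n):
            sid = f"{cls}_{i + 1:03d}"
            pheno = (
                "untested" if p_alive is None else ("alive" if alive[i] else "dead")
            )
            rows.append((sid, fam[i], vic[i], "none", pheno))
            labels[sid] = cls
    for ctrl in ("SS", "GG"):
        fam, vic = draw(ctrl, n_controls)
        for i in range(n_controls):
            sid = f"CTRL_{ctrl}_{i + 1}"
            rows.append((sid, fam[i], vic[i], ctrl, "untested"))
            labels[sid] = ctrl
    plate = pd.DataFrame(
        rows, columns=["sample_id", "fam_dR", "vic_dR", "control_type", "phenotype"]
    )
    return plate, pd.Series(labels, name="true_class")


# --------------------------------------------------------------------------
# qPCR Ct generator
# --------------------------------------------------------------------------

def generate_ct_table(
    samples: list[tuple[str, dict[str, float]]],
    efficiencies: dict[str, float],
    replicates: int = 3,
    ct_noise_sd: float = 0.0,
    base_ct: float | dict[str, float] = 24.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Simulate a qPCR Ct table from planted relative quantities.

    ``samples`` lists ``(sample_id, {amplicon: relative_quantity})``.
    For each technical replicate::

        Ct = base_ct[amplicon] - log(quantity) / log(1 + E) + noise

    so a doubling of template at E = 1 lowers Ct by exactly one cycle.
    Returns the long table (sample_id, amplicon, replicate, ct) and the
    planted quantities as truth.
    """
    if replicates < 1:
        raise ConfigError("replicates must be >= 1")
    if ct_noise_sd < 0:
        raise ConfigError("ct_noise_sd must be >= 0")
    for amp, e in efficiencies.items():
        if not 0.5 < e <= 1.2:
            raise ConfigError(f"efficiency for {amp!r} must be in (0.5, 1.2]")
    rng = np.random.default_rng(seed)
    rows = []
    truth: dict[str, dict[str, float]] = {}
    for sample_id, quantities in samples:
        truth[sample_id] = dict(quantities)
        for amp, q in quantities.items():
            if q <= 0:
                raise ConfigError(
                    f"quantity for {sample_id!r}/{amp!r} must be positive"
                )
            if amp not in efficiencies:
                raise ConfigError(f"no efficiency for amplicon {amp!r}")
            base = base_ct[amp] if isinstance(base_ct, dict) else base_ct
            e = efficiencies[amp]
            ct0 = base - np.log(q) / np.log(1.0 + e)
            for rep in range(1, replicates + 1):
                noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                rows.append((sample_id, amp, rep, ct0 + noise))
    table = pd.DataFrame(rows, columns=["sample_id", "amplicon", "replicate", "ct"])
    return table, truth


# --------------------------------------------------------------------------
# bioassay and dose-response generators
# --------------------------------------------------------------------------

def generate_bioassay_counts(
    conditions: list[tuple[str, str, bool, float, int, int]],
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate WHO-bioassay replicate mortality counts.

    ``conditions`` lists ``(insecticide, season, pbo, true_mortality,
    n_replicates, n_per_replicate)``; deaths per replicate are drawn
    Binomial(n_per_replicate, true_mortality).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for insecticide, season, pbo, p, n_reps, n_per in conditions:
        if not 0.0 <= p <= 1.0:
            raise ConfigError("true_mortality must be in [0, 1]")
        deaths = rng.binomial(n_per, p, size=n_reps)
        for r in range(n_reps):
            rows.append(
                (insecticide, season, bool(pbo), r + 1, n_per, int(deaths[r]))
            )
    return pd.DataFrame(
        rows,
        columns=["insecticide", "season", "pbo", "replicate", "n_exposed", "n_dead"],
    )


def expected_survival(
    dose: np.ndarray | float, lc50: float, slope: float, model: str = "linear"
) -> np.ndarray:
    """Expected survival proportion at ``dose``.

    ``linear``: p = clamp(0.5 - slope*(log10 dose - log10 lc50), 0, 1),
    the same form the LC50 fitter assumes, so noise-free recovery is
    exact.  ``logistic`` substitutes a logistic curve with matching
    local slope at the LC50, for robustness checks.
    """
    x = np.log10(np.asarray(dose, dtype=float)) - np.log10(lc50)
    if model == "linear":
        return np.clip(0.5 - slope * x, 0.0, 1.0)
    if model == "logistic":
        return 1.0 / (1.0 + np.exp(4.0 * slope * x))
    raise ConfigError(f"unknown dose-response model {model!r}")


def generate_dose_response(
    lines: list[tuple[str, float, float]],
    doses: list[float],
    n_per_vial: int = 10,
    noise: str = "binomial",
    model: str = "linear",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-vial dose-response survival for each line.

    ``lines`` lists ``(line_id, true_lc50, slope per log10 dose)``.
    With ``noise="none"`` the expected proportions are returned exactly
    (``n_survived`` may then be fractional); ``"binomial"`` draws
    integer counts.
    """
    if noise not in ("binomial", "none"):
        raise ConfigError(f"unknown noise mode {noise!r}")
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ConfigError("doses must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for line_id, lc50, slope in lines:
        if lc50 <= 0:
            raise ConfigError("true_lc50 must be positive")
        if slope == 0:
            raise ConfigError("slope must be nonzero (LC50 undefined)")
        p = expected_survival(doses, lc50, slope, model=model)
        if noise == "binomial":
            surv = rng.binomial(n_per_vial, p)
        else:
            surv = p * n_per_vial
        for d, s in zip(doses, surv):
            rows.append((line_id, float(d), n_per_vial, s))
    out = pd.DataFrame(rows, columns=["line_id", "dose_ug", "n", "n_survived"])
    out["survival"] = out["n_survived"] / out["n"]
    return out
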