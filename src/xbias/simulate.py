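"""Synthetic gene catalogs, tissue atlases, time courses and binding profiles.

The generator emulates the data model of the analysis: log-normal
baseline microarray intensities, multiplicative tissue-bias factors
planted toward single target tissues, monotone spermatocyte-activation
trajectories over larval testis development, and chromatin-protein
binding scores with planted positive (silencing-role) or negative
(activation-role) correlation to testis up-regulation, attenuated on the
X chromosome.  Every planted attribute is recorded in a ``Truth`` table
so downstream stages have parameter-recovery tests.

Randomness: a single root seed; each table draws from a substream
derived deterministically from ``(seed, table_name)``, so regenerating
one table never perturbs the others.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import ARMS, BindingProfile, ExpressionAtlas, GeneCatalog, TimeCourse

#: FlyAtlas-style tissue panel: adult testis plus somatic sources and ovary.
DEFAULT_TISSUES: tuple[str, ...] = (
    "testis",
    "accessory_gland",
    "brain",
    "head",
    "thoracic_ganglion",
    "crop",
    "midgut",
    "hindgut",
    "malpighian_tubule",
    "ovary",
    "salivary_gland",
    "carcass",
)

#: Chromatin proteins with role defaults (ChIP/DamID literature assignments).
DEFAULT_PROTEIN_ROLES: dict[str, str] = {
    "H1": "silencing",
    "H3K27me3": "silencing",
    "LamDm0": "silencing",
    "D1": "silencing",
    "Pc": "silencing",
    "esc": "silencing",
    "Sce": "silencing",
    "H3.3A": "activation",
    "H3K4me3": "activation",
    "DJun": "activation",
    "bcd": "activation",
}

#: Approximate euchromatic gene shares of the major arms (Release-5-like).
DEFAULT_ARM_PROPORTIONS: dict[str, float] = {
    "X": 0.165,
    "2L": 0.180,
    "2R": 0.210,
    "3L": 0.190,
    "3R": 0.245,
    "4": 0.010,
}

#: Bias-factor strata: (lower, upper, weight); factors drawn log-uniformly.
DEFAULT_BIAS_STRATA: tuple[tuple[float, float, float], ...] = (
    (2.0, 5.0, 0.40),
    (5.0, 10.0, 0.25),
    (10.0, 1000.0, 0.35),
)

_TABLE_CODES = {"catalog": 1, "atlas": 2, "timecourse": 3, "binding": 4}


@dataclass
class SimConfig:
    """Parameters of the synthetic-data generator.

    Defaults describe a genome-scale Drosophila-like study: ~13,000
    genes on six arms, a 12-tissue atlas with testis the richest source
    of highly biased genes, a six-condition larval testis time course
    with three replicates, and an 11-protein binding panel.
    """

    n_genes: int = 13000
    arm_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARM_PROPORTIONS)
    )
    #: natural-log mean/sd of baseline intensity (log-normal).
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 1.2
    tissues: Sequence[str] = DEFAULT_TISSUES
    #: fraction of genes planted as biased toward each tissue; a mapping
    #: may carry a "default" key (testis hosts more specific genes).
    bias_fraction_per_tissue: Mapping[str, float] | float = field(
        default_factory=lambda: {"default": 0.02, "testis": 0.08}
    )
    bias_strata: Sequence[tuple[float, float, float]] = DEFAULT_BIAS_STRATA
    #: multiplier on P(arm = X) for planted >=10x genes (<1 depletes the X).
    x_highbias_depletion: float = 0.5
    activation_fraction: float = 0.30
    trajectory_slope_range: tuple[float, float] = (0.25, 1.0)  # log2 per day
    days: Sequence[tuple[int, str]] = (
        (4, "feeding"),
        (5, "feeding"),
        (6, "feeding"),
        (7, "feeding"),
        (7, "wandering"),
        (10, "wandering"),
    )
    n_replicates: int = 3
    #: multiplicative noise coefficient of variation (log-normal).
    noise_cv: float = 0.2
    protein_roles: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PROTEIN_ROLES)
    )
    binding_rho_silencing: float = 0.3
    binding_rho_activation: float = -0.3
    #: factor in [0,1] shrinking planted binding correlation on the X.
    x_attenuation: float = 0.3
    binding_threshold_quantile: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        props = dict(self.arm_proportions)
        if set(props) - set(ARMS):
            raise ConfigError(f"unknown arms in arm_proportions: {set(props) - set(ARMS)}")
        total = sum(props.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"arm_proportions must sum to 1, got {total}")
        for name in (
            "x_highbias_depletion",
            "activation_fraction",
            "x_attenuation",
            "binding_threshold_quantile",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        for t, frac in self._bias_fractions().items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"bias fraction for {t!r} must be in [0,1]")
        if sum(self._bias_fractions().values()) > 1.0 + 1e-9:
            raise ConfigError("bias fractions sum above 1: cannot partition genes")
        w = sum(s[2] for s in self.bias_strata)
        if abs(w - 1.0) > 1e-9:
            raise ConfigError("bias_strata weights must sum to 1")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be nonnegative")
        for role in dict(self.protein_roles).values():
            if role not in ("silencing", "activation"):
                raise ConfigError(f"unknown protein role {role!r}")

    def _bias_fractions(self) -> dict[str, float]:
        if isinstance(self.bias_fraction_per_tissue, Mapping):
            default = self.bias_fraction_per_tissue.get("default", 0.0)
            return {
                t: float(self.bias_fraction_per_tissue.get(t, default))
                for t in self.tissues
            }
        return {t: float(self.bias_fraction_per_tissue) for t in self.tissues}

    def rng(self, table: str) -> np.random.Generator:
        """Deterministic substream for one output table."""
        return np.random.default_rng([int(self.seed), _TABLE_CODES[table]])

    @property
    def sigma_ln(self) -> float:
        """Natural-log sd of the multiplicative noise for the given CV."""
        return float(np.sqrt(np.log1p(self.noise_cv**2)))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["arm_proportions"] = dict(self.arm_proportions)
        d["tissues"] = list(self.tissues)
        d["bias_strata"] = [list(s) for s in self.bias_strata]
        d["days"] = [list(x) for x in self.days]
        d["protein_roles"] = dict(self.protein_roles)
        if isinstance(self.bias_fraction_per_tissue, Mapping):
            d["bias_fraction_per_tissue"] = dict(self.bias_fraction_per_tissue)
        return d


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_catalog(config: SimConfig) -> tuple[GeneCatalog, pd.DataFrame]:
    """Generate a gene catalog plus the planted-truth table.

    Genes are first assigned a planted tissue bias (target tissue and
    multiplicative factor from the configured strata), an activation flag
    and trajectory slope.  Arms are then drawn multinomially.  For
    planted high-bias (>=10x) genes the X probability is multiplied by
    ``x_highbias_depletion`` with the removed mass spread proportionally
    over the autosomal arms, so the parameter is exactly the planted X
    representation ratio of those genes.  ``arm_proportions`` describe
    the *marginal* (realized) genome composition — arm proportions
    measured from a real genome already include any depletion — so the
    non-high-bias genes receive a compensating X probability and the
    catalog matches ``arm_proportions`` in expectation regardless of the
    depletion setting.
    """
    rng = config.rng("catalog")
    n = config.n_genes
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")

    # planted tissue bias: partition a prefix-free random ordering
    order = rng.permutation(n)
    bias_target = np.array([""] * n, dtype=object)
    fractions = config._bias_fractions()
    pos = 0
    for tissue in config.tissues:
        k = int(round(fractions[tissue] * n))
        bias_target[order[pos : pos + k]] = tissue
        pos += k

    bias_factor = np.ones(n)
    biased = bias_target != ""
    strata = list(config.bias_strata)
    weights = np.array([s[2] for s in strata])
    idx = rng.choice(len(strata), size=int(biased.sum()), p=weights / weights.sum())
    lo = np.array([strata[i][0] for i in idx])
    hi = np.array([strata[i][1] for i in idx])
    u = rng.random(int(biased.sum()))
    bias_factor[biased] = np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))
    highbias = bias_factor >= 10.0

    activated = rng.random(n) < config.activation_fraction
    s_lo, s_hi = config.trajectory_slope_range
    slope = np.where(activated, rng.uniform(s_lo, s_hi, size=n), 0.0)

    arms = np.array(ARMS)
    base_p = np.array([dict(config.arm_proportions).get(a, 0.0) for a in ARMS])
    p_x = base_p[0]
    f_high = float(highbias.mean())
    dep_p = _with_x_probability(base_p, config.x_highbias_depletion * p_x)
    if f_high < 1.0:
        # compensate so the marginal X share stays at arm_proportions
        p_x_rest = p_x * (1.0 - config.x_highbias_depletion * f_high) / (1.0 - f_high)
        rest_p = _with_x_probability(base_p, min(p_x_rest, 1.0))
    else:
        rest_p = base_p
    arm_assign = np.empty(n, dtype=object)
    u = rng.random(n)
    for mask, probs in ((~highbias, rest_p), (highbias, dep_p)):
        if mask.any():
            edges = np.cumsum(probs)
            arm_assign[mask] = arms[np.searchsorted(edges, u[mask], side="right").clip(0, len(arms) - 1)]

    truth = pd.DataFrame(
        {
            "arm": arm_assign,
            "bias_target": np.where(biased, bias_target, "none"),
            "bias_factor": bias_factor,
            "highbias": highbias,
            "activated": activated,
            "slope": slope,
        },
        index=gene_ids,
    )
    catalog = GeneCatalog(truth[["arm"]].copy())
    return catalog, truth


def _with_x_probability(base_p: np.ndarray, p_x_new: float) -> np.ndarray:
    """Set the X probability, rescaling autosomal arms to keep the sum 1."""
    out = base_p.copy()
    out[0] = p_x_new
    p_x = base_p[0]
    if p_x < 1.0:
        out[1:] *= (1.0 - p_x_new) / (1.0 - p_x)
    return out


def generate_atlas(
    catalog: GeneCatalog,
    truth: pd.DataFrame,
    config: SimConfig,
    tissue_labels: Sequence[str] | None = None,
) -> ExpressionAtlas:
    """Tissue atlas: log-normal baseline × planted bias factor × noise."""
    tissues = list(tissue_labels if tissue_labels is not None else config.tissues)
    planted = set(truth["bias_target"]) - {"none"}
    unknown = planted - set(tissues)
    if unknown:
        raise ConfigError(f"planted target tissue(s) missing from atlas: {sorted(unknown)}")
    rng = config.rng("atlas")
    n = len(catalog)
    baseline = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n))
    values = np.empty((n, len(tissues)))
    target = truth["bias_target"].to_numpy()
    factor = truth["bias_factor"].to_numpy()
    for j, tissue in enumerate(tissues):
        col = baseline * np.where(target == tissue, factor, 1.0)
        values[:, j] = col
    if config.noise_cv > 0:
        values *= np.exp(rng.normal(0.0, config.sigma_ln, size=values.shape))
    return ExpressionAtlas(pd.DataFrame(values, index=catalog.gene_ids, columns=tissues))


def generate_timecourse(
    catalog: GeneCatalog,
    truth: pd.DataFrame,
    config: SimConfig,
    days: Sequence[tuple[int, str]] | None = None,
) -> TimeCourse:
    """Testis-development time course with monotone activated trajectories.

    Activated genes gain ``slope`` log2 units of expected expression per
    day past the earliest day; other genes stay flat.  Replicates are
    independent multiplicative-noise draws.
    """
    conditions = list(days if days is not None else config.days)
    if len(conditions) < 2:
        raise ConfigError("time course needs at least 2 conditions")
    rng = config.rng("timecourse")
    n = len(catalog)
    baseline_ln = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    slope = truth["slope"].to_numpy()
    d0 = min(d for d, _ in conditions)

    cols, meta = {}, {}
    for day, stage in conditions:
        ln_expected = baseline_ln + slope * (day - d0) * np.log(2.0)
        for rep in range(1, config.n_replicates + 1):
            name = f"d{day}{stage[:1]}_r{rep}"
            noise = (
                rng.normal(0.0, config.sigma_ln, size=n) if config.noise_cv > 0 else 0.0
            )
            cols[name] = np.exp(ln_expected + noise)
            meta[name] = {"day": day, "stage": stage, "replicate": rep}
    frame = pd.DataFrame(cols, index=catalog.gene_ids)
    samples = pd.DataFrame.from_dict(meta, orient="index")
    samples.index.name = "sample"
    return TimeCourse(frame, samples)


def planted_upregulation(truth: pd.DataFrame, config: SimConfig) -> pd.Series:
    """True total log2 fold change at the last condition vs the earliest."""
    days = [d for d, _ in config.days]
    span = max(days) - min(days)
    return pd.Series(truth["slope"].to_numpy() * span, index=truth.index, name="upregulation")


def generate_binding(
    catalog: GeneCatalog,
    truth: pd.DataFrame,
    config: SimConfig,
    proteins: Mapping[str, str] | None = None,
) -> BindingProfile:
    """Binding scores with planted correlation to testis up-regulation.

    For protein *p* with role correlation ρ (positive for silencing,
    negative for activation), the score of gene *g* is
    ``ρ_g z_g + sqrt(1 − ρ_g²) ε_g`` where ``z`` is the standardized
    planted up-regulation and ``ρ_g = ρ × x_attenuation`` on the X.
    Per-protein thresholds sit at the configured score quantile.
    """
    roles = dict(proteins if proteins is not None else config.protein_roles)
    rng = config.rng("binding")
    u = planted_upregulation(truth, config).to_numpy()
    sd = u.std()
    z = (u - u.mean()) / sd if sd > 0 else np.zeros_like(u)
    on_x = (truth["arm"] == "X").to_numpy()

    scores = {}
    thresholds = {}
    for protein, role in roles.items():
        rho = (
            config.binding_rho_silencing
            if role == "silencing"
            else config.binding_rho_activation
        )
        rho_g = np.where(on_x, rho * config.x_attenuation, rho)
        eps = rng.standard_normal(len(z))
        s = rho_g * z + np.sqrt(1.0 - rho_g**2) * eps
        scores[protein] = s
        thresholds[protein] = float(np.quantile(s, config.binding_threshold_quantile))
    return BindingProfile(
        pd.DataFrame(scores, index=catalog.gene_ids),
        pd.Series(thresholds, name="threshold"),
        pd.Series(roles, name="role"),
    )


def generate_all(config: SimConfig) -> dict:
    """Generate every table of one synthetic study under a single config."""
    catalog, truth = generate_catalog(config)
    return {
        "catalog": catalog,
        "truth": truth,
        "atlas": generate_atlas(catalog, truth, config),
        "timecourse": generate_timecourse(catalog, truth, config),
        "binding": generate_binding(catalog, truth, config),
    }
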