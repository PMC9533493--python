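"""Synthetic populations with a heritable, compositional rumen microbiome.

The generator emulates the statistical structure of a sire-family beef-cattle
study: unrelated sires with ~8 half-sib progeny each, biallelic SNPs in
Hardy-Weinberg proportions, goal traits (fatty-acid indices, optionally
methane yield) with chosen heritabilities and genomic correlations, and a
compositional microbial-gene table whose latent log-abundances carry a
host-genomic component. Genetic correlation between features and goal traits
is induced by factor loadings on the goal-trait breeding-value factors;
finite-depth multinomial resampling of the closed composition is the only
zero-generating mechanism.

Within-level phenotypic variance is 1 per trait on the latent scale, so a
trait's genetic variance equals its h2; the systematic (diet x breed x
experiment) effect adds variance f/(1-f) on top so that it explains a
fraction f of the total phenotypic variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coda import CompositionTable
from .genomics import GenotypeMatrix, Grm, compute_grm_vanraden2


def _default_goal_h2() -> dict[str, float]:
    return {"N3": 0.76, "CLA": 0.57}


@dataclass
class SimulationSpec:
    """Parameters of a synthetic population (defaults are desk scale)."""

    n_animals: int = 250
    n_sires: int | None = None  # default: ~8 progeny per sire
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_features: int = 300
    heritable_fraction: float = 0.3
    feature_h2_range: tuple[float, float] = (0.2, 0.6)
    goal_h2: dict[str, float] = field(default_factory=_default_goal_h2)
    goal_genomic_corr: np.ndarray | None = None  # default: rg(N3,CLA)=0.39
    goal_residual_corr: np.ndarray | None = None  # default: 0.2 off-diagonal
    index_goals: tuple[str, ...] = ("N3", "CLA")  # goals features load on
    correlated_fraction: float = 0.4  # heritable features with goal loadings
    feature_goal_rg: np.ndarray | None = None  # (n_corr_features, n_index_goals)
    rg_magnitude_range: tuple[float, float] = (0.3, 0.8)
    fixed_levels: int = 17
    fixed_variance_fraction: float = 0.40
    base_log_sd: float = 2.0  # spread of baseline feature log-abundances
    sequencing_depth: int | None = None  # None: calibrated to zero_target
    zero_target: float = 0.05
    grm_ridge: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sires is None:
            self.n_sires = max(1, round(self.n_animals / 8))
        if self.n_sires < 1:
            raise ValueError("n_sires must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        for prop in (
            self.heritable_fraction,
            self.correlated_fraction,
            self.fixed_variance_fraction,
            self.zero_target,
        ):
            if not 0 <= prop <= 1:
                raise ValueError("proportions must lie in [0, 1]")
        if not (0 <= self.feature_h2_range[0] <= self.feature_h2_range[1] < 1):
            raise ValueError("feature_h2_range must lie in [0, 1)")
        for h2 in self.goal_h2.values():
            if not 0 <= h2 < 1:
                raise ValueError("goal h2 must lie in [0, 1)")
        k = len(self.goal_h2)
        if self.goal_genomic_corr is None:
            self.goal_genomic_corr = _default_corr(list(self.goal_h2), 0.39)
        if self.goal_residual_corr is None:
            self.goal_residual_corr = _default_corr(list(self.goal_h2), 0.20)
        for name, m in (
            ("goal_genomic_corr", self.goal_genomic_corr),
            ("goal_residual_corr", self.goal_residual_corr),
        ):
            m = np.asarray(m, float)
            if m.shape != (k, k) or not np.allclose(m, m.T) or not np.allclose(np.diag(m), 1):
                raise ValueError(f"{name} must be a symmetric correlation matrix")
            if np.linalg.eigvalsh(m).min() <= 0:
                raise ValueError(f"{name} must be positive definite")
        missing = set(self.index_goals) - set(self.goal_h2)
        if missing:
            raise ValueError(f"index_goals not in goal_h2: {sorted(missing)}")

    @classmethod
    def with_ch4(cls, **kwargs) -> "SimulationSpec":
        """Goal set N3/CLA plus methane yield, unfavourably correlated."""
        goal_h2 = {"N3": 0.76, "CLA": 0.57, "CH4": 0.30}
        rg = np.array([[1.0, 0.39, -0.30], [0.39, 1.0, -0.30], [-0.30, -0.30, 1.0]])
        re = np.array([[1.0, 0.20, -0.10], [0.20, 1.0, -0.10], [-0.10, -0.10, 1.0]])
        kwargs.setdefault("goal_h2", goal_h2)
        kwargs.setdefault("goal_genomic_corr", rg)
        kwargs.setdefault("goal_residual_corr", re)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        import yaml

        d = self.__dict__.copy()
        for key in ("goal_genomic_corr", "goal_residual_corr", "feature_goal_rg"):
            if d[key] is not None:
                d[key] = np.asarray(d[key]).tolist()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


def _default_corr(names: list[str], rho: float) -> np.ndarray:
    k = len(names)
    m = np.full((k, k), rho)
    np.fill_diagonal(m, 1.0)
    return m


@dataclass
class GroundTruth:
    """Simulated truth for downstream parameter-recovery checks."""

    true_breeding_values: pd.DataFrame  # animals x goal traits
    true_h2: dict[str, float]
    true_rg: pd.DataFrame
    sire_ids: list[str]
    fixed_level: list[str]
    goal_factors: np.ndarray  # standardized genetic factors (animals x goals)
    feature_h2: np.ndarray | None = None
    feature_heritable: np.ndarray | None = None
    feature_rg: pd.DataFrame | None = None  # correlated features x index goals
    realized_zero_fraction: float | None = None


def simulate_genotypes(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, list[str]]:
    """Half-sib family genotypes: one sire gamete, one population gamete.

    Sires are unrelated draws from Hardy-Weinberg proportions at allele
    frequencies uniform on `maf_range`; each progeny receives a Mendelian
    gamete from its sire and an independent population gamete, giving the
    expected half-sib genomic relationship of ~0.25.
    """
    rng = rng or np.random.default_rng(spec.seed)
    p = rng.uniform(*spec.maf_range, size=spec.n_snps)
    sire_geno = rng.binomial(2, p, size=(spec.n_sires, spec.n_snps)).astype(float)
    sires = np.arange(spec.n_animals) % spec.n_sires
    sire_gamete = rng.binomial(1, sire_geno[sires] / 2.0)
    dam_gamete = rng.binomial(1, p, size=(spec.n_animals, spec.n_snps))
    dosages = (sire_gamete + dam_gamete).astype(float)
    animal_ids = [f"A{i:04d}" for i in range(spec.n_animals)]
    snp_ids = [f"SNP{j:05d}" for j in range(spec.n_snps)]
    geno = GenotypeMatrix(animal_ids, snp_ids, dosages)
    sire_ids = [f"S{s:03d}" for s in sires]
    return geno, sire_ids


def simulate_traits(
    grm: Grm, spec: SimulationSpec, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Goal-trait phenotypes: fixed-level effect + breeding value + residual.

    Breeding values follow the Kronecker-structured multivariate normal
    N(0, Sigma_g x G); per-trait genetic variance is h2 (within-level
    phenotypic variance 1).
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    n = grm.n_animals
    goals = list(spec.goal_h2)
    k = len(goals)
    h2 = np.array([spec.goal_h2[t] for t in goals])
    sigma_g = np.sqrt(h2)
    sigma_e = np.sqrt(1.0 - h2)

    lam, U = grm.eigendecompose()
    if lam.min() <= 0:
        raise ValueError("GRM must be positive definite (apply a ridge)")
    Lg = U * np.sqrt(lam)

    factors = Lg @ rng.standard_normal((n, k))  # columns ~ N(0, G), unit scale
    Lr = np.linalg.cholesky(np.asarray(spec.goal_genomic_corr, float))
    factors = factors @ Lr.T
    bv = factors * sigma_g

    Le = np.linalg.cholesky(np.asarray(spec.goal_residual_corr, float))
    resid = (rng.standard_normal((n, k)) @ Le.T) * sigma_e

    f = spec.fixed_variance_fraction
    fixed_sd = np.sqrt(f / (1.0 - f)) if f < 1 else 0.0
    level_effects = rng.normal(0.0, fixed_sd, size=(spec.fixed_levels, k))
    codes = np.arange(n) % spec.fixed_levels
    levels = [f"L{c:02d}" for c in codes]

    pheno = level_effects[codes] + bv + resid
    traits = pd.DataFrame(pheno, index=grm.animal_ids, columns=goals)
    traits["fixed_level"] = levels

    sires = [f"S{i % max(1, round(n / 8)):03d}" for i in range(n)]
    truth = GroundTruth(
        true_breeding_values=pd.DataFrame(bv, index=grm.animal_ids, columns=goals),
        true_h2=dict(spec.goal_h2),
        true_rg=pd.DataFrame(spec.goal_genomic_corr, index=goals, columns=goals),
        sire_ids=sires,
        fixed_level=levels,
        goal_factors=factors,
    )
    return traits, truth


def simulate_microbiome(
    grm: Grm,
    spec: SimulationSpec,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> tuple[CompositionTable, GroundTruth]:
    """Compositional microbial-gene counts with host-genomic structure.

    Latent per-feature log-abundance = baseline + fixed-level effect +
    genetic part (scaled to the feature's h2; a subset loads on the goal
    breeding-value factors at target genomic correlations) + residual.
    Closure by exponentiation/row-normalization, then multinomial count
    sampling at finite depth introduces the zeros.
    """
    rng = rng or np.random.default_rng(spec.seed + 2)
    n = grm.n_animals
    F = spec.n_features
    goals = list(truth.true_h2)
    prim = [goals.index(t) for t in spec.index_goals]
    R = np.asarray(spec.goal_genomic_corr, float)[np.ix_(prim, prim)]

    n_her = int(round(spec.heritable_fraction * F))
    heritable = np.zeros(F, bool)
    heritable[rng.choice(F, size=n_her, replace=False)] = True
    h2_f = np.zeros(F)
    h2_f[heritable] = rng.uniform(*spec.feature_h2_range, size=n_her)

    her_idx = np.where(heritable)[0]
    n_corr = int(round(spec.correlated_fraction * n_her))
    corr_idx = rng.choice(her_idx, size=n_corr, replace=False) if n_corr else np.array([], int)

    if spec.feature_goal_rg is not None:
        rho = np.asarray(spec.feature_goal_rg, float)
        if rho.shape != (n_corr, len(prim)):
            raise ValueError("feature_goal_rg must be (n_correlated, n_index_goals)")
    else:
        mags = rng.uniform(*spec.rg_magnitude_range, size=n_corr)
        signs = rng.choice([-1.0, 1.0], size=n_corr)
        # same sign for both index goals, second goal at reduced magnitude
        rho = np.stack([mags * signs, 0.7 * mags * signs], axis=1)[:, : len(prim)]

    lam, U = grm.eigendecompose()
    Lg = U * np.sqrt(lam)
    w = Lg @ rng.standard_normal((n, n_her))  # independent N(0, G) deviates
    factors = truth.goal_factors[:, prim]  # standardized N(0, G) goal factors

    g = np.zeros((n, F))
    col_of = {fi: c for c, fi in enumerate(her_idx)}
    corr_set = set(corr_idx.tolist())
    Rinv = np.linalg.inv(R)
    rho_row = {fi: rho[c] for c, fi in enumerate(corr_idx)}
    for fi in her_idx:
        if fi in corr_set:
            r = rho_row[fi]
            a = Rinv @ r
            b2 = 1.0 - float(r @ Rinv @ r)
            if b2 < 0:
                raise ValueError("feature_goal_rg targets are infeasible (b^2 < 0)")
            gen = factors @ a + np.sqrt(b2) * w[:, col_of[fi]]
        else:
            gen = w[:, col_of[fi]]
        g[:, fi] = np.sqrt(h2_f[fi]) * gen

    e = rng.standard_normal((n, F)) * np.sqrt(1.0 - h2_f)
    f = spec.fixed_variance_fraction
    fixed_sd = np.sqrt(f / (1.0 - f)) if f < 1 else 0.0
    level_effects = rng.normal(0.0, fixed_sd, size=(spec.fixed_levels, F))
    codes = np.array([int(lv[1:]) for lv in truth.fixed_level])
    base = rng.normal(0.0, spec.base_log_sd, size=F)

    latent = base + level_effects[codes] + g + e
    props = np.exp(latent - latent.max(axis=1, keepdims=True))
    props = props / props.sum(axis=1, keepdims=True)

    depth = spec.sequencing_depth
    if depth is None:
        depth = calibrate_depth(props, spec.zero_target)
    counts = np.stack([rng.multinomial(depth, p) for p in props])
    zero_frac = float((counts == 0).mean())

    feature_ids = [f"KO{j:05d}" for j in range(F)]
    table = CompositionTable.from_counts(
        pd.DataFrame(counts, index=grm.animal_ids, columns=feature_ids)
    )
    truth.feature_h2 = h2_f
    truth.feature_heritable = heritable
    truth.feature_rg = pd.DataFrame(
        rho, index=[feature_ids[i] for i in corr_idx], columns=list(spec.index_goals)
    )
    truth.realized_zero_fraction = zero_frac
    return table, truth


def calibrate_depth(
    props: np.ndarray, zero_target: float, lo: float = 10.0, hi: float = 1e9
) -> int:
    """Depth whose expected multinomial zero fraction matches the target.

    Uses the exact per-entry zero probability (1 - p)^depth, monotone in
    depth, solved by bisection.
    """

    def zero_frac(d: float) -> float:
        return float(np.mean((1.0 - props) ** d))

    if zero_frac(lo) < zero_target:
        return int(lo)
    if zero_frac(hi) > zero_target:
        return int(hi)
    for _ in range(80):
        mid = np.sqrt(lo * hi)
        if zero_frac(mid) > zero_target:
            lo = mid
        else:
            hi = mid
    return int(round(np.sqrt(lo * hi)))


def construct_fatty_acid_table(
    n3_values: np.ndarray,
    cla_values: np.ndarray,
    denominator_total: float = 2.0,
    animal_ids: list[str] | None = None,
):
    """Invert the N3/CLA index formulas into a per-animal fatty-acid table.

    The saturated denominator mass is split over C12:0/C14:0/C16:0 in fixed
    beef-like proportions, and each index's numerator mass (denominator x
    exp(index)) over its constituent fatty acids, so that recomputing the
    indices returns the inputs exactly.
    """
    from .coda import CLA_NUMERATOR, FattyAcidTable, INDEX_DENOMINATOR, N3_NUMERATOR

    if denominator_total <= 0:
        raise ValueError("denominator_total must be positive")
    n3 = np.asarray(n3_values, float)
    cla = np.asarray(cla_values, float)
    if animal_ids is None:
        animal_ids = [f"A{i:04d}" for i in range(len(n3))]
    denom_split = np.array([0.08, 0.22, 0.70])
    n3_split = np.array([0.60, 0.20, 0.15, 0.05])
    cla_split = np.array([0.25, 0.75])
    cols = {}
    for name, wgt in zip(INDEX_DENOMINATOR, denom_split):
        cols[name] = np.full(len(n3), denominator_total * wgt)
    n3_total = denominator_total * np.exp(n3)
    for name, wgt in zip(N3_NUMERATOR, n3_split):
        cols[name] = n3_total * wgt
    cla_total = denominator_total * np.exp(cla)
    for name, wgt in zip(CLA_NUMERATOR, cla_split):
        cols[name] = cla_total * wgt
    return FattyAcidTable(pd.DataFrame(cols, index=animal_ids))


@dataclass
class SimulatedPopulation:
    """Everything one synthetic study provides, with ground truth attached."""

    spec: SimulationSpec
    genotypes: GenotypeMatrix
    grm: Grm
    traits: pd.DataFrame  # goal traits + fixed_level column
    microbiome: CompositionTable
    fatty_acids: object
    truth: GroundTruth


def simulate_population(spec: SimulationSpec) -> SimulatedPopulation:
    """Full synthetic study: genotypes, GRM, goal traits, microbiome, FA table."""
    rng = np.random.default_rng(spec.seed)
    geno, sire_ids = simulate_genotypes(spec, rng)
    # Sampling (especially within few, large half-sib families) can fix an
    # allele even when its population frequency is positive; such SNPs carry
    # no relationship information and would be removed by any QC, so drop
    # them here before building the GRM.
    freq = geno.dosages.mean(axis=0) / 2.0
    poly = (freq > 0.0) & (freq < 1.0)
    if not poly.all():
        keep = [s for s, ok in zip(geno.snp_ids, poly) if ok]
        geno = GenotypeMatrix(geno.animal_ids, keep, geno.dosages[:, poly])
    grm = compute_grm_vanraden2(geno, ridge_epsilon=spec.grm_ridge)
    traits, truth = simulate_traits(grm, spec, rng)
    truth.sire_ids = sire_ids
    micro, truth = simulate_microbiome(grm, spec, truth, rng)
    fa = construct_fatty_acid_table(
        traits["N3"].to_numpy() if "N3" in traits else np.zeros(len(traits)),
        traits["CLA"].to_numpy() if "CLA" in traits else np.zeros(len(traits)),
        animal_ids=list(traits.index),
    )
    return SimulatedPopulation(spec, geno, grm, traits, micro, fa, truth)
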