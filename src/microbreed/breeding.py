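"""Selection-index machinery: covariance assembly, bending, microbiome-driven
breeding-value prediction, accuracy and response to selection.

The microbiome-driven strategy predicts goal-trait breeding values from the
selected log-ratio features alone: a multivariate GBLUP with the goal traits
set missing and the previously estimated (bent) genomic/residual covariance
matrices held fixed. Animals are ranked on the equal-weight sum of their
goal-trait EBVs; response to truncation selection at proportion p is the
posterior distribution of the difference between the selected animals' mean
EBV and the population mean, in phenotypic standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gblup import GBLUP, McmcConfig
from .genomics import Grm

SELECTION_PROPORTIONS = (0.40, 0.30, 0.20, 0.10, 0.05)


@dataclass
class VarianceComponents:
    """Multi-trait genomic and residual covariance matrices (possibly bent)."""

    trait_ids: list[str]
    sigma_g: np.ndarray
    sigma_e: np.ndarray
    bending_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = len(self.trait_ids)
        for name, m in (("sigma_g", self.sigma_g), ("sigma_e", self.sigma_e)):
            m = np.asarray(m, float)
            if m.shape != (t, t) or not np.allclose(m, m.T, atol=1e-8):
                raise ValueError(f"{name} must be a symmetric {t}x{t} matrix")
        self.sigma_g = np.asarray(self.sigma_g, float)
        self.sigma_e = np.asarray(self.sigma_e, float)

    def subset(self, traits: list[str]) -> "VarianceComponents":
        idx = [self.trait_ids.index(t) for t in traits]
        return VarianceComponents(
            list(traits),
            self.sigma_g[np.ix_(idx, idx)],
            self.sigma_e[np.ix_(idx, idx)],
            dict(self.bending_log),
        )

    def genomic_variance(self, trait: str) -> float:
        i = self.trait_ids.index(trait)
        return float(self.sigma_g[i, i])

    def bend(self, tolerance: float = 0.001) -> "VarianceComponents":
        sg, log_g = bend_to_pd(self.sigma_g, tolerance)
        se, log_e = bend_to_pd(self.sigma_e, tolerance)
        return VarianceComponents(
            list(self.trait_ids), sg, se, {"sigma_g": log_g, "sigma_e": log_e}
        )


def assemble_covariance(pairwise: pd.DataFrame) -> VarianceComponents:
    """Build T x T covariance matrices from bivariate posterior means.

    `pairwise` has one row per unordered trait pair with columns
    ``trait_a, trait_b, cov_g, var_g_a, var_g_b, cov_e, var_e_a, var_e_b``.
    Off-diagonals come from the pair's covariance estimate; each diagonal is
    the average of that trait's variance estimates over all pairs containing
    it. Every pair must appear exactly once.
    """
    traits: list[str] = []
    for _, row in pairwise.iterrows():
        for t in (row["trait_a"], row["trait_b"]):
            if t not in traits:
                traits.append(str(t))
    T = len(traits)
    idx = {t: i for i, t in enumerate(traits)}
    expected = {frozenset((a, b)) for a in traits for b in traits if a < b}
    seen = {frozenset((str(r["trait_a"]), str(r["trait_b"]))) for _, r in pairwise.iterrows()}
    if len(seen) != len(pairwise):
        raise ValueError("a trait pair appears more than once")
    missing = expected - seen
    if missing:
        raise ValueError(f"missing trait pairs: {sorted(tuple(sorted(m)) for m in missing)}")

    sg = np.zeros((T, T))
    se = np.zeros((T, T))
    var_g_acc: dict[int, list[float]] = {i: [] for i in range(T)}
    var_e_acc: dict[int, list[float]] = {i: [] for i in range(T)}
    for _, row in pairwise.iterrows():
        i, j = idx[str(row["trait_a"])], idx[str(row["trait_b"])]
        sg[i, j] = sg[j, i] = row["cov_g"]
        se[i, j] = se[j, i] = row["cov_e"]
        var_g_acc[i].append(row["var_g_a"])
        var_g_acc[j].append(row["var_g_b"])
        var_e_acc[i].append(row["var_e_a"])
        var_e_acc[j].append(row["var_e_b"])
    for i in range(T):
        sg[i, i] = float(np.mean(var_g_acc[i]))
        se[i, i] = float(np.mean(var_e_acc[i]))
    return VarianceComponents(traits, sg, se)


def bend_to_pd(matrix: np.ndarray, tolerance: float = 0.001) -> tuple[np.ndarray, dict]:
    """Raise eigenvalues below `tolerance` to it and reconstruct.

    Returns the bent matrix and a change report (minimum eigenvalue before
    and after, Frobenius and max elementwise change) so the perturbation can
    be compared against posterior standard errors.
    """
    m = np.asarray(matrix, float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("bend_to_pd needs a symmetric matrix")
    vals, vecs = np.linalg.eigh(m)
    min_before = float(vals.min())
    if min_before >= tolerance:
        return m.copy(), {
            "changed": False,
            "min_eig_before": min_before,
            "min_eig_after": min_before,
            "frobenius_change": 0.0,
            "max_abs_change": 0.0,
        }
    bent_vals = np.maximum(vals, tolerance)
    bent = (vecs * bent_vals) @ vecs.T
    bent = (bent + bent.T) / 2.0
    report = {
        "changed": True,
        "min_eig_before": min_before,
        "min_eig_after": float(np.linalg.eigvalsh(bent).min()),
        "frobenius_change": float(np.linalg.norm(bent - m)),
        "max_abs_change": float(np.abs(bent - m).max()),
    }
    return bent, report


@dataclass
class EbvResult:
    """Posterior mean/sd of breeding values with per-animal accuracies."""

    ebv_mean: pd.DataFrame  # animals x traits
    ebv_sd: pd.DataFrame
    accuracy: pd.DataFrame
    ebv_draws: dict[str, np.ndarray]  # trait -> draws x animals
    grm_diag: pd.Series
    genomic_variance: dict[str, float]

    @property
    def animal_ids(self) -> list[str]:
        return list(self.ebv_mean.index.astype(str))

    def write_csv(self, path) -> None:
        out = []
        for t in self.ebv_mean.columns:
            out.append(
                pd.DataFrame(
                    {
                        "animal": self.ebv_mean.index,
                        "trait": t,
                        "ebv": self.ebv_mean[t].to_numpy(),
                        "sd": self.ebv_sd[t].to_numpy(),
                        "accuracy": self.accuracy[t].to_numpy(),
                    }
                )
            )
        pd.concat(out).to_csv(path, index=False)


def ebv_accuracy(sd_i, g_ii, sigma2_g: float):
    """Accuracy of an EBV: sqrt(1 - sd_i^2 / (g_ii * sigma2_g)).

    sd_i is the posterior standard deviation of the animal's genomic value;
    ratios above 1 (Monte-Carlo noise) are clamped to accuracy 0.
    """
    sd_i = np.asarray(sd_i, float)
    g_ii = np.asarray(g_ii, float)
    if sigma2_g <= 0 or np.any(g_ii <= 0):
        raise ValueError("g_ii and sigma2_g must be positive")
    ratio = sd_i**2 / (g_ii * sigma2_g)
    if np.any(ratio > 1 + 1e-9):
        warnings.warn("sd_i^2 exceeds g_ii * sigma2_g; accuracy clamped to 0", stacklevel=2)
    return np.sqrt(np.maximum(0.0, 1.0 - np.minimum(ratio, 1.0)))


def predict_goal_ebvs(
    feature_data: pd.DataFrame,
    grm: Grm,
    vc: VarianceComponents,
    fixed_factor,
    goal_traits: list[str],
    config: McmcConfig | None = None,
    goals_missing: bool = True,
    goal_phenotypes: pd.DataFrame | None = None,
) -> EbvResult:
    """Goal-trait EBVs from microbial features under fixed variance components.

    Fits the multivariate GBLUP with the goal traits missing (microbiome-
    driven scenario); with ``goals_missing=False`` and observed
    ``goal_phenotypes`` the goals enter as records (benchmark scenario).
    """
    if np.linalg.eigvalsh(vc.sigma_g).min() <= 0 or np.linalg.eigvalsh(vc.sigma_e).min() <= 0:
        raise ValueError("variance components must be positive definite (bend first)")
    endog = feature_data.copy()
    for goal in goal_traits:
        if goals_missing:
            endog[goal] = np.nan
        else:
            if goal_phenotypes is None or goal not in goal_phenotypes:
                raise ValueError("observed goal phenotypes required when goals_missing=False")
            endog[goal] = goal_phenotypes[goal].reindex(endog.index).to_numpy()
    order = [t for t in vc.trait_ids if t in endog.columns]
    if set(order) != set(endog.columns):
        raise ValueError("variance components must cover exactly the model traits")
    endog = endog[order]
    vc_sub = vc.subset(order)
    model = GBLUP(
        endog,
        grm,
        fixed_factor,
        fixed_variance_components=(vc_sub.sigma_g, vc_sub.sigma_e),
        store_ebv_draws=goal_traits,
    )
    res = model.fit(config or McmcConfig())
    g_diag = pd.Series(grm.diagonal(), index=grm.animal_ids)
    sigma2 = {t: vc_sub.genomic_variance(t) for t in goal_traits}
    acc = pd.DataFrame(
        {
            t: ebv_accuracy(res.ebv_sd[t].to_numpy(), g_diag.to_numpy(), sigma2[t])
            for t in goal_traits
        },
        index=res.ebv.index,
    )
    return EbvResult(
        ebv_mean=res.ebv[goal_traits],
        ebv_sd=res.ebv_sd[goal_traits],
        accuracy=acc,
        ebv_draws={t: res.chain.ebv_draws[t] for t in goal_traits},
        grm_diag=g_diag,
        genomic_variance=sigma2,
    )


def aggregate_rank(ebvs: pd.DataFrame, weights: np.ndarray | None = None) -> list[str]:
    """Animals ranked by descending (equal-weight) sum of goal EBVs.

    Ties are broken by animal id, so the ranking is stable under input
    permutation.
    """
    w = np.ones(ebvs.shape[1]) if weights is None else np.asarray(weights, float)
    total = ebvs.to_numpy(float) @ w
    order = sorted(zip(-total, ebvs.index.astype(str)))
    return [a for _, a in order]


def selection_intensity(p: float) -> float:
    """Truncation-selection intensity i = phi(z) / p for proportion p.

    z is the standard-normal upper-p quantile (infinite-population theory);
    p = 1 (no selection) gives 0.
    """
    if not 0 < p <= 1:
        raise ValueError("selection proportion must lie in (0, 1]")
    if p == 1:
        return 0.0
    z = stats.norm.ppf(1.0 - p)
    return float(stats.norm.pdf(z) / p)


def response_to_selection(
    ebv_draws: np.ndarray,
    ranking: list[str],
    animal_ids: list[str],
    p: float,
    phenotypic_sd: float,
    trait_mean: float | None = None,
) -> dict:
    """Posterior response: mean EBV of the selected minus the population mean.

    Computed per stored draw and standardized by the phenotypic sd; also in
    percent of the trait mean when one is given.
    """
    if phenotypic_sd <= 0:
        raise ValueError("phenotypic_sd must be positive")
    n = len(animal_ids)
    k = int(round(p * n))
    if k < 1:
        raise ValueError("selection proportion selects no animals")
    pos = {a: i for i, a in enumerate(animal_ids)}
    sel_idx = np.array([pos[a] for a in ranking[:k]])
    per_draw = (ebv_draws[:, sel_idx].mean(axis=1) - ebv_draws.mean(axis=1)) / phenotypic_sd
    out = {
        "proportion": p,
        "intensity": selection_intensity(p),
        "n_selected": k,
        "response_mean": float(per_draw.mean()),
        "response_sd": float(per_draw.std(ddof=1)) if len(per_draw) > 1 else 0.0,
        "selected": [ranking[i] for i in range(k)],
    }
    if trait_mean is not None and trait_mean != 0:
        out["response_pct_mean"] = 100.0 * out["response_mean"] * phenotypic_sd / abs(trait_mean)
    return out


@dataclass
class SelectionReport:
    """Responses per trait and selection proportion, plus selected animals."""

    table: pd.DataFrame
    selected: dict[float, list[str]]
    ranking: list[str]

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def __str__(self) -> str:
        lines = ["Response to selection (phenotypic-sd units):"]
        for _, r in self.table.iterrows():
            lines.append(
                f"  {r['trait']:>8s}  p={r['proportion']:.2f} (i={r['intensity']:.3f}): "
                f"{r['response_mean']:+.3f} +/- {r['response_sd']:.3f}"
            )
        return "\n".join(lines)


def selection_report(
    ebv_result: EbvResult,
    phenotypic_sd: dict[str, float],
    proportions: tuple[float, ...] = SELECTION_PROPORTIONS,
    ranking_traits: list[str] | None = None,
    trait_means: dict[str, float] | None = None,
) -> SelectionReport:
    """Rank on the aggregate EBV and tabulate responses for each proportion.

    Response traits are all traits with stored EBV draws (goal traits and,
    when present, correlated traits such as methane yield predicted from the
    same ranking).
    """
    ranking_traits = ranking_traits or list(ebv_result.ebv_mean.columns)
    ranking = aggregate_rank(ebv_result.ebv_mean[ranking_traits])
    rows = []
    selected: dict[float, list[str]] = {}
    for p in proportions:
        for trait, draws in ebv_result.ebv_draws.items():
            res = response_to_selection(
                draws,
                ranking,
                ebv_result.animal_ids,
                p,
                phenotypic_sd[trait],
                (trait_means or {}).get(trait),
            )
            selected[p] = res.pop("selected")
            res["trait"] = trait
            rows.append(res)
    table = pd.DataFrame(rows)[
        ["trait", "proportion", "intensity", "n_selected", "response_mean", "response_sd"]
        + (["response_pct_mean"] if trait_means else [])
    ]
    return SelectionReport(table=table, selected=selected, ranking=ranking)
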