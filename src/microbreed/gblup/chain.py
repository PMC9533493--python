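"""Chain storage and posterior summaries for the GBLUP Gibbs samplers."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class McmcConfig:
    """Gibbs-chain settings.

    The defaults are desk-scale (20,000 iterations, 4,000 burn-in, thin 4),
    which give 4,000 stored draws; `paper_scale()` returns the full-scale
    settings (1,000,000 / 200,000 / 100) used for the published estimates.
    """

    n_iter: int = 20_000
    burn_in: int = 4_000
    thin: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "McmcConfig":
        return cls(n_iter=1_000_000, burn_in=200_000, thin=100, seed=seed)


@dataclass
class PosteriorChain:
    """Thinned post-burn-in draws of model parameters.

    `params` holds one column per scalar parameter (fixed effects, genomic and
    residual (co)variance entries) plus the per-draw log-likelihood of the
    observed data. Breeding-value draws are stored only for requested traits
    (`ebv_draws`); running means/sds are kept for all.
    """

    trait_ids: list[str]
    animal_ids: list[str]
    params: pd.DataFrame
    ebv_mean: np.ndarray  # animals x traits
    ebv_sd: np.ndarray
    beta_mean: np.ndarray  # levels x traits
    ebv_draws: dict[str, np.ndarray] = field(default_factory=dict)
    variances_sampled: bool = True
    bound_hits: int = 0
    config: McmcConfig | None = None

    @property
    def n_draws(self) -> int:
        return len(self.params)

    def loglik_draws(self) -> np.ndarray:
        return self.params["loglik"].to_numpy()

    def sigma_g_draws(self, t1: str, t2: str | None = None) -> np.ndarray:
        t2 = t2 or t1
        col = _vc_name("sigma_g", self.trait_ids, t1, t2)
        if col not in self.params.columns:
            raise KeyError(f"no sampled genomic variance for ({t1}, {t2})")
        return self.params[col].to_numpy()

    def sigma_e_draws(self, t1: str, t2: str | None = None) -> np.ndarray:
        t2 = t2 or t1
        return self.params[_vc_name("sigma_e", self.trait_ids, t1, t2)].to_numpy()

    def write_tsv(self, path) -> None:
        self.params.to_csv(path, sep="\t", index=False)


def _vc_name(prefix: str, trait_ids: list[str], t1: str, t2: str) -> str:
    i, j = sorted((trait_ids.index(t1), trait_ids.index(t2)))
    return f"{prefix}[{trait_ids[i]},{trait_ids[j]}]"


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing `prob` of the sorted draws."""
    x = np.sort(np.asarray(draws, float))
    n = len(x)
    k = max(1, int(np.ceil(prob * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def p0_sign_probability(draws: np.ndarray) -> float:
    """Posterior probability of sharing the sign of the posterior mean."""
    x = np.asarray(draws, float)
    m = x.mean()
    if m >= 0:
        return float((x > 0).mean() + 0.5 * (x == 0).mean())
    return float((x < 0).mean() + 0.5 * (x == 0).mean())


def _spectral_var(x: np.ndarray, lag_fraction: float = 0.04) -> float:
    """Spectral density at zero via a Bartlett-windowed autocovariance sum."""
    n = len(x)
    x = x - x.mean()
    max_lag = max(1, int(np.floor(lag_fraction * n)))
    acov = np.array(
        [np.dot(x[: n - k], x[k:]) / n for k in range(max_lag + 1)]
    )
    w = 1.0 - np.arange(1, max_lag + 1) / (max_lag + 1)
    return float(acov[0] + 2.0 * np.sum(w * acov[1:]))


def geweke_z(draws: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence Z: first-10% vs last-50% window means.

    Window variances use the spectral density at zero (Bartlett window over
    4% of the segment length). Returns NaN for a constant chain.
    """
    x = np.asarray(draws, float)
    n = len(x)
    a = x[: max(2, int(first * n))]
    b = x[-max(2, int(last * n)):]
    va = _spectral_var(a)
    vb = _spectral_var(b)
    denom = va / len(a) + vb / len(b)
    if denom <= 0:
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(denom))


def mc_standard_error(draws: np.ndarray, n_batches: int = 20) -> float:
    """Monte-Carlo standard error of the mean by batch means."""
    x = np.asarray(draws, float)
    n = len(x)
    b = max(2, min(n_batches, n // 2))
    size = n // b
    means = x[: b * size].reshape(b, size).mean(axis=1)
    return float(np.sqrt(np.var(means, ddof=1) / b))


def summarize_draws(draws: np.ndarray, prob: float = 0.95) -> dict:
    """Posterior mean, sd, HPD, sign probability, Geweke Z and MC error."""
    x = np.asarray(draws, float)
    lo, hi = hpd_interval(x, prob)
    sd = float(x.std(ddof=1)) if len(x) > 1 else 0.0
    if sd == 0.0:
        warnings.warn("constant chain: Geweke Z undefined", stacklevel=2)
        gz = float("nan")
    else:
        gz = geweke_z(x)
    mcse = mc_standard_error(x)
    out = {
        "mean": float(x.mean()),
        "sd": sd,
        "hpd_low": lo,
        "hpd_high": hi,
        "p0": p0_sign_probability(x),
        "geweke_z": gz,
        "mcse": mcse,
        "mcse_flag": bool(sd > 0 and mcse * 10 > sd),
    }
    return out


def summarize(chain: PosteriorChain, prob: float = 0.95, min_draws: int = 50) -> pd.DataFrame:
    """Summary table (one row per scalar parameter) for a posterior chain."""
    if chain.n_draws < min_draws:
        raise ValueError(f"need at least {min_draws} stored draws")
    rows = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for col in chain.params.columns:
            rows[col] = summarize_draws(chain.params[col].to_numpy(), prob)
    return pd.DataFrame(rows).T
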