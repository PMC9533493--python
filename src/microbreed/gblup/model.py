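"""Bayesian GBLUP animal models fitted by Gibbs sampling.

The model for T traits on n animals is

    y_it = beta_{l(i),t} + g_it + e_it

with a single categorical fixed factor l(i) (diet x breed x experiment in the
motivating application), additive host-genomic values vec(g) ~ N(0, Sigma_g x G)
(Kronecker structure over a genomic relationship matrix G), and residual rows
e_i ~ N(0, Sigma_e) independent across animals. Priors are bounded flat for
all unknowns, so the variance-matrix full conditionals are inverse-Wishart
(scaled inverse chi-square for one trait) with df n - T - 1, rejected at the
bounds.

The breeding-value block is sampled after rotating by the eigenvectors of G,
which de-correlates animals and reduces the update to n independent TxT
Gaussian draws; a direct joint (MME) sampler is available for small problems
as a cross-check. Missing phenotypes are data-augmented from their Gaussian
conditionals each iteration, which is how traits recorded on no animal at all
(the prediction scenarios) are handled — their fixed effects are then pinned
at zero and their EBVs coincide with the BLUP solutions of the corresponding
mixed-model equations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import logsumexp
from scipy.stats import invwishart

from ..genomics import Grm
from .chain import McmcConfig, PosteriorChain, summarize

_LOG2PI = np.log(2.0 * np.pi)
_BOUND_FACTORS = (1e-8, 1e8)
_MAX_REJECT = 50


class GBLUP:
    """Gaussian animal model with a GRM-structured random genetic effect.

    Parameters
    ----------
    endog : DataFrame, animals x traits
        Phenotypes; NaN marks a missing record. A trait may be entirely
        missing only when variance components are fixed.
    grm : Grm or None
        Genomic relationship matrix (must be positive definite, i.e. ridged).
        ``None`` (or ``include_genomic=False``) drops the genetic effect.
    fixed_factor : sequence
        Categorical level per animal (single systematic effect).
    fixed_variance_components : (Sigma_g, Sigma_e), optional
        T x T arrays (scalars for one trait). When given, variance components
        are held fixed and not sampled.
    store_ebv_draws : list of trait names, optional
        Traits whose per-draw breeding values are kept in the chain (running
        mean/sd are always kept for every trait).
    """

    def __init__(
        self,
        endog: pd.DataFrame,
        grm: Grm | None,
        fixed_factor,
        include_genomic: bool = True,
        fixed_variance_components: tuple | None = None,
        store_ebv_draws: list[str] | None = None,
    ) -> None:
        self.endog = pd.DataFrame(endog).copy()
        self.trait_ids = [str(c) for c in self.endog.columns]
        self.animal_ids = [str(i) for i in self.endog.index]
        self.n = len(self.animal_ids)
        self.T = len(self.trait_ids)
        self.include_genomic = include_genomic and grm is not None
        self.grm = grm

        levels = pd.Categorical(np.asarray(fixed_factor))
        if len(levels) != self.n:
            raise ValueError("fixed_factor length must match the animal count")
        self.level_names = [str(c) for c in levels.categories]
        self.codes = np.asarray(levels.codes)
        self.L = len(self.level_names)

        self.Y = self.endog.to_numpy(float)
        self.obs = ~np.isnan(self.Y)
        n_obs = self.obs.sum(axis=0)
        self._free_traits = np.where(n_obs > 0)[0]
        self._pinned_traits = np.where(n_obs == 0)[0]

        if fixed_variance_components is not None:
            sg, se = fixed_variance_components
            self.sigma_g0 = np.atleast_2d(np.asarray(sg, float))
            self.sigma_e0 = np.atleast_2d(np.asarray(se, float))
            for m, name in ((self.sigma_g0, "Sigma_g"), (self.sigma_e0, "Sigma_e")):
                if m.shape != (self.T, self.T):
                    raise ValueError(f"{name} must be {self.T}x{self.T}")
                if np.any(np.linalg.eigvalsh(m) <= 0):
                    raise ValueError(f"{name} must be positive definite")
            self.sample_vc = False
        else:
            self.sigma_g0 = self.sigma_e0 = None
            self.sample_vc = True
            if np.any(n_obs < 2):
                raise ValueError(
                    "every trait needs >= 2 records unless variance components are fixed"
                )

        if self.include_genomic:
            if grm.n_animals != self.n or list(grm.animal_ids) != self.animal_ids:
                grm = grm.reorder(self.animal_ids)
                self.grm = grm
            lam, U = grm.eigendecompose()
            if lam.min() <= 0:
                raise ValueError(
                    "GRM is not positive definite; construct it with a ridge"
                )
            self._lam = lam
            self._U = U

        self.store_ebv_draws = list(store_ebv_draws or [])
        unknown = set(self.store_ebv_draws) - set(self.trait_ids)
        if unknown:
            raise KeyError(f"unknown traits in store_ebv_draws: {sorted(unknown)}")

        # unique missingness patterns, for augmentation and the likelihood
        self._patterns = []
        if self.obs.all():
            self._patterns.append((np.arange(self.n), np.arange(self.T), np.array([], int)))
        else:
            uniq, inv = np.unique(self.obs, axis=0, return_inverse=True)
            for k, row in enumerate(uniq):
                rows = np.where(inv == k)[0]
                self._patterns.append((rows, np.where(row)[0], np.where(~row)[0]))

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        traits: list[str],
        grm: Grm | None,
        fixed_factor: str,
        **kwargs,
    ) -> "GBLUP":
        """Build from a tidy table holding trait columns and the factor column."""
        return cls(data[traits], grm, data[fixed_factor], **kwargs)

    # -- sampling ---------------------------------------------------------
    def fit(
        self,
        config: McmcConfig | None = None,
        seed: int | None = None,
        g_sampler: str = "eig",
    ) -> "GBLUPResults":
        """Run the Gibbs sampler and return results with the stored chain.

        ``g_sampler`` is "eig" (eigendecomposition rotation, default) or
        "direct" (joint draw from the full mixed-model conditional; O(n^3 T^3),
        intended for small cross-check problems).
        """
        config = config or McmcConfig()
        if seed is not None:
            config = McmcConfig(config.n_iter, config.burn_in, config.thin, seed)
        rng = np.random.default_rng(config.seed)
        n, T, L = self.n, self.T, self.L

        obs_var = np.array(
            [
                np.nanvar(self.Y[:, t][self.obs[:, t]]) if self.obs[:, t].any() else 1.0
                for t in range(T)
            ]
        )
        obs_var = np.where(obs_var <= 0, 1.0, obs_var)
        lo_b = _BOUND_FACTORS[0] * obs_var
        hi_b = _BOUND_FACTORS[1] * obs_var

        # initial values
        beta = np.zeros((L, T))
        for t in self._free_traits:
            col = self.Y[:, t]
            for l in range(L):
                sel = (self.codes == l) & self.obs[:, t]
                beta[l, t] = col[sel].mean() if sel.any() else 0.0
        mu = beta[self.codes]
        Yaug = np.where(self.obs, self.Y, mu)
        g = np.zeros((n, T))
        if self.sample_vc:
            resid_var = np.maximum(np.var(Yaug - mu, axis=0), 1e-8)
            sigma_g = np.diag(resid_var / 2.0)
            sigma_e = np.diag(resid_var / 2.0)
        else:
            sigma_g = self.sigma_g0.copy()
            sigma_e = self.sigma_e0.copy()

        direct = g_sampler == "direct"
        if direct and self.include_genomic:
            Ginv = np.linalg.inv(self.grm.values)

        # fixed-VC precomputations for the genetic update
        fixed_g_cache = None
        if self.include_genomic and not self.sample_vc and not direct and T > 1:
            fixed_g_cache = self._g_update_matrices(sigma_g, sigma_e)

        n_cols = []
        for l in range(L):
            for t in range(T):
                n_cols.append(f"beta[{self.level_names[l]},{self.trait_ids[t]}]")
        tri = [(i, j) for i in range(T) for j in range(i, T)]
        if self.sample_vc:
            if self.include_genomic:
                n_cols += [
                    f"sigma_g[{self.trait_ids[i]},{self.trait_ids[j]}]" for i, j in tri
                ]
            n_cols += [
                f"sigma_e[{self.trait_ids[i]},{self.trait_ids[j]}]" for i, j in tri
            ]
        n_cols.append("loglik")
        store = np.empty((config.n_stored, len(n_cols)))
        ebv_draws = {t: np.empty((config.n_stored, n)) for t in self.store_ebv_draws}
        ebv_idx = {t: self.trait_ids.index(t) for t in self.store_ebv_draws}
        g_sum = np.zeros((n, T))
        g_sumsq = np.zeros((n, T))
        beta_sum = np.zeros((L, T))

        level_counts = np.bincount(self.codes, minlength=L).astype(float)
        if (level_counts == 0).any():
            raise ValueError("every fixed-factor level must contain an animal")
        df_vc = n - T - 1
        if self.sample_vc and df_vc <= T - 1:
            raise ValueError("too few animals to sample variance components")
        bound_hits = 0
        stored = 0

        for it in range(config.n_iter):
            # 1. augment missing phenotypes
            if self._pinned_traits.size or not self.obs.all():
                mu = beta[self.codes] + g
                for rows, O, M in self._patterns:
                    if M.size == 0:
                        continue
                    if O.size == 0:
                        cov = sigma_e
                        mean = np.zeros((len(rows), T))
                        Lc = np.linalg.cholesky(cov)
                        z = rng.standard_normal((len(rows), T))
                        Yaug[rows[:, None], M] = mu[rows][:, M] + (mean + z @ Lc.T)
                        continue
                    See = sigma_e[np.ix_(O, O)]
                    Smo = sigma_e[np.ix_(M, O)]
                    A = np.linalg.solve(See, Smo.T).T
                    cov = sigma_e[np.ix_(M, M)] - A @ Smo.T
                    cov = (cov + cov.T) / 2.0
                    Lc = np.linalg.cholesky(cov + 1e-12 * np.eye(len(M)))
                    r_o = self.Y[rows][:, O] - mu[rows][:, O]
                    z = rng.standard_normal((len(rows), len(M)))
                    r_m = r_o @ A.T + z @ Lc.T
                    Yaug[rows[:, None], M] = mu[rows][:, M] + r_m

            # 2. fixed effects (per level, traits jointly)
            resid = Yaug - g
            level_means = np.stack(
                [
                    np.bincount(self.codes, weights=resid[:, t], minlength=L)
                    for t in range(T)
                ],
                axis=1,
            ) / level_counts[:, None]
            beta = self._draw_beta(level_means, level_counts, sigma_e, rng)

            # 3. breeding values
            if self.include_genomic:
                R = Yaug - beta[self.codes]
                if direct:
                    g = self._draw_g_direct(R, sigma_g, sigma_e, Ginv, rng)
                else:
                    g = self._draw_g_eig(R, sigma_g, sigma_e, rng, fixed_g_cache)

            # 4./5. variance components
            if self.sample_vc:
                if self.include_genomic:
                    gs = self._U.T @ g
                    Sg = gs.T @ (gs / self._lam[:, None])
                    sigma_g, hits = _draw_cov(Sg, df_vc, lo_b, hi_b, sigma_g, rng)
                    bound_hits += hits
                E = Yaug - beta[self.codes] - g
                Se = E.T @ E
                sigma_e, hits = _draw_cov(Se, df_vc, lo_b, hi_b, sigma_e, rng)
                bound_hits += hits

            # 6./7. store
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                ll = self._loglik(beta, g, sigma_e)
                row = [beta[l, t] for l in range(L) for t in range(T)]
                if self.sample_vc:
                    if self.include_genomic:
                        row += [sigma_g[i, j] for i, j in tri]
                    row += [sigma_e[i, j] for i, j in tri]
                row.append(ll)
                store[stored] = row
                for t, col in ebv_draws.items():
                    col[stored] = g[:, ebv_idx[t]]
                g_sum += g
                g_sumsq += g * g
                beta_sum += beta
                stored += 1

        params = pd.DataFrame(store[:stored], columns=n_cols)
        m = stored
        ebv_mean = g_sum / m
        ebv_var = np.maximum(g_sumsq / m - ebv_mean**2, 0.0)
        ebv_sd = np.sqrt(ebv_var * m / max(m - 1, 1))
        chain = PosteriorChain(
            trait_ids=self.trait_ids,
            animal_ids=self.animal_ids,
            params=params,
            ebv_mean=ebv_mean,
            ebv_sd=ebv_sd,
            beta_mean=beta_sum / m,
            ebv_draws={t: v[:stored] for t, v in ebv_draws.items()},
            variances_sampled=self.sample_vc,
            bound_hits=bound_hits,
            config=config,
        )
        if bound_hits > 0.01 * config.n_iter:
            warnings.warn(
                f"variance draws hit the prior bounds {bound_hits} times; "
                "posterior may be pressed against the bounded flat prior",
                stacklevel=2,
            )
        return GBLUPResults(self, chain)

    # -- conditional draws -------------------------------------------------
    def _draw_beta(self, level_means, level_counts, sigma_e, rng) -> np.ndarray:
        L, T = self.L, self.T
        beta = np.zeros((L, T))
        free = self._free_traits
        pinned = self._pinned_traits
        if pinned.size == 0:
            Lc = np.linalg.cholesky(sigma_e)
            z = rng.standard_normal((L, T))
            return level_means + (z @ Lc.T) / np.sqrt(level_counts)[:, None]
        # condition the free-trait block on the pinned traits being 0
        Sff = sigma_e[np.ix_(free, free)]
        Sfp = sigma_e[np.ix_(free, pinned)]
        Spp = sigma_e[np.ix_(pinned, pinned)]
        A = np.linalg.solve(Spp, Sfp.T).T  # free x pinned
        cov = Sff - A @ Sfp.T
        cov = (cov + cov.T) / 2.0
        Lc = np.linalg.cholesky(cov + 1e-12 * np.eye(len(free)))
        cond_mean = level_means[:, free] + (0.0 - level_means[:, pinned]) @ A.T
        z = rng.standard_normal((L, len(free)))
        beta[:, free] = cond_mean + (z @ Lc.T) / np.sqrt(level_counts)[:, None]
        return beta

    def _g_update_matrices(self, sigma_g, sigma_e):
        """Per-animal posterior covariance/cholesky/mean-map for the rotated g."""
        se_inv = np.linalg.inv(sigma_e)
        sg_inv = np.linalg.inv(sigma_g)
        P = se_inv[None, :, :] + sg_inv[None, :, :] / self._lam[:, None, None]
        C = np.linalg.inv(P)
        Lc = np.linalg.cholesky((C + np.transpose(C, (0, 2, 1))) / 2.0)
        A = C @ se_inv  # (n, T, T): maps rotated residual to posterior mean
        return A, Lc

    def _draw_g_eig(self, R, sigma_g, sigma_e, rng, cache=None) -> np.ndarray:
        n, T = self.n, self.T
        Rs = self._U.T @ R
        if T == 1:
            se = sigma_e[0, 0]
            sg = sigma_g[0, 0]
            c = 1.0 / (1.0 / se + 1.0 / (self._lam * sg))
            mean = c * Rs[:, 0] / se
            gs = mean + np.sqrt(c) * rng.standard_normal(n)
            return (self._U @ gs)[:, None]
        A, Lc = cache if cache is not None else self._g_update_matrices(sigma_g, sigma_e)
        mean = np.einsum("nij,nj->ni", A, Rs)
        z = rng.standard_normal((n, T))
        gs = mean + np.einsum("nij,nj->ni", Lc, z)
        return self._U @ gs

    def _draw_g_direct(self, R, sigma_g, sigma_e, Ginv, rng) -> np.ndarray:
        """Joint draw of vec(g) (trait-major) from the full MME conditional."""
        n, T = self.n, self.T
        se_inv = np.linalg.inv(sigma_e)
        sg_inv = np.linalg.inv(sigma_g)
        P = np.kron(se_inv, np.eye(n)) + np.kron(sg_inv, Ginv)
        rhs = (R @ se_inv).T.reshape(-1)  # trait-major vec of Se^-1-weighted residuals
        Lp = np.linalg.cholesky(P)
        mean = linalg.cho_solve((Lp, True), rhs)
        z = rng.standard_normal(n * T)
        dev = linalg.solve_triangular(Lp, z, lower=True, trans="T")
        vecg = mean + dev
        return vecg.reshape(T, n).T

    # -- likelihood ---------------------------------------------------------
    def _loglik(self, beta, g, sigma_e) -> float:
        """Gaussian log-likelihood of the observed records given locations."""
        mu = beta[self.codes] + g
        ll = 0.0
        for rows, O, _ in self._patterns:
            if O.size == 0:
                continue
            r = self.Y[rows][:, O] - mu[rows][:, O]
            if O.size == 1:
                s = sigma_e[O[0], O[0]]
                ll += -0.5 * (
                    len(rows) * (_LOG2PI + np.log(s)) + (r[:, 0] ** 2).sum() / s
                )
                continue
            S = sigma_e[np.ix_(O, O)]
            Lc = np.linalg.cholesky(S)
            w = linalg.solve_triangular(Lc, r.T, lower=True)
            logdet = 2.0 * np.log(np.diag(Lc)).sum()
            ll += -0.5 * (len(rows) * (O.size * _LOG2PI + logdet) + (w**2).sum())
        return float(ll)


def _draw_cov(S, df, lo, hi, previous, rng):
    """Inverse-Wishart / scaled-inverse-chi-square draw with bound rejection."""
    T = S.shape[0]
    for attempt in range(_MAX_REJECT):
        if T == 1:
            draw = np.array([[S[0, 0] / rng.chisquare(df)]])
        else:
            draw = invwishart.rvs(df=df, scale=S, random_state=rng)
            draw = np.atleast_2d(draw)
        d = np.diag(draw)
        if np.all(d >= lo) and np.all(d <= hi):
            return draw, 0
    return previous, 1


class GBLUPResults:
    """Posterior chain plus derived quantities for a fitted GBLUP model."""

    def __init__(self, model: GBLUP, chain: PosteriorChain) -> None:
        self.model = model
        self.chain = chain

    # -- basic accessors ---------------------------------------------------
    @property
    def trait_ids(self) -> list[str]:
        return self.model.trait_ids

    @property
    def ebv(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.chain.ebv_mean, index=self.model.animal_ids, columns=self.trait_ids
        )

    @property
    def ebv_sd(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.chain.ebv_sd, index=self.model.animal_ids, columns=self.trait_ids
        )

    # -- genetic parameters --------------------------------------------------
    def heritability_draws(self, trait: str) -> np.ndarray:
        """Per-draw h2 = sigma2_g / (sigma2_g + sigma2_e) for one trait."""
        if not self.chain.variances_sampled:
            raise ValueError("variance components were fixed; no h2 draws")
        sg = self.chain.sigma_g_draws(trait)
        se = self.chain.sigma_e_draws(trait)
        return sg / (sg + se)

    def heritability(self, trait: str) -> float:
        return float(self.heritability_draws(trait).mean())

    def genomic_correlation_draws(self, t1: str, t2: str) -> np.ndarray:
        """Per-draw rg = cov_g(t1,t2) / sqrt(var_g(t1) var_g(t2))."""
        if not self.chain.variances_sampled:
            raise ValueError("variance components were fixed; no rg draws")
        if t1 == t2:
            raise ValueError("genomic correlation needs two distinct traits")
        c = self.chain.sigma_g_draws(t1, t2)
        v1 = self.chain.sigma_g_draws(t1)
        v2 = self.chain.sigma_g_draws(t2)
        return c / np.sqrt(v1 * v2)

    def genomic_correlation(self, t1: str, t2: str) -> float:
        return float(self.genomic_correlation_draws(t1, t2).mean())

    # -- model comparison -----------------------------------------------------
    def dic(self) -> float:
        """Deviance information criterion from the conditional deviance.

        D = -2 log p(y_obs | beta, g, Sigma_e); DIC = Dbar + pD with
        pD = Dbar - D(posterior means of the location parameters).
        """
        ll = self.chain.loglik_draws()
        dbar = float((-2.0 * ll).mean())
        g_hat = self.chain.ebv_mean
        sigma_e_hat = self._posterior_mean_sigma_e()
        dhat = -2.0 * self.model._loglik(self.chain.beta_mean, g_hat, sigma_e_hat)
        return dbar + (dbar - dhat)

    def _posterior_mean_sigma_e(self) -> np.ndarray:
        T = self.model.T
        if not self.chain.variances_sampled:
            return self.model.sigma_e0
        S = np.empty((T, T))
        for i in range(T):
            for j in range(i, T):
                v = self.chain.sigma_e_draws(self.trait_ids[i], self.trait_ids[j]).mean()
                S[i, j] = S[j, i] = v
        return S

    # -- reporting --------------------------------------------------------------
    def summary(self, prob: float = 0.95) -> pd.DataFrame:
        """Posterior mean/sd, HPD, sign probability, Geweke Z and MC error."""
        table = summarize(self.chain, prob=prob)
        extra = {}
        if self.chain.variances_sampled:
            for t in self.trait_ids:
                from .chain import summarize_draws

                extra[f"h2[{t}]"] = summarize_draws(self.heritability_draws(t), prob)
            for i, t1 in enumerate(self.trait_ids):
                for t2 in self.trait_ids[i + 1 :]:
                    extra[f"rg[{t1},{t2}]"] = summarize_draws(
                        self.genomic_correlation_draws(t1, t2), prob
                    )
        if extra:
            table = pd.concat([table, pd.DataFrame(extra).T])
        return table

    def plot_trace(self, param: str, ax=None):
        """Trace plot of one stored parameter column."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.chain.params[param].to_numpy(), lw=0.5)
        ax.set_xlabel("stored draw")
        ax.set_ylabel(param)
        return ax


def log_bayes_factor(
    full: GBLUPResults | PosteriorChain,
    reduced: GBLUPResults | PosteriorChain,
    estimator: str = "posterior-mean-likelihood",
) -> float:
    """Log Bayes factor of the full vs reduced model from likelihood draws.

    "posterior-mean-likelihood" takes the ratio of arithmetic means of the
    per-draw observed-data likelihoods (computed with log-sum-exp);
    "harmonic-mean" is the Newton-Raftery harmonic-mean estimator.
    """
    ll_f = full.chain.loglik_draws() if isinstance(full, GBLUPResults) else full.loglik_draws()
    ll_r = (
        reduced.chain.loglik_draws()
        if isinstance(reduced, GBLUPResults)
        else reduced.loglik_draws()
    )
    if estimator == "posterior-mean-likelihood":
        lf = logsumexp(ll_f) - np.log(len(ll_f))
        lr = logsumexp(ll_r) - np.log(len(ll_r))
    elif estimator == "harmonic-mean":
        lf = np.log(len(ll_f)) - logsumexp(-ll_f)
        lr = np.log(len(ll_r)) - logsumexp(-ll_r)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return float(lf - lr)


def bayes_factor(
    full, reduced, estimator: str = "posterior-mean-likelihood"
) -> float:
    """Bayes factor (full / reduced); clipped to avoid overflow at ~1e300."""
    return float(np.exp(min(log_bayes_factor(full, reduced, estimator), 690.0)))
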