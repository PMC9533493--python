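"""Screening for host-genomically influenced features and goal-trait links.

A feature belongs to the host-genomically influenced functional core (HGFC)
when the genomic model is decisively better than the model without genomic
effects: DIC at least 20 points lower AND a Bayes factor above an
FDR-controlled threshold. Genomic correlations with the goal traits are
declared significant when the posterior probability of sharing the sign of
the posterior mean (P0) is at least 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DIC_CUT = -20.0
BF_ALPHA = 1e-4
P0_CUT = 0.95


def wen_bf_threshold(
    bfs: np.ndarray, alpha: float = BF_ALPHA, pi0: float | None = None
) -> tuple[float, float]:
    """Bayes-factor rejection threshold controlling the Bayesian FDR.

    The null fraction pi0 is bounded from above using the sample mean of the
    observed Bayes factors (E[BF] = 1 under the null, so a large average
    caps the plausible null share at 1/mean(BF)); pass ``pi0=1`` for the
    fully conservative variant. The threshold is the smallest observed BF t
    such that the estimated FDR of the rejection set {BF >= t} — the average
    posterior null probability pi0 / (pi0 + (1 - pi0) BF_i) over rejections —
    is at most alpha. Returns (threshold, pi0); threshold is +inf when no
    rejection set satisfies the bound.
    """
    bfs = np.asarray(bfs, float)
    if bfs.size == 0:
        raise ValueError("empty Bayes-factor vector")
    if np.any(bfs <= 0):
        raise ValueError("Bayes factors must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if pi0 is None:
        pi0 = min(1.0, 1.0 / float(bfs.mean()))
    if pi0 >= 1.0:
        return float("inf"), 1.0
    order = np.argsort(bfs)[::-1]
    sorted_bf = bfs[order]
    post_null = pi0 / (pi0 + (1.0 - pi0) * sorted_bf)
    fdr = np.cumsum(post_null) / np.arange(1, len(bfs) + 1)
    ok = np.where(fdr <= alpha)[0]
    if ok.size == 0:
        return float("inf"), float(pi0)
    return float(sorted_bf[ok.max()]), float(pi0)


def classify_hgfc(
    dic_diff: float, bf: float, bf_threshold: float, dic_cut: float = DIC_CUT
) -> bool:
    """Joint rule: DIC_diff < cut (full minus reduced) AND BF >= threshold."""
    return bool(dic_diff < dic_cut) and bool(bf >= bf_threshold)


@dataclass
class ScreeningResult:
    """Per-feature screening statistics and flags.

    `table` columns: h2 mean/HPD, dic_diff, bf, hgfc flag, per-goal rg mean,
    HPD, P0 and significance flags, and the same-sign flag across goals.
    """

    table: pd.DataFrame
    bf_threshold: float
    pi0: float
    goals: list[str]

    @property
    def n_hgfc(self) -> int:
        return int(self.table["hgfc"].sum())

    def significant_features(self, goal: str | None = None) -> list[str]:
        t = self.table
        if goal is None:
            cols = [f"sig_{g}" for g in self.goals]
            mask = t[cols].any(axis=1)
        else:
            mask = t[f"sig_{goal}"]
        return list(t.index[mask])

    def same_sign_features(self) -> list[str]:
        """Features significant for >= 1 goal whose rg means share one sign."""
        t = self.table
        cols = [f"sig_{g}" for g in self.goals]
        mask = t[cols].any(axis=1) & t["same_sign"]
        return list(t.index[mask])

    def counts(self) -> dict:
        t = self.table
        out = {"n_features": len(t), "n_hgfc": self.n_hgfc}
        for g in self.goals:
            out[f"n_sig_{g}"] = int(t[f"sig_{g}"].sum())
        out["n_sig_any"] = len(self.significant_features())
        out["n_same_sign"] = len(self.same_sign_features())
        return out

    def write_csv(self, path) -> None:
        self.table.to_csv(path)


def screen_features(
    feature_stats: pd.DataFrame,
    goal_stats: dict[str, pd.DataFrame],
    alpha: float = BF_ALPHA,
    p0_cut: float = P0_CUT,
    dic_cut: float = DIC_CUT,
    pi0: float | None = None,
) -> ScreeningResult:
    """Assemble per-feature univariate and bivariate summaries into flags.

    Parameters
    ----------
    feature_stats : DataFrame indexed by feature
        Columns ``h2``, ``h2_low``, ``h2_high``, ``dic_diff``, ``bf``.
    goal_stats : mapping goal -> DataFrame indexed by feature
        Columns ``rg``, ``rg_low``, ``rg_high``, ``p0``.
    """
    goals = list(goal_stats)
    if not goals:
        raise ValueError("goal_stats must contain at least one goal trait")
    thr, pi0_hat = wen_bf_threshold(feature_stats["bf"].to_numpy(), alpha, pi0)
    table = feature_stats.copy()
    table["hgfc"] = [
        classify_hgfc(d, b, thr, dic_cut)
        for d, b in zip(table["dic_diff"], table["bf"])
    ]
    for g in goals:
        gs = goal_stats[g].reindex(table.index)
        table[f"rg_{g}"] = gs["rg"]
        table[f"rg_{g}_low"] = gs.get("rg_low")
        table[f"rg_{g}_high"] = gs.get("rg_high")
        table[f"p0_{g}"] = gs["p0"]
        table[f"sig_{g}"] = (gs["p0"] >= p0_cut).fillna(False).astype(bool)
    signs = np.stack([np.sign(table[f"rg_{g}"].to_numpy()) for g in goals], axis=1)
    table["same_sign"] = (signs == signs[:, [0]]).all(axis=1)
    return ScreeningResult(table=table, bf_threshold=thr, pi0=pi0_hat, goals=goals)


def screen_correlations(
    summaries: dict[str, dict[str, dict]], p0_cut: float = P0_CUT
) -> pd.DataFrame:
    """Flag significant genomic correlations from {feature: {goal: summary}}.

    Each summary needs keys ``mean`` and ``p0`` (as produced by
    `microbreed.gblup.summarize_draws`). Returns a per-feature table with
    significance flags per goal and the same-sign flag among features
    significant for at least one goal.
    """
    rows = {}
    goals: list[str] | None = None
    for feat, per_goal in summaries.items():
        if goals is None:
            goals = list(per_goal)
        missing = set(goals) - set(per_goal)
        if missing:
            raise ValueError(f"feature {feat} lacks goal summaries: {sorted(missing)}")
        row = {}
        for g in goals:
            row[f"rg_{g}"] = per_goal[g]["mean"]
            row[f"p0_{g}"] = per_goal[g]["p0"]
            row[f"sig_{g}"] = per_goal[g]["p0"] >= p0_cut
        rows[feat] = row
    df = pd.DataFrame(rows).T
    sig_cols = [f"sig_{g}" for g in goals]
    df["sig_any"] = df[sig_cols].any(axis=1)
    signs = np.stack([np.sign(df[f"rg_{g}"].to_numpy(float)) for g in goals], axis=1)
    df["same_sign"] = (signs == signs[:, [0]]).all(axis=1)
    return df
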