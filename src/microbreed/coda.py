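"""Compositional preprocessing of microbial-gene abundance tables.

Relative abundances live on the simplex, so standard covariance-based
statistics on the raw proportions produce spurious correlations. All
downstream genetic analyses therefore operate on log-ratio coordinates:
the additive log-ratio (alr) against a carefully chosen reference part, or
the centred log-ratio (clr) when no reference with good isometry exists.

Zeros must be replaced before any log-ratio transform. The replacement here
is Bayesian-multiplicative: each zero becomes the Dirichlet-posterior
expected proportion under a data-driven (geometric-mean) prior, and the
non-zero parts are rescaled multiplicatively so their ratios are untouched.

The alr reference is selected by a trade-off between (a) a high Procrustes
correlation of the alr geometry with the exact log-ratio geometry (so that
between-sample distances are nearly preserved) and (b) a low variance of the
reference's log abundance (so each alr feature is interpretable through its
numerator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CompositionTable",
    "LogRatioTable",
    "ReferenceReport",
    "FattyAcidTable",
    "filter_core",
    "replace_zeros_gbm",
    "alr_transform",
    "clr_transform",
    "procrustes_correlation",
    "select_alr_reference",
    "compute_fatty_acid_indices",
]

_CLOSE_TOL = 1e-8


class ZerosPresentError(ValueError):
    """Raised when a log-ratio transform meets zero proportions."""


@dataclass
class CompositionTable:
    """Samples x parts relative abundances closed to 1.

    Occupancy (fraction of samples where a part is > 0) and the mean relative
    abundance are computed on first construction, i.e. before any zero
    replacement: zeros are real absences for occupancy purposes.
    """

    sample_ids: list[str]
    part_ids: list[str]
    values: np.ndarray
    occupancy: np.ndarray = field(default=None)  # type: ignore[assignment]
    mean_ra: np.ndarray = field(default=None)  # type: ignore[assignment]
    row_totals: np.ndarray | None = None  # original counts per sample, if known

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.sample_ids),
            len(self.part_ids),
        ):
            raise ValueError("values must be samples x parts")
        if (self.values < 0).any():
            raise ValueError("relative abundances must be non-negative")
        totals = self.values.sum(axis=1)
        if (totals <= 0).any():
            raise ValueError("every sample must have positive total abundance")
        self.values = self.values / totals[:, None]
        if self.occupancy is None:
            self.occupancy = (self.values > 0).mean(axis=0)
        if self.mean_ra is None:
            self.mean_ra = self.values.mean(axis=0)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_parts(self) -> int:
        return len(self.part_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.part_ids)

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "CompositionTable":
        """Build from a samples x parts count table, keeping row depths."""
        vals = counts.to_numpy(float)
        return cls(
            list(counts.index.astype(str)),
            list(counts.columns.astype(str)),
            vals,
            row_totals=vals.sum(axis=1),
        )

    def write_tsv(self, path) -> None:
        # features x samples orientation, matching common KO-table exports
        self.to_frame().T.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "CompositionTable":
        df = pd.read_csv(path, sep="\t", index_col=0).T
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(float))


@dataclass
class LogRatioTable:
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    transform_kind: str  # "alr" or "clr"
    reference_id: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class ReferenceReport:
    """Per-candidate alr-reference diagnostics, ranked best first."""

    table: pd.DataFrame  # columns: procrustes_correlation, log_variance, cv, five-point summary
    best: str
    epsilon: float

    def to_frame(self) -> pd.DataFrame:
        return self.table


def filter_core(
    table: CompositionTable,
    min_occupancy: float = 0.70,
    min_mean_ra: float = 1e-5,
) -> tuple[CompositionTable, dict]:
    """Keep parts present in >= `min_occupancy` of samples with mean RA >= threshold.

    Both thresholds are inclusive. The retained table is re-closed; the report
    gives the retained count and cumulative relative abundance retained.
    """
    if not (0 <= min_occupancy <= 1 and 0 <= min_mean_ra <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    keep = (table.occupancy >= min_occupancy) & (table.mean_ra >= min_mean_ra)
    if not keep.any():
        raise ValueError("core filter removed every part")
    out = CompositionTable(
        list(table.sample_ids),
        [p for p, k in zip(table.part_ids, keep) if k],
        table.values[:, keep],
        occupancy=table.occupancy[keep],
        mean_ra=table.mean_ra[keep],
        row_totals=table.row_totals,
    )
    report = {
        "n_in": table.n_parts,
        "n_retained": int(keep.sum()),
        "cumulative_ra_retained": float(table.values[:, keep].sum(axis=1).mean()),
    }
    return out, report


def _gbm_prior(table: CompositionTable) -> tuple[np.ndarray, np.ndarray]:
    """Data-driven Dirichlet prior: expected proportions t and strengths s_i.

    t is the closed columnwise geometric mean of the positive observed
    proportions; the per-sample strength is 1/g(t) with g the geometric mean
    over parts, which reduces to the Bayes-Laplace strength D for a uniform t.
    """
    vals = table.values
    with np.errstate(divide="ignore"):
        logs = np.where(vals > 0, np.log(vals), np.nan)
    t = np.exp(np.nanmean(logs, axis=0))
    t = t / t.sum()
    s = 1.0 / np.exp(np.mean(np.log(t)))
    return t, np.full(table.n_samples, s)


def replace_zeros_gbm(
    table: CompositionTable, pseudo_total: float | np.ndarray | None = None
) -> CompositionTable:
    """Bayesian-multiplicative zero replacement (geometric-mean Dirichlet prior).

    A zero in sample i, part j becomes ``s_i * t_j / (n_i + s_i)`` where n_i
    is the sample's (pseudo-)count total; non-zero parts are rescaled by the
    remaining mass so their pairwise ratios are exactly preserved.
    """
    vals = table.values
    if (vals.sum(axis=1) <= 0).any():
        raise ValueError("a sample with all-zero abundance cannot be replaced")
    if not (vals == 0).any():
        return table
    if pseudo_total is None:
        if table.row_totals is not None:
            totals = np.asarray(table.row_totals, dtype=float)
        else:
            totals = np.full(table.n_samples, 10000.0)
    else:
        totals = np.broadcast_to(np.asarray(pseudo_total, dtype=float), (table.n_samples,)).copy()
    if (totals <= 0).any():
        raise ValueError("pseudo_total must be positive")

    t, s = _gbm_prior(table)
    zero = vals == 0
    repl = (s[:, None] * t[None, :]) / (totals[:, None] + s[:, None])
    zero_mass = np.where(zero, repl, 0.0).sum(axis=1)
    if (zero_mass >= 1).any():
        raise ValueError("replacement mass exceeds 1; increase pseudo_total")
    nonzero_sum = np.where(zero, 0.0, vals).sum(axis=1)
    scaled = vals * ((1.0 - zero_mass) / nonzero_sum)[:, None]
    out = np.where(zero, repl, scaled)
    return CompositionTable(
        list(table.sample_ids),
        list(table.part_ids),
        out,
        occupancy=table.occupancy,
        mean_ra=table.mean_ra,
        row_totals=table.row_totals,
    )


def _require_positive(table: CompositionTable) -> np.ndarray:
    if (table.values <= 0).any():
        raise ZerosPresentError(
            "zeros present; run replace_zeros_gbm before log-ratio transforms"
        )
    return table.values


def alr_transform(table: CompositionTable, reference_id: str) -> LogRatioTable:
    """Additive log-ratio: ln(x_j) - ln(x_ref), reference column dropped."""
    vals = _require_positive(table)
    if reference_id not in table.part_ids:
        raise KeyError(f"reference part {reference_id!r} not in table")
    ref_idx = table.part_ids.index(reference_id)
    logv = np.log(vals)
    out = logv - logv[:, [ref_idx]]
    keep = [j for j in range(table.n_parts) if j != ref_idx]
    return LogRatioTable(
        list(table.sample_ids),
        [table.part_ids[j] for j in keep],
        out[:, keep],
        "alr",
        reference_id,
    )


def clr_transform(table: CompositionTable) -> LogRatioTable:
    """Centred log-ratio: ln(x_j) minus the sample's mean log abundance."""
    vals = _require_positive(table)
    logv = np.log(vals)
    out = logv - logv.mean(axis=1, keepdims=True)
    return LogRatioTable(list(table.sample_ids), list(table.part_ids), out, "clr")


def procrustes_correlation(target: np.ndarray, test: np.ndarray) -> float:
    """Correlation between two sample configurations after Procrustes fitting.

    Both configurations are centred and scaled to unit Frobenius norm; the
    correlation is the sum of singular values of their cross-product, i.e.
    sqrt(1 - m12^2) for the symmetric Procrustes statistic m12^2. Invariant to
    translation, orthogonal rotation and positive scaling of either input.
    """
    a = np.asarray(target, float)
    b = np.asarray(test, float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] != b.shape[0]:
        raise ValueError("configurations must share the sample dimension")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 samples for a Procrustes fit")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("degenerate (constant) configuration")
    a /= na
    b /= nb
    sv = np.linalg.svd(a.T @ b, compute_uv=False)
    return float(min(1.0, sv.sum()))


def select_alr_reference(
    table: CompositionTable,
    candidates: list[str] | None = None,
    epsilon: float = 0.005,
) -> ReferenceReport:
    """Rank alr-reference candidates by Procrustes correlation / log-variance.

    The exact log-ratio geometry is taken as the clr coordinates (isometric
    to the full pairwise log-ratio geometry). Ranking is lexicographic with
    tolerance: among candidates within `epsilon` of the best Procrustes
    correlation, the one with the smallest log-abundance variance wins.
    """
    vals = _require_positive(table)
    if candidates is None:
        candidates = list(table.part_ids)
    if not candidates:
        raise ValueError("empty candidate set")
    logv = np.log(vals)
    clr_coords = logv - logv.mean(axis=1, keepdims=True)
    rows = []
    for cand in candidates:
        j = table.part_ids.index(cand)
        alr_coords = np.delete(logv - logv[:, [j]], j, axis=1)
        pc = procrustes_correlation(clr_coords, alr_coords)
        lv = float(np.var(logv[:, j], ddof=1))
        col = logv[:, j]
        mean = float(col.mean())
        cv = float(np.sqrt(lv) / abs(mean)) if mean != 0 else np.inf
        rows.append(
            {
                "part_id": cand,
                "procrustes_correlation": pc,
                "log_variance": lv,
                "cv": cv,
                "min": float(col.min()),
                "q1": float(np.quantile(col, 0.25)),
                "median": float(np.median(col)),
                "mean": mean,
                "q3": float(np.quantile(col, 0.75)),
                "max": float(col.max()),
            }
        )
    df = pd.DataFrame(rows).set_index("part_id")
    best_pc = df["procrustes_correlation"].max()
    near = df[df["procrustes_correlation"] >= best_pc - epsilon]
    best = near["log_variance"].idxmin()
    order = df.index.isin(near.index)
    df = df.iloc[np.lexsort((df["log_variance"].to_numpy(), ~order))]
    return ReferenceReport(table=df, best=str(best), epsilon=epsilon)


# ---------------------------------------------------------------------------
# Fatty-acid indices

N3_NUMERATOR = ["C18:3n-3", "C20:5n-3", "C22:5n-3", "C22:6n-3"]
CLA_NUMERATOR = ["cis-9 trans-11 C18:2", "trans-11 C18:1"]
INDEX_DENOMINATOR = ["C12:0", "C14:0", "C16:0"]


@dataclass
class FattyAcidTable:
    """Per-animal fatty-acid contents in g / 100 g meat."""

    table: pd.DataFrame  # index: animal ids; columns: fatty acids

    def __post_init__(self) -> None:
        required = N3_NUMERATOR + CLA_NUMERATOR + INDEX_DENOMINATOR
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"missing fatty-acid columns: {missing}")
        if (self.table[required] < 0).any().any():
            raise ValueError("fatty-acid contents must be non-negative")

    @property
    def animal_ids(self) -> list[str]:
        return list(self.table.index.astype(str))

    def write_csv(self, path) -> None:
        self.table.to_csv(path)

    @classmethod
    def read_csv(cls, path) -> "FattyAcidTable":
        return cls(pd.read_csv(path, index_col=0))


def compute_fatty_acid_indices(fa: FattyAcidTable) -> pd.DataFrame:
    """N3 and CLA health indices.

    N3  = ln((C18:3n-3 + C20:5n-3 + C22:5n-3 + C22:6n-3) / (C12:0 + C14:0 + C16:0))
    CLA = ln((cis-9,trans-11 C18:2 + trans-11 C18:1) / (C12:0 + C14:0 + C16:0))

    Animals with a non-positive numerator or denominator get NaN with a warning.
    """
    import warnings

    t = fa.table
    denom = t[INDEX_DENOMINATOR].sum(axis=1).to_numpy()
    n3_num = t[N3_NUMERATOR].sum(axis=1).to_numpy()
    cla_num = t[CLA_NUMERATOR].sum(axis=1).to_numpy()
    bad = (denom <= 0) | (n3_num <= 0) | (cla_num <= 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} animals have non-positive index terms; set to NaN",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        n3 = np.where(bad, np.nan, np.log(n3_num / denom))
        cla = np.where(bad, np.nan, np.log(cla_num / denom))
    return pd.DataFrame({"N3": n3, "CLA": cla}, index=t.index)
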