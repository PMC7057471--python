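"""Agreement and validity statistics with participant-clustered,
bias-corrected bootstrap confidence intervals.

Each claims-based index classifier is cross-tabulated against each clinical
standard over the analysis set.  From the 2x2 table with cells

====  ==================  ==================
cell  index classifier    standard
====  ==================  ==================
a     positive            positive
b     positive            negative
c     negative            positive
d     negative            negative
====  ==================  ==================

the module computes observed agreement ``(a+d)/n``, Cohen's kappa
``(p_o - p_e)/(1 - p_e)`` with chance agreement from the marginal products,
sensitivity ``a/(a+c)``, specificity ``d/(b+d)``, PPV ``a/(a+b)`` and NPV
``d/(c+d)``.  Because participants can contribute several events, confidence
intervals resample whole participants with replacement (cluster bootstrap)
and use the bias-corrected percentile method: the anchor percentiles are
shifted by ``z0``, the normal quantile of the fraction of replicates below
the point estimate (replicates tied with the point estimate count half).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "TwoByTwo",
    "AgreementResult",
    "prevalence",
    "cross_tabulate",
    "kappa",
    "validity_measures",
    "cluster_bootstrap_ci",
    "pair_agreement",
    "evaluate_pairs",
    "STATISTICS",
]

STATISTICS = ("observed_agreement", "kappa", "sensitivity", "specificity", "ppv", "npv")


@dataclass(frozen=True)
class TwoByTwo:
    """Cross-tabulation of an index classifier against a standard."""

    a: int  # index+, standard+
    b: int  # index+, standard-
    c: int  # index-, standard+
    d: int  # index-, standard-

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d], dtype=float)


def prevalence(flags: Sequence[bool]) -> float:
    """Fraction of positive flags."""
    arr = np.asarray(flags, dtype=bool)
    if arr.size == 0:
        raise ValueError("prevalence of an empty vector is undefined")
    return float(arr.mean())


def cross_tabulate(index: Sequence[bool], standard: Sequence[bool]) -> TwoByTwo:
    idx = np.asarray(index, dtype=bool)
    std = np.asarray(standard, dtype=bool)
    if idx.shape != std.shape:
        raise ValueError(f"length mismatch: index {idx.shape} vs standard {std.shape}")
    return TwoByTwo(
        a=int(np.sum(idx & std)),
        b=int(np.sum(idx & ~std)),
        c=int(np.sum(~idx & std)),
        d=int(np.sum(~idx & ~std)),
    )


def _stats_from_cells(a, b, c, d):
    """Vectorized statistics from (arrays of) 2x2 cells.

    Zero denominators yield NaN (statistic absent), never 0.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        po = np.where(n > 0, (a + d) / n, np.nan)
        pe = np.where(
            n > 0, ((a + b) * (a + c) + (c + d) * (b + d)) / np.where(n > 0, n * n, 1), np.nan
        )
        kap = np.where(pe < 1, (po - pe) / (1 - pe), np.nan)
        sens = np.where(a + c > 0, a / (a + c), np.nan)
        spec = np.where(b + d > 0, d / (b + d), np.nan)
        ppv = np.where(a + b > 0, a / (a + b), np.nan)
        npv = np.where(c + d > 0, d / (c + d), np.nan)
    return {
        "observed_agreement": po,
        "kappa": kap,
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
    }


def kappa(t: TwoByTwo) -> float:
    """Cohen's kappa for a 2x2 table (NaN when chance agreement is 1)."""
    return float(_stats_from_cells(t.a, t.b, t.c, t.d)["kappa"])


def validity_measures(t: TwoByTwo) -> dict[str, float]:
    """Point estimates of all six agreement/validity statistics."""
    return {name: float(v) for name, v in _stats_from_cells(t.a, t.b, t.c, t.d).items()}


@dataclass
class AgreementResult:
    """Point estimates with bootstrap confidence intervals for one pair."""

    index_name: str
    standard_name: str
    table: TwoByTwo
    estimates: dict[str, float]
    ci: dict[str, tuple[float, float]]
    B: int
    seed: int
    n_clusters: int
    n_degenerate: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _bc_interval(
    replicates: np.ndarray, point: float, alpha: float
) -> tuple[tuple[float, float], int, str | None]:
    """Bias-corrected percentile interval from bootstrap replicates.

    Returns ``((low, high), n_degenerate, warning)``.  Degenerate (NaN)
    replicates are dropped; ties with the point estimate count as half below
    when locating ``z0``.
    """
    valid = replicates[np.isfinite(replicates)]
    n_degen = replicates.size - valid.size
    if valid.size == 0 or not np.isfinite(point):
        return (np.nan, np.nan), n_degen, "all bootstrap replicates degenerate"
    frac = (np.sum(valid < point) + 0.5 * np.sum(valid == point)) / valid.size
    # guard the normal quantile against 0/1 fractions
    frac = min(max(frac, 1.0 / (valid.size + 1)), valid.size / (valid.size + 1.0))
    z0 = norm.ppf(frac)
    zcrit = norm.ppf(1 - alpha / 2)
    lo_p = norm.cdf(2 * z0 - zcrit)
    hi_p = norm.cdf(2 * z0 + zcrit)
    lo, hi = np.quantile(valid, [lo_p, hi_p])
    warning = None
    if not (lo <= point <= hi):
        warning = f"point estimate {point:.4f} outside BC interval [{lo:.4f}, {hi:.4f}]"
    return (float(lo), float(hi)), n_degen, warning


def _cluster_cells(index: np.ndarray, standard: np.ndarray, clusters: np.ndarray) -> np.ndarray:
    """Per-cluster contributions to the 2x2 cells, shape (m, 4)."""
    codes = (~index).astype(np.int64) * 2 + (~standard).astype(np.int64)  # 0=a,1=b,2=c,3=d
    # order-of-appearance factorization keeps the resampling protocol
    # identical between clustered and unclustered data with the same seed
    inv, uniques = pd.factorize(clusters)
    m = len(uniques)
    cells = np.zeros((m, 4), dtype=np.int64)
    np.add.at(cells, (inv, codes), 1)
    return cells


def cluster_bootstrap_ci(
    index: Sequence[bool],
    standard: Sequence[bool],
    clusters: Sequence,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    method: str = "bc",
) -> tuple[dict[str, tuple[float, float]], dict[str, int], list[str]]:
    """Clustered bootstrap CIs for all six statistics of one 2x2 pair.

    Whole clusters (participants with all their events) are resampled with
    replacement; ``method`` is ``"bc"`` (bias-corrected percentile, default)
    or ``"percentile"``.  Returns ``(ci, n_degenerate, warnings)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if method not in ("bc", "percentile"):
        raise ValueError(f"unknown bootstrap method {method!r}")
    idx = np.asarray(index, dtype=bool)
    std = np.asarray(standard, dtype=bool)
    clu = np.asarray(clusters)
    if not (idx.shape == std.shape == clu.shape):
        raise ValueError("index, standard and clusters must be aligned")

    cells = _cluster_cells(idx, std, clu)
    m = cells.shape[0]
    points = _stats_from_cells(*cross_tabulate(idx, std).as_array())

    rng = np.random.default_rng(seed)
    draw = rng.integers(0, m, size=(B, m))
    boot_cells = cells[draw].sum(axis=1)  # (B, 4)
    boot = _stats_from_cells(*(boot_cells[:, j] for j in range(4)))

    ci: dict[str, tuple[float, float]] = {}
    n_degen: dict[str, int] = {}
    warns: list[str] = []
    for name in STATISTICS:
        reps = boot[name]
        point = float(points[name])
        if method == "bc":
            interval, nd, warning = _bc_interval(reps, point, alpha)
        else:
            valid = reps[np.isfinite(reps)]
            nd = reps.size - valid.size
            if valid.size == 0:
                interval, warning = (np.nan, np.nan), "all bootstrap replicates degenerate"
            else:
                interval = tuple(np.quantile(valid, [alpha / 2, 1 - alpha / 2]))
                warning = None
        ci[name] = interval
        n_degen[name] = nd
        if warning:
            warns.append(f"{name}: {warning}")
    for w in warns:
        warnings.warn(w, stacklevel=2)
    return ci, n_degen, warns


def pair_agreement(
    df: pd.DataFrame,
    index_col: str,
    standard_col: str,
    cluster_col: str = "participant_id",
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    method: str = "bc",
) -> AgreementResult:
    """Full agreement analysis of one (index, standard) classifier pair."""
    table = cross_tabulate(df[index_col].to_numpy(), df[standard_col].to_numpy())
    estimates = validity_measures(table)
    ci, n_degen, warns = cluster_bootstrap_ci(
        df[index_col].to_numpy(),
        df[standard_col].to_numpy(),
        df[cluster_col].to_numpy(),
        B=B,
        seed=seed,
        alpha=alpha,
        method=method,
    )
    return AgreementResult(
        index_name=index_col,
        standard_name=standard_col,
        table=table,
        estimates=estimates,
        ci=ci,
        B=B,
        seed=seed,
        n_clusters=df[cluster_col].nunique(),
        n_degenerate=n_degen,
        warnings=warns,
    )


DEFAULT_PAIRS = tuple(
    (index, standard)
    for index in ("implicit_explicit", "cms")
    for standard in ("sofa_sepsis", "qsofa_sepsis", "ehr_sepsis")
)


def evaluate_pairs(
    analysis: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    method: str = "bc",
) -> pd.DataFrame:
    """Agreement table over all (claims index x clinical standard) pairs.

    One row per pair and statistic with point estimate and CI; per-pair
    bootstrap seeds are spawned deterministically from ``seed``.
    """
    child_seeds = np.random.SeedSequence(seed).generate_state(len(pairs)) % (2**31)
    rows = []
    for (index_col, standard_col), s in zip(pairs, child_seeds):
        res = pair_agreement(
            analysis, index_col, standard_col, B=B, seed=int(s), alpha=alpha, method=method
        )
        for stat in STATISTICS:
            lo, hi = res.ci[stat]
            rows.append(
                {
                    "index": index_col,
                    "standard": standard_col,
                    "statistic": stat,
                    "estimate": res.estimates[stat],
                    "ci_low": lo,
                    "ci_high": hi,
                    "a": res.table.a,
                    "b": res.table.b,
                    "c": res.table.c,
                    "d": res.table.d,
                    "n": res.table.n,
                    "B": B,
                    "seed": int(s),
                }
            )
    return pd.DataFrame(rows)


def spine_plot(table: TwoByTwo, index_name: str = "index", standard_name: str = "standard", ax=None):
    """Render a spine plot of a 2x2 table: rectangle areas are cell
    proportions, columns split by the standard classifier."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    n = table.n or 1
    w_pos = (table.a + table.c) / n  # standard-positive column width
    cols = [
        (0.0, w_pos, table.a / max(table.a + table.c, 1), "#9ecae1", "#3182bd"),
        (w_pos, 1 - w_pos, table.b / max(table.b + table.d, 1), "#fc9272", "#de2d26"),
    ]
    for x0, width, h_pos, color_pos, color_neg in cols:
        if width <= 0:
            continue
        ax.bar(x0, h_pos, width=width, align="edge", color=color_neg, edgecolor="k")
        ax.bar(x0, 1 - h_pos, bottom=h_pos, width=width, align="edge", color=color_pos, edgecolor="k")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel(f"{standard_name} (+ left, - right)")
    ax.set_ylabel(f"proportion {index_name}+")
    return ax
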