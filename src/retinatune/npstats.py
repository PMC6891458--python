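"""Nonparametric comparison protocol for stochastic optimiser results.

Omnibus Kruskal-Wallis and Friedman tests, pairwise Mann-Whitney U under the
normal approximation, and multiple-comparison adjustments: Bonferroni with a
configurable multiplier, classical Hochberg and Hommel step procedures, and
the step-up m/j (Benjamini-Hochberg-style) arithmetic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "HVTable",
    "StatReport",
    "kruskal_wallis",
    "friedman",
    "mann_whitney_u",
    "adjust_pvalues",
    "compare_algorithms",
    "ADJUST_METHODS",
]

ADJUST_METHODS = ("bonferroni", "hochberg", "hommel", "step_up_bh")


@dataclass(frozen=True)
class HVTable:
    """runs x algorithms matrix of hypervolume scores."""

    values: np.ndarray
    algorithms: tuple[str, ...]
    run_seeds: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D runs x algorithms matrix")
        if values.shape[1] != len(self.algorithms):
            raise ValueError("one column per algorithm required")
        if values.shape[0] < 2 or values.shape[1] < 2:
            raise ValueError("need at least 2 runs and 2 algorithms")
        if np.any(~np.isfinite(values)):
            raise ValueError("missing or non-finite entries are not allowed")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "algorithms", tuple(self.algorithms))


@dataclass
class StatReport:
    kruskal_h: float
    kruskal_p: float
    friedman_chi2: float
    friedman_p: float
    pairwise_p: dict[tuple[str, str], float]
    adjusted: dict[str, dict[tuple[str, str], float]]
    significant: dict[str, dict[tuple[str, str], bool]]
    alpha: float
    box_summary: dict[str, dict[str, float]] = field(default_factory=dict)


def _tie_term(pooled: np.ndarray) -> float:
    """sum(t^3 - t) over tie groups."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(np.float64) ** 3 - counts))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Rank-based omnibus test with tie correction; chi-square p, k-1 df.

    All values identical yields (0, 1) by convention.
    """
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need at least 2 nonempty groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for arr in arrays:
        r = ranks[start : start + arr.size]
        h += r.sum() ** 2 / arr.size
        start += arr.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    correction = 1.0 - _tie_term(pooled) / (n_total**3 - n_total)
    if correction <= 0:
        return 0.0, 1.0
    h /= correction
    p = float(sps.chi2.sf(h, len(groups) - 1))
    return float(h), p


def friedman(matrix: np.ndarray) -> tuple[float, float]:
    """Friedman rank test over a blocks x treatments matrix (ties averaged)."""
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a blocks x treatments matrix, both >= 2")
    n, k = m.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    mean_ranks = ranks.mean(axis=0)
    chi2 = 12.0 * n / (k * (k + 1)) * float(np.sum((mean_ranks - (k + 1) / 2.0) ** 2))
    p = float(sps.chi2.sf(chi2, k - 1))
    return chi2, p


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], continuity: bool = False
) -> tuple[float, float]:
    """U statistic (for x) and two-sided p via the normal approximation.

    The variance uses the tie-corrected form; the continuity correction is
    off by default.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be nonempty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_x = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    total = n + m
    tie = _tie_term(pooled)
    var = n * m / 12.0 * ((total + 1) - tie / (total * (total - 1)))
    if var <= 0:
        return u_x, 1.0
    diff = abs(u_x - n * m / 2.0)
    if continuity:
        diff = max(diff - 0.5, 0.0)
    z = diff / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(z))
    return u_x, min(p, 1.0)


def _adjust_bonferroni(p: np.ndarray, m: int) -> np.ndarray:
    return np.minimum(1.0, m * p)


def _adjust_hochberg(p: np.ndarray, m: int) -> np.ndarray:
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    k = p.size
    scaled = (m - np.arange(1, k + 1) + 1) * sorted_p
    # step-up: q(i) = min_{j >= i} scaled(j), capped
    q = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


def _adjust_hommel(p: np.ndarray) -> np.ndarray:
    """Hommel (1988) adjusted p-values (same arithmetic as R's p.adjust)."""
    n = p.size
    order = np.argsort(p, kind="stable")
    s = p[order]
    if n == 1:
        return p.copy()
    q = np.full(n, min(np.min(n * s / np.arange(1, n + 1)), 1.0))
    pa = q.copy()
    for mm in range(n - 1, 1, -1):
        i1 = np.arange(n - mm + 1)
        i2 = np.arange(n - mm + 1, n)
        q1 = np.min(mm * s[i2] / np.arange(2, mm + 1))
        q[i1] = np.minimum(mm * s[i1], q1)
        q[i2] = q[n - mm]
        pa = np.maximum(pa, q)
    pa = np.maximum(pa, s)
    out = np.empty_like(pa)
    out[order] = np.minimum(pa, 1.0)
    return out


def _adjust_step_up_bh(p: np.ndarray, m: int) -> np.ndarray:
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    k = p.size
    scaled = m / np.arange(1, k + 1) * sorted_p
    q = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


def adjust_pvalues(
    pvals: Sequence[float], method: str, m: int | None = None
) -> np.ndarray:
    """Multiple-comparison adjustment, output in input order.

    ``m`` is the multiplier (family size); it defaults to ``len(pvals)`` and
    may be larger to account for additional implicit comparisons.  The Hommel
    procedure is defined only for m equal to the list length.
    """
    p = np.asarray(pvals, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a nonempty 1-D sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("multiplier m must be at least len(pvals)")
    if method == "bonferroni":
        return _adjust_bonferroni(p, m)
    if method == "hochberg":
        return _adjust_hochberg(p, m)
    if method == "hommel":
        if m != p.size:
            raise ValueError("the Hommel procedure requires m == len(pvals)")
        return _adjust_hommel(p)
    if method == "step_up_bh":
        return _adjust_step_up_bh(p, m)
    raise ValueError(f"unknown method {method!r}; expected one of {ADJUST_METHODS}")


def compare_algorithms(
    table: HVTable,
    alpha: float = 0.05,
    adjust_methods: Mapping[str, int | None] | Sequence[str] = ADJUST_METHODS,
) -> StatReport:
    """Full protocol: omnibus tests, pairwise U tests, requested adjustments.

    ``adjust_methods`` may map method name -> multiplier (None = default).
    """
    if not isinstance(adjust_methods, Mapping):
        adjust_methods = {name: None for name in adjust_methods}

    columns = [table.values[:, j] for j in range(len(table.algorithms))]
    if all(np.ptp(col) == 0 for col in columns) and len({c[0] for c in columns}) == 1:
        kw_h, kw_p = 0.0, 1.0
        fr_chi2, fr_p = 0.0, 1.0
    else:
        kw_h, kw_p = kruskal_wallis(columns)
        fr_chi2, fr_p = friedman(table.values)

    pairs = list(itertools.combinations(range(len(table.algorithms)), 2))
    pair_labels = [(table.algorithms[i], table.algorithms[j]) for i, j in pairs]
    raw_p = [mann_whitney_u(columns[i], columns[j])[1] for i, j in pairs]
    pairwise = dict(zip(pair_labels, raw_p))

    adjusted: dict[str, dict[tuple[str, str], float]] = {}
    significant: dict[str, dict[tuple[str, str], bool]] = {}
    for method, mult in adjust_methods.items():
        adj = adjust_pvalues(raw_p, method, m=mult)
        adjusted[method] = dict(zip(pair_labels, adj.tolist()))
        significant[method] = {k: v < alpha for k, v in adjusted[method].items()}

    box = {}
    for name, col in zip(table.algorithms, columns):
        q1, med, q3 = np.percentile(col, [25, 50, 75])
        box[name] = {
            "min": float(col.min()),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "max": float(col.max()),
        }

    return StatReport(
        kruskal_h=kw_h,
        kruskal_p=kw_p,
        friedman_chi2=fr_chi2,
        friedman_p=fr_p,
        pairwise_p=pairwise,
        adjusted=adjusted,
        significant=significant,
        alpha=alpha,
        box_summary=box,
    )
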