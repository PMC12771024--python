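"""Between-session statistics for longitudinal imaging.

Distribution-valued metrics (per-segment diameter, length, tortuosity,
inter-vessel distance; per-plaque radius) are compared with a two-sided
Mann–Whitney U test after an advisory Shapiro–Wilk normality screen; scalar
totals (vessel volume, plaque volume) are summarized as percent change.
Significance stars follow the usual mapping *p<0.05, **p<0.01, ***p<0.001.

The U statistic is implemented from its definition (count of pairs where a
beats b, half-counting ties). For small tie-free samples the two-sided
p-value is computed by exact enumeration of all rank assignments; otherwise
a tie-corrected normal approximation with continuity correction is used.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger("threepmorph")


class DegenerateSampleError(ValueError):
    """Raised when a statistical operation receives a constant sample."""


def percent_change(v1: float, v2: float) -> float:
    """100 × (v2 − v1) / v1 — the session-2 vs. session-1 change in percent."""
    if v1 == 0:
        raise ValueError("percent change undefined for a zero session-1 value")
    return 100.0 * (v2 - v1) / v1


def normality_check(values) -> tuple[float, float]:
    """Advisory Shapiro–Wilk normality test: (statistic, p).

    Advisory because the downstream comparison is nonparametric regardless
    of the outcome; the result is logged, not used as a gate.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("normality check requires at least 3 values")
    if np.all(v == v[0]):
        raise DegenerateSampleError("normality undefined for a constant sample")
    stat, p = stats.shapiro(v)
    return float(stat), float(p)


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p: float
    method: str  # "exact" or "normal"


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U = Σ_ij [a_i > b_j] + ½·[a_i = b_j], via the rank-sum identity."""
    n = a.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n].sum()
    return float(r1 - n * (n + 1) / 2.0)


def mann_whitney_u(a, b, exact_max: int = 8) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test.

    Exact enumeration over all C(n+m, n) rank assignments when
    min(n, m) ≤ ``exact_max`` and the pooled sample is tie-free; otherwise
    the normal approximation with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = a.size, b.size
    if n == 0 or m == 0:
        raise ValueError("Mann–Whitney requires two non-empty samples")
    u = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < n + m

    enumerable = min(n, m) <= exact_max and math.comb(n + m, n) <= 200_000
    if enumerable and not has_ties:
        # enumerate U over every way to assign n of the n+m ranks to sample a
        total = n + m
        base = n * (n + 1) / 2.0
        center = n * m / 2.0
        dev = abs(u - center)
        hits = 0
        count = 0
        for subset in combinations(range(1, total + 1), n):
            u_s = sum(subset) - base
            count += 1
            if abs(u_s - center) >= dev - 1e-12:
                hits += 1
        return MannWhitneyResult(U=u, p=hits / count, method="exact")

    mu = n * m / 2.0
    tie_term = 0.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts[tie_counts > 1]
    if t.size:
        tie_term = float((t**3 - t).sum()) / ((n + m) * (n + m - 1))
    sigma2 = n * m / 12.0 * ((n + m + 1) - tie_term)
    if sigma2 <= 0:
        return MannWhitneyResult(U=u, p=1.0, method="normal")
    sigma = math.sqrt(sigma2)
    # continuity correction toward the mean
    z = (u - mu - 0.5 * np.sign(u - mu)) / sigma if u != mu else 0.0
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return MannWhitneyResult(U=u, p=float(p), method="normal")


def summarize(values) -> tuple[float, float]:
    """Sample mean and standard error of the mean (n−1 denominator SD)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("mean ± SEM requires at least 2 values")
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size))


def stars(p: float) -> str:
    """Significance stars: *p<0.05, **p<0.01, ***p<0.001, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional rigor; off by default)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    k = p.size
    for rank, idx in enumerate(order):
        running = max(running, (k - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


@dataclass
class SessionComparison:
    """One metric compared between two sessions.

    Distribution metrics carry the U test and per-session mean ± SEM;
    scalar totals carry the percent change only.
    """

    metric: str
    session1: np.ndarray | float
    session2: np.ndarray | float
    percent_change: float | None = None
    normality1: tuple[float, float] | None = None
    normality2: tuple[float, float] | None = None
    mw_u: float | None = None
    mw_p: float | None = None
    significance: str | None = None
    mean_sem1: tuple[float, float] | None = None
    mean_sem2: tuple[float, float] | None = None

    def to_record(self) -> dict:
        return {
            "metric": self.metric,
            "mw_u": self.mw_u,
            "mw_p": self.mw_p,
            "significance": self.significance,
            "percent_change": self.percent_change,
            "mean1": None if self.mean_sem1 is None else self.mean_sem1[0],
            "sem1": None if self.mean_sem1 is None else self.mean_sem1[1],
            "mean2": None if self.mean_sem2 is None else self.mean_sem2[0],
            "sem2": None if self.mean_sem2 is None else self.mean_sem2[1],
            "shapiro_p1": None if self.normality1 is None else self.normality1[1],
            "shapiro_p2": None if self.normality2 is None else self.normality2[1],
        }


def compare_sessions(
    metrics1: Mapping[str, Sequence[float] | float],
    metrics2: Mapping[str, Sequence[float] | float],
    holm: bool = False,
) -> list[SessionComparison]:
    """Compare every shared metric between two sessions.

    Array-valued entries are treated as distributions (unpaired two-sided
    Mann–Whitney U, advisory normality screen, mean ± SEM per session);
    scalar entries as totals (percent change). Metric sets must match.
    """
    if set(metrics1) != set(metrics2):
        raise ValueError(
            f"metric-name mismatch: {sorted(set(metrics1) ^ set(metrics2))}"
        )
    comparisons: list[SessionComparison] = []
    for name in sorted(metrics1):
        v1, v2 = metrics1[name], metrics2[name]
        if np.isscalar(v1) or isinstance(v1, float):
            comparisons.append(
                SessionComparison(
                    metric=name,
                    session1=float(v1),
                    session2=float(v2),
                    percent_change=percent_change(float(v1), float(v2)),
                )
            )
            continue
        a = np.asarray(v1, dtype=float)
        b = np.asarray(v2, dtype=float)
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        comp = SessionComparison(metric=name, session1=a, session2=b)
        for attr, sample in (("normality1", a), ("normality2", b)):
            try:
                setattr(comp, attr, normality_check(sample))
            except (ValueError, DegenerateSampleError):
                pass
        res = mann_whitney_u(a, b)
        comp.mw_u, comp.mw_p = res.U, res.p
        comp.significance = stars(res.p)
        if a.size >= 2:
            comp.mean_sem1 = summarize(a)
        if b.size >= 2:
            comp.mean_sem2 = summarize(b)
        comparisons.append(comp)
    if holm:
        tested = [c for c in comparisons if c.mw_p is not None]
        adj = holm_adjust([c.mw_p for c in tested])
        for c, p in zip(tested, adj):
            c.mw_p = p
            c.significance = stars(p)
    return comparisons
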