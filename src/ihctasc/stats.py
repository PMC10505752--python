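"""Group comparisons, correlations and categorical tests for reporting.

The reporting stage mirrors a conventional nonparametric IHC analysis:
Kruskal-Wallis omnibus tests with Dunn's post-hoc pairwise comparisons
(Bonferroni family correction by default), Pearson chi-squared for
categorical outcomes, and Spearman rank correlation.  Normality is
reported (Shapiro-Wilk) but never gates the nonparametric pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DomainError


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None = None
    notes: dict = field(default_factory=dict)


def dunn_posthoc(
    samples: Mapping[str, Sequence[float]],
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons after Kruskal-Wallis.

    For groups i, j the statistic is
    ``z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))``
    with mid-ranks over the pooled data and tie correction
    ``T = sum(t^3 - t) / (12 (N - 1))``.  Two-sided normal p-values are
    adjusted over the whole family of pairs.
    """
    names = list(samples)
    data = [np.asarray(samples[g], dtype=float) for g in names]
    pooled = np.concatenate(data)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    split = np.cumsum([d.size for d in data])[:-1]
    group_ranks = np.split(ranks, split)
    rbar = {g: r.mean() for g, r in zip(names, group_ranks)}
    sizes = {g: d.size for g, d in zip(names, data)}

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for a, b in combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (rbar[a] - rbar[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_unadjusted": min(p, 1.0)})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = multipletests(
            table["p_unadjusted"], method=adjust
        )[1]
    return table


def compare_groups(
    samples: Mapping[str, Sequence[float]],
    adjust: str = "bonferroni",
) -> ComparisonResult:
    """Kruskal-Wallis omnibus test plus Dunn's pairwise post-hoc."""
    if len(samples) < 2:
        raise DomainError("need at least two groups")
    for g, v in samples.items():
        if len(v) < 1:
            raise DomainError(f"group {g!r} is empty")
    arrays = [np.asarray(v, dtype=float) for v in samples.values()]
    if all((a == arrays[0][0]).all() for a in arrays):
        stat, p = 0.0, 1.0  # all observations identical; no evidence of effect
    else:
        stat, p = sps.kruskal(*arrays)
    return ComparisonResult(
        test="kruskal_wallis",
        groups=tuple(samples),
        statistic=float(stat),
        p_value=float(p),
        pairwise=dunn_posthoc(samples, adjust=adjust),
    )


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "spearman"
) -> tuple[float, float]:
    """Rank correlation (average mid-ranks for ties).

    Returns ``(rho, p_value)``; a constant input yields ``(nan, nan)``
    with a warning rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError("x and y must be paired vectors of equal length")
    if x.size < 3:
        raise DomainError("need at least 3 pairs")
    if method != "spearman":
        raise DomainError(f"unsupported correlation method {method!r}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        import warnings

        warnings.warn("constant input: correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def categorical_test(table: Sequence[Sequence[float]]) -> ComparisonResult:
    """Pearson chi-squared test on a contingency table (no continuity
    correction)."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise DomainError("contingency table must be 2D")
    if (arr < 0).any():
        raise DomainError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DomainError("zero-margin row or column")
    stat, p, dof, _ = sps.chi2_contingency(arr, correction=False)
    return ComparisonResult(
        test="chi_squared",
        groups=(),
        statistic=float(stat),
        p_value=float(p),
        notes={"dof": int(dof)},
    )


def normality_report(samples: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Shapiro-Wilk normality check per group, reported but not gating."""
    rows = []
    for g, v in samples.items():
        v = np.asarray(v, dtype=float)
        if v.size >= 3 and np.ptp(v) > 0:
            stat, p = sps.shapiro(v)
        else:
            stat, p = float("nan"), float("nan")
        rows.append({"group": g, "shapiro_w": stat, "p_value": p, "n": v.size})
    return pd.DataFrame(rows)
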