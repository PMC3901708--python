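"""Cross-signature and cross-platform comparison statistics.

Hypergeometric/Fisher overlap tests between gene or probe signatures,
exact 2x2 Fisher tests and two-sample t-tests for cohort characteristic
tables, and Pearson concordance of fold changes between platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GeneSet:
    """A labelled id set with an optional explicit universe."""

    label: str
    members: frozenset
    universe: frozenset | None = None

    def __post_init__(self):
        if self.universe is not None and not self.members <= self.universe:
            extra = sorted(self.members - self.universe)[:3]
            raise ValueError(f"{self.label}: members outside universe "
                             f"(e.g. {extra})")

    def __len__(self) -> int:
        return len(self.members)

    @classmethod
    def from_file(cls, label: str, path) -> "GeneSet":
        with open(path) as fh:
            members = frozenset(line.strip() for line in fh if line.strip())
        return cls(label=label, members=members)


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    n_overlap: int
    universe: int
    p: float            # upper-tail hypergeometric
    odds_ratio: float   # of the induced 2x2
    shared: tuple = field(default_factory=tuple)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N population, K successes,
    n draws), by exact tail sum."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def set_overlap_test(a: GeneSet, b: GeneSet,
                     universe_size: int | None = None) -> OverlapResult:
    """Enrichment of the overlap between two id sets.

    The p-value is the exact upper hypergeometric tail
    P[X >= |A intersect B|], identical to a one-sided Fisher exact test on
    the induced 2x2 table.  ``universe_size`` defaults to the explicit
    universe of either set.
    """
    if universe_size is None:
        for s in (a, b):
            if s.universe is not None:
                universe_size = len(s.universe)
                break
    if universe_size is None:
        raise ValueError("no universe size available")
    union = len(a.members | b.members)
    if universe_size < union:
        raise ValueError(f"universe {universe_size} smaller than union {union}")
    shared = a.members & b.members
    k = len(shared)
    p = hypergeom_upper_tail(k, universe_size, len(a), len(b))
    t11 = k
    t12 = len(a) - k
    t21 = len(b) - k
    t22 = universe_size - len(a) - len(b) + k
    if t12 * t21 == 0:
        odds = math.inf if t11 * t22 > 0 else np.nan
    else:
        odds = t11 * t22 / (t12 * t21)
    return OverlapResult(n_a=len(a), n_b=len(b), n_overlap=k,
                         universe=universe_size, p=p, odds_ratio=odds,
                         shared=tuple(sorted(shared)))


def fisher_2x2(table) -> dict:
    """Two-sided Fisher exact test on a 2x2 table of counts.

    Two-sided p sums all tables (at fixed margins) whose conditional
    probability is at most the observed one (with 1e-7 relative slack for
    ties).  A zero row or column margin is degenerate: p = 1, flagged.
    Odds ratio is ad/bc (inf for a zero in bc with nonzero ad).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    (a, b), (c, d) = t
    degenerate = (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any()
    if degenerate:
        return {"p": 1.0, "odds_ratio": np.nan, "degenerate": True}
    if b * c == 0:
        odds = math.inf if a * d > 0 else 0.0
    else:
        odds = a * d / (b * c)
    # enumerate tables with the observed margins
    row1 = a + b
    col1 = a + c
    n = t.sum()
    amin = max(0, col1 - (n - row1))
    amax = min(row1, col1)
    support = np.arange(amin, amax + 1)
    probs = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    p = float(probs[probs <= p_obs * (1 + 1e-7)].sum())
    return {"p": min(p, 1.0), "odds_ratio": float(odds), "degenerate": False}


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    variant: str
    boundary: bool = False


def two_sample_t(group1, group2, variant: str = "pooled") -> TTestResult:
    """Two-sample t-test from raw vectors or (mean, sd, n) summaries.

    ``variant``: 'pooled' (classical, df = n1+n2-2) or 'welch'
    (Satterthwaite df).  Each group is either an array of raw values or a
    (mean, sd, n) tuple; summary and raw inputs agree when the summaries
    are exact.
    """
    def _summ(g):
        if isinstance(g, tuple) and len(g) == 3:
            mean, sd, n = g
        else:
            arr = np.asarray(g, dtype=float)
            mean, sd, n = arr.mean(), arr.std(ddof=1), arr.size
        if n < 2:
            raise ValueError("need n >= 2 per group")
        if sd < 0:
            raise ValueError("sd must be >= 0")
        return float(mean), float(sd), int(n)

    m1, s1, n1 = _summ(group1)
    m2, s2, n2 = _summ(group2)
    diff = m1 - m2
    if s1 == 0 and s2 == 0:
        if diff == 0:
            return TTestResult(t=0.0, df=n1 + n2 - 2, p=1.0, variant=variant)
        return TTestResult(t=math.copysign(math.inf, diff), df=n1 + n2 - 2,
                           p=0.0, variant=variant, boundary=True)
    if variant == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / df
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    elif variant == "welch":
        se2_1, se2_2 = s1 ** 2 / n1, s2 ** 2 / n2
        se = math.sqrt(se2_1 + se2_2)
        df = (se2_1 + se2_2) ** 2 / (se2_1 ** 2 / (n1 - 1)
                                     + se2_2 ** 2 / (n2 - 1))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if se == 0:
        return TTestResult(t=0.0, df=df, p=1.0, variant=variant)
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=t, df=df, p=p, variant=variant)


def fold_change_concordance(fc_a: pd.Series, fc_b: pd.Series
                            ) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation of fold changes measured on two platforms over
    their shared regions.  Returns (r, two-sided p, scatter table)."""
    shared = fc_a.index.intersection(fc_b.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared regions; need >= 3")
    x = fc_a.loc[shared].astype(float)
    y = fc_b.loc[shared].astype(float)
    if x.nunique() < 2 or y.nunique() < 2:
        raise ValueError("constant fold-change vector; r undefined")
    r, p = stats.pearsonr(x, y)
    scatter = pd.DataFrame({"region": shared, "fc_a": x.to_numpy(),
                            "fc_b": y.to_numpy()})
    return float(r), float(p), scatter


def common_probe_overlap(calls_a, calls_b, universe_size: int
                         ) -> tuple[frozenset, OverlapResult]:
    """Shared differentially methylated probe/CpG ids between two call
    sets plus the enrichment of the overlap."""
    a = frozenset(calls_a)
    b = frozenset(calls_b)
    if not a or not b:
        raise ValueError("both call sets must be non-empty")
    result = set_overlap_test(GeneSet("A", a), GeneSet("B", b),
                              universe_size=universe_size)
    return frozenset(result.shared), result
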