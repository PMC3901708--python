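"""Two-level differential-methylation calling on promoter tiling arrays.

Probe level: an empirical-Bayes moderated t-statistic per probe.  The
per-probe residual variance s_g^2 (pooled across the two groups, d_g
degrees of freedom) is shrunk toward a prior s_0^2 with d_0 prior degrees
of freedom, estimated by moment matching on log s_g^2 under the scaled-F
sampling model:

    s_tilde^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t_tilde   = log2FC / (s_tilde * sqrt(1/n1 + 1/n2)),  df = d0 + d_g

Promoter level: each promoter's probe t-statistics are compared against all
other probes on the array with a Wilcoxon rank-sum test, one-sided in both
directions; the reported two-sided p is 2*min(p_pos, p_neg) capped at 1 and
the direction is the smaller side.  Promoter p-values are converted to q
(Benjamini-Hochberg).  A promoter is called differentially methylated when
its q <= 0.05 and it contains at least one probe with uncorrected probe
p <= 0.05 and |log2FC| >= 0.25 whose sign matches the promoter direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .genomics import ArrayDesign
from .preprocess import NormalizedRatios

logger = logging.getLogger(__name__)

DEFAULT_PROBE_P = 0.05
DEFAULT_MIN_LFC = 0.25
DEFAULT_MAX_Q = 0.05
EXACT_MAX_PROMOTER = 8
EXACT_MAX_TOTAL = 25


@dataclass(frozen=True)
class EBayesPrior:
    """Scaled-F prior on residual variances: d0 prior df (may be inf),
    s0_sq prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self):
        if not (self.d0 > 0):
            raise ValueError("d0 must be > 0 (use math.inf for no spread)")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be > 0")


def trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 50
                     ) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def fit_ebayes_prior(s2: np.ndarray, df) -> EBayesPrior:
    """Moment-match the scaled-F prior on the log scale.

    Uses the sampling identities for z = log(s_g^2) given a chi-square
    residual: E[z] = log(s0^2) + digamma(d_g/2) - log(d_g/2)
                      - digamma(d0/2) + log(d0/2)
    and Var[z] = trigamma(d_g/2) + trigamma(d0/2).  When the empirical
    variance of z does not exceed the sampling term, d0 = inf and s0^2 is
    the arithmetic mean of the s_g^2.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (df >= 1)
    if ok.sum() < 10:
        raise ValueError("need >= 10 positive variances with df >= 1")
    s2, df = s2[ok], df[ok]
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    emean = e.mean()
    evar = e.var(ddof=1)
    evar_prior = evar - special.polygamma(1, df / 2).mean()
    if evar_prior <= 0:
        return EBayesPrior(d0=math.inf, s0_sq=float(s2.mean()))
    d0 = 2.0 * trigamma_inverse(evar_prior)
    s0_sq = math.exp(emean + special.digamma(d0 / 2) - math.log(d0 / 2))
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


def probe_moderated_t(ratios: NormalizedRatios | pd.DataFrame,
                      groups: pd.Series,
                      prior: EBayesPrior | None = None) -> pd.DataFrame:
    """Per-probe moderated t comparing CPA vs NPA subjects.

    ``ratios``: subjects x probes merged log-ratio matrix. ``groups`` maps
    subject to CPA/NPA.  With ``prior=None`` the prior is fitted from the
    data; pass ``EBayesPrior(d0=..)`` to override (d0 -> 0 limit recovers
    the classical pooled two-sample t).

    Returns a DataFrame indexed by probe_id: log2fc, s2, df, s2_post, t, p.
    """
    values = ratios.values if isinstance(ratios, NormalizedRatios) else ratios
    groups = groups.loc[values.index]
    g1 = values.loc[groups == "CPA"]
    g2 = values.loc[groups == "NPA"]
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >= 2 subjects per group (got {n1} CPA, {n2} NPA)")

    bad = values.isna().any(axis=0)
    if bad.any():
        logger.warning("skipping %d probes with missing values", int(bad.sum()))
        g1, g2 = g1.loc[:, ~bad], g2.loc[:, ~bad]

    x1, x2 = g1.to_numpy(), g2.to_numpy()
    lfc = x1.mean(axis=0) - x2.mean(axis=0)
    v1 = x1.var(axis=0, ddof=1)
    v2 = x2.var(axis=0, ddof=1)
    dg = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / dg

    if prior is None:
        prior = fit_ebayes_prior(s2, dg)

    if prior.d0 == 0:
        s2_post = s2
        df_total = float(dg)
    elif math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = math.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + dg * s2) / (prior.d0 + dg)
        df_total = prior.d0 + dg

    scale = math.sqrt(1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / (np.sqrt(s2_post) * scale)
    t = np.where(np.isnan(t), 0.0, t)  # 0/0: no difference, no evidence
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    out = pd.DataFrame({
        "log2fc": lfc, "s2": s2, "df": float(dg),
        "s2_post": s2_post, "t": t, "p": p,
    }, index=g1.columns)
    out.index.name = "probe_id"
    out.attrs["prior_d0"] = prior.d0
    out.attrs["prior_s0_sq"] = prior.s0_sq
    return out


# --- promoter-level rank-sum ------------------------------------------------

def _exact_ranksum_tail(doubled_ranks: np.ndarray, k: int,
                        w2_obs: float) -> tuple[float, float]:
    """Exact one-sided tail probabilities of the rank-sum of a random
    size-k subset, by dynamic programming over doubled (integer) ranks.

    Returns (P[W >= w_obs], P[W <= w_obs]) where w2_obs is the doubled
    observed rank-sum.
    """
    ranks = np.rint(doubled_ranks).astype(np.int64)
    total = int(ranks.sum())
    # f[j, s] = number of size-j subsets with doubled rank-sum s
    f = np.zeros((k + 1, total + 1), dtype=float)
    f[0, 0] = 1.0
    for r in ranks:
        # 0/1 knapsack update, descending j so each rank is used once
        for j in range(k - 1, -1, -1):
            f[j + 1, r:] += f[j, :total + 1 - r]
    counts = f[k]
    n_total = counts.sum()
    w2 = int(round(w2_obs))
    p_ge = counts[w2:].sum() / n_total
    p_le = counts[:w2 + 1].sum() / n_total
    return float(p_ge), float(p_le)


def _normal_ranksum_tail(w: np.ndarray, k: np.ndarray, n: int,
                         tie_term: float) -> tuple[np.ndarray, np.ndarray]:
    """Normal approximation with tie and continuity correction for the
    rank-sum of a random size-k subset of n average ranks."""
    mean = k * (n + 1) / 2.0
    var = (k * (n - k) / 12.0) * ((n + 1) - tie_term / (n * (n - 1)))
    sd = np.sqrt(np.maximum(var, 1e-300))
    p_ge = stats.norm.sf((w - mean - 0.5) / sd)
    p_le = stats.norm.cdf((w - mean + 0.5) / sd)
    return p_ge, p_le


def promoter_ranksum(probe_stats: pd.DataFrame, design: ArrayDesign,
                     min_probes: int = 3) -> pd.DataFrame:
    """Rank-sum enrichment of each promoter's probe t-statistics against
    all other probes on the array.

    Promoters with fewer than ``min_probes`` scored probes are reported
    untested (p = NaN, excluded from FDR).  Exact tail enumeration is used
    when the promoter has <= 8 probes and the array <= 25 in total;
    otherwise the normal approximation with tie and continuity correction.

    Returns a DataFrame indexed by promoter_id with columns n_probes, W,
    p_pos, p_neg, p, direction, q, tested.
    """
    t = probe_stats["t"]
    n = len(t)
    ranks = pd.Series(stats.rankdata(t.to_numpy()), index=t.index)
    _, tie_counts = np.unique(t.to_numpy(), return_counts=True)
    tie_term = float((tie_counts ** 3 - tie_counts).sum())

    rows = []
    for prom, prow in design.promoters.iterrows():
        in_prom = [p for p in prow["probe_ids"] if p in ranks.index]
        k = len(in_prom)
        if k < min_probes or n - k < 1:
            rows.append({"promoter_id": prom, "n_probes": k, "W": np.nan,
                         "p_pos": np.nan, "p_neg": np.nan, "p": np.nan,
                         "direction": "", "tested": False,
                         "reason": f"{k} scored probes < {min_probes}"})
            continue
        w = float(ranks.loc[in_prom].sum())
        if k <= EXACT_MAX_PROMOTER and n <= EXACT_MAX_TOTAL:
            p_ge, p_le = _exact_ranksum_tail(2 * ranks.to_numpy(), k, 2 * w)
        else:
            p_ge_a, p_le_a = _normal_ranksum_tail(
                np.array([w]), np.array([k]), n, tie_term)
            p_ge, p_le = float(p_ge_a[0]), float(p_le_a[0])
        p_two = min(1.0, 2.0 * min(p_ge, p_le))
        direction = "hyper" if p_ge < p_le else "hypo"
        rows.append({"promoter_id": prom, "n_probes": k, "W": w,
                     "p_pos": p_ge, "p_neg": p_le, "p": p_two,
                     "direction": direction, "tested": True, "reason": ""})
    out = pd.DataFrame(rows).set_index("promoter_id")
    out["q"] = np.nan
    tested = out["tested"]
    out.loc[tested, "q"] = bh_fdr(out.loc[tested, "p"].to_numpy())
    return out


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} p_(j)*m/j."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(adj, 1.0)
    return q


def call_dmrs(probe_stats: pd.DataFrame, promoter_stats: pd.DataFrame,
              design: ArrayDesign,
              probe_p: float = DEFAULT_PROBE_P,
              min_lfc: float = DEFAULT_MIN_LFC,
              max_q: float = DEFAULT_MAX_Q,
              sign_consistency: bool = True
              ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the combined call rule.

    A promoter is called differentially methylated iff its rank-sum
    q <= ``max_q`` and at least one of its probes has uncorrected
    p <= ``probe_p`` and |log2FC| >= ``min_lfc`` (with the log2FC sign
    matching the promoter direction unless ``sign_consistency=False``).

    Returns (calls, direction_counts); calls has one row per called
    promoter with its qualifying probes.
    """
    rows = []
    counts = {"hyper": 0, "hypo": 0}
    for prom, prow in promoter_stats.iterrows():
        if not prow["tested"] or not (prow["q"] <= max_q):
            continue
        probe_ids = [p for p in design.promoters.at[prom, "probe_ids"]
                     if p in probe_stats.index]
        sub = probe_stats.loc[probe_ids]
        ok = (sub["p"] <= probe_p) & (sub["log2fc"].abs() >= min_lfc)
        if sign_consistency:
            want = 1.0 if prow["direction"] == "hyper" else -1.0
            ok &= np.sign(sub["log2fc"]) == want
        if not ok.any():
            continue
        qual = sub.loc[ok]
        counts[prow["direction"]] += 1
        rows.append({
            "promoter_id": prom,
            "gene_id": design.promoters.at[prom, "gene_id"],
            "chrom": design.promoters.at[prom, "chrom"],
            "window_start": design.promoters.at[prom, "window_start"],
            "window_end": design.promoters.at[prom, "window_end"],
            "direction": prow["direction"],
            "q": prow["q"],
            "p": prow["p"],
            "n_qualifying": int(ok.sum()),
            "qualifying_probes": ";".join(qual.index),
            "best_probe": qual["p"].idxmin(),
        })
    calls = pd.DataFrame(rows)
    if len(calls):
        calls = calls.set_index("promoter_id")
    return calls, counts


def representative_probes(calls: pd.DataFrame, probe_stats: pd.DataFrame,
                          ratios: NormalizedRatios | pd.DataFrame,
                          design: ArrayDesign) -> pd.DataFrame:
    """One probe per called gene for the heatmap: the probe with the most
    extreme t-statistic among the gene's called promoters; |t| ties break
    toward the smaller genomic start coordinate.

    Returns a genes x subjects matrix of normalized ratios.
    """
    if calls.empty:
        raise ValueError("no calls to select representative probes from")
    values = ratios.values if isinstance(ratios, NormalizedRatios) else ratios
    chosen = {}
    for prom, crow in calls.iterrows():
        gene = crow["gene_id"]
        for probe in design.promoters.at[prom, "probe_ids"]:
            if probe not in probe_stats.index:
                continue
            key = (abs(probe_stats.at[probe, "t"]),
                   -int(design.probes.at[probe, "start"]))
            if gene not in chosen or key > chosen[gene][0]:
                chosen[gene] = (key, probe)
    mat = pd.DataFrame({gene: values[probe]
                        for gene, (_, probe) in sorted(chosen.items())}).T
    mat.index.name = "gene_id"
    return mat


def ward_cluster(matrix: pd.DataFrame) -> dict[str, np.ndarray]:
    """Ward minimum-variance linkage with Pearson-correlation distance
    (d = 1 - r) for rows and columns of a heatmap matrix."""
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    def _link(X: pd.DataFrame, axis_name: str) -> np.ndarray:
        arr = X.to_numpy(dtype=float)
        if arr.shape[0] < 2:
            raise ValueError(f"need >= 2 {axis_name} to cluster")
        sd = arr.std(axis=1)
        if np.any(sd == 0):
            bad = list(X.index[sd == 0])
            raise ValueError(f"constant {axis_name} (Pearson undefined): {bad}")
        d = 1.0 - np.corrcoef(arr)
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2, 0.0, None)
        return linkage(squareform(d, checks=False), method="ward")

    return {"rows": _link(matrix, "rows"),
            "cols": _link(matrix.T, "columns")}
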