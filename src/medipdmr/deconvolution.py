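"""Grid-posterior deconvolution of absolute promoter methylation.

MeDIP enrichment is a relative signal: the log2(bound/input) ratio of a
probe grows with the methylation of the CpGs a pulled-down fragment can
carry.  This module inverts that link with a deliberately transparent
model: per promoter, probe ratios are

    r_j ~ Normal(a * m * w_j + b, sigma^2)

where m is the promoter methylation level in [0, 1], w_j is a CpG-coupling
weight (CpG count of the probe plus neighbours within the coupling
distance, normalized to the promoter maximum), and the gain a, offset b
and noise sigma are estimated globally.  The posterior over m on a uniform
grid gives a posterior mean and SD per promoter.  This is a sanity-check
estimator, not a full fragment-resolution deconvolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomics import ArrayDesign
from .simulate import coupled_cpg_weights

logger = logging.getLogger(__name__)


@dataclass
class DeconvolutionConfig:
    coupling_distance: int = 200      # bp reach of CpG coupling
    grid_resolution: float = 0.01     # methylation grid step on [0, 1]
    gain: float | None = None         # fix a instead of estimating
    offset: float | None = None       # fix b instead of estimating
    noise_sd: float | None = None     # fix sigma instead of estimating
    mean_methylation: float = 0.5     # assumed cohort mean, for gain identifiability
    min_sigma: float = 1e-3           # numerical floor for the noise SD

    def __post_init__(self):
        if self.coupling_distance <= 0:
            raise ValueError("coupling_distance must be > 0")
        if not 0 < self.grid_resolution <= 0.5:
            raise ValueError("grid_resolution must be in (0, 0.5]")

    @property
    def grid(self) -> np.ndarray:
        n = int(round(1.0 / self.grid_resolution))
        return np.linspace(0.0, 1.0, n + 1)


def estimate_gain_offset(r: pd.Series, w: pd.Series,
                         config: DeconvolutionConfig,
                         n_bins: int = 10) -> tuple[float, float, float]:
    """Global (a, b, sigma) from the array-wide relation of ratio to
    CpG-coupling weight.

    Probe ratios are binned by weight; a line through the bin means has
    slope a * mean_methylation and intercept b (the cohort-mean methylation
    is not identifiable from enrichment alone, so the configured
    ``mean_methylation`` converts slope to gain).  Sigma is the residual SD
    around the fitted line.
    """
    w_arr, r_arr = w.to_numpy(float), r.loc[w.index].to_numpy(float)
    edges = np.quantile(w_arr, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        raise ValueError("too few distinct coupling weights to bin")
    which = np.clip(np.searchsorted(edges, w_arr, side="right") - 1,
                    0, len(edges) - 2)
    wm = np.array([w_arr[which == i].mean() for i in range(len(edges) - 1)
                   if (which == i).any()])
    rm = np.array([r_arr[which == i].mean() for i in range(len(edges) - 1)
                   if (which == i).any()])
    slope, intercept = np.polyfit(wm, rm, 1)
    a = slope / config.mean_methylation
    b = float(intercept)
    resid = r_arr - (slope * w_arr + intercept)
    sigma = max(float(resid.std(ddof=2)), config.min_sigma)
    return float(a), b, sigma


def estimate_promoter_methylation(avg_ratios: pd.Series, design: ArrayDesign,
                                  config: DeconvolutionConfig | None = None
                                  ) -> pd.DataFrame:
    """Posterior mean/SD of methylation per promoter from cohort-averaged
    probe ratios.

    ``avg_ratios``: probe_id -> mean normalized log2 ratio across the
    cohort.  Promoters with no probe carrying a CpG within coupling reach
    are reported with m_hat = NaN and reason 'no CpG coverage'.
    """
    config = config or DeconvolutionConfig()
    w_all = coupled_cpg_weights(design, config.coupling_distance)
    # raw coupled counts decide informativeness (weight > 0 <=> count > 0)
    shared = avg_ratios.index.intersection(w_all.index)
    if shared.empty:
        raise ValueError("no probes shared between ratios and design")

    if config.gain is None or config.offset is None or config.noise_sd is None:
        a_est, b_est, s_est = estimate_gain_offset(
            avg_ratios.loc[shared], w_all.loc[shared], config)
    else:
        a_est = b_est = s_est = None
    a = config.gain if config.gain is not None else a_est
    b = config.offset if config.offset is not None else b_est
    sigma = max(config.noise_sd if config.noise_sd is not None else s_est,
                config.min_sigma)

    grid = config.grid
    rows = []
    for prom, prow in design.promoters.iterrows():
        probes = [p for p in prow["probe_ids"] if p in shared]
        w = w_all.loc[probes].to_numpy(float) if probes else np.empty(0)
        keep = w > 0
        if keep.sum() == 0:
            rows.append({"promoter_id": prom, "m_hat": np.nan,
                         "post_sd": np.nan, "n_informative": 0,
                         "reason": "no CpG coverage"})
            continue
        r = avg_ratios.loc[probes].to_numpy(float)[keep]
        wj = w[keep]
        pred = a * np.outer(grid, wj) + b          # (grid, probes)
        loglik = -0.5 * ((r[None, :] - pred) ** 2).sum(axis=1) / sigma ** 2
        loglik -= loglik.max()
        post = np.exp(loglik)
        post /= post.sum()
        m_hat = float((post * grid).sum())
        post_sd = float(np.sqrt((post * (grid - m_hat) ** 2).sum()))
        rows.append({"promoter_id": prom, "m_hat": m_hat,
                     "post_sd": post_sd, "n_informative": int(keep.sum()),
                     "reason": ""})
    out = pd.DataFrame(rows).set_index("promoter_id")
    out.attrs["gain"] = a
    out.attrs["offset"] = b
    out.attrs["sigma"] = sigma
    return out


def methylation_expression_association(estimates: pd.DataFrame,
                                       expression: pd.Series,
                                       design: ArrayDesign,
                                       n_bins: int = 20) -> dict:
    """Association between estimated promoter methylation and gene
    expression, the classic inverse-relationship sanity check.

    Genes are partitioned into ``n_bins`` expression-percentile bins
    (default twenty 5%-wide bins); per-bin methylation summaries plus a
    global Spearman correlation are returned.
    """
    gene_of = design.promoters["gene_id"]
    meth = estimates["m_hat"].dropna()
    gene_meth = meth.groupby(gene_of.loc[meth.index]).mean()
    shared = gene_meth.index.intersection(expression.index)
    if len(shared) < 100:
        raise ValueError(f"only {len(shared)} genes shared; need >= 100")
    x = expression.loc[shared].astype(float)
    y = gene_meth.loc[shared]
    if x.nunique() < 2:
        raise ValueError("expression is constant; correlation undefined")
    pct = x.rank(pct=True)
    bins = np.minimum((pct * n_bins).astype(int), n_bins - 1)
    summary = pd.DataFrame({
        "expression_bin": np.arange(n_bins),
        "n_genes": [int((bins == i).sum()) for i in range(n_bins)],
        "mean_m": [float(y[bins == i].mean()) if (bins == i).any() else np.nan
                   for i in range(n_bins)],
        "median_m": [float(y[bins == i].median()) if (bins == i).any() else np.nan
                     for i in range(n_bins)],
    })
    rho, p = stats.spearmanr(x, y)
    return {"n_genes": int(len(shared)), "spearman_rho": float(rho),
            "p": float(p), "bins": summary}
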