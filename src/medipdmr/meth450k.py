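"""Pooled bisulfite-array (450K-style) validation arm.

Works on a beta-value table measured on pooled genomic DNA (several
subjects per pool, a few pools per group).  Probes failing the detection
p-value threshold in any pool or carrying a SNP within 10 bp of the CpG
are excluded; group differences are tested per CpG with a Welch t-test on
M-values (logit2 of beta, clipped away from the bounds), corrected by
Benjamini-Hochberg FDR, and significant CpGs are mapped back to promoter
windows of the tiling-array design.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import bh_fdr
from .genomics import ArrayDesign

logger = logging.getLogger(__name__)

DETECTION_P_MAX = 0.001
SNP_MIN_DISTANCE = 10  # bp, inclusive exclusion boundary
BETA_CLIP = (0.01, 0.99)


def pools_of(pool_sheet: pd.DataFrame) -> dict[str, list[str]]:
    out = {}
    for grp in ("CPA", "NPA"):
        out[grp] = list(pool_sheet.loc[pool_sheet["group"] == grp, "pool_id"])
    return out


def filter_probes(beta: pd.DataFrame, manifest: pd.DataFrame,
                  detection_p_max: float = DETECTION_P_MAX,
                  snp_min_distance: float = SNP_MIN_DISTANCE
                  ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the detection-p and SNP-proximity probe filters.

    A CpG is dropped when its detection p exceeds ``detection_p_max`` in
    *any* pool (with only a handful of pools per group, one unreliable
    beta value leaves the test undefined), or when the manifest places a
    SNP at distance <= ``snp_min_distance`` from the CpG (missing SNP
    distance is treated as no nearby SNP).  Returns the filtered table and
    per-filter drop counts.
    """
    missing = beta.index.difference(manifest.index)
    if len(missing):
        raise ValueError(f"manifest does not cover {len(missing)} CpGs "
                         f"(e.g. {list(missing[:3])})")
    det_cols = [c for c in beta.columns if c.endswith("_detection_p")]
    fail_det = (beta[det_cols] > detection_p_max).any(axis=1)
    snp = manifest.loc[beta.index, "snp_distance"]
    fail_snp = snp.notna() & (snp <= snp_min_distance)
    keep = ~(fail_det | fail_snp)
    report = {
        "n_input": int(len(beta)),
        "dropped_detection": int(fail_det.sum()),
        "dropped_snp": int(fail_snp.sum()),
        "dropped_both": int((fail_det & fail_snp).sum()),
        "n_kept": int(keep.sum()),
    }
    logger.info("450K probe filters: %s", report)
    if report["n_kept"] == 0:
        raise ValueError("no CpGs survive the probe filters")
    return beta.loc[keep], report


def _welch(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray,
                                                  np.ndarray, np.ndarray]:
    """Vectorized Welch t over columns; returns (t, df, p, zero_var_flag)."""
    n1, n2 = x.shape[0], y.shape[0]
    m1, m2 = x.mean(axis=0), y.mean(axis=0)
    v1 = x.var(axis=0, ddof=1)
    v2 = y.var(axis=0, ddof=1)
    se2 = v1 / n1 + v2 / n2
    zero = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # degenerate zero-variance CpGs: equal means carry no evidence (p = 1),
    # different means are the noiseless limit (p = 0); both flagged
    diff_means = m1 != m2
    signed_inf = np.where(m1 >= m2, np.inf, -np.inf)
    t = np.where(zero, np.where(diff_means, signed_inf, 0.0), t)
    df = np.where(zero, n1 + n2 - 2.0, df)
    p = np.where(zero, np.where(diff_means, 0.0, 1.0), p)
    return t, df, p, zero


def pool_differential(beta: pd.DataFrame, pool_sheet: pd.DataFrame,
                      beta_clip: tuple[float, float] = BETA_CLIP,
                      fdr: float = 0.05) -> pd.DataFrame:
    """Per-CpG group comparison of pooled beta values.

    Delta-beta is the difference of raw group mean betas (CPA - NPA); the
    test is Welch's t on M-values M = log2(beta / (1 - beta)) with beta
    clipped to ``beta_clip`` before the transform (variance stabilization
    near the bounds).  q is Benjamini-Hochberg over all tested CpGs.
    """
    groups = pools_of(pool_sheet)
    for grp, pools in groups.items():
        if len(pools) < 2:
            raise ValueError(f"group {grp} has {len(pools)} pools; need >= 2")
    b_cpa = beta[[f"{p}_beta" for p in groups["CPA"]]].to_numpy(float)
    b_npa = beta[[f"{p}_beta" for p in groups["NPA"]]].to_numpy(float)
    delta = b_cpa.mean(axis=1) - b_npa.mean(axis=1)

    lo, hi = beta_clip
    m_cpa = np.log2(np.clip(b_cpa, lo, hi) / (1 - np.clip(b_cpa, lo, hi)))
    m_npa = np.log2(np.clip(b_npa, lo, hi) / (1 - np.clip(b_npa, lo, hi)))
    t, df, p, zero = _welch(m_cpa.T, m_npa.T)

    out = pd.DataFrame({
        "delta_beta": delta, "t": t, "df": df, "p": p,
        "zero_variance": zero,
    }, index=beta.index)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr
    return out


def map_cpgs_to_promoters(diff: pd.DataFrame, manifest: pd.DataFrame,
                          design: ArrayDesign) -> pd.DataFrame:
    """Promoter hit list: a promoter is a hit when at least one significant
    CpG lies inside its TSS-1000..TSS+200 window.

    Returns one row per hit promoter with the contributing CpGs and their
    delta-beta values.
    """
    sig = diff.loc[diff["significant"]]
    pos = manifest.loc[manifest.index.intersection(sig.index)]
    no_coord = pos["pos"].isna()
    if no_coord.any():
        logger.warning("%d significant CpGs without coordinates skipped",
                       int(no_coord.sum()))
        pos = pos.loc[~no_coord]
    rows = []
    prom = design.promoters
    for pid, prow in prom.iterrows():
        on_chrom = pos.loc[(pos["chrom"] == prow["chrom"])
                           & (pos["pos"] >= prow["window_start"])
                           & (pos["pos"] < prow["window_end"])]
        if len(on_chrom) == 0:
            continue
        db = sig.loc[on_chrom.index, "delta_beta"]
        rows.append({
            "promoter_id": pid,
            "gene_id": prow["gene_id"],
            "n_cpgs": int(len(on_chrom)),
            "cpg_ids": ";".join(on_chrom.index),
            "max_abs_delta_beta": float(db.abs().max()),
            "mean_delta_beta": float(db.mean()),
            "min_q": float(sig.loc[on_chrom.index, "q"].min()),
        })
    out = pd.DataFrame(rows)
    if len(out):
        out = out.set_index("promoter_id")
    return out
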