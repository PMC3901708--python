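"""Quality control and normalization of two-channel MeDIP intensities.

Raw scanner intensities (bound = immunoprecipitated channel, input = total
DNA channel) become per-sample log2(bound/input) ratios via:

1. per-channel background subtraction (a provided background column if
   present, otherwise the channel's 1st-percentile value);
2. an epsilon floor so no intensity is <= 0 before the log;
3. r = log2(bound / input) per probe per array;
4. quantile normalization of r across arrays (each array's order statistics
   replaced by the across-array mean order statistic; tied values receive
   the mean of their quantile values);
5. averaging of replicate arrays into one vector per subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .genomics import SampleSheet, intensity_arrays

logger = logging.getLogger(__name__)

EPSILON = 1.0  # intensity floor after background subtraction


@dataclass
class QCReport:
    """Per-array summary statistics and flags.

    ``table`` rows: array, median_m (median log-ratio), median_a (median
    log-intensity), ma_slope (slope of M on A), frac_negative,
    frac_saturated, replicate_corr (NaN when the subject has a single
    array), flagged, flag_reason.
    """

    table: pd.DataFrame
    m_threshold: float = 1.0
    corr_threshold: float = 0.8

    @property
    def flagged_arrays(self) -> list[str]:
        return list(self.table.loc[self.table["flagged"], "array"])


@dataclass
class NormalizedRatios:
    """samples x probes matrix of normalized log2(bound/input) plus
    provenance of the steps that produced it."""

    values: pd.DataFrame           # rows = arrays or subjects, cols = probes
    steps: tuple[str, ...]
    offset: float = EPSILON
    replicate_map: dict | None = None

    @property
    def probes(self) -> pd.Index:
        return self.values.columns


def _log_ratios(raw: pd.DataFrame, saturation: float = 2 ** 16
                ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Background-subtract, floor, and log both channels.

    Returns (M, A, qc_frame) where M rows are arrays, columns probes.
    """
    arrays = intensity_arrays(raw)
    if not arrays:
        raise ValueError("no arrays found in intensity table")
    m_rows, a_rows, qc = {}, {}, []
    for arr in arrays:
        out = {}
        for channel in ("bound", "input"):
            x = raw[f"{arr}_{channel}"].astype(float)
            bg_col = f"{arr}_{channel}_bg"
            if bg_col in raw.columns:
                bg = raw[bg_col].astype(float)
            else:
                bg = np.nanpercentile(x, 1.0)
            out[channel] = np.maximum(x - bg, EPSILON)
        bound, inp = out["bound"], out["input"]
        m = np.log2(bound / inp)
        a = 0.5 * np.log2(bound * inp)
        m_rows[arr] = m
        a_rows[arr] = a
        finite = np.isfinite(m) & np.isfinite(a)
        slope = (np.polyfit(a[finite], m[finite], 1)[0]
                 if finite.sum() > 2 and np.ptp(a[finite]) > 0 else np.nan)
        qc.append({
            "array": arr,
            "median_m": float(np.nanmedian(m)),
            "median_a": float(np.nanmedian(a)),
            "ma_slope": float(slope) if np.isfinite(slope) else np.nan,
            "frac_negative": float((raw[[f"{arr}_bound", f"{arr}_input"]]
                                    .to_numpy() < 0).mean()),
            "frac_saturated": float((raw[[f"{arr}_bound", f"{arr}_input"]]
                                     .to_numpy() >= saturation).mean()),
        })
    M = pd.DataFrame(m_rows, index=raw.index).T
    A = pd.DataFrame(a_rows, index=raw.index).T
    return M, A, pd.DataFrame(qc)


def qc_summary(raw: pd.DataFrame, samples: SampleSheet,
               m_threshold: float = 1.0, corr_threshold: float = 0.8
               ) -> QCReport:
    """Per-array QC: dye-bias (|median M|) and replicate agreement.

    Replicate correlation is the Pearson correlation of an array's log
    ratios with the mean of its subject's other replicate arrays; reported
    absent (NaN) for single-replicate subjects.
    """
    M, _, qc = _log_ratios(raw)
    corr = {}
    for subj, arrays in samples.arrays_of().items():
        for arr in arrays:
            others = [a for a in arrays if a != arr]
            if not others:
                corr[arr] = np.nan
                continue
            x = M.loc[arr]
            y = M.loc[others].mean(axis=0)
            corr[arr] = float(np.corrcoef(x, y)[0, 1])
    qc["replicate_corr"] = qc["array"].map(corr)
    reasons = []
    for row in qc.itertuples(index=False):
        r = []
        if abs(row.median_m) > m_threshold:
            r.append(f"|median M| {abs(row.median_m):.2f} > {m_threshold}")
        if np.isfinite(row.replicate_corr) and row.replicate_corr < corr_threshold:
            r.append(f"replicate corr {row.replicate_corr:.2f} < {corr_threshold}")
        reasons.append("; ".join(r))
    qc["flag_reason"] = reasons
    qc["flagged"] = qc["flag_reason"] != ""
    for row in qc[qc["flagged"]].itertuples(index=False):
        logger.warning("QC flag on array %s: %s", row.array, row.flag_reason)
    return QCReport(table=qc, m_threshold=m_threshold,
                    corr_threshold=corr_threshold)


def quantile_normalize(M: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize rows (arrays) of a matrix.

    Every array's sorted values are replaced by the across-array mean of
    order statistics; ranks are preserved and ties within an array receive
    the mean of the quantile values at the tied positions.
    """
    X = M.to_numpy(dtype=float)
    if np.any(np.ptp(X, axis=1) == 0):
        const = M.index[np.ptp(X, axis=1) == 0]
        raise ValueError(f"array(s) with all-constant ratios: {list(const)}")
    mean_quant = np.sort(X, axis=1).mean(axis=0)
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        order = np.argsort(X[i], kind="stable")
        assigned = np.empty(X.shape[1])
        assigned[order] = mean_quant
        # tie groups share the mean of their assigned quantile values
        _, inverse, counts = np.unique(X[i], return_inverse=True,
                                       return_counts=True)
        if np.any(counts > 1):
            sums = np.bincount(inverse, weights=assigned)
            assigned = (sums / counts)[inverse]
        out[i] = assigned
    return pd.DataFrame(out, index=M.index, columns=M.columns)


def normalize(raw: pd.DataFrame) -> NormalizedRatios:
    """Raw two-channel intensities -> quantile-normalized log2 ratios
    (one row per array; replicates not yet merged)."""
    M, _, _ = _log_ratios(raw)
    if M.isna().any().any():
        n_before = M.shape[1]
        M = M.dropna(axis=1)
        logger.warning("dropped %d probes with missing ratios",
                       n_before - M.shape[1])
    normed = quantile_normalize(M)
    return NormalizedRatios(values=normed,
                            steps=("background_subtract", "epsilon_floor",
                                   "log2_ratio", "quantile_normalize"))


def merge_replicates(ratios: NormalizedRatios, samples: SampleSheet,
                     exclude: set[str] | frozenset[str] = frozenset()
                     ) -> NormalizedRatios:
    """Average replicate arrays into one row per subject.

    ``exclude`` removes QC-failed arrays first; a subject left with zero
    usable arrays is an error.
    """
    rows = {}
    rep_map = {}
    for subj, arrays in samples.arrays_of().items():
        usable = [a for a in arrays if a not in exclude]
        if not usable:
            raise ValueError(f"subject {subj} has no usable arrays "
                             f"(all excluded: {arrays})")
        missing = [a for a in usable if a not in ratios.values.index]
        if missing:
            raise ValueError(f"subject {subj}: arrays {missing} absent "
                             "from normalized matrix")
        rows[subj] = ratios.values.loc[usable].mean(axis=0)
        rep_map[subj] = usable
    merged = pd.DataFrame(rows).T
    merged.index.name = "subject_id"
    return NormalizedRatios(values=merged,
                            steps=ratios.steps + ("replicate_mean",),
                            offset=ratios.offset, replicate_map=rep_map)
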