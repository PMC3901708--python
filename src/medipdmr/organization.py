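"""Genomic organization of methylation differences.

Two statistics describe how differentially methylated promoters sit in the
genome:

* **Normalized CpG density** per region — observed CpG dinucleotide density
  divided by the expected density (product of C and G mononucleotide
  densities), compared between hyper- and hypomethylated call sets.

* **Distance correlation curve** — the Pearson correlation of between-group
  methylation differences over probe pairs at increasing genomic
  separation, with bootstrap confidence intervals and a coordinate-
  permutation null band.  The decorrelation length is the largest distance
  out to which the bootstrap CI stays clear of the null band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genomics import count_cpg

logger = logging.getLogger(__name__)

DEFAULT_MAX_PAIRS = 200_000
MIN_PAIRS_PER_BIN = 30


def default_bins(max_distance: float = 4e6, n_log: int = 8) -> np.ndarray:
    """Bin edges: 0, 50 kb, then log-spaced up to ``max_distance``.

    Eight bins by default: wide enough that each per-bin correlation
    estimate rests on many effectively independent probe pairs, while
    still resolving the sub-100 kb and megabase regimes.
    """
    return np.concatenate([[0.0], np.geomspace(5e4, max_distance, n_log)])


# --- CpG density ------------------------------------------------------------

def region_counts_from_fasta(regions: pd.DataFrame, fasta_path) -> pd.DataFrame:
    """Add cpg/c/g/length columns to a region table (chrom, start, end)
    by counting in the genome sequence."""
    from pyfaidx import Fasta
    genome = Fasta(str(fasta_path), as_raw=True)
    out = regions.copy()
    counts = [count_cpg(str(genome[row.chrom][row.start:row.end]))
              for row in regions.itertuples(index=False)]
    out["cpg"] = [c[0] for c in counts]
    out["c"] = [c[1] for c in counts]
    out["g"] = [c[2] for c in counts]
    out["length"] = out["end"] - out["start"]
    return out


def normalized_cpg_density(regions: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Observed/expected CpG density per region plus a hyper-vs-hypo test.

    ``regions`` needs columns cpg, c, g, length and a ``group`` column with
    values in {hyper, hypo, background}.  The normalized density is

        rho = (cpg / (L - 1)) / ((c / L) * (g / L))

    Regions with no C or no G have undefined rho and are excluded (logged).
    Hyper vs hypo groups are compared with a two-sided Mann-Whitney U.
    """
    out = regions.copy()
    L = out["length"].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = ((out["cpg"] / (L - 1))
               / ((out["c"] / L) * (out["g"] / L)))
    rho = rho.where((out["c"] > 0) & (out["g"] > 0))
    n_undef = int(rho.isna().sum())
    if n_undef:
        logger.warning("%d regions with undefined CpG density excluded",
                       n_undef)
    out["rho"] = rho

    hyper = out.loc[(out["group"] == "hyper") & rho.notna(), "rho"]
    hypo = out.loc[(out["group"] == "hypo") & rho.notna(), "rho"]
    test = {"n_hyper": int(len(hyper)), "n_hypo": int(len(hypo)),
            "median_hyper": float(hyper.median()) if len(hyper) else np.nan,
            "median_hypo": float(hypo.median()) if len(hypo) else np.nan,
            "statistic": np.nan, "p": np.nan}
    if len(hyper) >= 1 and len(hypo) >= 1:
        u, p = stats.mannwhitneyu(hyper, hypo, alternative="two-sided")
        test["statistic"], test["p"] = float(u), float(p)
    return out, test


# --- distance correlation ---------------------------------------------------

@dataclass
class SpatialCorrCurve:
    """Per-distance-bin correlation of methylation differences.

    ``table`` columns: bin_lo, bin_hi, n_pairs, r, ci_lo, ci_hi (bootstrap
    2.5-97.5%), null_lo, null_hi (central 95% of coordinate-permutation r).
    """

    table: pd.DataFrame
    n_boot: int
    n_perm: int
    seed: int
    pair_cap: int = DEFAULT_MAX_PAIRS


def _sym_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r over the orientation-symmetrized pair set
    {(x_i, y_i)} U {(y_i, x_i)} via sufficient statistics."""
    n2 = 2.0 * x.size
    s = x.sum() + y.sum()
    ss = (x ** 2).sum() + (y ** 2).sum()
    sxy = 2.0 * (x * y).sum()
    var = ss - s * s / n2
    if var <= 0:
        return np.nan
    return float((sxy - s * s / n2) / var)


def _sym_r_from_stats(s, ss, sxy, n) -> np.ndarray:
    """Symmetrized r from pooled sufficient statistics (arrays ok)."""
    n2 = 2.0 * n
    var = ss - s * s / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        return (sxy - s * s / n2) / var


def _bootstrap_r(x: np.ndarray, y: np.ndarray, n_boot: int,
                 rng: np.random.Generator, chunk: int = 200) -> np.ndarray:
    """Bootstrap distribution of the symmetrized r over pair resamples.

    Each replicate only needs three per-pair sums, so the pair-level
    quantities are pre-combined and gathered once per replicate.
    """
    n = x.size
    u = x + y                # -> s
    v = x * x + y * y        # -> ss
    w = 2.0 * x * y          # -> sxy
    out = np.empty(n_boot)
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        out[done:done + b] = _sym_r_from_stats(
            u[idx].sum(axis=1), v[idx].sum(axis=1), w[idx].sum(axis=1), n)
        done += b
    return out


def _sample_bin_pairs(pos: np.ndarray, lo: float, hi: float, cap: int,
                      rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Indices (i, j), i < j, of same-chromosome pairs with separation in
    [lo, hi), uniformly subsampled to at most ``cap`` pairs.

    ``pos`` must be sorted ascending.
    """
    left = np.searchsorted(pos, pos + lo, side="left")
    right = np.searchsorted(pos, pos + hi, side="left")
    left = np.maximum(left, np.arange(pos.size) + 1)
    counts = np.maximum(right - left, 0)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, int), np.empty(0, int)
    cum = np.concatenate([[0], np.cumsum(counts)])
    if total <= cap:
        flat = np.arange(total)
    else:
        flat = rng.choice(total, size=cap, replace=False)
    i = np.searchsorted(cum, flat, side="right") - 1
    j = left[i] + (flat - cum[i])
    return i, j


def spatial_correlation_curve(delta: pd.Series, coords: pd.DataFrame,
                              bins: np.ndarray | None = None,
                              n_boot: int = 1000, n_perm: int = 500,
                              seed: int = 0,
                              pair_cap: int = DEFAULT_MAX_PAIRS
                              ) -> SpatialCorrCurve:
    """Distance-binned correlation of methylation differences.

    ``delta``: probe-level group mean differences (CPA - NPA), indexed by
    probe_id.  ``coords``: matching table with columns chrom, pos (probe
    center).  For each distance bin, same-chromosome probe pairs with
    separation inside the bin are collected (uniformly subsampled to
    ``pair_cap``); Pearson r is computed over the orientation-symmetrized
    pairs; a bootstrap over pairs gives the 95% CI and coordinate
    permutations within chromosome give the null band.  Bins with fewer
    than 30 pairs are reported with r absent.
    """
    if bins is None:
        bins = default_bins()
    bins = np.asarray(bins, dtype=float)
    if np.any(np.diff(bins) <= 0):
        raise ValueError("bin edges must be strictly ascending")
    d = delta.to_numpy(dtype=float)
    if np.ptp(d) == 0:
        raise ValueError("methylation differences are constant")
    coords = coords.loc[delta.index]
    rng = np.random.default_rng(seed)

    # per-chromosome sorted positions and values
    chrom_data = []
    for chrom, sub in coords.groupby("chrom", sort=True):
        order = np.argsort(sub["pos"].to_numpy(), kind="stable")
        pos = sub["pos"].to_numpy()[order].astype(float)
        vals = delta.loc[sub.index].to_numpy()[order]
        if len(pos) >= 2:
            chrom_data.append((chrom, pos, vals))

    # one matrix of permuted values per chromosome, reused across bins
    perm_mats = [np.stack([rng.permutation(v) for _ in range(n_perm)])
                 for _, _, v in chrom_data]

    rows = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        xs, ys = [], []
        pair_idx = []  # (chrom_index, i, j) for permutation reuse
        for ci, (_, pos, vals) in enumerate(chrom_data):
            i, j = _sample_bin_pairs(pos, lo, hi, pair_cap, rng)
            if i.size:
                xs.append(vals[i])
                ys.append(vals[j])
                pair_idx.append((ci, i, j))
        n_pairs = sum(x.size for x in xs)
        row = {"bin_lo": lo, "bin_hi": hi, "n_pairs": int(n_pairs),
               "r": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
               "null_lo": np.nan, "null_hi": np.nan}
        if n_pairs >= MIN_PAIRS_PER_BIN:
            x = np.concatenate(xs)
            y = np.concatenate(ys)
            row["r"] = _sym_r(x, y)
            boot = _bootstrap_r(x, y, n_boot, rng)
            boot = boot[np.isfinite(boot)]
            if boot.size:
                row["ci_lo"], row["ci_hi"] = np.percentile(boot, [2.5, 97.5])
            # pooled sufficient statistics over chromosomes per permutation
            s = np.zeros(n_perm)
            ss = np.zeros(n_perm)
            sxy = np.zeros(n_perm)
            for ci, i, j in pair_idx:
                px, py = perm_mats[ci][:, i], perm_mats[ci][:, j]
                s += px.sum(axis=1) + py.sum(axis=1)
                ss += (px ** 2).sum(axis=1) + (py ** 2).sum(axis=1)
                sxy += 2.0 * (px * py).sum(axis=1)
            null_r = _sym_r_from_stats(s, ss, sxy, n_pairs)
            null_r = null_r[np.isfinite(null_r)]
            if null_r.size:
                row["null_lo"], row["null_hi"] = np.percentile(
                    null_r, [2.5, 97.5])
        rows.append(row)
    return SpatialCorrCurve(table=pd.DataFrame(rows), n_boot=n_boot,
                            n_perm=n_perm, seed=seed, pair_cap=pair_cap)


def decorrelation_length(curve: SpatialCorrCurve) -> float:
    """Largest distance out to which methylation differences stay
    correlated above the permutation null.

    Returns the upper edge of the largest-distance bin such that every
    estimated bin at or below it has a bootstrap CI disjoint from the
    permutation null band; 0 when no bin qualifies.
    """
    t = curve.table
    est = t.dropna(subset=["r", "ci_lo", "ci_hi", "null_lo", "null_hi"])
    if len(est) < 3:
        raise ValueError("need >= 3 bins with estimates")
    length = 0.0
    for row in est.itertuples(index=False):
        disjoint = row.ci_lo > row.null_hi or row.ci_hi < row.null_lo
        if disjoint:
            length = row.bin_hi
        else:
            break
    return length
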