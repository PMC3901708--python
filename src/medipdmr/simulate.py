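"""Synthetic MeDIP cohorts with known ground truth.

Generates everything the pipeline consumes — a promoter tiling design with
realistic CpG-density structure, two-channel probe intensities for a
CPA-vs-NPA cohort, and pooled bisulfite-array beta tables — from a single
seeded configuration, so that every downstream stage can be tested against
a known truth without any external data.

The generative model, per promoter i, probe j, subject s, replicate rep:

    r[i,j,s] = a * m[i,s] * w[j] + b + subject_offset[s] + probe_offset[j]
    log2(bound/input)[j, array] = r + replicate_noise

where ``m[i,s]`` is subject methylation (baseline plus a group effect for
effect promoters plus biological noise), ``w[j]`` is a CpG-coupling weight
(CpG count of the probe and its neighbours within the antibody's effective
fragment reach, normalized to the promoter maximum), and the input channel
is log-normal per array.  Effect promoters are placed in megabase-scale
clusters, with direction hypomethylated-in-CPA at a configurable bias and
hypermethylated effects drawn preferentially from CpG-dense promoters —
the spatial and compositional structure the analysis is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genomics import ArrayDesign, SampleSheet

# distinct sub-streams per generator stage, all derived from config.seed
_STAGE_DESIGN = 11
_STAGE_TRUTH = 12
_STAGE_ARRAYS = 13
_STAGE_POOLS = 14
_STAGE_METH = 15

PROBES_PER_PROMOTER = 12
PROBE_SPACING = 100
PROBE_LENGTH = 60


@dataclass
class SimConfig:
    """Cohort and noise configuration; defaults mirror the study design
    (5 CPA vs 14 NPA women, two replicate arrays each, three pools per
    group) at desk scale (2,000 genes instead of the full 20,318)."""

    n_genes: int = 2000
    n_cpa: int = 5
    n_npa: int = 14
    replicates: int = 2
    effect_fraction: float = 0.02      # pi: fraction of promoters with an effect
    hypo_bias: float = 0.82            # P(effect is hypomethylated in CPA)
    delta: float = 0.3                 # effect size on the methylation scale
    gain: float = 2.0                  # a: log2-ratio units per methylation unit
    offset: float = -1.0               # b: log2-ratio at zero methylation
    coupling_distance: int = 200       # bp reach of CpG coupling
    cluster_scale: float = 1.5e6       # L: exponential clustering scale (bp)
    field_amplitude: float = 0.022     # saturation of the cluster-wide shift
    spacing_min: int = 30_000          # TSS-to-TSS spacing (uniform)
    spacing_max: int = 150_000
    noise_sd_replicate: float = 0.45   # log2-ratio noise per array
    noise_sd_probe: float = 0.15       # fixed probe affinity offsets
    noise_sd_subject: float = 0.10     # per-array global offset
    bio_sd: float = 0.01               # subject-level methylation noise
    input_sd: float = 0.5              # log2 spread of the input channel
    background_level: float = 50.0     # additive scanner background (intensity units)
    pools_per_group: int = 3
    cpgs_per_promoter: int = 2
    pool_beta_sd: float = 0.03
    detection_fail_frac: float = 0.02
    snp_proximal_frac: float = 0.05
    density_link: bool = True          # hyper effects prefer CpG-dense promoters
    seed: int = 0

    def __post_init__(self):
        for name in ("noise_sd_replicate", "noise_sd_probe",
                     "noise_sd_subject", "bio_sd", "input_sd", "pool_beta_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("effect_fraction", "hypo_bias"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


@dataclass
class TruthSet:
    """Simulator ground truth: one row per promoter.

    ``promoters`` columns: gene_id, tss, density_class (0/1/2), m0 (baseline
    methylation), effect (bool), direction ('hypo'/'hyper'/''), delta,
    cluster_id (-1 for non-effect), m_cpa, m_npa, win_cpg, win_c, win_g,
    win_len (window sequence composition).
    """

    promoters: pd.DataFrame
    config: SimConfig
    cluster_centers: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def effect_ids(self) -> pd.Index:
        return self.promoters.index[self.promoters["effect"]]

    def to_json(self, path) -> None:
        import json
        payload = {
            "config": asdict(self.config),
            "cluster_centers": self.cluster_centers.tolist(),
            "promoters": self.promoters.reset_index().to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        import json
        with open(path) as fh:
            payload = json.load(fh)
        prom = pd.DataFrame(payload["promoters"]).set_index("promoter_id")
        return cls(promoters=prom, config=SimConfig(**payload["config"]),
                   cluster_centers=np.asarray(payload["cluster_centers"]))


_GC_BY_CLASS = (0.40, 0.50, 0.60)   # window GC content per density class
_OE_BY_CLASS = (0.2, 0.5, 1.0)      # target CpG observed/expected ratio


def _window_sequences(n: int, length: int, classes: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """(n, length) array of nucleotide codes 0..3 = A,C,G,T with
    class-dependent GC content and CpG depletion.

    Vertebrate promoters range from CpG-depleted (observed/expected ~0.2)
    to island-like (~1.0); sequences are drawn iid at the class GC content
    (which alone gives obs/exp = 1) and CG dinucleotides are then knocked
    out (G -> A) with probability 1 - target, emulating methylation-driven
    CpG erosion.
    """
    seqs = np.empty((n, length), dtype=np.int8)
    for cls in range(3):
        rows = np.where(classes == cls)[0]
        if rows.size == 0:
            continue
        gc = _GC_BY_CLASS[cls]
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        block = rng.choice(4, size=(rows.size, length), p=p)
        deplete = 1.0 - _OE_BY_CLASS[cls]
        if deplete > 0:
            cg = (block[:, :-1] == 1) & (block[:, 1:] == 2)
            knock = cg & (rng.random(cg.shape) < deplete)
            gpos = np.zeros_like(block, dtype=bool)
            gpos[:, 1:] = knock
            block[gpos] = 0  # G -> A
        seqs[rows] = block
    return seqs


def _probe_counts(seqs: np.ndarray, offsets: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-probe CpG/C/G counts from window sequences.

    ``offsets``: probe start offsets within the window.  Returns arrays of
    shape (n_promoters, n_probes).
    """
    is_c = seqs == 1
    is_g = seqs == 2
    is_cg = is_c[:, :-1] & is_g[:, 1:]
    cpg = np.stack([is_cg[:, o:o + PROBE_LENGTH - 1].sum(axis=1)
                    for o in offsets], axis=1)
    cc = np.stack([is_c[:, o:o + PROBE_LENGTH].sum(axis=1)
                   for o in offsets], axis=1)
    gg = np.stack([is_g[:, o:o + PROBE_LENGTH].sum(axis=1)
                   for o in offsets], axis=1)
    return cpg, cc, gg


def simulate_truth(config: SimConfig) -> tuple[TruthSet, ArrayDesign]:
    """Lay out the array design and draw per-promoter ground truth.

    Deterministic given ``config.seed``.  Effect promoters are assigned by
    sampling cluster centers uniformly along the chromosome and accepting
    each promoter with probability proportional to the summed exponential
    kernel ``exp(-distance / cluster_scale)`` over centers, scaled so the
    expected effect count is ``effect_fraction * n_genes``.
    """
    import warnings

    n = config.n_genes
    rng_d = config.rng(_STAGE_DESIGN)
    rng_t = config.rng(_STAGE_TRUTH)

    spacing = rng_d.integers(config.spacing_min, config.spacing_max + 1, size=n)
    tss = 2000 + np.cumsum(spacing)
    classes = rng_d.integers(0, 3, size=n)

    wstart = tss - ArrayDesign.UPSTREAM
    wlen = ArrayDesign.UPSTREAM + ArrayDesign.DOWNSTREAM
    seqs = _window_sequences(n, wlen, classes, rng_d)
    offsets = np.arange(PROBES_PER_PROMOTER) * PROBE_SPACING
    cpg, cc, gg = _probe_counts(seqs, offsets)

    is_c = seqs == 1
    is_g = seqs == 2
    win_cpg = (is_c[:, :-1] & is_g[:, 1:]).sum(axis=1)
    win_c = is_c.sum(axis=1)
    win_g = is_g.sum(axis=1)

    prom_ids = [f"prom{i:05d}" for i in range(n)]
    gene_ids = [f"gene{i:05d}" for i in range(n)]
    probe_ids = np.array([[f"p{i:05d}_{j:02d}" for j in range(PROBES_PER_PROMOTER)]
                          for i in range(n)])

    probes = pd.DataFrame({
        "chrom": "chr1",
        "start": (wstart[:, None] + offsets[None, :]).ravel(),
        "end": (wstart[:, None] + offsets[None, :] + PROBE_LENGTH).ravel(),
        "promoter_ids": [(p,) for p in np.repeat(prom_ids, PROBES_PER_PROMOTER)],
        "cpg_count": pd.array(cpg.ravel(), dtype="Int64"),
        "c_count": pd.array(cc.ravel(), dtype="Int64"),
        "g_count": pd.array(gg.ravel(), dtype="Int64"),
    }, index=pd.Index(probe_ids.ravel(), name="probe_id"))

    promoters = pd.DataFrame({
        "gene_id": gene_ids,
        "chrom": "chr1",
        "tss": tss,
        "strand": "+",
        "window_start": wstart,
        "window_end": wstart + wlen,
        "probe_ids": [tuple(row) for row in probe_ids],
    }, index=pd.Index(prom_ids, name="promoter_id"))
    design = ArrayDesign(probes=probes, promoters=promoters)

    # --- effects -----------------------------------------------------------
    # Effect promoters sit in clusters; on top of the promoter-level binary
    # effects, each cluster carries a signed sub-threshold methylation field
    # decaying at scale L, producing the megabase-range correlation of
    # group differences without creating callable promoters by itself.
    target = config.effect_fraction * n
    if 0 < target < 1:
        warnings.warn("effect_fraction * n_genes < 1: near-null simulation")
    effect = np.zeros(n, dtype=bool)
    centers = np.empty(0)
    fieldv = np.zeros(n)
    direction = np.array([""] * n, dtype=object)
    cluster_id = np.full(n, -1)
    if target > 0:
        # centers tiled at ~L spacing: the signed, saturated field then
        # fluctuates genome-wide with sign changes on the ~L scale
        span = float(tss[-1] - tss[0])
        n_clusters = max(1, int(round(span / config.cluster_scale)))
        centers = rng_t.uniform(tss[0], tss[-1], size=n_clusters)
        kernel = np.exp(-np.abs(tss[:, None] - centers[None, :])
                        / config.cluster_scale)
        weight = kernel.sum(axis=1)
        # field signs are symmetric: the direction bias is carried by the
        # callable promoter-level effects, while the field models local
        # co-fluctuation of group differences (a biased field would mostly
        # add a constant offset that pair correlations ignore)
        signs = np.where(rng_t.random(n_clusters) < 0.5, -1.0, 1.0)
        # sharp tanh saturation: the field sits near +-amplitude almost
        # everywhere, maximizing the distance correlation attainable at a
        # given per-promoter shift (overlapping clusters cannot stack into
        # callable promoters)
        fieldv = config.field_amplitude * np.tanh(6.0 * (kernel @ signs))

        # promoter-level effects: counts from the configured fraction and
        # direction bias; placement follows the cluster kernel, and the
        # density link draws hyper effects from CpG-rich promoters and
        # hypo effects from CpG-poor ones
        n_eff = min(n, rng_t.binomial(n, config.effect_fraction))
        n_hyper = rng_t.binomial(n_eff, 1.0 - config.hypo_bias)
        if config.density_link:
            pref_hyper = weight * np.exp(2.0 * classes)
            pref_hypo = weight * np.exp(-1.0 * classes)
        else:
            pref_hyper = pref_hypo = weight.astype(float)
        hyper_idx = rng_t.choice(n, size=n_hyper, replace=False,
                                 p=pref_hyper / pref_hyper.sum())
        p_hypo = pref_hypo.copy()
        p_hypo[hyper_idx] = 0.0
        hypo_idx = rng_t.choice(n, size=n_eff - n_hyper, replace=False,
                                p=p_hypo / p_hypo.sum())
        effect[hyper_idx] = True
        effect[hypo_idx] = True
        direction[hyper_idx] = "hyper"
        direction[hypo_idx] = "hypo"
        eff_idx = np.where(effect)[0]
        cluster_id[eff_idx] = np.argmin(
            np.abs(tss[eff_idx, None] - centers[None, :]), axis=1)

    m0 = rng_t.uniform(0.25, 0.75, size=n)
    delta = np.where(effect, config.delta, 0.0)
    shift = np.where(direction == "hypo", -delta,
                     np.where(direction == "hyper", delta, 0.0))
    m_cpa = np.clip(m0 + shift + fieldv, 0.0, 1.0)
    m_npa = m0.copy()

    truth_table = pd.DataFrame({
        "gene_id": gene_ids, "tss": tss, "density_class": classes,
        "m0": m0, "effect": effect, "direction": direction, "delta": delta,
        "field": fieldv, "cluster_id": cluster_id,
        "m_cpa": m_cpa, "m_npa": m_npa,
        "win_cpg": win_cpg, "win_c": win_c, "win_g": win_g, "win_len": wlen,
    }, index=pd.Index(prom_ids, name="promoter_id"))

    return TruthSet(promoters=truth_table, config=config,
                    cluster_centers=centers), design


def coupled_cpg_weights(design: ArrayDesign, coupling_distance: int = 200
                        ) -> pd.Series:
    """CpG-coupling weight per probe: CpG count summed over probes of the
    same promoter whose centers lie within ``coupling_distance``, normalized
    to the promoter maximum (floored at 1).  Models the antibody pulling
    down whole fragments rather than the probe window alone."""
    counts = design.probes["cpg_count"].astype(float)
    if counts.isna().any():
        raise ValueError("design lacks CpG counts; attach a genome first")
    centers = (design.probes["start"] + design.probes["end"]).to_numpy() / 2
    pos = {pid: i for i, pid in enumerate(design.probes.index)}
    cvals = counts.to_numpy()
    w = np.zeros(len(design.probes))
    for _, prow in design.promoters.iterrows():
        idx = np.array([pos[p] for p in prow["probe_ids"]])
        cen = centers[idx]
        near = np.abs(cen[:, None] - cen[None, :]) <= coupling_distance
        coupled = near @ cvals[idx]
        w[idx] = coupled / max(1.0, coupled.max())
    return pd.Series(w, index=design.probes.index, name="coupling_weight")


def subject_methylation(truth: TruthSet, config: SimConfig
                        ) -> tuple[pd.DataFrame, SampleSheet]:
    """Per-subject promoter methylation and the cohort sample sheet."""
    rng = config.rng(_STAGE_METH)
    subjects = ([f"CPA{i + 1:02d}" for i in range(config.n_cpa)]
                + [f"NPA{i + 1:02d}" for i in range(config.n_npa)])
    groups = ["CPA"] * config.n_cpa + ["NPA"] * config.n_npa
    sheet = SampleSheet(pd.DataFrame({
        "subject_id": subjects,
        "group": groups,
        "sex": "F",
        "array_ids": [[f"{s}_r{k + 1}" for k in range(config.replicates)]
                      for s in subjects],
    }))
    base = np.where(np.array(groups)[None, :] == "CPA",
                    truth.promoters["m_cpa"].to_numpy()[:, None],
                    truth.promoters["m_npa"].to_numpy()[:, None])
    m = np.clip(base + rng.normal(0, config.bio_sd, size=base.shape), 0, 1)
    return pd.DataFrame(m, index=truth.promoters.index, columns=subjects), sheet


def simulate_medip_arrays(truth: TruthSet, design: ArrayDesign,
                          config: SimConfig
                          ) -> tuple[pd.DataFrame, SampleSheet]:
    """Two-channel raw intensities for the full cohort.

    Returns an intensity table (rows = probes, columns ``<array>_bound`` /
    ``<array>_input``) and the matching :class:`SampleSheet`.
    """
    rng = config.rng(_STAGE_ARRAYS)
    meth, sheet = subject_methylation(truth, config)

    w = coupled_cpg_weights(design, config.coupling_distance)
    # probe -> promoter row index (simulated probes map to one promoter each)
    prom_of_probe = design.probes["promoter_ids"].map(lambda t: t[0])
    m_probe = meth.loc[prom_of_probe].to_numpy()          # (P, S)
    r_true = (config.gain * m_probe * w.to_numpy()[:, None]
              + config.offset)

    n_probes = len(design.probes)
    probe_offset = rng.normal(0, config.noise_sd_probe, size=n_probes)
    cols = {}
    for s_i, subj in enumerate(meth.columns):
        for rep in range(config.replicates):
            array = f"{subj}_r{rep + 1}"
            array_offset = rng.normal(0, config.noise_sd_subject)
            eps = rng.normal(0, config.noise_sd_replicate, size=n_probes)
            r = r_true[:, s_i] + probe_offset + array_offset + eps
            log2_input = (10.0
                          + rng.normal(0, config.input_sd, size=n_probes))
            inp = np.exp2(log2_input)
            bg = config.background_level
            cols[f"{array}_bound"] = inp * np.exp2(r) + bg
            cols[f"{array}_input"] = inp + bg
            # scanner-style per-spot background estimates
            cols[f"{array}_bound_bg"] = np.full(n_probes, bg)
            cols[f"{array}_input_bg"] = np.full(n_probes, bg)
    table = pd.DataFrame(cols, index=design.probes.index.copy())
    table.index.name = "probe_id"
    return table, sheet


def simulate_450k_pools(truth: TruthSet, config: SimConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pooled bisulfite-array beta table, CpG manifest, and pool sheet.

    Beta per CpG per pool = the pool's group-level promoter methylation plus
    bounded noise, clipped to [0, 1].  A configurable fraction of CpGs is
    given a failing detection p-value in one pool, and another fraction a
    SNP within 10 bp, to exercise the filters.
    """
    if config.pools_per_group < 2:
        raise ValueError("need >= 2 pools per group for a differential test")
    rng = config.rng(_STAGE_POOLS)
    prom = truth.promoters
    n_cpg = config.cpgs_per_promoter
    wlen = int(prom["win_len"].iloc[0])

    cpg_ids, coords, prom_ids = [], [], []
    counter = 0
    for pid, row in prom.iterrows():
        for _ in range(n_cpg):
            cpg_ids.append(f"cg{counter:08d}")
            coords.append(int(row["tss"]) - ArrayDesign.UPSTREAM
                          + int(rng.integers(0, wlen)))
            prom_ids.append(pid)
            counter += 1
    n_sites = len(cpg_ids)

    pools = ([f"CPA_pool{i + 1}" for i in range(config.pools_per_group)]
             + [f"NPA_pool{i + 1}" for i in range(config.pools_per_group)])
    pool_groups = (["CPA"] * config.pools_per_group
                   + ["NPA"] * config.pools_per_group)

    m_cpa = prom.loc[prom_ids, "m_cpa"].to_numpy()
    m_npa = prom.loc[prom_ids, "m_npa"].to_numpy()
    betas = {}
    det = {}
    for pool, grp in zip(pools, pool_groups):
        base = m_cpa if grp == "CPA" else m_npa
        noise = rng.normal(0, config.pool_beta_sd, size=n_sites)
        betas[f"{pool}_beta"] = np.clip(base + noise, 0.0, 1.0)
        det[f"{pool}_detection_p"] = rng.uniform(0, 5e-4, size=n_sites)

    beta = pd.DataFrame({**betas, **det},
                        index=pd.Index(cpg_ids, name="cpg_id"))

    n_fail = int(round(config.detection_fail_frac * n_sites))
    if n_fail:
        fail_rows = rng.choice(n_sites, size=n_fail, replace=False)
        fail_pool = rng.choice(pools, size=n_fail)
        for r, p in zip(fail_rows, fail_pool):
            beta.iloc[r, beta.columns.get_loc(f"{p}_detection_p")] = 0.01

    snp_distance = rng.integers(50, 5000, size=n_sites).astype(float)
    n_snp = int(round(config.snp_proximal_frac * n_sites))
    if n_snp:
        snp_rows = rng.choice(n_sites, size=n_snp, replace=False)
        snp_distance[snp_rows] = rng.integers(0, 11, size=n_snp)

    manifest = pd.DataFrame({
        "chrom": "chr1",
        "pos": coords,
        "snp_distance": snp_distance,
        "promoter_id": prom_ids,
        "gene_id": prom.loc[prom_ids, "gene_id"].to_numpy(),
    }, index=pd.Index(cpg_ids, name="cpg_id"))

    pool_sheet = pd.DataFrame({"pool_id": pools, "group": pool_groups})
    return beta, manifest, pool_sheet
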