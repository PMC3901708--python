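"""End-to-end pipeline driver with a reproducibility manifest.

Stages (each restartable from its predecessors' file outputs):

    normalize   raw intensities -> normalized, replicate-merged ratios
    dmr         probe moderated t -> promoter rank-sum -> calls
    deconvolve  cohort-averaged ratios -> promoter methylation estimates
    organization CpG-density asymmetry + distance-correlation curve
    beta450k    pooled beta table -> filtered differential CpGs -> promoter hits

Every run writes a JSON manifest recording the configuration, input file
checksums, per-stage outputs with row counts, and the seeds used, so that
identical configuration and inputs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genomics import (ArrayDesign, SampleSheet, load_array_design,
                       load_intensity_table, write_bed)
from . import dmr as dmr_mod
from . import preprocess
from .deconvolution import DeconvolutionConfig, estimate_promoter_methylation
from .meth450k import filter_probes, map_cpgs_to_promoters, pool_differential
from .organization import (decorrelation_length, normalized_cpg_density,
                           spatial_correlation_curve)

logger = logging.getLogger(__name__)

ALL_STAGES = ("normalize", "dmr", "deconvolve", "organization", "beta450k")


@dataclass
class PipelineConfig:
    design: str = ""
    intensities: str = ""
    samples: str = ""
    genome: str | None = None
    betas: str | None = None
    manifest_450k: str | None = None
    pools: str | None = None
    out_dir: str = "medipdmr_out"
    stages: tuple[str, ...] = ALL_STAGES
    probe_p: float = 0.05
    min_lfc: float = 0.25
    max_q: float = 0.05
    min_probes: int = 3
    detection_p_max: float = 0.001
    snp_min_distance: float = 10.0
    strict_qc: bool = False
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        for name, lo, hi in (("probe_p", 0, 1), ("max_q", 0, 1),
                             ("detection_p_max", 0, 1)):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.min_lfc < 0 or self.snp_min_distance < 0:
            raise ValueError("min_lfc and snp_min_distance must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def validate_inputs(self) -> None:
        required = {"normalize": ["design", "intensities", "samples"],
                    "dmr": ["design"], "deconvolve": ["design"],
                    "organization": ["design"],
                    "beta450k": ["betas", "manifest_450k", "pools", "design"]}
        for stage in self.stages:
            for attr in required[stage]:
                val = getattr(self, attr)
                if not val:
                    raise ValueError(f"stage {stage} requires {attr}")
                if not Path(val).exists():
                    raise FileNotFoundError(f"{attr}: {val} does not exist")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run manifest."""
    config.validate_inputs()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()[:16],
        "inputs": {}, "stages": {}, "seed": config.seed,
    }
    for attr in ("design", "intensities", "samples", "genome", "betas",
                 "manifest_450k", "pools"):
        val = getattr(config, attr)
        if val and Path(val).exists():
            manifest["inputs"][attr] = _sha256(val)

    design = load_array_design(config.design, genome_path=config.genome)
    samples = SampleSheet.from_csv(config.samples) if config.samples else None

    merged = None
    probe_stats = promoter_stats = calls = None
    try:
        if "normalize" in config.stages:
            raw = load_intensity_table(config.intensities, design)
            qc = preprocess.qc_summary(raw, samples)
            exclude = set(qc.flagged_arrays) if config.strict_qc else set()
            normed = preprocess.normalize(raw)
            merged = preprocess.merge_replicates(normed, samples,
                                                 exclude=frozenset(exclude))
            ratios_path = out / "ratios.tsv"
            merged.values.T.to_csv(ratios_path, sep="\t")
            qc.table.to_csv(out / "qc.tsv", sep="\t", index=False)
            manifest["stages"]["normalize"] = {
                "outputs": {"ratios": str(ratios_path),
                            "qc": str(out / "qc.tsv")},
                "n_arrays": int(len(qc.table)),
                "n_flagged": int(len(qc.flagged_arrays)),
                "n_probes": int(merged.values.shape[1]),
            }

        if "dmr" in config.stages:
            if merged is None:
                raise ValueError("dmr stage requires the normalize stage")
            groups = samples.group_of()
            probe_stats = dmr_mod.probe_moderated_t(merged, groups)
            promoter_stats = dmr_mod.promoter_ranksum(
                probe_stats, design, min_probes=config.min_probes)
            calls, counts = dmr_mod.call_dmrs(
                probe_stats, promoter_stats, design,
                probe_p=config.probe_p, min_lfc=config.min_lfc,
                max_q=config.max_q)
            probe_stats.to_csv(out / "probe_stats.tsv", sep="\t")
            promoter_stats.to_csv(out / "promoter_stats.tsv", sep="\t")
            calls.to_csv(out / "dmr_calls.tsv", sep="\t")
            if len(calls):
                bed = calls.reset_index().rename(columns={
                    "window_start": "start", "window_end": "end",
                    "promoter_id": "name"})
                bed["strand"] = "."
                write_bed(bed[["chrom", "start", "end", "name", "q",
                               "strand"]], out / "dmr_calls.bed")
                heat = dmr_mod.representative_probes(
                    calls, probe_stats, merged, design)
                heat.to_csv(out / "heatmap_matrix.tsv", sep="\t")
                if len(heat) >= 2:
                    link = dmr_mod.ward_cluster(heat)
                    with open(out / "linkage.json", "w") as fh:
                        json.dump({k: v.tolist() for k, v in link.items()}, fh)
            manifest["stages"]["dmr"] = {
                "outputs": {"calls": str(out / "dmr_calls.tsv")},
                "n_probes_tested": int(len(probe_stats)),
                "n_promoters_tested": int(promoter_stats["tested"].sum()),
                "n_called": int(len(calls)),
                "direction_counts": counts,
                "prior_d0": float(probe_stats.attrs["prior_d0"]),
            }

        if "deconvolve" in config.stages:
            if merged is None:
                raise ValueError("deconvolve stage requires normalize")
            avg = merged.values.mean(axis=0)
            est = estimate_promoter_methylation(avg, design,
                                                DeconvolutionConfig())
            est.to_csv(out / "methylation_estimates.tsv", sep="\t")
            manifest["stages"]["deconvolve"] = {
                "outputs": {"estimates": str(out / "methylation_estimates.tsv")},
                "n_estimated": int(est["m_hat"].notna().sum()),
            }

        if "organization" in config.stages:
            if probe_stats is None or calls is None:
                raise ValueError("organization stage requires dmr")
            regions = _call_regions(calls, design)
            density, test = normalized_cpg_density(regions)
            density.to_csv(out / "cpg_density.tsv", sep="\t", index=False)
            delta = probe_stats["log2fc"]
            coords = pd.DataFrame({
                "chrom": design.probes.loc[delta.index, "chrom"],
                "pos": (design.probes.loc[delta.index, "start"]
                        + design.probes.loc[delta.index, "end"]) / 2.0,
            })
            curve = spatial_correlation_curve(delta, coords,
                                              seed=config.seed)
            curve.table.to_csv(out / "distance_correlation.tsv", sep="\t",
                               index=False)
            manifest["stages"]["organization"] = {
                "outputs": {"density": str(out / "cpg_density.tsv"),
                            "curve": str(out / "distance_correlation.tsv")},
                "density_test": test,
                "decorrelation_length_bp": float(decorrelation_length(curve)),
            }

        if "beta450k" in config.stages:
            beta = pd.read_csv(config.betas, index_col=0)
            man450 = pd.read_csv(config.manifest_450k, index_col=0)
            pool_sheet = pd.read_csv(config.pools)
            filtered, report = filter_probes(
                beta, man450, detection_p_max=config.detection_p_max,
                snp_min_distance=config.snp_min_distance)
            diff = pool_differential(filtered, pool_sheet)
            hits = map_cpgs_to_promoters(diff, man450, design)
            diff.to_csv(out / "cpg_diff.tsv", sep="\t")
            hits.to_csv(out / "promoter_hits_450k.tsv", sep="\t")
            manifest["stages"]["beta450k"] = {
                "outputs": {"diff": str(out / "cpg_diff.tsv"),
                            "hits": str(out / "promoter_hits_450k.tsv")},
                "filter_report": report,
                "n_significant_cpgs": int(diff["significant"].sum()),
                "n_promoter_hits": int(len(hits)),
            }
    except Exception as exc:
        manifest["failed_at"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _call_regions(calls: pd.DataFrame, design: ArrayDesign) -> pd.DataFrame:
    """Promoter windows of called DMRs plus a background sample, with CpG
    composition from the design's probe counts."""
    rows = []
    called = set(calls.index) if len(calls) else set()
    for pid, prow in design.promoters.iterrows():
        probes = design.probes.loc[list(prow["probe_ids"])]
        if probes["cpg_count"].isna().any():
            continue
        if pid in called:
            group = calls.at[pid, "direction"]
        else:
            group = "background"
        length = int((probes["end"] - probes["start"]).sum())
        rows.append({
            "region_id": pid, "group": group,
            "cpg": int(probes["cpg_count"].sum()),
            "c": int(probes["c_count"].sum()),
            "g": int(probes["g_count"].sum()),
            "length": length,
        })
    return pd.DataFrame(rows)


def analyze_synthetic_cohort(sim_config) -> dict:
    """Simulate a cohort and run the in-memory MeDIP analysis chain.

    Returns a dict with the truth set, design, merged ratios, probe and
    promoter statistics, DMR calls and direction counts — the working
    material for calibration and recovery studies.
    """
    from .simulate import simulate_medip_arrays, simulate_truth
    truth, design = simulate_truth(sim_config)
    raw, sheet = simulate_medip_arrays(truth, design, sim_config)
    merged = preprocess.merge_replicates(preprocess.normalize(raw), sheet)
    probe_stats = dmr_mod.probe_moderated_t(merged, sheet.group_of())
    promoter_stats = dmr_mod.promoter_ranksum(probe_stats, design)
    calls, counts = dmr_mod.call_dmrs(probe_stats, promoter_stats, design)
    coords = pd.DataFrame({
        "chrom": design.probes["chrom"],
        "pos": (design.probes["start"] + design.probes["end"]) / 2.0,
    })
    return {"truth": truth, "design": design, "samples": sheet,
            "merged": merged, "probe_stats": probe_stats,
            "promoter_stats": promoter_stats, "calls": calls,
            "direction_counts": counts, "probe_coords": coords}


def simulate_cohort_files(out_dir, config=None) -> dict:
    """Generate a full synthetic cohort on disk (design, intensities,
    samples, betas, 450K manifest, pools, truth).  Returns the paths."""
    from .simulate import (SimConfig, simulate_450k_pools,
                           simulate_medip_arrays, simulate_truth)
    config = config or SimConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth, design = simulate_truth(config)
    raw, sheet = simulate_medip_arrays(truth, design, config)
    beta, manifest, pools = simulate_450k_pools(truth, config)
    paths = {
        "design": out / "design.tsv",
        "intensities": out / "intensities.tsv",
        "samples": out / "samples.csv",
        "betas": out / "betas.csv",
        "manifest_450k": out / "manifest_450k.csv",
        "pools": out / "pools.csv",
        "truth": out / "truth.json",
    }
    design.to_tsv(paths["design"])
    raw.to_csv(paths["intensities"], sep="\t")
    sheet.to_csv(paths["samples"])
    beta.to_csv(paths["betas"])
    manifest.to_csv(paths["manifest_450k"])
    pools.to_csv(paths["pools"], index=False)
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
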