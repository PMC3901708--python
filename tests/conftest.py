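"""Shared fixtures: small synthetic cohorts and handmade design files."""

import textwrap

import numpy as np
import pandas as pd
import pytest

from medipdmr import SampleSheet, SimConfig
from medipdmr.simulate import simulate_medip_arrays, simulate_truth


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-gene cohort with signal, shared across read-only tests."""
    cfg = SimConfig(n_genes=300, seed=11)
    truth, design = simulate_truth(cfg)
    raw, sheet = simulate_medip_arrays(truth, design, cfg)
    return {"config": cfg, "truth": truth, "design": design,
            "raw": raw, "samples": sheet}


@pytest.fixture()
def tiny_design_tsv(tmp_path):
    """A 2-promoter, 5-probe design file with a matching 600 bp genome."""
    # promoter A: + strand, TSS at position 1100 (1-based 1101)
    # promoter B: - strand, TSS at position 1500 (1-based 1501)
    rows = [
        # chrom start end probe_id promoter_id gene_id tss strand
        ("chr1", 100, 160, "pA_00", "promA", "geneA", 1101, "+"),
        ("chr1", 200, 260, "pA_01", "promA", "geneA", 1101, "+"),
        ("chr1", 300, 360, "pA_02", "promA", "geneA", 1101, "+"),
        ("chr1", 700, 760, "pB_00", "promB", "geneB", 1501, "-"),
        ("chr1", 800, 860, "pB_01", "promB", "geneB", 1501, "-"),
    ]
    path = tmp_path / "design.tsv"
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tprobe_id\tpromoter_id\tgene_id\ttss\tstrand\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
    return path


@pytest.fixture()
def tiny_genome_fasta(tmp_path):
    """A deterministic 3 kb chromosome with known CpG content."""
    rng = np.random.default_rng(42)
    seq = rng.choice(list("ACGT"), size=3000)
    # plant a CpG island in probe pA_01's window for variety
    seq[210:230] = list("CG" * 10)
    path = tmp_path / "genome.fa"
    with open(path, "w") as fh:
        fh.write(">chr1\n")
        fh.write(textwrap.fill("".join(seq), 60) + "\n")
    return path


@pytest.fixture()
def four_subject_sheet():
    return SampleSheet(pd.DataFrame({
        "subject_id": ["s1", "s2", "s3", "s4"],
        "group": ["CPA", "CPA", "NPA", "NPA"],
        "sex": ["F"] * 4,
        "array_ids": [["s1_r1", "s1_r2"], ["s2_r1", "s2_r2"],
                      ["s3_r1", "s3_r2"], ["s4_r1", "s4_r2"]],
    }))
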