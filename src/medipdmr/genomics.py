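"""Genomic data model and file I/O for promoter tiling-array analysis.

The pipeline works on a custom promoter tiling design: probes laid out at
fixed spacing across windows from 1000 bp upstream to 200 bp downstream of
every annotated transcription start site.  This module defines the in-memory
containers (probes, promoters, the array design, the sample sheet), the
TSV/FASTA/CSV readers, and the BED writer used for exporting calls.

Coordinate conventions
----------------------
All internal coordinates are 0-based half-open (BED convention).  Printed
1-based inclusive ranges (as found in publication tables) must be converted
exactly once, at the parser boundary, via :func:`interval_from_1based`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VALID_NUC = frozenset("ACGTN")

DESIGN_COLUMNS = ["chrom", "start", "end", "probe_id", "promoter_id",
                  "gene_id", "tss", "strand"]


class DesignError(ValueError):
    """Malformed or internally inconsistent array-design input."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


def interval_from_1based(chrom: str, start1: int, end1: int,
                         strand: str = ".") -> GenomicInterval:
    """Convert a printed 1-based inclusive range to the internal convention."""
    return GenomicInterval(chrom, start1 - 1, end1, strand)


def count_cpg(sequence: str) -> tuple[int, int, int]:
    """Count CG dinucleotides and C/G mononucleotides in a sequence.

    Case-insensitive; ``N`` positions are excluded from all counts (an ``N``
    never participates in a CG dinucleotide).  Returns
    ``(cpg_count, c_count, g_count)``.

    Raises
    ------
    ValueError
        If the sequence contains a character outside {A, C, G, T, N}.
    """
    seq = sequence.upper()
    bad = set(seq) - _VALID_NUC
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    c = seq.count("C")
    g = seq.count("G")
    cpg = seq.count("CG")
    return cpg, c, g


@dataclass
class SampleSheet:
    """Subject-level metadata: group membership and replicate arrays.

    ``table`` has one row per subject with columns ``subject_id``, ``group``
    (CPA or NPA), ``sex`` (F/M) and ``array_ids`` (list of replicate array
    column names in the intensity table); ``pool_id`` is optional.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = {"subject_id", "group", "sex", "array_ids"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns {sorted(missing)}")
        if t["subject_id"].duplicated().any():
            raise ValueError("duplicate subject_id in sample sheet")
        bad_groups = set(t["group"]) - {"CPA", "NPA"}
        if bad_groups:
            raise ValueError(f"unknown groups {sorted(bad_groups)}")
        for _, row in t.iterrows():
            if len(row["array_ids"]) < 1:
                raise ValueError(
                    f"subject {row['subject_id']} has no arrays")
        for grp in ("CPA", "NPA"):
            if not (t["group"] == grp).any():
                raise ValueError(f"group {grp} is empty")

    @property
    def subjects(self) -> list[str]:
        return list(self.table["subject_id"])

    def group_of(self) -> pd.Series:
        return self.table.set_index("subject_id")["group"]

    def arrays_of(self) -> dict[str, list[str]]:
        return dict(zip(self.table["subject_id"], self.table["array_ids"]))

    @classmethod
    def from_csv(cls, path) -> "SampleSheet":
        raw = pd.read_csv(path, dtype=str)
        raw["array_ids"] = raw["array_ids"].str.split(";")
        return cls(raw)

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["array_ids"] = out["array_ids"].map(";".join)
        out.to_csv(path, index=False)


@dataclass
class ArrayDesign:
    """Probe and promoter tables with mutually consistent cross-references.

    ``probes``: indexed by ``probe_id`` with columns chrom, start, end,
    promoter_ids (tuple), and cpg_count / c_count / g_count (nullable Int64
    until a genome is attached).
    ``promoters``: indexed by ``promoter_id`` with columns gene_id, chrom,
    tss (0-based position), strand, window_start, window_end, probe_ids
    (tuple, ordered by coordinate).
    """

    probes: pd.DataFrame
    promoters: pd.DataFrame
    genome_build: str = "synthetic"

    UPSTREAM = 1000
    DOWNSTREAM = 200

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.probes.index.duplicated().any():
            raise DesignError("duplicate probe_ids")
        if self.promoters.index.duplicated().any():
            raise DesignError("duplicate promoter_ids")
        known_prom = set(self.promoters.index)
        for pid, row in self.probes.iterrows():
            unknown = set(row["promoter_ids"]) - known_prom
            if unknown:
                raise DesignError(
                    f"probe {pid} references unknown promoters {sorted(unknown)}")
        probe_index = set(self.probes.index)
        for prom, row in self.promoters.iterrows():
            missing = set(row["probe_ids"]) - probe_index
            if missing:
                raise DesignError(
                    f"promoter {prom} references unknown probes {sorted(missing)}")
            for probe in row["probe_ids"]:
                if prom not in self.probes.at[probe, "promoter_ids"]:
                    raise DesignError(
                        f"probe {probe} of promoter {prom} lacks back-reference")
            wlen = row["window_end"] - row["window_start"]
            if wlen != self.UPSTREAM + self.DOWNSTREAM:
                raise DesignError(
                    f"promoter {prom} window length {wlen} != "
                    f"{self.UPSTREAM + self.DOWNSTREAM}")

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def n_promoters(self) -> int:
        return len(self.promoters)

    @property
    def n_genes(self) -> int:
        return self.promoters["gene_id"].nunique()

    def design_hash(self) -> str:
        """Stable fingerprint used to detect mismatched stat tables."""
        import hashlib
        h = hashlib.sha256()
        h.update(",".join(self.probes.index).encode())
        h.update(self.probes[["start", "end"]].to_numpy().tobytes())
        return h.hexdigest()[:16]

    def attach_genome(self, fasta_path) -> None:
        """Fill per-probe CpG/C/G counts from a genome FASTA."""
        from pyfaidx import Fasta
        genome = Fasta(str(fasta_path), as_raw=True)
        cpg, cc, gg = [], [], []
        for pid, row in self.probes.iterrows():
            chrom = row["chrom"]
            if chrom not in genome:
                raise DesignError(f"probe {pid}: chromosome {chrom} not in genome")
            if row["end"] > len(genome[chrom]):
                raise DesignError(
                    f"probe {pid} extends past end of {chrom} "
                    f"({row['end']} > {len(genome[chrom])})")
            seq = str(genome[chrom][row["start"]:row["end"]])
            a, b, c = count_cpg(seq)
            cpg.append(a)
            cc.append(b)
            gg.append(c)
        self.probes["cpg_count"] = pd.array(cpg, dtype="Int64")
        self.probes["c_count"] = pd.array(cc, dtype="Int64")
        self.probes["g_count"] = pd.array(gg, dtype="Int64")

    def to_tsv(self, path) -> None:
        rows = []
        for prom, prow in self.promoters.iterrows():
            tss1 = prow["tss"] + 1  # printed 1-based
            for probe in prow["probe_ids"]:
                b = self.probes.loc[probe]
                rows.append({
                    "chrom": b["chrom"], "start": b["start"], "end": b["end"],
                    "probe_id": probe, "promoter_id": prom,
                    "gene_id": prow["gene_id"], "tss": tss1,
                    "strand": prow["strand"],
                    "cpg_count": b.get("cpg_count", pd.NA),
                    "c_count": b.get("c_count", pd.NA),
                    "g_count": b.get("g_count", pd.NA),
                })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_array_design(design_path, genome_path=None) -> ArrayDesign:
    """Build an :class:`ArrayDesign` from a long-format TSV.

    One row per (probe, promoter) assignment with columns
    ``chrom start end probe_id promoter_id gene_id tss strand`` and optional
    pre-computed ``cpg_count c_count g_count``.  ``start``/``end`` are 0-based
    half-open; ``tss`` is 1-based as printed in annotation tables.  When
    ``genome_path`` is given, CpG/C/G counts are (re)filled from sequence.
    """
    try:
        df = pd.read_csv(design_path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise DesignError(f"cannot parse design file {design_path}: {exc}")
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise DesignError(f"design file missing columns {sorted(missing)}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if not (0 <= row.start < row.end):
            raise DesignError(f"line {i}: invalid interval {row.start}-{row.end}")

    has_counts = {"cpg_count", "c_count", "g_count"} <= set(df.columns)

    probe_rows = {}
    for row in df.itertuples(index=False):
        entry = probe_rows.setdefault(row.probe_id, {
            "chrom": row.chrom, "start": int(row.start), "end": int(row.end),
            "promoter_ids": set(),
        })
        if (entry["chrom"], entry["start"], entry["end"]) != \
                (row.chrom, int(row.start), int(row.end)):
            raise DesignError(f"probe {row.probe_id} has conflicting coordinates")
        entry["promoter_ids"].add(row.promoter_id)
        if has_counts and "cpg_count" not in entry:
            entry["cpg_count"] = int(row.cpg_count)
            entry["c_count"] = int(row.c_count)
            entry["g_count"] = int(row.g_count)

    probes = pd.DataFrame.from_dict(probe_rows, orient="index")
    probes.index.name = "probe_id"
    probes["promoter_ids"] = probes["promoter_ids"].map(
        lambda s: tuple(sorted(s)))

    prom_rows = {}
    for row in df.itertuples(index=False):
        tss0 = int(row.tss) - 1
        if row.strand == "+":
            wstart = tss0 - ArrayDesign.UPSTREAM
            wend = tss0 + ArrayDesign.DOWNSTREAM
        elif row.strand == "-":
            wstart = tss0 + 1 - ArrayDesign.DOWNSTREAM
            wend = tss0 + 1 + ArrayDesign.UPSTREAM
        else:
            raise DesignError(
                f"promoter {row.promoter_id}: strand must be + or -")
        entry = prom_rows.setdefault(row.promoter_id, {
            "gene_id": row.gene_id, "chrom": row.chrom, "tss": tss0,
            "strand": row.strand, "window_start": wstart, "window_end": wend,
            "probe_ids": [],
        })
        entry["probe_ids"].append((int(row.start), row.probe_id))

    for entry in prom_rows.values():
        entry["probe_ids"] = tuple(p for _, p in sorted(entry["probe_ids"]))
    promoters = pd.DataFrame.from_dict(prom_rows, orient="index")
    promoters.index.name = "promoter_id"

    if not has_counts:
        for col in ("cpg_count", "c_count", "g_count"):
            probes[col] = pd.array([pd.NA] * len(probes), dtype="Int64")

    design = ArrayDesign(probes=probes, promoters=promoters)
    if genome_path is not None:
        design.attach_genome(genome_path)
    return design


def load_intensity_table(path, design: ArrayDesign | None = None
                         ) -> pd.DataFrame:
    """Read a two-channel raw intensity TSV.

    Expected layout: a ``probe_id`` column plus one column per array/channel
    named ``<array>_bound`` and ``<array>_input`` (optionally
    ``<array>_bound_bg`` / ``<array>_input_bg`` background columns).  Probes
    absent from the design are dropped with a logged warning; duplicated
    probe rows are an error.  Negative intensities are retained (the
    normalization offset policy deals with them) but counted in the log.
    """
    df = pd.read_csv(path, sep="\t")
    if "probe_id" not in df.columns:
        raise ValueError("intensity table needs a probe_id column")
    if df["probe_id"].duplicated().any():
        dups = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValueError(f"duplicated probe rows: {dups[:5]}")
    df = df.set_index("probe_id")
    bad = [c for c in df.columns
           if not re.search(r"_(bound|input)(_bg)?$", c)]
    if bad:
        raise ValueError(f"unrecognized intensity columns: {bad}")
    if design is not None:
        unknown = df.index.difference(design.probes.index)
        if len(unknown):
            logger.warning("dropping %d probes not in design (e.g. %s)",
                           len(unknown), list(unknown[:3]))
            df = df.loc[df.index.intersection(design.probes.index)]
    n_neg = int((df.to_numpy() < 0).sum())
    if n_neg:
        logger.warning("%d negative intensities retained for QC", n_neg)
    return df


def intensity_arrays(table: pd.DataFrame) -> list[str]:
    """Array names present in an intensity table."""
    names = []
    for c in table.columns:
        m = re.match(r"(.+)_bound$", c)
        if m:
            names.append(m.group(1))
    return names


def write_bed(records: pd.DataFrame, path) -> None:
    """Write promoter calls as BED6.

    ``records`` needs columns chrom, start, end, name, q, strand.  The BED
    score is ``-10*log10(q)`` capped at 1000 (q = 0 maps to the cap; q = 1
    maps to 0).
    """
    with open(path, "w") as fh:
        fh.write('track name="medipdmr_calls" description="promoter DMR calls"\n')
        for row in records.itertuples(index=False):
            q = float(row.q)
            if q <= 0:
                score = 1000
            else:
                score = min(1000, int(round(-10.0 * np.log10(q))))
            strand = getattr(row, "strand", ".")
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}"
                     f"\t{score}\t{strand}\n")
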