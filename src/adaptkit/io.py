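"""File-format frontends: VCF, BED, GFF3, population maps and flat panels.

VCF read/write goes through pysam.  Simulated haplotype panels are exported
as minimal GT-only phased VCFs on one pseudo-contig (selfing strains are
haploid samples), and round-trip exactly.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import pysam

from .coalescent import HaplotypePanel
from .filters import MISSING, SiteRecord

__all__ = [
    "read_vcf",
    "write_panel_vcf",
    "read_panel_vcf",
    "read_bed",
    "read_popmap",
    "write_panel_text",
    "read_panel_text",
    "write_windows_tsv",
]

_INFO_KEYS = ("Q", "MQ", "QD", "ReadPosRankSum", "DP", "FS")


def read_vcf(path) -> list[SiteRecord]:
    """Read site records (GT + the hard-filter INFO keys) from a VCF."""
    records = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        for rec in vcf:
            gts = []
            for sample in rec.samples.values():
                alleles = sample["GT"]
                gts.append([MISSING if a is None else int(a) for a in alleles])
            ann = {}
            for key in _INFO_KEYS:
                if key == "Q":
                    if rec.qual is not None:
                        ann["Q"] = float(rec.qual)
                elif key in rec.info:
                    val = rec.info[key]
                    ann[key] = float(val[0] if isinstance(val, tuple) else val)
            alt = tuple(rec.alts or ())
            is_snp = len(rec.ref) == 1 and all(len(a) == 1 for a in alt)
            records.append(
                SiteRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    genotypes=np.array(gts, dtype=np.int16),
                    annotations=ann,
                    variant_class="SNP" if is_snp else "indel",
                )
            )
    return records


def _panel_header(panel: HaplotypePanel, contig: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={panel.sequence_length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for i, label in enumerate(panel.pop_labels):
        header.add_sample(f"{label}_{i}")
    return header


def write_panel_vcf(panel: HaplotypePanel, path, contig: str = "sim1") -> None:
    """Write a panel as a minimal phased GT-only haploid VCF."""
    header = _panel_header(panel, contig)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as vcf:
        for s in range(panel.n_sites):
            rec = vcf.new_record(
                contig=contig,
                start=int(panel.positions[s]) - 1,
                alleles=("A", "T"),
            )
            for i, sample in enumerate(rec.samples.values()):
                sample["GT"] = (int(panel.matrix[i, s]),)
                sample.phased = True
            vcf.write(rec)


def read_panel_vcf(path) -> HaplotypePanel:
    """Read a haploid GT-only VCF written by :func:`write_panel_vcf`."""
    with pysam.VariantFile(os.fspath(path)) as vcf:
        samples = list(vcf.header.samples)
        contigs = vcf.header.contigs
        length = max(contigs[c].length for c in contigs)
        labels = [s.rsplit("_", 1)[0] for s in samples]
        positions, cols = [], []
        for rec in vcf:
            positions.append(rec.pos)
            cols.append([int(s["GT"][0]) for s in rec.samples.values()])
    matrix = np.array(cols, dtype=np.int8).T if cols else np.zeros((len(labels), 0), np.int8)
    return HaplotypePanel(matrix, np.array(positions, np.int64), int(length), labels)


def read_bed(path) -> list[tuple[str, int, int]]:
    """(chrom, start, end) triples from a BED file (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return [(str(c), int(s), int(e)) for c, s, e in df.itertuples(index=False)]


def read_popmap(path) -> dict[str, str]:
    """Sample -> population mapping from a two-column TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "pop"], comment="#")
    return dict(zip(df["sample"].astype(str), df["pop"].astype(str)))


def write_panel_text(panel: HaplotypePanel, path) -> None:
    """Flat text panel: header, positions line, then one row per haplotype."""
    with open(path, "w") as fh:
        fh.write(f"#length={panel.sequence_length}\n")
        fh.write("#labels=" + ",".join(panel.pop_labels) + "\n")
        fh.write("positions\t" + "\t".join(map(str, panel.positions.tolist())) + "\n")
        for row in panel.matrix:
            fh.write("".join(map(str, row.tolist())) + "\n")


def read_panel_text(path) -> HaplotypePanel:
    with open(path) as fh:
        length = int(fh.readline().strip().split("=")[1])
        labels = fh.readline().strip().split("=")[1].split(",")
        pos_line = fh.readline().strip().split("\t")[1:]
        positions = np.array([int(p) for p in pos_line], np.int64)
        rows = [[int(c) for c in line.strip()] for line in fh if line.strip()]
    matrix = np.array(rows, np.int8) if rows else np.zeros((len(labels), 0), np.int8)
    return HaplotypePanel(matrix, positions, length, labels)


def write_windows_tsv(table: np.ndarray, path, statistic: str, chrom: str = "sim1") -> None:
    """BED-like TSV (chrom, start, end, value) for windowed statistics."""
    df = pd.DataFrame({
        "chrom": chrom,
        "start": table[:, 0].astype(int),
        "end": table[:, 1].astype(int),
        statistic: table[:, 2],
    })
    df.to_csv(path, sep="\t", index=False)
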