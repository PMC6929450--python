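"""Plain-file I/O: panel TSV/BED, genotype matrix TSV, allele-count TSV,
strata TSV, VCF (via pysam) and FASTA (via pyfaidx).

All genomic coordinates in files are 1-based inclusive except BED, which is
0-based half-open per the format.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .calling import AlleleDepthTable
from .matrix import MISSING, GenotypeMatrix
from .panel import CandidateRecord, CandidateVariantSet, MarkerPanel, SnpLocus

_NA = "NA"


# -- panel -------------------------------------------------------------------

_PANEL_COLS = ["locus_id", "chrom", "pos", "major", "minor", "flank_left", "flank_right"]


def write_panel_tsv(panel: MarkerPanel, path: str | Path) -> None:
    rows = [
        (l.locus_id, l.chrom, l.pos, l.major_allele, l.minor_allele,
         l.flank_left or _NA, l.flank_right or _NA)
        for l in panel
    ]
    df = pd.DataFrame(rows, columns=_PANEL_COLS)
    df.to_csv(path, sep="\t", index=False)


def read_panel_tsv(path: str | Path, genome_label: str = "") -> MarkerPanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    loci = []
    flank_width = 100
    for _, r in df.iterrows():
        left = "" if r["flank_left"] == _NA else str(r["flank_left"])
        right = "" if r["flank_right"] == _NA else str(r["flank_right"])
        if left:
            flank_width = len(left)
        loci.append(
            SnpLocus(
                locus_id=str(r["locus_id"]),
                chrom=str(r["chrom"]),
                pos=int(r["pos"]),
                major_allele=str(r["major"]),
                minor_allele=str(r["minor"]),
                flank_left=left,
                flank_right=right,
            )
        )
    return MarkerPanel(loci, genome_label=genome_label, flank_width=flank_width)


def write_panel_bed(panel: MarkerPanel, path: str | Path) -> None:
    """Target regions as BED (0-based half-open), one amplicon per locus."""
    with open(path, "w") as fh:
        for l in panel:
            start = max(l.pos - 1 - panel.flank_width, 0)
            end = l.pos + panel.flank_width
            fh.write(f"{l.chrom}\t{start}\t{end}\t{l.locus_id}\n")


# -- genotype matrix ---------------------------------------------------------


def write_genotype_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Rows = samples, columns = loci, dosage codes with NA for missing."""
    df = pd.DataFrame(matrix.codes, index=matrix.samples, columns=matrix.loci)
    df = df.replace(MISSING, np.nan)
    df.to_csv(path, sep="\t", index_label="sample", na_rep=_NA, float_format="%.0f")


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample", na_values=[_NA, "."])
    codes = df.to_numpy(dtype=float)
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
    return GenotypeMatrix([str(s) for s in df.index], [str(c) for c in df.columns], codes)


# -- allele depth table ------------------------------------------------------


def write_counts_tsv(table: AlleleDepthTable, path: str | Path) -> None:
    """Long format: sample, locus, allele, count."""
    rows = []
    for s in table.samples:
        for l in table.loci:
            for a, c in sorted(table.get(s, l).items()):
                rows.append((s, l, a, c))
    pd.DataFrame(rows, columns=["sample", "locus", "allele", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_counts_tsv(path: str | Path) -> AlleleDepthTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "locus": str, "allele": str})
    counts: dict[str, dict[str, dict[str, int]]] = {}
    for r in df.itertuples(index=False):
        counts.setdefault(r.sample, {}).setdefault(r.locus, {})[r.allele] = int(r.count)
    samples = sorted(counts)
    loci = sorted({l for per in counts.values() for l in per})
    return AlleleDepthTable(samples=samples, loci=loci, counts=counts)


# -- strata ------------------------------------------------------------------


def read_strata_tsv(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample, population) -> mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    sample_col, pop_col = df.columns[:2]
    return dict(zip(df[sample_col], df[pop_col]))


def write_strata_tsv(strata: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(strata.items()), columns=["sample", "population"]
    ).to_csv(path, sep="\t", index=False)


# -- FASTA -------------------------------------------------------------------


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = str(sequences[name])
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA into memory (indexed access via pyfaidx)."""
    from pyfaidx import Fasta

    with Fasta(str(path), as_raw=True, rebuild=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


# -- VCF ---------------------------------------------------------------------


def read_candidates_vcf(path: str | Path) -> CandidateVariantSet:
    """Read a multi-sample VCF (GT field) into a candidate variant set."""
    import pysam

    records: list[CandidateRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alleles = tuple(a.upper() for a in rec.alleles)
            gts = np.full((len(samples), 2), -1, dtype=np.int16)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT", (None, None))
                if gt is None:
                    continue
                a0 = gt[0] if len(gt) > 0 else None
                a1 = gt[1] if len(gt) > 1 else a0
                if a0 is not None and a1 is not None:
                    gts[i] = (a0, a1)
            records.append(CandidateRecord(rec.chrom, rec.pos, alleles, gts))
    return CandidateVariantSet(samples=samples, records=records)


def write_candidates_vcf(
    candidates: CandidateVariantSet,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a minimal GT-only multi-sample VCF."""
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"), ("Description", "Genotype")])
    chroms = sorted({r.chrom for r in candidates.records})
    for c in chroms:
        length = (contig_lengths or {}).get(
            c, max(r.pos for r in candidates.records if r.chrom == c) + 1000
        )
        header.contigs.add(c, length=length)
    for s in candidates.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in sorted(candidates.records, key=lambda x: (x.chrom, x.pos)):
            rec = out.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=r.alleles, id=".",
            )
            for i, s in enumerate(candidates.samples):
                a0, a1 = int(r.genotypes[i, 0]), int(r.genotypes[i, 1])
                rec.samples[s]["GT"] = (None, None) if a0 < 0 else (a0, a1)
            out.write(rec)


def write_genotype_vcf(
    matrix: GenotypeMatrix, panel: MarkerPanel, path: str | Path
) -> None:
    """Write called genotypes as a minimal GT-only VCF against the panel.

    REF is the panel major allele, ALT the minor; dosage 0/1/2 maps to
    0/0, 0/1 and 1/1.
    """
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"), ("Description", "Genotype")])
    for c in sorted({l.chrom for l in panel}):
        header.contigs.add(c, length=max(l.pos for l in panel if l.chrom == c) + 1000)
    for s in matrix.samples:
        header.add_sample(s)
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for l in panel:
            if l.locus_id not in matrix.loci:
                continue
            j = matrix.locus_index(l.locus_id)
            rec = out.new_record(
                contig=l.chrom, start=l.pos - 1,
                alleles=(l.major_allele, l.minor_allele), id=l.locus_id,
            )
            for i, s in enumerate(matrix.samples):
                rec.samples[s]["GT"] = gt_map[int(matrix.codes[i, j])]
            out.write(rec)


def read_genotype_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a biallelic GT-only VCF into a dosage matrix (REF dosage 0)."""
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        loci: list[str] = []
        cols: list[np.ndarray] = []
        for rec in vcf:
            lid = rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}"
            col = np.full(len(samples), MISSING, dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT", (None, None))
                if gt and gt[0] is not None and len(gt) > 1 and gt[1] is not None:
                    col[i] = int(gt[0] > 0) + int(gt[1] > 0)
            loci.append(lid)
            cols.append(col)
    codes = np.stack(cols, axis=1) if cols else np.zeros((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(samples, loci, codes)
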