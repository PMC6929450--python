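"""Genotype calling from per-locus allele read counts.

Calls follow the read-frequency rules of targeted amplicon genotyping: the
allele with the most reads is the sample's major allele at the locus; if its
frequency exceeds ``major_threshold`` (default 0.7) the call is homozygous,
else if both the major and second allele reach ``het_threshold`` (default
0.35) the call is heterozygous, and anything in between — an ambiguous
mixture neither clearly homozygous nor clearly balanced — is missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import ConfigError
from .matrix import MISSING, GenotypeMatrix
from .panel import MarkerPanel


@dataclass
class AlleleDepthTable:
    """Read counts per (sample, locus, allele).

    ``counts[sample][locus]`` maps allele strings (possibly including
    non-panel noise alleles) to non-negative read counts.
    """

    samples: list[str]
    loci: list[str]
    counts: dict[str, dict[str, dict[str, int]]]

    def get(self, sample: str, locus: str) -> dict[str, int]:
        """Counts for one cell; empty dict when no reads were observed."""
        return self.counts.get(sample, {}).get(locus, {})

    def total_depth(self, sample: str, locus: str) -> int:
        return sum(self.get(sample, locus).values())

    def depth_matrix(self) -> np.ndarray:
        """(n_samples, n_loci) array of total read depth per cell."""
        out = np.zeros((len(self.samples), len(self.loci)), dtype=np.int64)
        for i, s in enumerate(self.samples):
            for j, l in enumerate(self.loci):
                out[i, j] = self.total_depth(s, l)
        return out


@dataclass(frozen=True)
class GenotypeCall:
    """One diploid call: state, allele pair, evidence summary."""

    state: str  # hom_major | hom_minor | het | missing
    alleles: tuple[str, ...]
    major_freq: float
    total_depth: int

    def __post_init__(self) -> None:
        if self.state == "het" and (len(self.alleles) != 2 or self.alleles[0] == self.alleles[1]):
            raise ValueError("het call must carry two distinct alleles")
        if self.state == "missing" and self.alleles:
            raise ValueError("missing call must carry no alleles")


_MISSING_CALL = GenotypeCall("missing", (), 0.0, 0)


def call_genotype(
    allele_counts: Mapping[str, int],
    major_threshold: float = 0.7,
    het_threshold: float = 0.35,
    min_depth: int = 20,
    panel_alleles: tuple[str, str] | None = None,
    top_two_only: bool = False,
) -> GenotypeCall:
    """Call one diploid genotype from allele read counts.

    Frequencies are computed over all reads at the locus, including noise
    alleles (set ``top_two_only=True`` to renormalise over the two most
    abundant alleles instead).  Ties in read count are broken
    lexicographically on the allele.  A total depth below ``min_depth`` (or
    all-zero counts) yields a missing call; so does the ambiguous gap where
    the top frequency is <= ``major_threshold`` but the second allele is
    below ``het_threshold``.

    When ``panel_alleles`` (major, minor) is given, homozygous calls are
    labelled ``hom_major``/``hom_minor`` relative to the panel, and any call
    involving a non-panel allele becomes missing.  Without panel context the
    state of a homozygous call is ``hom_major``.
    """
    counts = {a: int(c) for a, c in allele_counts.items() if c > 0}
    total = sum(counts.values())
    if total == 0 or total < min_depth:
        return GenotypeCall("missing", (), 0.0, total)
    ranked = sorted(counts, key=lambda a: (-counts[a], a))
    major = ranked[0]
    minor = ranked[1] if len(ranked) > 1 else None
    denom = total
    if top_two_only:
        denom = counts[major] + (counts[minor] if minor else 0)
    f_major = counts[major] / denom
    f_minor = (counts[minor] / denom) if minor else 0.0

    if f_major > major_threshold:
        state, alleles = "hom", (major, major)
    elif f_major >= het_threshold and f_minor >= het_threshold:
        state, alleles = "het", tuple(sorted((major, minor)))
    else:
        return GenotypeCall("missing", (), float(f_major), total)

    if panel_alleles is not None:
        pmaj, pmin = panel_alleles
        if state == "hom":
            if major == pmaj:
                state = "hom_major"
            elif major == pmin:
                state = "hom_minor"
            else:
                return GenotypeCall("missing", (), float(f_major), total)
        else:  # het
            if set(alleles) != {pmaj, pmin}:
                return GenotypeCall("missing", (), float(f_major), total)
    elif state == "hom":
        state = "hom_major"
    return GenotypeCall(state, alleles, float(f_major), total)


_STATE_TO_CODE = {"hom_major": 0, "het": 1, "hom_minor": 2, "missing": MISSING}


@dataclass
class CallReport:
    """Accounting of a matrix-wide calling run."""

    n_calls: int = 0
    n_missing: int = 0
    n_low_depth: int = 0
    n_gap_zone: int = 0
    n_non_panel: int = 0
    non_panel_cells: list[tuple[str, str]] = field(default_factory=list)


def call_matrix(
    depth_table: AlleleDepthTable,
    panel: MarkerPanel,
    major_threshold: float = 0.7,
    het_threshold: float = 0.35,
    min_depth: int = 20,
    top_two_only: bool = False,
) -> tuple[GenotypeMatrix, CallReport]:
    """Call every (sample, locus) cell of a depth table against a panel.

    Calls whose alleles are neither the panel major nor minor are set to
    missing and tallied in the report.
    """
    panel_ids = set(panel.locus_ids)
    unknown = [l for l in depth_table.loci if l not in panel_ids]
    if unknown:
        raise ConfigError(f"depth table loci not in panel: {unknown[:5]}")
    loci = list(depth_table.loci)  # keep the caller's column order
    codes = np.full((len(depth_table.samples), len(loci)), MISSING, dtype=np.int8)
    report = CallReport()
    for j, lid in enumerate(loci):
        locus = panel.get(lid)
        pa = (locus.major_allele, locus.minor_allele)
        for i, s in enumerate(depth_table.samples):
            cell = depth_table.get(s, lid)
            report.n_calls += 1
            # Detect non-panel involvement before the panel filter hides it.
            raw = call_genotype(
                cell, major_threshold, het_threshold, min_depth,
                panel_alleles=None, top_two_only=top_two_only,
            )
            call = call_genotype(
                cell, major_threshold, het_threshold, min_depth,
                panel_alleles=pa, top_two_only=top_two_only,
            )
            codes[i, j] = _STATE_TO_CODE[call.state]
            if call.state == "missing":
                report.n_missing += 1
                total = sum(cell.values())
                if total < min_depth:
                    report.n_low_depth += 1
                elif raw.state != "missing":
                    report.n_non_panel += 1
                    report.non_panel_cells.append((s, lid))
                else:
                    report.n_gap_zone += 1
    return GenotypeMatrix(list(depth_table.samples), loci, codes), report


def count_alleles_from_reads(
    reads_by_sample: Mapping[str, Iterable[str] | str | Path],
    panel: MarkerPanel,
    match_window: int = 15,
) -> tuple[AlleleDepthTable, dict[str, dict[str, int]]]:
    """Tally allele support by exact flank-context matching of reads.

    A read supports allele ``a`` of a locus iff it contains the exact
    substring ``flank_left[-match_window:] + a + flank_right[:match_window]``.
    Reads matching no locus context are counted as unaligned.  Matching is
    exact (no mismatches), so counts are deterministic for fixed input.

    ``reads_by_sample`` maps sample id to either an iterable of read strings
    or a FASTQ path (parsed with pysam).

    Returns the depth table and per-sample read accounting with keys
    ``total``, ``aligned`` and ``target`` (aligned == target here: the only
    alignment this matcher knows is to the target contexts).
    """
    for locus in panel:
        if len(locus.flank_left) < match_window or len(locus.flank_right) < match_window:
            raise ConfigError(
                f"match_window={match_window} exceeds stored flank length "
                f"for {locus.locus_id}"
            )
    contexts = []  # (locus_id, allele, pattern)
    for locus in panel:
        left = locus.flank_left[-match_window:]
        right = locus.flank_right[:match_window]
        for a in "ACGT":
            contexts.append((locus.locus_id, a, left + a + right))
    samples = sorted(reads_by_sample)
    counts: dict[str, dict[str, dict[str, int]]] = {s: {} for s in samples}
    accounting: dict[str, dict[str, int]] = {}
    for s in samples:
        total = matched = 0
        for read in _iter_reads(reads_by_sample[s]):
            total += 1
            hit = False
            for lid, a, pattern in contexts:
                if pattern in read:
                    counts[s].setdefault(lid, {}).setdefault(a, 0)
                    counts[s][lid][a] += 1
                    hit = True
            if hit:
                matched += 1
        accounting[s] = {"total": total, "aligned": matched, "target": matched}
    return (
        AlleleDepthTable(samples=samples, loci=list(panel.locus_ids), counts=counts),
        accounting,
    )


def _iter_reads(source: Iterable[str] | str | Path) -> Iterable[str]:
    if isinstance(source, (str, Path)):
        import pysam

        with pysam.FastxFile(str(source)) as fh:
            for entry in fh:
                yield entry.sequence.upper()
    else:
        for read in source:
            yield str(read).upper()
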