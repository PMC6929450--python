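"""Marker panel design: screening candidate variants for "perfect" SNPs.

A perfect SNP is a panel candidate that is highly informative and safe for
multiplex PCR primer design: high minor allele frequency, little missing
data, little residual heterozygosity (the discovery panel is inbred lines),
strictly biallelic, and with no other segregating site inside the flanking
window on either side.  Loci passing all five screens are emitted as a
:class:`MarkerPanel` with reference flanking sequence attached.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateLocusError, MissingSequenceError

_NUCS = frozenset("ACGT")


@dataclass(frozen=True)
class SnpLocus:
    """A biallelic target SNP with genomic coordinates and flanks.

    ``pos`` is a 1-based reference coordinate.  ``major_allele`` and
    ``minor_allele`` are the two panel alleles ordered by descending
    frequency in the discovery set.
    """

    locus_id: str
    chrom: str
    pos: int
    major_allele: str
    minor_allele: str
    flank_left: str = ""
    flank_right: str = ""

    def __post_init__(self) -> None:
        if self.major_allele == self.minor_allele:
            raise ValueError(f"{self.locus_id}: identical major/minor alleles")
        for a in (self.major_allele, self.minor_allele):
            if a not in _NUCS:
                raise ValueError(f"{self.locus_id}: invalid allele {a!r}")
        for fl in (self.flank_left, self.flank_right):
            if set(fl) - set("ACGTN"):
                raise ValueError(f"{self.locus_id}: invalid flank characters")


@dataclass
class MarkerPanel:
    """An ordered collection of target SNP loci.

    Loci are kept sorted by (chrom, pos); duplicate coordinates and duplicate
    locus ids are rejected.
    """

    loci: list[SnpLocus]
    genome_label: str = ""
    flank_width: int = 100

    def __post_init__(self) -> None:
        self.loci = sorted(self.loci, key=lambda l: (l.chrom, l.pos))
        coords = [(l.chrom, l.pos) for l in self.loci]
        if len(set(coords)) != len(coords):
            raise ValueError("duplicate (chrom, pos) in panel")
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus ids in panel")
        self._by_id = {l.locus_id: l for l in self.loci}

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def get(self, locus_id: str) -> SnpLocus:
        return self._by_id[locus_id]

    def chroms(self) -> list[str]:
        """Chromosome of each locus, in panel order."""
        return [l.chrom for l in self.loci]


@dataclass(frozen=True)
class PerfectSnpCriteria:
    """Thresholds of the five perfect-SNP screens.

    Defaults follow the published screen: MAF > 0.4, missing rate < 0.2,
    heterozygous-call rate < 0.2, invariant 100 bp flanks, exactly 2 alleles.
    """

    maf_min: float = 0.4
    miss_max: float = 0.2
    het_max: float = 0.2
    flank_width: int = 100
    max_alleles: int = 2

    def __post_init__(self) -> None:
        for name in ("maf_min", "miss_max", "het_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.flank_width <= 0:
            raise ValueError("flank_width must be positive")


@dataclass
class CandidateRecord:
    """One candidate variant site with per-sample diploid genotypes.

    ``genotypes`` is an (n_samples, 2) int array of allele indices into
    ``alleles``; -1/-1 marks a missing genotype.
    """

    chrom: str
    pos: int
    alleles: tuple[str, ...]
    genotypes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != 2:
            raise ValueError("genotypes must have shape (n_samples, 2)")


@dataclass
class CandidateVariantSet:
    """All candidate variants of a discovery cohort, with sample ids."""

    samples: list[str]
    records: list[CandidateRecord]

    def __post_init__(self) -> None:
        self._positions_by_chrom: dict[str, np.ndarray] | None = None

    def positions_by_chrom(self) -> dict[str, np.ndarray]:
        """Sorted arrays of every segregating position, per chromosome."""
        if self._positions_by_chrom is None:
            acc: dict[str, list[int]] = {}
            for r in self.records:
                acc.setdefault(r.chrom, []).append(r.pos)
            self._positions_by_chrom = {
                c: np.unique(np.asarray(p, dtype=np.int64)) for c, p in acc.items()
            }
        return self._positions_by_chrom


@dataclass(frozen=True)
class LocusStats:
    """Per-locus screening statistics computed from diploid genotypes."""

    maf: float
    miss_rate: float
    het_rate: float
    n_alleles: int


def evaluate_locus(record: CandidateRecord) -> LocusStats:
    """Compute MAF, missing rate, heterozygosity rate and allele count.

    Each non-missing diploid genotype contributes two allele observations;
    missing genotypes are excluded from the allele-frequency denominator.
    MAF is the smallest frequency among the alleles actually observed.

    Raises
    ------
    DegenerateLocusError
        If every genotype at the locus is missing.
    """
    gt = record.genotypes
    n = gt.shape[0]
    missing = (gt[:, 0] < 0) | (gt[:, 1] < 0)
    n_obs = int(n - missing.sum())
    if n_obs == 0:
        raise DegenerateLocusError(f"{record.chrom}:{record.pos}: all genotypes missing")
    obs = gt[~missing]
    counts = np.bincount(obs.ravel(), minlength=len(record.alleles))
    present = counts[counts > 0]
    freqs = present / present.sum()
    maf = float(freqs.min()) if len(present) > 1 else 0.0
    het = float(np.mean(obs[:, 0] != obs[:, 1]))
    return LocusStats(
        maf=maf,
        miss_rate=float(missing.sum() / n),
        het_rate=het,
        n_alleles=int((counts > 0).sum()),
    )


def flank_is_invariant(
    pos: int, variant_positions: Sequence[int] | np.ndarray, flank_width: int
) -> bool:
    """True iff no other segregating site lies within ``flank_width`` bp.

    The window is two-sided and boundary-inclusive: a variant exactly
    ``flank_width`` bp away disqualifies the locus.  ``variant_positions``
    is the set of all segregating positions on the locus's chromosome; the
    locus's own position is ignored.
    """
    p = np.asarray(variant_positions, dtype=np.int64)
    d = np.abs(p - pos)
    return not bool(np.any((d > 0) & (d <= flank_width)))


def extract_flanks(
    reference: Mapping[str, str], chrom: str, pos: int, flank_width: int
) -> tuple[str, str, bool]:
    """Extract left/right flanking sequence around a 1-based position.

    Returns ``(flank_left, flank_right, truncated)``.  Flanks that run off a
    contig end are padded with ``N`` on the outside and flagged truncated.

    Raises
    ------
    MissingSequenceError
        If ``chrom`` is absent from the reference.
    """
    if chrom not in reference:
        raise MissingSequenceError(f"chromosome {chrom!r} not in reference")
    seq = str(reference[chrom]).upper()
    if not 1 <= pos <= len(seq):
        raise MissingSequenceError(f"{chrom}:{pos} outside contig of length {len(seq)}")
    lo = pos - 1 - flank_width
    left = seq[max(lo, 0) : pos - 1]
    right = seq[pos : pos + flank_width]
    truncated = False
    if len(left) < flank_width:
        left = "N" * (flank_width - len(left)) + left
        truncated = True
    if len(right) < flank_width:
        right = right + "N" * (flank_width - len(right))
        truncated = True
    return left, right, truncated


@dataclass
class FilterReport:
    """Outcome of a perfect-SNP screen.

    ``rejections`` counts, per criterion, how many candidates violated it (a
    candidate failing several screens is counted under each).  ``reasons``
    maps each rejected candidate's ``chrom:pos`` key to the full list of
    violated criteria.
    """

    n_candidates: int
    n_retained: int
    rejections: Counter = field(default_factory=Counter)
    reasons: dict[str, list[str]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def filter_perfect_snps(
    candidates: CandidateVariantSet,
    criteria: PerfectSnpCriteria = PerfectSnpCriteria(),
    reference: Mapping[str, str] | None = None,
    genome_label: str = "",
    id_prefix: str = "SNP",
) -> tuple[MarkerPanel, FilterReport]:
    """Screen candidates with the five perfect-SNP criteria.

    A candidate is retained iff MAF > ``maf_min``, missing rate < ``miss_max``,
    heterozygosity rate < ``het_max``, exactly ``max_alleles`` observed
    alleles, and no other variant within ``flank_width`` bp on either side
    (boundary inclusive).  Major/minor alleles of retained loci are assigned
    by descending observed frequency (lexicographic on ties).  If a reference
    is given, flanks are attached and the reference base at each retained
    position is checked against the locus alleles (mismatch -> warning).

    Returns the (possibly empty) panel and a :class:`FilterReport`.
    """
    if not candidates.records:
        raise ValueError("empty candidate set")
    pos_by_chrom = candidates.positions_by_chrom()
    report = FilterReport(n_candidates=len(candidates.records), n_retained=0)
    retained: list[SnpLocus] = []
    seen_coords: set[tuple[str, int]] = set()
    for rec in candidates.records:
        key = f"{rec.chrom}:{rec.pos}"
        if (rec.chrom, rec.pos) in seen_coords:
            report.warnings.append(f"duplicate candidate at {key}; keeping first")
            continue
        seen_coords.add((rec.chrom, rec.pos))
        stats = evaluate_locus(rec)
        failed: list[str] = []
        if not stats.maf > criteria.maf_min:
            failed.append("maf")
        if not stats.miss_rate < criteria.miss_max:
            failed.append("miss")
        if not stats.het_rate < criteria.het_max:
            failed.append("het")
        if stats.n_alleles != criteria.max_alleles:
            failed.append("n_alleles")
        if not flank_is_invariant(rec.pos, pos_by_chrom[rec.chrom], criteria.flank_width):
            failed.append("flank")
        if failed:
            report.rejections.update(failed)
            report.reasons[key] = failed
            continue
        retained.append(_to_locus(rec, criteria, reference, report))
    # stable ids in (chrom, pos) order
    retained.sort(key=lambda l: (l.chrom, l.pos))
    width = max(3, len(str(len(retained))))
    final = [
        SnpLocus(
            locus_id=f"{id_prefix}{i + 1:0{width}d}",
            chrom=l.chrom,
            pos=l.pos,
            major_allele=l.major_allele,
            minor_allele=l.minor_allele,
            flank_left=l.flank_left,
            flank_right=l.flank_right,
        )
        for i, l in enumerate(retained)
    ]
    report.n_retained = len(final)
    if not final:
        report.warnings.append("no candidate passed all criteria; panel is empty")
        warnings.warn("perfect-SNP screen retained no loci", stacklevel=2)
    return (
        MarkerPanel(final, genome_label=genome_label, flank_width=criteria.flank_width),
        report,
    )


def _to_locus(
    rec: CandidateRecord,
    criteria: PerfectSnpCriteria,
    reference: Mapping[str, str] | None,
    report: FilterReport,
) -> SnpLocus:
    gt = rec.genotypes
    obs = gt[(gt[:, 0] >= 0) & (gt[:, 1] >= 0)]
    counts = np.bincount(obs.ravel(), minlength=len(rec.alleles))
    order = sorted(
        (i for i in range(len(rec.alleles)) if counts[i] > 0),
        key=lambda i: (-counts[i], rec.alleles[i]),
    )
    major, minor = rec.alleles[order[0]], rec.alleles[order[1]]
    left = right = ""
    if reference is not None:
        left, right, truncated = extract_flanks(
            reference, rec.chrom, rec.pos, criteria.flank_width
        )
        if truncated:
            report.warnings.append(f"{rec.chrom}:{rec.pos}: flank truncated, N-padded")
        ref_base = str(reference[rec.chrom])[rec.pos - 1].upper()
        if ref_base not in (major, minor):
            report.warnings.append(
                f"{rec.chrom}:{rec.pos}: reference base {ref_base} is neither "
                f"panel allele ({major}/{minor})"
            )
    return SnpLocus(
        locus_id=f"{rec.chrom}:{rec.pos}",
        chrom=rec.chrom,
        pos=rec.pos,
        major_allele=major,
        minor_allele=minor,
        flank_left=left,
        flank_right=right,
    )
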