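"""Synthetic data with known truth: structured genotypes, noisy allele
read counts, reads, and candidate variant sets with planted panel loci.

The genotype generator uses the Balding–Nichols model: ancestral allele
frequencies are uniform on [0.1, 0.9], each population's frequency is a
Beta((1-F)/F * p, (1-F)/F * (1-p)) draw around the ancestral value with
divergence parameter F (F = 0 means all populations share frequencies), and
diploid genotypes are Binomial(2, p_pop).  Defaults mirror a 271-variety,
92-SNP, five-subpopulation collection with mid-range differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calling import AlleleDepthTable
from .errors import ConfigError
from .matrix import GenotypeMatrix
from .panel import CandidateRecord, CandidateVariantSet, MarkerPanel, SnpLocus

#: Default collection shape: five subpopulations totalling 271 varieties.
DEFAULT_SIZES: tuple[int, ...] = (98, 44, 24, 14, 91)
DEFAULT_N_LOCI: int = 92
DEFAULT_FST: float = 0.25
DEFAULT_MEAN_DEPTH: float = 2064.0

_NUCS = np.array(list("ACGT"))


@dataclass
class SimulationTruth:
    """Ground truth of a structured-genotype simulation."""

    ancestral_freqs: np.ndarray
    pop_freqs: np.ndarray  # (n_pops, n_loci)
    population_labels: dict[str, str]
    fst_star: float
    seed: int


def simulate_structured_genotypes(
    sizes: Sequence[int] = DEFAULT_SIZES,
    n_loci: int = DEFAULT_N_LOCI,
    fst_star: float = DEFAULT_FST,
    seed: int = 0,
    maf_range: tuple[float, float] = (0.1, 0.9),
) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Draw diploid genotypes for structured populations (Balding–Nichols).

    Returns the genotype matrix (codes = minor-allele dosage) and the
    :class:`SimulationTruth` carrying ancestral and per-population allele
    frequencies plus population labels.  Deterministic under ``seed``.
    """
    if not 0.0 <= fst_star < 1.0:
        raise ConfigError("fst_star must be in [0, 1)")
    if any(s < 1 for s in sizes):
        raise ConfigError("population sizes must be >= 1")
    if n_loci < 1:
        raise ConfigError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    n_pops = len(sizes)
    p0 = rng.uniform(*maf_range, size=n_loci)
    if fst_star == 0.0:
        pops = np.tile(p0, (n_pops, 1))
    else:
        c = (1.0 - fst_star) / fst_star
        pops = rng.beta(c * p0, c * (1.0 - p0), size=(n_pops, n_loci))
    codes = np.concatenate(
        [rng.binomial(2, pops[k], size=(sizes[k], n_loci)) for k in range(n_pops)]
    ).astype(np.int8)
    samples = [f"S{i + 1:04d}" for i in range(sum(sizes))]
    loci = [f"SNP{j + 1:03d}" for j in range(n_loci)]
    labels = {}
    start = 0
    for k, sz in enumerate(sizes):
        for s in samples[start : start + sz]:
            labels[s] = f"Pop{k + 1}"
        start += sz
    truth = SimulationTruth(
        ancestral_freqs=p0,
        pop_freqs=pops,
        population_labels=labels,
        fst_star=fst_star,
        seed=seed,
    )
    return GenotypeMatrix(samples, loci, codes), truth


def panel_for_matrix(matrix: GenotypeMatrix, seed: int = 0, flank_width: int = 100) -> MarkerPanel:
    """A synthetic marker panel matching a genotype matrix's loci.

    Alleles and flanks are random but deterministic under ``seed``; loci are
    spread over 12 chromosomes in round-robin order, mimicking a genome-wide
    panel layout.
    """
    rng = np.random.default_rng(seed)
    loci = []
    pos_counter: dict[str, int] = {}
    for j, lid in enumerate(matrix.loci):
        chrom = f"chr{j % 12 + 1:02d}"
        pos_counter[chrom] = pos_counter.get(chrom, 0) + 10_000
        major, minor = rng.choice(_NUCS, size=2, replace=False)
        left = "".join(rng.choice(_NUCS, size=flank_width))
        right = "".join(rng.choice(_NUCS, size=flank_width))
        loci.append(
            SnpLocus(
                locus_id=lid,
                chrom=chrom,
                pos=pos_counter[chrom],
                major_allele=str(major),
                minor_allele=str(minor),
                flank_left=left,
                flank_right=right,
            )
        )
    return MarkerPanel(loci, genome_label="synthetic", flank_width=flank_width)


def simulate_allele_counts(
    matrix: GenotypeMatrix,
    panel: MarkerPanel,
    mean_depth: float = DEFAULT_MEAN_DEPTH,
    error_rate: float = 0.01,
    dispersion: float = 10.0,
    seed: int = 0,
) -> AlleleDepthTable:
    """Noisy amplicon read counts for every (sample, locus) cell.

    Depth is negative-binomial with the given mean and dispersion (gamma
    shape); reads are multinomial over the four nucleotides with mass
    ``1 - error_rate`` on the true allele(s) (split evenly for hets) and the
    error mass spread evenly over the remaining nucleotides.
    """
    if mean_depth <= 0:
        raise ConfigError("mean_depth must be positive")
    if not 0.0 <= error_rate < 0.5:
        raise ConfigError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    nuc_index = {n: i for i, n in enumerate("ACGT")}
    counts: dict[str, dict[str, dict[str, int]]] = {s: {} for s in matrix.samples}
    p_nb = dispersion / (dispersion + mean_depth)
    for j, lid in enumerate(matrix.loci):
        locus = panel.get(lid)
        probs_by_code = {}
        for code in (0, 1, 2):
            p = np.zeros(4)
            if code == 0:
                true = [nuc_index[locus.major_allele]]
            elif code == 2:
                true = [nuc_index[locus.minor_allele]]
            else:
                true = [nuc_index[locus.major_allele], nuc_index[locus.minor_allele]]
            for t in true:
                p[t] = (1.0 - error_rate) / len(true)
            others = [i for i in range(4) if i not in true]
            for o in others:
                p[o] = error_rate / len(others)
            probs_by_code[code] = p
        for i, s in enumerate(matrix.samples):
            code = int(matrix.codes[i, j])
            depth = int(rng.negative_binomial(dispersion, p_nb))
            if code == -1 or depth == 0:
                continue
            draw = rng.multinomial(depth, probs_by_code[code])
            cell = {str(_NUCS[k]): int(c) for k, c in enumerate(draw) if c > 0}
            if cell:
                counts[s][lid] = cell
    return AlleleDepthTable(samples=list(matrix.samples), loci=list(matrix.loci), counts=counts)


def simulate_reads(
    matrix: GenotypeMatrix,
    panel: MarkerPanel,
    reads_per_locus: int = 30,
    match_window: int = 15,
    n_offtarget: int = 5,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Synthetic demultiplexed reads embedding each locus's flank context.

    Each read carries ``match_window`` bp of flank on both sides of the
    sampled allele, padded with random sequence; ``n_offtarget`` random
    reads per sample emulate off-target amplification.
    """
    rng = np.random.default_rng(seed)
    reads: dict[str, list[str]] = {}
    for i, s in enumerate(matrix.samples):
        sample_reads: list[str] = []
        for j, lid in enumerate(matrix.loci):
            code = int(matrix.codes[i, j])
            if code == -1:
                continue
            locus = panel.get(lid)
            alleles = {
                0: [locus.major_allele],
                1: [locus.major_allele, locus.minor_allele],
                2: [locus.minor_allele],
            }[code]
            for _ in range(reads_per_locus):
                a = alleles[int(rng.integers(len(alleles)))]
                core = (
                    locus.flank_left[-match_window:] + a + locus.flank_right[:match_window]
                )
                pad_l = "".join(rng.choice(_NUCS, size=10))
                pad_r = "".join(rng.choice(_NUCS, size=10))
                sample_reads.append(pad_l + core + pad_r)
        for _ in range(n_offtarget):
            sample_reads.append("".join(rng.choice(_NUCS, size=2 * match_window + 21)))
        reads[s] = sample_reads
    return reads


@dataclass
class ToyPanelTruth:
    """Planted candidate set with the ids expected to pass the screen."""

    reference: dict[str, str]
    candidates: CandidateVariantSet
    expected_positions: list[tuple[str, int]]  # loci that must be retained
    category: dict[tuple[str, int], str]  # position -> planted category


def make_toy_panel(
    n_perfect: int = 10,
    n_maf_fail: int = 5,
    n_miss_fail: int = 0,
    n_het_fail: int = 0,
    n_flank_fail: int = 5,
    n_multiallelic: int = 0,
    n_samples: int = 35,
    flank_width: int = 100,
    spacing: int = 400,
    seed: int = 0,
) -> ToyPanelTruth:
    """Reference + candidate VCF-style set where a known subset is perfect.

    Candidates are spaced ``spacing`` bp apart (> 2x the flank window) on a
    single synthetic contig, so only deliberately planted neighbours violate
    the flank-invariance screen.  Each flank-failing locus is paired with a
    companion variant 50 bp away; the companion is given a failing MAF so
    the retained set is exactly the perfect loci.
    """
    if spacing <= 2 * flank_width:
        raise ConfigError("spacing must exceed twice the flank width")
    if n_samples < 10:
        raise ConfigError("need at least 10 discovery samples")
    rng = np.random.default_rng(seed)
    plan: list[str] = (
        ["perfect"] * n_perfect
        + ["maf"] * n_maf_fail
        + ["miss"] * n_miss_fail
        + ["het"] * n_het_fail
        + ["flank"] * n_flank_fail
        + ["multi"] * n_multiallelic
    )
    if not plan:
        plan = []
    records: list[CandidateRecord] = []
    category: dict[tuple[str, int], str] = {}
    expected: list[tuple[str, int]] = []
    chrom = "chr01"
    contig_length = spacing * (len(plan) + 2) + 2 * flank_width
    seq = rng.choice(_NUCS, size=contig_length)
    pos = flank_width + spacing
    for kind in plan:
        alleles = tuple(rng.choice(_NUCS, size=2, replace=False))
        if kind == "perfect":
            gt = _genotypes(n_samples, maf=0.45, miss=0.0, het=0.1, rng=rng)
            expected.append((chrom, pos))
        elif kind == "maf":
            gt = _genotypes(n_samples, maf=0.2, miss=0.0, het=0.1, rng=rng)
        elif kind == "miss":
            gt = _genotypes(n_samples, maf=0.45, miss=0.4, het=0.1, rng=rng)
        elif kind == "het":
            gt = _genotypes(n_samples, maf=0.45, miss=0.0, het=0.4, rng=rng)
        elif kind == "flank":
            gt = _genotypes(n_samples, maf=0.45, miss=0.0, het=0.1, rng=rng)
        else:  # multi
            alleles = tuple(rng.choice(_NUCS, size=3, replace=False))
            gt = _genotypes(n_samples, maf=0.45, miss=0.0, het=0.1, rng=rng)
            # recode a few homozygotes to the third allele
            hom = np.nonzero((gt[:, 0] == gt[:, 1]) & (gt[:, 0] == 0))[0]
            gt[hom[:2]] = 2
        seq[pos - 1] = alleles[0]  # reference base = major allele
        records.append(CandidateRecord(chrom, pos, alleles, gt))
        category[(chrom, pos)] = kind
        if kind == "flank":
            # companion variant 50 bp away breaks the flank screen for both;
            # it also fails MAF so it can never be retained itself
            npos = pos + 50
            nall = tuple(rng.choice(_NUCS, size=2, replace=False))
            ngt = _genotypes(n_samples, maf=0.15, miss=0.0, het=0.1, rng=rng)
            seq[npos - 1] = nall[0]
            records.append(CandidateRecord(chrom, npos, nall, ngt))
            category[(chrom, npos)] = "flank_companion"
        pos += spacing
    samples = [f"L{i + 1:03d}" for i in range(n_samples)]
    return ToyPanelTruth(
        reference={chrom: "".join(seq)},
        candidates=CandidateVariantSet(samples=samples, records=records),
        expected_positions=expected,
        category=category,
    )


def _genotypes(
    n: int, maf: float, miss: float, het: float, rng: np.random.Generator
) -> np.ndarray:
    """Deterministic-count diploid genotypes hitting target maf/miss/het.

    Counts are rounded so the realised rates sit at (or just below) the
    requested values; allele index 0 is the major allele.
    """
    n_miss = int(round(miss * n))
    n_obs = n - n_miss
    n_het = int(round(het * n_obs))
    # minor allele count among 2*n_obs alleles
    n_minor = int(round(maf * 2 * n_obs))
    n_hom_minor = max((n_minor - n_het) // 2, 0)
    n_hom_major = n_obs - n_het - n_hom_minor
    gt = np.full((n, 2), -1, dtype=np.int16)
    rows = rng.permutation(n)
    k = 0
    for _ in range(n_hom_major):
        gt[rows[k]] = (0, 0)
        k += 1
    for _ in range(n_het):
        gt[rows[k]] = (0, 1)
        k += 1
    for _ in range(n_hom_minor):
        gt[rows[k]] = (1, 1)
        k += 1
    return gt
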