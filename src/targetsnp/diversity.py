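"""Per-locus and per-population genetic diversity statistics.

For a locus with allele frequencies :math:`P_1, \\dots, P_l`:

- minor allele frequency MAF = smallest observed allele frequency;
- observed heterozygosity Ho = heterozygous calls / non-missing calls;
- expected heterozygosity (Nei's gene diversity) He = :math:`1 - \\sum P_i^2`,
  without small-sample correction;
- polymorphism information content
  PIC = :math:`1 - \\sum P_i^2 - \\sum_{i<j} 2 P_i^2 P_j^2`.

For a biallelic locus PIC = He - 2 p^2 q^2 <= He, with maxima He = 0.5 and
PIC = 0.375 at p = q = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateLocusError
from .matrix import MISSING, GenotypeMatrix


def allele_freqs(
    matrix: GenotypeMatrix,
    locus: str | int,
    sample_subset: Sequence[str] | None = None,
) -> np.ndarray:
    """Frequencies (major-coded allele, minor-coded allele) at one locus.

    Each non-missing diploid sample contributes two alleles.  Frequencies
    sum to 1 over the two panel alleles (the code-0 allele first).

    Raises
    ------
    DegenerateLocusError
        If all genotypes in the subset are missing.
    """
    j = locus if isinstance(locus, int) else matrix.locus_index(locus)
    codes = matrix.codes[:, j]
    if sample_subset is not None:
        idx = [matrix.sample_index(s) for s in sample_subset]
        codes = codes[idx]
    obs = codes[codes != MISSING]
    if obs.size == 0:
        raise DegenerateLocusError(f"locus {locus}: all genotypes missing")
    p_minor = float(obs.sum() / (2 * obs.size))
    return np.array([1.0 - p_minor, p_minor])


def pic(freqs: Sequence[float]) -> float:
    """Polymorphism information content of an allele-frequency vector."""
    p = np.asarray(freqs, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("allele frequencies must sum to 1")
    p2 = p**2
    cross = np.sum(np.outer(p2, p2)) - np.sum(p2**2)  # 2 * sum_{i<j} Pi^2 Pj^2
    return float(1.0 - p2.sum() - cross)


def expected_het(freqs: Sequence[float]) -> float:
    """Nei's gene diversity He = 1 - sum p_i^2 (no sample-size correction)."""
    p = np.asarray(freqs, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("allele frequencies must sum to 1")
    return float(1.0 - np.sum(p**2))


def observed_het(
    matrix: GenotypeMatrix,
    locus: str | int,
    sample_subset: Sequence[str] | None = None,
) -> float:
    """Fraction of heterozygous calls among non-missing calls at a locus."""
    j = locus if isinstance(locus, int) else matrix.locus_index(locus)
    codes = matrix.codes[:, j]
    if sample_subset is not None:
        idx = [matrix.sample_index(s) for s in sample_subset]
        codes = codes[idx]
    obs = codes[codes != MISSING]
    if obs.size == 0:
        raise DegenerateLocusError(f"locus {locus}: all genotypes missing")
    return float(np.mean(obs == 1))


@dataclass
class DiversitySummary:
    """Locus-level and population-level diversity tables.

    ``per_locus`` has one row per (population, locus) plus an ``ALL``
    population covering every sample, with columns maf, ho, he, pic and
    n_used (non-missing samples).  ``per_population`` averages those
    statistics per population and counts monomorphic loci (PIC = 0).
    """

    per_locus: pd.DataFrame
    per_population: pd.DataFrame
    small_populations: list[str]


def summarize(
    matrix: GenotypeMatrix,
    population_labels: Mapping[str, str] | None = None,
) -> DiversitySummary:
    """Per-locus and per-population MAF/Ho/He/PIC summary.

    ``population_labels`` maps every sample to a population name; pass None
    for a single undivided collection.  Loci with no data inside a
    population get NaN statistics and n_used = 0.  Populations with fewer
    than two samples are flagged (statistics still computed).
    """
    if population_labels is None:
        population_labels = {s: "ALL" for s in matrix.samples}
    unlabeled = [s for s in matrix.samples if s not in population_labels]
    if unlabeled:
        raise ValueError(f"samples without population label: {unlabeled[:5]}")
    pops = sorted(set(population_labels[s] for s in matrix.samples))
    groups: dict[str, list[str]] = {p: [] for p in pops}
    for s in matrix.samples:
        groups[population_labels[s]].append(s)
    scopes = [("ALL", list(matrix.samples))] + [(p, groups[p]) for p in pops if p != "ALL"]

    rows = []
    for pop, members in scopes:
        idx = [matrix.sample_index(s) for s in members]
        sub = matrix.codes[idx]
        for j, lid in enumerate(matrix.loci):
            codes = sub[:, j]
            obs = codes[codes != MISSING]
            if obs.size == 0:
                rows.append(
                    dict(population=pop, locus=lid, maf=np.nan, ho=np.nan,
                         he=np.nan, pic=np.nan, n_used=0)
                )
                continue
            p_minor = float(obs.sum() / (2 * obs.size))
            freqs = np.array([1.0 - p_minor, p_minor])
            rows.append(
                dict(
                    population=pop,
                    locus=lid,
                    maf=float(freqs.min()),
                    ho=float(np.mean(obs == 1)),
                    he=expected_het(freqs),
                    pic=pic(freqs),
                    n_used=int(obs.size),
                )
            )
    per_locus = pd.DataFrame(rows)

    pop_rows = []
    for pop, members in scopes:
        block = per_locus[per_locus["population"] == pop]
        valid = block.dropna(subset=["maf"])
        pop_rows.append(
            dict(
                population=pop,
                n_samples=len(members),
                maf=valid["maf"].mean(),
                ho=valid["ho"].mean(),
                he=valid["he"].mean(),
                pic=valid["pic"].mean(),
                n_monomorphic=int((valid["pic"] == 0).sum()),
            )
        )
    per_population = pd.DataFrame(pop_rows).set_index("population")
    small = [p for p, m in scopes if p != "ALL" and len(m) < 2]
    return DiversitySummary(per_locus=per_locus, per_population=per_population,
                            small_populations=small)
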