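"""Diploid genotype matrix container.

Genotypes at biallelic loci are stored as dosage codes: 0 = homozygous for
the major (panel reference) allele, 1 = heterozygous, 2 = homozygous for the
minor allele.  Missing calls use the sentinel :data:`MISSING` (-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

#: Sentinel dosage code for a missing genotype call.
MISSING: int = -1

_VALID_CODES = frozenset({-1, 0, 1, 2})


@dataclass
class GenotypeMatrix:
    """Samples x loci matrix of diploid dosage codes.

    Parameters
    ----------
    samples : list of str
        Sample (variety) identifiers, one per row.
    loci : list of str
        Locus identifiers, one per column.
    codes : ndarray of int8, shape (n_samples, n_loci)
        Dosage codes in {0, 1, 2} with -1 for missing.
    """

    samples: list[str]
    loci: list[str]
    codes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.samples), len(self.loci)):
            raise ConfigError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        bad = set(np.unique(self.codes)) - _VALID_CODES
        if bad:
            raise ConfigError(f"invalid dosage codes present: {sorted(bad)}")
        if len(set(self.samples)) != len(self.samples):
            raise ConfigError("duplicate sample ids")
        if len(set(self.loci)) != len(self.loci):
            raise ConfigError("duplicate locus ids")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, locus_id: str) -> int:
        try:
            return self.loci.index(locus_id)
        except ValueError:
            raise KeyError(f"unknown locus {locus_id!r}") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), list(self.loci), self.codes[idx])

    def subset_loci(self, locus_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.locus_index(l) for l in locus_ids]
        return GenotypeMatrix(list(self.samples), list(locus_ids), self.codes[:, idx])

    def missing_mask(self) -> np.ndarray:
        """Boolean mask of missing cells."""
        return self.codes == MISSING
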