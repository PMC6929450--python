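"""Greedy core-marker selection by pairwise discrimination.

For every SNP i and every unordered sample pair j, :math:`X_{ij} = 1` if
the two samples carry different (both non-missing) genotypes at that SNP.
The first core SNP maximises :math:`\\sum_j X_{ij}`; each later step adds
the SNP resolving the most still-unresolved pairs, preferring on ties a SNP
from a chromosome not yet in the set, then the lowest panel index.  The
saturation curve tracks the discrimination power — the fraction of samples
whose multilocus genotype over the selected subset is unique — after each
step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .matrix import MISSING, GenotypeMatrix


def n_pairs(n_samples: int) -> int:
    """Number of unordered sample pairs, n(n-1)/2."""
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    return n_samples * (n_samples - 1) // 2


def pair_distinguished(
    matrix: GenotypeMatrix, snp: str | int, sample_a: str | int, sample_b: str | int
) -> int:
    """1 iff the two samples have unequal, both non-missing codes at the SNP.

    A missing call on either side cannot certify a difference and counts 0.
    """
    j = snp if isinstance(snp, int) else matrix.locus_index(snp)
    a = sample_a if isinstance(sample_a, int) else matrix.sample_index(sample_a)
    b = sample_b if isinstance(sample_b, int) else matrix.sample_index(sample_b)
    ca, cb = matrix.codes[a, j], matrix.codes[b, j]
    return int(ca != MISSING and cb != MISSING and ca != cb)


def _pair_difference_matrix(codes: np.ndarray) -> np.ndarray:
    """Boolean (n_snps, n_pairs) matrix of certified pairwise differences."""
    n, m = codes.shape
    ia, ib = np.triu_indices(n, k=1)
    a, b = codes[ia], codes[ib]  # (n_pairs, n_snps)
    diff = (a != b) & (a != MISSING) & (b != MISSING)
    return diff.T.copy()


def discrimination_power(codes_or_matrix, snp_subset: Sequence[int] | None = None) -> float:
    """Fraction of samples with a unique multilocus genotype over a subset.

    Genotype vectors are compared by strict equality, missing included.
    """
    codes = codes_or_matrix.codes if isinstance(codes_or_matrix, GenotypeMatrix) else np.asarray(codes_or_matrix)
    if snp_subset is not None:
        if len(snp_subset) == 0:
            raise ValueError("snp_subset must be non-empty")
        codes = codes[:, list(snp_subset)]
    _, inverse, counts = np.unique(codes, axis=0, return_inverse=True, return_counts=True)
    unique = counts[inverse] == 1
    return float(unique.mean())


@dataclass
class SelectionResult:
    """Ordered core-SNP set with its saturation curve.

    ``curve[t]`` is the discrimination power after step t+1;
    ``pairs_resolved[t]`` the cumulative count of certified-different pairs.
    """

    ordered_snps: list[str]
    ordered_idx: list[int]
    curve: list[float]
    pairs_resolved: list[int]
    tie_events: list[dict] = field(default_factory=list)
    saturated: bool = False
    total_pairs: int = 0
    full_panel_pairs: int = 0


def greedy_select(
    matrix: GenotypeMatrix,
    chroms: Sequence[str] | None = None,
    k_max: int | None = None,
) -> SelectionResult:
    """Stepwise greedy selection of a discriminating SNP subset.

    Stops when no remaining SNP resolves a new pair (saturation) or after
    ``k_max`` SNPs.  ``chroms`` gives each SNP's chromosome for the
    new-chromosome tie preference; omit it to fall back to lowest-index
    tie-breaking only.
    """
    codes = matrix.codes
    n, m = codes.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    D = _pair_difference_matrix(codes)
    total = n_pairs(n)
    full_panel = int(np.any(D, axis=0).sum())
    resolved = np.zeros(total, dtype=bool)
    chosen: list[int] = []
    chosen_chroms: set[str] = set()
    result = SelectionResult([], [], [], [], total_pairs=total, full_panel_pairs=full_panel)
    remaining = set(range(m))
    while remaining and (k_max is None or len(chosen) < k_max):
        gains = {s: int(np.sum(D[s] & ~resolved)) for s in remaining}
        best_gain = max(gains.values())
        if best_gain == 0 and chosen:
            result.saturated = True
            break
        cands = sorted(s for s, g in gains.items() if g == best_gain)
        pick = cands[0]
        if len(cands) > 1:
            rule = "lowest_index"
            if chroms is not None:
                fresh = [s for s in cands if chroms[s] not in chosen_chroms]
                if fresh and len(fresh) < len(cands):
                    pick = fresh[0]
                    rule = "new_chromosome"
                elif fresh:
                    pick = fresh[0]
            result.tie_events.append(
                {"step": len(chosen) + 1, "candidates": [matrix.loci[s] for s in cands],
                 "picked": matrix.loci[pick], "rule": rule}
            )
        chosen.append(pick)
        remaining.discard(pick)
        if chroms is not None:
            chosen_chroms.add(chroms[pick])
        resolved |= D[pick]
        result.ordered_idx.append(pick)
        result.ordered_snps.append(matrix.loci[pick])
        result.pairs_resolved.append(int(resolved.sum()))
        result.curve.append(discrimination_power(codes, chosen))
        if int(resolved.sum()) == full_panel:
            result.saturated = True
            break
    return result


def exhaustive_minimum(
    matrix: GenotypeMatrix, max_size: int | None = None
) -> tuple[int | None, tuple[int, ...] | None]:
    """Smallest SNP subset matching the full panel's resolved-pair set.

    Brute-force enumeration over all subsets up to ``max_size`` (default:
    panel size); intended as an exactness oracle on small instances.
    Returns (size, subset indices) or (None, None) if no subset within the
    size bound achieves full-panel coverage.
    """
    codes = matrix.codes
    m = codes.shape[1]
    D = _pair_difference_matrix(codes)
    target = np.any(D, axis=0)
    if max_size is None:
        max_size = m
    for k in range(1, max_size + 1):
        for subset in combinations(range(m), k):
            if np.array_equal(np.any(D[list(subset)], axis=0), target):
                return k, subset
    return None, None


@dataclass
class RedundancyGroups:
    """Partition of samples into identical-genotype groups."""

    groups: list[list[str]]
    n_non_redundant: int


def redundancy_groups(
    matrix: GenotypeMatrix, missing_tolerant: bool = False
) -> RedundancyGroups:
    """Group samples sharing the same multilocus genotype.

    Strict mode (default) requires exact vector equality, missing cells
    included.  ``missing_tolerant`` mode treats a missing cell as compatible
    with anything and merges samples connected by pairwise compatibility
    (transitive closure), which can chain distinct genotypes together — it
    is an upper bound on redundancy, not an equivalence of genotypes.
    """
    codes = matrix.codes
    n = codes.shape[0]
    if not missing_tolerant:
        _, inverse = np.unique(codes, axis=0, return_inverse=True)
        buckets: dict[int, list[str]] = {}
        for i, g in enumerate(inverse):
            buckets.setdefault(int(g), []).append(matrix.samples[i])
        groups = sorted(buckets.values(), key=lambda g: matrix.samples.index(g[0]))
    else:
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for k in range(i + 1, n):
                a, b = codes[i], codes[k]
                ok = (a == MISSING) | (b == MISSING) | (a == b)
                if bool(np.all(ok)):
                    parent[find(k)] = find(i)
        buckets = {}
        for i in range(n):
            buckets.setdefault(find(i), []).append(matrix.samples[i])
        groups = sorted(buckets.values(), key=lambda g: matrix.samples.index(g[0]))
    return RedundancyGroups(groups=groups, n_non_redundant=len(groups))


def deduplicate(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Keep the first representative of each identical-genotype group."""
    reps = [g[0] for g in redundancy_groups(matrix).groups]
    return matrix.subset_samples(reps)


class CoreSnpSelector(SelectorMixin, BaseEstimator):
    """scikit-learn feature selector wrapping the greedy core-SNP search.

    Parameters
    ----------
    chroms : sequence of str, optional
        Chromosome label per feature, enabling the new-chromosome tie rule.
    k_max : int, optional
        Maximum number of SNPs to select; default runs to saturation.

    Attributes
    ----------
    support_ : boolean mask of selected features.
    ordering_ : selection order (column indices).
    curve_ : discrimination power after each step.
    result_ : the full :class:`SelectionResult`.
    """

    def __init__(self, chroms: Sequence[str] | None = None, k_max: int | None = None):
        self.chroms = chroms
        self.k_max = k_max

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x SNPs)")
        self.n_features_in_ = X.shape[1]
        gm = GenotypeMatrix(
            [f"s{i}" for i in range(X.shape[0])],
            [f"snp{j}" for j in range(X.shape[1])],
            X.astype(np.int8),
        )
        self.result_ = greedy_select(gm, chroms=self.chroms, k_max=self.k_max)
        self.ordering_ = list(self.result_.ordered_idx)
        self.curve_ = list(self.result_.curve)
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ordering_] = True
        self.support_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
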