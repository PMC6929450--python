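"""Population structure statistics on diploid dosage matrices.

Covers: simple matching distance, neighbor-joining trees, PCA, three-level
AMOVA (among groups / among samples within groups / within samples) with a
label-permutation significance test, and pairwise Fst (Nei 1987 default,
Weir–Cockerham 1984 alternative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import ConfigError
from .matrix import MISSING, GenotypeMatrix

# ---------------------------------------------------------------------------
# distances and trees
# ---------------------------------------------------------------------------


def simple_matching_distance(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise fraction of loci at which two genotype vectors differ.

    d(a, b) = (# loci with unequal codes) / (# loci where both are
    non-missing).  Pairs sharing no scored locus are undefined; they are set
    to 1.0 with a warning.
    """
    codes = matrix.codes
    n = codes.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    obs = codes != MISSING
    shared = (obs.astype(np.int32) @ obs.T.astype(np.int32)).astype(float)
    # mismatches over shared loci
    D = np.zeros((n, n))
    for i in range(n):
        both = obs[i] & obs
        diff = (codes[i] != codes) & both
        D[i] = diff.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(shared > 0, D / shared, np.nan)
    undefined = np.isnan(D)
    np.fill_diagonal(undefined, False)
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum()) // 2} sample pairs share no scored loci; "
            "distance set to 1.0",
            stacklevel=2,
        )
        D[undefined] = 1.0
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=matrix.samples, columns=matrix.samples)


def nj_tree(distances: pd.DataFrame) -> str:
    """Neighbor-joining (Saitou–Nei) tree as a newick string.

    Negative branch lengths produced by the NJ update are clamped to zero
    and the deficit transferred to the sister branch (standard convention).
    Requires at least 3 taxa.
    """
    labels = list(distances.index)
    n = len(labels)
    if n < 3:
        raise ValueError("NJ needs at least 3 taxa")
    D = np.asarray(distances, dtype=float).copy()
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    nodes = [_escape(l) for l in labels]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_s, j_s = np.unravel_index(np.argmin(Q), Q.shape)
        if i_s > j_s:
            i_s, j_s = j_s, i_s
        i, j = active[i_s], active[j_s]
        dij = sub[i_s, j_s]
        li = 0.5 * dij + (r[i_s] - r[j_s]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp_transfer(li, lj)
        # distances from the new node to every other active node
        dnew = 0.5 * (D[i, active] + D[j, active] - dij)
        D = np.vstack([D, np.zeros((1, D.shape[1]))])
        D = np.hstack([D, np.zeros((D.shape[0], 1))])
        new = D.shape[0] - 1
        for k_s, k in enumerate(active):
            D[new, k] = D[k, new] = max(dnew[k_s], 0.0)
        nodes.append(f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})")
        active = [k for k in active if k not in (i, j)] + [new]
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    return f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g},{nodes[c]}:{lc:.10g});"


def _clamp_transfer(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def _escape(label: str) -> str:
    if any(c in label for c in "(),:; \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    coordinates: pd.DataFrame
    explained_variance_ratio: np.ndarray


def pca(matrix: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """PCA of the dosage matrix: locus-mean imputation then centering.

    Missing cells are replaced by their locus mean before the
    eigendecomposition; variance-explained fractions sum to <= 1.  A matrix
    with no variance yields all-zero coordinates and a warning.
    """
    codes = matrix.codes.astype(float)
    if codes.shape[0] < 2 or codes.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 loci")
    X = codes.copy()
    miss = matrix.missing_mask()
    if miss.any():
        col_mean = np.nanmean(np.where(miss, np.nan, X), axis=0)
        col_mean = np.nan_to_num(col_mean)  # all-missing locus -> 0
        X[miss] = np.take(col_mean, np.nonzero(miss)[1])
    X -= X.mean(axis=0)
    n_components = min(n_components, min(X.shape) - 1) or 1
    if not np.any(X):
        warnings.warn("constant genotype matrix; PCA components are zero", stacklevel=2)
        coords = np.zeros((codes.shape[0], n_components))
        ratio = np.zeros(n_components)
    else:
        model = PCA(n_components=n_components, svd_solver="full")
        coords = model.fit_transform(X)
        ratio = model.explained_variance_ratio_
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PcaResult(
        coordinates=pd.DataFrame(coords, index=matrix.samples, columns=cols),
        explained_variance_ratio=np.asarray(ratio),
    )


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


@dataclass
class AmovaResult:
    """Three-level hierarchical AMOVA.

    Rows of ``table``: among_groups, among_samples_within_groups,
    within_samples, total; columns: df, sum_of_squares, mean_square,
    variance_component (raw), variance_clamped, percent (from clamped
    components).  ``phi`` holds Phi_ST, Phi_IS, Phi_IT.
    """

    table: pd.DataFrame
    phi: dict[str, float]
    n_loci_used: int
    degenerate: bool = False


def _amova_ss(codes: np.ndarray, groups: np.ndarray) -> tuple[float, float, float, float]:
    """Sums of squares for the three-level decomposition.

    Works on the implicit 2N haplotypes of N diploid samples; the distance
    between two haplotypes is the number of differing alleles, which for
    binary allele indicators equals the squared Euclidean distance, so the
    SS of a haplotype set is the usual moment form
    ``sum_l [T_l - T_l^2 / n]`` with T_l the allele-1 count.
    """
    n = codes.shape[0]
    t = codes.astype(float)  # per-sample alt dosage (0/1/2)
    T = t.sum(axis=0)  # total alt alleles per locus
    ss_total = float(np.sum(T - T**2 / (2 * n)))
    ss_within_groups = 0.0
    for g in np.unique(groups):
        sub = t[groups == g]
        Tg = sub.sum(axis=0)
        ss_within_groups += float(np.sum(Tg - Tg**2 / (2 * sub.shape[0])))
    # within one individual: SS of its two haplotypes = 0.5 * (#het loci)
    ss_within_ind = 0.5 * float(np.sum(codes == 1))
    ss_among_ind = ss_within_groups - ss_within_ind
    ss_among_groups = ss_total - ss_within_groups
    return ss_among_groups, ss_among_ind, ss_within_ind, ss_total


def amova(
    matrix: GenotypeMatrix, strata: Mapping[str, str]
) -> AmovaResult:
    """Excoffier-style AMOVA: among groups / among samples / within samples.

    The molecular distance is the number of differing alleles between
    genotypes, which places residual heterozygosity in the within-sample
    stratum.  Loci with any missing call are excluded.  Negative variance
    components are clamped to zero before percentages; raw values are kept
    in the table.
    """
    groups = np.asarray([strata[s] for s in matrix.samples])
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ConfigError("AMOVA needs at least 2 groups")
    keep = ~matrix.missing_mask().any(axis=0)
    codes = matrix.codes[:, keep].astype(np.int16)
    n_loci = int(keep.sum())
    if n_loci == 0:
        raise ConfigError("no loci without missing data")
    N = codes.shape[0]
    a = len(uniq)
    ss_ag, ss_ai, ss_wi, ss_total = _amova_ss(codes, groups)
    df = np.array([a - 1, N - a, N, 2 * N - 1], dtype=float)
    ss = np.array([ss_ag, ss_ai, ss_wi, ss_total])
    with np.errstate(invalid="ignore", divide="ignore"):
        ms = np.where(df > 0, ss / df, np.nan)
    sizes = np.array([(groups == g).sum() for g in uniq], dtype=float)
    # expected-mean-square coefficients; with 2 haplotypes per individual the
    # among-individual coefficient is exactly 2 at both levels
    n_cc = (2 * N - np.sum((2 * sizes) ** 2) / (2 * N)) / (a - 1)
    sigma_wi = ms[2]
    sigma_ai = (ms[1] - ms[2]) / 2.0
    sigma_ag = (ms[0] - ms[1]) / n_cc if not np.isnan(ms[0]) else np.nan
    raw = np.array([sigma_ag, sigma_ai, sigma_wi])
    clamped = np.clip(raw, 0.0, None)
    total_var = clamped.sum()
    degenerate = not total_var > 0
    if degenerate:
        warnings.warn("zero total variance; AMOVA percentages undefined", stacklevel=2)
        pct = np.full(3, np.nan)
    else:
        pct = 100.0 * clamped / total_var
    table = pd.DataFrame(
        {
            "df": np.append(df[:3], df[3]),
            "sum_of_squares": ss,
            "mean_square": ms,
            "variance_component": np.append(raw, raw.sum()),
            "variance_clamped": np.append(clamped, clamped.sum()),
            "percent": np.append(pct, np.nansum(pct) if not degenerate else np.nan),
        },
        index=[
            "among_groups",
            "among_samples_within_groups",
            "within_samples",
            "total",
        ],
    )
    if degenerate:
        phi = {"phi_st": np.nan, "phi_is": np.nan, "phi_it": np.nan}
    else:
        phi = {
            "phi_st": float(clamped[0] / total_var),
            "phi_is": float(clamped[1] / (clamped[1] + clamped[2]))
            if (clamped[1] + clamped[2]) > 0
            else np.nan,
            "phi_it": float((clamped[0] + clamped[1]) / total_var),
        }
    return AmovaResult(table=table, phi=phi, n_loci_used=n_loci, degenerate=degenerate)


@dataclass
class RandomizationResult:
    observed: float
    permuted: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    statistic: str


def randomization_test(
    matrix: GenotypeMatrix,
    strata: Mapping[str, str],
    statistic: str = "sigma_among",
    n_perm: int = 999,
    seed: int = 0,
) -> RandomizationResult:
    """Permutation test of among-group differentiation.

    Sample-to-group labels are permuted (group sizes preserved) and the
    chosen statistic — ``sigma_among`` (raw among-group variance component)
    or ``phi_st`` — recomputed; p = (1 + #{perm >= observed}) / (n_perm + 1).
    The permutation distribution is returned for plotting.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    if statistic not in ("sigma_among", "phi_st"):
        raise ConfigError(f"unknown statistic {statistic!r}")

    def stat(strata_map: Mapping[str, str]) -> float:
        res = amova(matrix, strata_map)
        if statistic == "sigma_among":
            return float(res.table.loc["among_groups", "variance_component"])
        return res.phi["phi_st"]

    observed = stat(strata)
    rng = np.random.default_rng(seed)
    labels = np.asarray([strata[s] for s in matrix.samples])
    permuted = np.empty(n_perm)
    for k in range(n_perm):
        shuffled = rng.permutation(labels)
        permuted[k] = stat(dict(zip(matrix.samples, shuffled)))
    p = (1.0 + np.sum(permuted >= observed)) / (n_perm + 1.0)
    return RandomizationResult(
        observed=float(observed),
        permuted=permuted,
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
        statistic=statistic,
    )


# ---------------------------------------------------------------------------
# Fst
# ---------------------------------------------------------------------------


@dataclass
class FstResult:
    """Pairwise Fst matrices: raw estimates and a clamped-at-zero copy."""

    raw: pd.DataFrame
    clamped: pd.DataFrame
    estimator: str
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)


def _pop_stats(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (n individuals, alt freq, observed het) for one population."""
    obs = codes != MISSING
    n = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, codes, 0).sum(axis=0) / (2 * n)
        h = np.where(obs, codes == 1, False).sum(axis=0) / n
    return n, p, h


def _nei_fst_pair(ca: np.ndarray, cb: np.ndarray) -> float:
    """Nei (1987) Fst for two populations with sample-size correction.

    Per locus: Hs = nt/(nt-1) * (1 - mean_s sum_a p_sa^2 - Ho/(2 nt)) with nt
    the harmonic mean sample size; Ht = 1 - sum_a pbar_a^2 + Hs/(2 nt) -
    Ho/(4 nt).  Fst = (mean Ht - mean Hs) / mean Ht over loci polymorphic in
    the pair.
    """
    na, pa, ha = _pop_stats(ca)
    nb, pb, hb = _pop_stats(cb)
    ok = (na > 1) & (nb > 1)
    poly = ok & ~(((pa <= 0) & (pb <= 0)) | ((pa >= 1) & (pb >= 1)))
    if not poly.any():
        return np.nan
    pa, pb, ha, hb, na, nb = (x[poly] for x in (pa, pb, ha, hb, na, nb))
    nt = 2.0 / (1.0 / na + 1.0 / nb)
    mho = (ha + hb) / 2.0
    msp2 = ((pa**2 + (1 - pa) ** 2) + (pb**2 + (1 - pb) ** 2)) / 2.0
    hs = nt / (nt - 1.0) * (1.0 - msp2 - mho / (2.0 * nt))
    pbar = (pa + pb) / 2.0
    ht = 1.0 - (pbar**2 + (1 - pbar) ** 2) + hs / (2.0 * nt) - mho / (4.0 * nt)
    mht = float(np.mean(ht))
    if mht <= 0:
        return np.nan
    return float((mht - np.mean(hs)) / mht)


def _wc_theta(blocks: list[np.ndarray]) -> float:
    """Weir–Cockerham (1984) theta over r populations, ratio of sums."""
    r = len(blocks)
    stats = [_pop_stats(c) for c in blocks]
    ok = np.all([s[0] > 0 for s in stats], axis=0)
    ns = np.stack([s[0] for s in stats])[:, ok]
    ps = np.stack([s[1] for s in stats])[:, ok]
    hs = np.stack([s[2] for s in stats])[:, ok]
    nbar = ns.mean(axis=0)
    nc = (r * nbar - (ns**2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (ns * ps).sum(axis=0) / (r * nbar)
    s2 = (ns * (ps - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (ns * hs).sum(axis=0) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (
            nbar
            / nc
            * (
                s2
                - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
            )
        )
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
    c = hbar / 2.0
    valid = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = float(np.sum((a + b + c)[valid]))
    if denom == 0:
        return np.nan
    return float(np.sum(a[valid]) / denom)


def pairwise_fst(
    matrix: GenotypeMatrix,
    pops: Mapping[str, str],
    estimator: str = "nei",
) -> FstResult:
    """Pairwise population Fst.

    ``estimator='nei'`` (default) is Nei 1987 (Ht - Hs)/Ht with two-
    population sample-size-corrected heterozygosities, skipping loci
    monomorphic across the pair — the convention of ``pairwise.neifst``.
    ``estimator='wc'`` is Weir–Cockerham 1984 theta, which estimates the
    divergence parameter of an island/Balding–Nichols model; the two are
    not expected to coincide numerically.
    """
    if estimator not in ("nei", "wc"):
        raise ConfigError(f"unknown estimator {estimator!r}")
    labels = np.asarray([pops[s] for s in matrix.samples])
    names = sorted(set(labels.tolist()))
    small = [g for g in names if (labels == g).sum() < 2]
    if small:
        raise ConfigError(f"populations with <2 samples: {small}")
    k = len(names)
    out = np.zeros((k, k))
    undefined: list[tuple[str, str]] = []
    for i in range(k):
        for j in range(i + 1, k):
            ca = matrix.codes[labels == names[i]]
            cb = matrix.codes[labels == names[j]]
            if estimator == "nei":
                f = _nei_fst_pair(ca, cb)
            else:
                f = _wc_theta([ca, cb])
            if np.isnan(f):
                undefined.append((names[i], names[j]))
                warnings.warn(
                    f"Fst undefined for pair ({names[i]}, {names[j]})", stacklevel=2
                )
            out[i, j] = out[j, i] = f
    raw = pd.DataFrame(out, index=names, columns=names)
    return FstResult(
        raw=raw,
        clamped=raw.clip(lower=0.0),
        estimator=estimator,
        undefined_pairs=undefined,
    )


def global_fst(matrix: GenotypeMatrix, pops: Mapping[str, str], estimator: str = "wc") -> float:
    """Multi-population Fst (Weir–Cockerham theta over all groups)."""
    if estimator != "wc":
        raise ConfigError("global_fst currently supports the 'wc' estimator only")
    labels = np.asarray([pops[s] for s in matrix.samples])
    names = sorted(set(labels.tolist()))
    blocks = [matrix.codes[labels == g] for g in names]
    return _wc_theta(blocks)
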