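"""Sequencing QC metrics for a targeted amplicon run.

Per variety: alignment rate (reads aligned / total reads), target alignment
rate (reads on target / total reads), sequence depth (bases on target /
total target length) and the uniformity index — the fraction of panel SNPs
whose depth exceeds 10% of that variety's mean SNP depth.  Per run: average
depth = S / (M x N x L) with S total bases, M varieties, N SNPs, L mean read
length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .calling import AlleleDepthTable
from .errors import ConfigError
from .panel import MarkerPanel


@dataclass
class QcReport:
    """Per-sample table plus run-level depth summary.

    ``per_sample`` columns: total_reads, aligned_reads, target_reads,
    alignment_rate, target_alignment_rate, mean_snp_depth, sample_depth,
    uniformity.  Run level: S (total target bases), M (varieties), N (SNPs),
    L (read length), average_depth = S/(M*N*L), and the mean per-sample
    uniformity.
    """

    per_sample: pd.DataFrame
    S: int
    M: int
    N: int
    L: float
    average_depth: float
    mean_uniformity: float


def average_depth(S: float, M: int, N: int, L: float) -> float:
    """Run-level average depth S/(M*N*L).

    S: total bases generated on target; M: number of varieties; N: number of
    panel SNPs; L: mean read length.
    """
    denom = M * N * L
    if denom <= 0:
        raise ConfigError("M, N and L must all be positive")
    return S / denom


def uniformity_index(snp_depths: np.ndarray, threshold: float = 0.10) -> float:
    """Fraction of SNPs with depth above ``threshold`` x mean depth.

    Equal nonzero depths give uniformity 1; an all-zero profile gives 0.
    """
    d = np.asarray(snp_depths, dtype=float)
    if d.size == 0:
        return 0.0
    mean = d.mean()
    if mean == 0:
        return 0.0
    return float(np.mean(d > threshold * mean))


def compute_qc(
    read_accounting: Mapping[str, Mapping[str, int]],
    depth_table: AlleleDepthTable,
    panel: MarkerPanel,
    read_length: float,
    uniformity_threshold: float = 0.10,
) -> QcReport:
    """Compute run and per-sample QC from read accounting and depths.

    ``read_accounting[sample]`` must provide ``total``, ``aligned`` and
    ``target`` read counts with target <= aligned <= total.  Per-SNP depth
    is taken as (bases on the SNP) / read_length; since every counted read
    covers its SNP, that equals the read count at the cell.  The target
    region length per locus is the amplicon span ``2*flank_width + 1``.
    """
    if read_length <= 0:
        raise ConfigError("read_length must be positive")
    depth = depth_table.depth_matrix().astype(float)
    target_len = len(panel) * (2 * panel.flank_width + 1)
    rows = []
    for i, s in enumerate(depth_table.samples):
        acc = read_accounting.get(s, {"total": 0, "aligned": 0, "target": 0})
        total, aligned, target = acc["total"], acc["aligned"], acc["target"]
        if not target <= aligned <= total:
            raise ConfigError(f"{s}: need target <= aligned <= total reads")
        if total == 0:
            warnings.warn(f"{s}: zero total reads; rates set to 0", stacklevel=2)
            align_rate = target_rate = 0.0
        else:
            align_rate = aligned / total
            target_rate = target / total
        snp_depths = depth[i]
        rows.append(
            {
                "sample": s,
                "total_reads": total,
                "aligned_reads": aligned,
                "target_reads": target,
                "alignment_rate": align_rate,
                "target_alignment_rate": target_rate,
                "mean_snp_depth": float(snp_depths.mean()) if snp_depths.size else 0.0,
                "sample_depth": float(snp_depths.sum() * read_length / target_len)
                if target_len
                else 0.0,
                "uniformity": uniformity_index(snp_depths, uniformity_threshold),
            }
        )
    per_sample = pd.DataFrame(rows).set_index("sample")
    S = int(depth.sum() * read_length)
    M = len(depth_table.samples)
    N = len(panel)
    denom = M * N * read_length
    average_depth = S / denom if denom else 0.0
    return QcReport(
        per_sample=per_sample,
        S=S,
        M=M,
        N=N,
        L=float(read_length),
        average_depth=float(average_depth),
        mean_uniformity=float(per_sample["uniformity"].mean()) if M else 0.0,
    )
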