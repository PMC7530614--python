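"""Pairwise linkage-disequilibrium statistics.

Rogers-Huff r is the Pearson correlation of genotype dosage vectors (it
does not require phase); Lewontin's D' is computed on phased haplotypes.
Monomorphic loci yield NaN with a warning rather than an error so that
matrix construction never aborts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import HaplotypeDataset, genotypes_from_haplotypes


@dataclass
class LDResult:
    r: float
    dprime: float
    n_used: int


def rogers_huff_r(gA: np.ndarray, gB: np.ndarray) -> float:
    """Genotype correlation between two dosage vectors (values in {0,1,2})."""
    gA = np.asarray(gA, dtype=float)
    gB = np.asarray(gB, dtype=float)
    if gA.shape != gB.shape or gA.size < 2:
        raise ValueError("dosage vectors must have equal length >= 2")
    if np.ptp(gA) == 0 or np.ptp(gB) == 0:
        warnings.warn("constant dosage vector; r undefined")
        return float("nan")
    return float(np.corrcoef(gA, gB)[0, 1])


def lewontin_dprime(hA: np.ndarray, hB: np.ndarray) -> float:
    """Normalised gametic disequilibrium D' from phased haplotype vectors.

    D = p_AB - p_A p_B; D' = D / D_max with
    D_max = min(p_A (1-p_B), (1-p_A) p_B) if D >= 0,
            min(p_A p_B, (1-p_A)(1-p_B))  if D < 0.
    """
    hA = np.asarray(hA)
    hB = np.asarray(hB)
    if hA.shape != hB.shape or hA.size < 2:
        raise ValueError("haplotype vectors must have equal length >= 2")
    if not (np.isin(hA, (0, 1)).all() and np.isin(hB, (0, 1)).all()):
        raise ValueError("haplotype entries must be 0/1")
    pA = hA.mean()
    pB = hB.mean()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        warnings.warn("monomorphic locus; D' undefined")
        return float("nan")
    pAB = float(np.mean(hA * hB))
    D = pAB - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    if dmax == 0:
        return float("nan")
    return float(D / dmax)


def pairwise_ld_matrix(
    ds: HaplotypeDataset, variant_ids: list[tuple[str, int]]
) -> pd.DataFrame:
    """Symmetric r and D' matrices for the listed (chrom, pos) variants.

    Returns a long-form frame (variant_i, variant_j, r, dprime, n_used);
    use :func:`ld_matrices` for square numpy arrays.
    """
    idx = [ds.variant_index(chrom, pos) for chrom, pos in variant_ids]
    gm = genotypes_from_haplotypes(ds)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for a in range(len(idx)):
            for b in range(len(idx)):
                if a == b:
                    r = dp = 1.0
                else:
                    r = rogers_huff_r(gm.matrix[idx[a]], gm.matrix[idx[b]])
                    dp = lewontin_dprime(ds.matrix[idx[a]], ds.matrix[idx[b]])
                rows.append(
                    (
                        f"{variant_ids[a][0]}:{variant_ids[a][1]}",
                        f"{variant_ids[b][0]}:{variant_ids[b][1]}",
                        r,
                        dp,
                        ds.n_samples,
                    )
                )
    return pd.DataFrame(rows, columns=["variant_i", "variant_j", "r", "dprime", "n_used"])


def ld_matrices(
    ds: HaplotypeDataset, variant_ids: list[tuple[str, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Square (r, dprime) matrices in the order of ``variant_ids``."""
    long = pairwise_ld_matrix(ds, variant_ids)
    k = len(variant_ids)
    r = long["r"].to_numpy().reshape(k, k)
    dp = long["dprime"].to_numpy().reshape(k, k)
    return r, dp
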