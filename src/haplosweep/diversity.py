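"""Nucleotide diversity, pi_N/pi_S and windowed between-group divergence.

pi uses the unbiased per-site estimator sum 2 p (1-p) n/(n-1) over variants
divided by accessible bases; Dxy is the mean between-group pairwise
difference per accessible site.  The Dxy-ratio scan contrasts a focal
haplotype group against two reference backgrounds to localise introgressed
tracts: windows with ratio < 1 are closer to the first reference, > 1
closer to the second.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import HaplotypeDataset, WindowSpec
from .sweep import jackknife_haplotypes


@dataclass
class DiversityResult:
    pi: float
    pi_n: float
    pi_s: float
    ratio: float
    pi_se: float
    pi_n_se: float
    pi_s_se: float
    ratio_se: float


@dataclass
class DxyProfile:
    windows: pd.DataFrame  # start, end, dxy_refA, dxy_refB, ratio, defined


def sequence_diversity(haps: np.ndarray, accessible_bases: int) -> float:
    """Mean pairwise differences per accessible site within a group."""
    haps = np.asarray(haps)
    n = haps.shape[1]
    if n < 2:
        raise ValueError("pi requires >= 2 haplotypes")
    if accessible_bases <= 0:
        raise ValueError("accessible_bases must be positive")
    p = haps.mean(axis=1)
    return float((2.0 * p * (1.0 - p) * n / (n - 1)).sum() / accessible_bases)


def pi_n_ps(
    ds: HaplotypeDataset,
    group: np.ndarray | None = None,
    accessible_bases: int | None = None,
) -> DiversityResult:
    """pi over all, nonsynonymous-only and synonymous-only variants, their
    ratio, and haplotype-jackknife SEs.

    Both class-restricted estimates use the same accessible-base
    denominator, which cancels in the ratio; the ratio is therefore a pure
    variant-sum ratio independent of per-class site counts.
    """
    acc = accessible_bases or ds.accessible_bases
    haps = ds.matrix if group is None else ds.take_haplotypes(group).matrix
    eff = ds.variants["effect_class"].to_numpy()
    nonsyn = np.flatnonzero(eff == "nonsynonymous")
    syn = np.flatnonzero(eff == "synonymous")

    def _pi(rows: np.ndarray):
        return lambda h: sequence_diversity(h[rows], acc) if len(rows) else 0.0

    def _ratio(h: np.ndarray) -> float:
        ps = sequence_diversity(h[syn], acc) if len(syn) else 0.0
        pn = sequence_diversity(h[nonsyn], acc) if len(nonsyn) else 0.0
        return pn / ps if ps > 0 else float("nan")

    all_rows = np.arange(ds.n_variants)
    pi = sequence_diversity(haps, acc)
    pn = sequence_diversity(haps[nonsyn], acc) if len(nonsyn) else 0.0
    ps = sequence_diversity(haps[syn], acc) if len(syn) else 0.0
    if ps == 0:
        warnings.warn("pi_S is zero; pi_N/pi_S undefined")
        ratio = float("nan")
    else:
        ratio = pn / ps
    _, pi_se = jackknife_haplotypes(_pi(all_rows), haps)
    _, pn_se = jackknife_haplotypes(_pi(nonsyn), haps)
    _, ps_se = jackknife_haplotypes(_pi(syn), haps)
    if ps > 0:
        _, ratio_se = jackknife_haplotypes(_ratio, haps)
    else:
        ratio_se = float("nan")
    return DiversityResult(pi, pn, ps, ratio, pi_se, pn_se, ps_se, ratio_se)


def dxy(hapsA: np.ndarray, hapsB: np.ndarray, accessible_bases: int) -> float:
    """Absolute divergence: mean between-group pairwise differences per site."""
    hapsA = np.asarray(hapsA)
    hapsB = np.asarray(hapsB)
    if hapsA.shape[1] == 0 or hapsB.shape[1] == 0:
        raise ValueError("both groups must be non-empty")
    if accessible_bases <= 0:
        raise ValueError("accessible_bases must be positive")
    pA = hapsA.mean(axis=1)
    pB = hapsB.mean(axis=1)
    return float((pA * (1 - pB) + pB * (1 - pA)).sum() / accessible_bases)


def dxy_ratio_scan(
    ds: HaplotypeDataset,
    focal: np.ndarray,
    refA: np.ndarray,
    refB: np.ndarray,
    spec: WindowSpec,
    region_start: int | None = None,
    region_end: int | None = None,
) -> DxyProfile:
    """Windowed dxy(focal, refA) / dxy(focal, refB) profile (bp windows).

    Ratio < 1 marks windows where the focal group is closer to refA, > 1
    closer to refB; zero-denominator windows are reported as undefined.
    The per-window accessible length defaults to the window size.
    """
    for name, g in (("focal", focal), ("refA", refA), ("refB", refB)):
        if np.asarray(g).size == 0:
            raise ValueError(f"group {name} is empty")
    pos = ds.positions
    start = region_start if region_start is not None else int(pos.min())
    end = region_end if region_end is not None else int(pos.max()) + 1
    fa = ds.take_haplotypes(focal).matrix
    ra = ds.take_haplotypes(refA).matrix
    rb = ds.take_haplotypes(refB).matrix
    rows = []
    for w_start, w_end in spec.bp_windows(start, end):
        rows_in = np.flatnonzero((pos >= w_start) & (pos < w_end))
        da = dxy(fa[rows_in], ra[rows_in], spec.size) if len(rows_in) else 0.0
        db = dxy(fa[rows_in], rb[rows_in], spec.size) if len(rows_in) else 0.0
        defined = db > 0
        rows.append(
            {
                "start": w_start,
                "end": w_end,
                "n_vars": len(rows_in),
                "dxy_refA": da,
                "dxy_refB": db,
                "ratio": (da / db) if defined else float("nan"),
                "defined": defined,
            }
        )
    if not rows:
        raise ValueError("no complete bp window fits the region")
    return DxyProfile(windows=pd.DataFrame(rows))
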