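"""Selective-sweep statistics on phased haplotype groups.

EHH (extended haplotype homozygosity) decay from a core variant, the
EHH-threshold core span, Garud's haplotype-frequency-spectrum statistics
(H1, H12, H123, H2/H1), haplotype diversity, moving-window scans and the
leave-one-haplotype-out jackknife.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .core import HaplotypeDataset, WindowSpec


@dataclass
class EHHCurve:
    """EHH values at flanking variants left and right of a core.

    ``left``/``right`` are frames (pos, ehh) ordered away from the core;
    EHH at the core itself is 1 by definition (empty extension).
    """

    core_pos: int
    left: pd.DataFrame
    right: pd.DataFrame


@dataclass
class SweepScanResult:
    windows: pd.DataFrame  # start/end indices and bp, h1, h12, h123, h2_h1, hap_diversity


def _class_frequencies(haps: np.ndarray) -> np.ndarray:
    """Sorted (desc) frequencies of distinct haplotype columns."""
    _, counts = np.unique(haps.T, axis=0, return_counts=True)
    freqs = np.sort(counts)[::-1] / haps.shape[1]
    return freqs


def _identity_prob(haps: np.ndarray) -> float:
    """Probability two haplotypes drawn without replacement are identical:
    sum_h C(c_h, 2) / C(n, 2)."""
    _, counts = np.unique(haps.T, axis=0, return_counts=True)
    n = haps.shape[1]
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh_decay(
    haps: np.ndarray, core_index: int, positions: np.ndarray
) -> EHHCurve:
    """EHH at each flanking variant in both directions from the core.

    At flank x the statistic is the probability that two haplotypes from
    the group are identical over the closed variant interval from the core
    to x; computed independently leftward and rightward.
    """
    haps = np.asarray(haps)
    n = haps.shape[1]
    if n < 2:
        raise ValueError("EHH requires a group of >= 2 haplotypes")
    n_var = haps.shape[0]
    right_rows = []
    for x in range(core_index + 1, n_var):
        right_rows.append((int(positions[x]), _identity_prob(haps[core_index : x + 1])))
    left_rows = []
    for x in range(core_index - 1, -1, -1):
        left_rows.append((int(positions[x]), _identity_prob(haps[x : core_index + 1])))
    return EHHCurve(
        core_pos=int(positions[core_index]),
        left=pd.DataFrame(left_rows, columns=["pos", "ehh"]),
        right=pd.DataFrame(right_rows, columns=["pos", "ehh"]),
    )


def core_span(curve: EHHCurve, upper: float = 0.95) -> int:
    """Length (bp) of the maximal contiguous interval around the core where
    EHH stays above ``upper`` on both sides."""
    left_pos = curve.core_pos
    for row in curve.left.itertuples(index=False):
        if row.ehh > upper:
            left_pos = row.pos
        else:
            break
    right_pos = curve.core_pos
    for row in curve.right.itertuples(index=False):
        if row.ehh > upper:
            right_pos = row.pos
        else:
            break
    return int(right_pos - left_pos)


def decay_point(curve: EHHCurve, lower: float = 0.05) -> tuple[int | None, int | None]:
    """First flank position per side where EHH drops below ``lower``."""
    left = next((r.pos for r in curve.left.itertuples(index=False) if r.ehh < lower), None)
    right = next((r.pos for r in curve.right.itertuples(index=False) if r.ehh < lower), None)
    return left, right


def garud_h(window_haps: np.ndarray) -> tuple[float, float, float, float]:
    """Garud's H1, H12, H123 and H2/H1 from haplotype-class frequencies."""
    if window_haps.shape[1] < 2:
        raise ValueError("Garud H requires >= 2 haplotypes")
    p = _class_frequencies(window_haps)
    h1 = float((p**2).sum())
    h12 = float((p[:2].sum()) ** 2 + (p[2:] ** 2).sum())
    h123 = float((p[:3].sum()) ** 2 + (p[3:] ** 2).sum())
    h2 = h1 - float(p[0] ** 2)
    return h1, h12, h123, h2 / h1


def haplotype_diversity(window_haps: np.ndarray) -> float:
    """Unbiased haplotype diversity (1 - sum p_i^2) * n / (n - 1)."""
    n = window_haps.shape[1]
    if n < 2:
        raise ValueError("haplotype diversity requires >= 2 haplotypes")
    p = _class_frequencies(window_haps)
    return float((1.0 - (p**2).sum()) * n / (n - 1))


def moving_scan(
    ds: HaplotypeDataset,
    group: np.ndarray | None,
    spec: WindowSpec,
) -> SweepScanResult:
    """Sliding-window Garud H and haplotype diversity profile.

    ``group`` selects haplotype columns (boolean mask or index array); None
    scans all haplotypes.  Windows advance by ``spec.step`` variants; the
    trailing partial window is dropped.
    """
    haps = ds.matrix if group is None else ds.take_haplotypes(group).matrix
    pos = ds.positions
    rows = []
    for start, stop in spec.variant_windows(ds.n_variants):
        w = haps[start:stop]
        h1, h12, h123, h2h1 = garud_h(w)
        rows.append(
            {
                "start_index": start,
                "stop_index": stop,
                "start_bp": int(pos[start]),
                "end_bp": int(pos[stop - 1]),
                "n_vars": stop - start,
                "h1": h1,
                "h12": h12,
                "h123": h123,
                "h2_h1": h2h1,
                "hap_diversity": haplotype_diversity(w),
            }
        )
    if not rows:
        raise ValueError("no complete window fits the dataset")
    return SweepScanResult(windows=pd.DataFrame(rows))


def jackknife_haplotypes(
    statistic: Callable[[np.ndarray], float], haps: np.ndarray
) -> tuple[float, float]:
    """Leave-one-haplotype-out jackknife mean and SE of a group statistic.

    SE = sqrt((n-1)/n * sum (theta_i - theta_bar)^2).
    """
    n = haps.shape[1]
    if n < 3:
        raise ValueError("jackknife requires >= 3 haplotypes")
    thetas = np.array(
        [statistic(np.delete(haps, i, axis=1)) for i in range(n)], dtype=float
    )
    mean = thetas.mean()
    se = float(np.sqrt((n - 1) / n * ((thetas - mean) ** 2).sum()))
    return float(mean), se


def group_point_estimates(
    ds: HaplotypeDataset, group: np.ndarray | None, region: str
) -> pd.DataFrame:
    """Jackknifed H statistics and haplotype diversity for one group over an
    explicit region (mean +/- SE per statistic)."""
    sub = ds.region(region)
    haps = sub.matrix if group is None else sub.take_haplotypes(group).matrix
    stats: dict[str, Callable[[np.ndarray], float]] = {
        "h1": lambda h: garud_h(h)[0],
        "h12": lambda h: garud_h(h)[1],
        "h123": lambda h: garud_h(h)[2],
        "h2_h1": lambda h: garud_h(h)[3],
        "hap_diversity": haplotype_diversity,
    }
    rows = []
    for name, fn in stats.items():
        point = fn(haps)
        mean, se = jackknife_haplotypes(fn, haps)
        rows.append({"statistic": name, "estimate": point, "jackknife_mean": mean, "se": se})
    return pd.DataFrame(rows)
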