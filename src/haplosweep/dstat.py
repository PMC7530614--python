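"""Patterson's D (ABBA-BABA) with block-jackknife inference and the
complementary-test direction logic.

Sign convention: D > 0 indicates an excess of derived-allele sharing
between populations A and C, D < 0 between B and C, under a (((A,B),C),O)
topology.  Per site (outgroup-polarised frequencies):

    num = [pA (1-pB) - (1-pA) pB] * pC * (1-pO)
    den = [pA (1-pB) + (1-pA) pB] * pC * (1-pO)
    D   = sum(num) / sum(den)

Frequencies are polarised by the outgroup before pattern computation:
sites with pO > 0.5 are flipped in all four populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import HaplotypeDataset, WindowSpec


@dataclass
class DStatResult:
    d: float
    se: float
    z: float
    p: float
    n_blocks: int
    n_sites: int
    degenerate_se: bool = False  # identical delete-one estimates (SE == 0)
    profile: pd.DataFrame | None = None


@dataclass
class DirectionVerdict:
    test1: DStatResult  # A = resistant_i, B = wt_i, C = wt of species j
    test2: DStatResult  # A = resistant_j, B = wt_j, C = wt of species i
    verdict: str  # origin_in_j | origin_in_i | inconclusive
    alpha: float
    groups: dict = field(default_factory=dict)


def _polarize(freqs: np.ndarray) -> np.ndarray:
    """Flip sites where the outgroup frequency exceeds 0.5."""
    out = freqs.copy().astype(float)
    flip = out[:, 3] > 0.5
    out[flip] = 1.0 - out[flip]
    return out


def _patterns(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    f = _polarize(freqs)
    pA, pB, pC, pO = f.T
    ac = pA * (1 - pB) * pC * (1 - pO)  # A and C share the derived allele
    bc = (1 - pA) * pB * pC * (1 - pO)  # B and C share it
    return ac - bc, ac + bc


def patterson_d(
    pA: np.ndarray, pB: np.ndarray, pC: np.ndarray, pO: np.ndarray
) -> tuple[float, float, float]:
    """Return (numerator sum, denominator sum, D)."""
    freqs = np.column_stack([pA, pB, pC, pO])
    if freqs.shape[0] < 1:
        raise ValueError("need at least one site")
    num, den = _patterns(freqs)
    num_s, den_s = float(num.sum()), float(den.sum())
    if den_s == 0:
        warnings.warn("zero ABBA+BABA denominator; D undefined")
        return num_s, den_s, float("nan")
    return num_s, den_s, num_s / den_s


def block_jackknife_d(
    freqs: np.ndarray | pd.DataFrame, block_len_variants: int = 100
) -> DStatResult:
    """Genome-wide D with delete-one-block jackknife SE, Z and two-sided p.

    Blocks are contiguous runs of ``block_len_variants`` sites (the trailing
    partial block is merged into the last full one); linked sites therefore
    leave and enter together.  SE = sqrt((m-1)/m * sum (theta_i -
    theta_bar)^2) over the m delete-one estimates.
    """
    f = np.asarray(freqs, dtype=float)
    n_sites = f.shape[0]
    m = n_sites // block_len_variants
    if m < 3:
        raise ValueError("block jackknife requires >= 3 complete blocks")
    num, den = _patterns(f)
    bounds = [i * block_len_variants for i in range(m)] + [n_sites]
    block_num = np.array([num[bounds[i] : bounds[i + 1]].sum() for i in range(m)])
    block_den = np.array([den[bounds[i] : bounds[i + 1]].sum() for i in range(m)])
    tot_num, tot_den = num.sum(), den.sum()
    if tot_den == 0:
        warnings.warn("zero ABBA+BABA denominator; D undefined")
        nan = float("nan")
        return DStatResult(nan, nan, nan, nan, m, n_sites)
    d = float(tot_num / tot_den)
    loo_den = tot_den - block_den
    with np.errstate(invalid="ignore", divide="ignore"):
        thetas = (tot_num - block_num) / loo_den
    thetas = thetas[np.isfinite(thetas)]
    mbar = thetas.mean()
    se = float(np.sqrt((len(thetas) - 1) / len(thetas) * ((thetas - mbar) ** 2).sum()))
    if se == 0:
        # identical delete-one estimates: report a 0-SE flag, treat any
        # nonzero D as infinitely significant
        z = float("inf") if d != 0 else 0.0
        p = 0.0 if d != 0 else 1.0
        return DStatResult(d, 0.0, z, p, m, n_sites, degenerate_se=True)
    z = d / se
    p = float(2.0 * sstats.norm.sf(abs(z)))
    p = max(p, np.finfo(float).tiny)  # don't pretend sub-machine resolution
    return DStatResult(d, se, float(z), p, m, n_sites)


def moving_d(freqs: np.ndarray | pd.DataFrame, spec: WindowSpec) -> pd.DataFrame:
    """Per-window D over variant-count windows; trailing partial dropped."""
    if spec.mode != "variant_count":
        raise ValueError("moving_d requires a variant_count WindowSpec")
    f = np.asarray(freqs, dtype=float)
    rows = []
    for start, stop in spec.variant_windows(f.shape[0]):
        _, _, d = patterson_d(*f[start:stop].T)
        rows.append({"start_index": start, "stop_index": stop, "d": d})
    if not rows:
        raise ValueError("no complete window fits the data")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group frequencies and the complementary direction test
# ---------------------------------------------------------------------------

def group_frequencies(ds: HaplotypeDataset, groups: dict) -> np.ndarray:
    """Stack per-site alternate-allele frequencies for named column sets
    (order of dict = A, B, C, O)."""
    cols = []
    for name, sel in groups.items():
        sel = np.asarray(sel)
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
        if sel.size == 0:
            raise ValueError(f"group {name!r} is empty")
        cols.append(ds.allele_frequencies(sel))
    return np.column_stack(cols)


def homozygote_columns(
    ds: HaplotypeDataset,
    species: str,
    focal_chrom: str,
    focal_pos: int,
    allele: int,
    karyotype: str | None = None,
) -> np.ndarray:
    """Haplotype columns of samples homozygous for ``allele`` at the focal
    variant (and optionally for a karyotype class), within one species.

    The restriction to homozygotes is the conservative grouping used for
    direction testing: it avoids mixing resistant and wild-type haplotypes
    within a specimen.
    """
    vi = ds.variant_index(focal_chrom, focal_pos)
    sp = ds.hap_species
    mask = np.zeros(ds.n_haplotypes, dtype=bool)
    for s in range(ds.n_samples):
        c0, c1 = 2 * s, 2 * s + 1
        if sp[c0] != species:
            continue
        if ds.matrix[vi, c0] != allele or ds.matrix[vi, c1] != allele:
            continue
        if karyotype is not None:
            sid = ds.haplotype_labels[c0][0]
            if ds.sample_table.loc[sid, "karyotype"] != karyotype:
                continue
        mask[c0] = mask[c1] = True
    return np.flatnonzero(mask)


def _significant_positive(res: DStatResult, alpha: float) -> bool:
    return np.isfinite(res.d) and res.d > 0 and (res.p < alpha)


def direction_test(
    ds: HaplotypeDataset,
    species_i: str,
    species_j: str,
    focal: tuple[str, int],
    outgroup_species: str,
    region: str | None = None,
    alpha: float = 0.05,
    karyotype: str | None = None,
    block_len_variants: int = 100,
) -> DirectionVerdict:
    """Paired complementary Patterson's D tests for the origin of a focal
    (resistance) allele shared by two species.

    Test 1 uses A = focal-allele homozygotes of species i, B = wild-type
    homozygotes of species i, C = wild-type homozygotes of species j.
    Test 2 swaps the species roles.  If test 1 shows significant positive D
    (the species-i resistant haplotypes share their background with
    species-j wild types) while test 2 does not, the allele originated in
    species j; symmetrically for species i; anything else is inconclusive.
    """
    sub = ds.region(region) if region else ds
    chrom, pos = focal
    out_cols = np.flatnonzero(sub.hap_species == outgroup_species)
    if out_cols.size == 0:
        raise ValueError(f"outgroup species {outgroup_species!r} has no haplotypes")

    def cols(species: str, allele: int) -> np.ndarray:
        c = homozygote_columns(sub, species, chrom, pos, allele, karyotype=karyotype)
        if c.size == 0:
            raise ValueError(
                f"empty group: species={species!r} allele={allele} karyotype={karyotype!r}"
            )
        return c

    groups1 = {
        "A(res_i)": cols(species_i, 1),
        "B(wt_i)": cols(species_i, 0),
        "C(wt_j)": cols(species_j, 0),
        "O": out_cols,
    }
    groups2 = {
        "A(res_j)": cols(species_j, 1),
        "B(wt_j)": cols(species_j, 0),
        "C(wt_i)": cols(species_i, 0),
        "O": out_cols,
    }
    test1 = block_jackknife_d(group_frequencies(sub, groups1), block_len_variants)
    test2 = block_jackknife_d(group_frequencies(sub, groups2), block_len_variants)
    sig1 = _significant_positive(test1, alpha)
    sig2 = _significant_positive(test2, alpha)
    if sig1 and not sig2:
        verdict = "origin_in_j"
    elif sig2 and not sig1:
        verdict = "origin_in_i"
    else:
        verdict = "inconclusive"
    return DirectionVerdict(
        test1=test1,
        test2=test2,
        verdict=verdict,
        alpha=alpha,
        groups={
            "test1": {k: len(v) for k, v in groups1.items()},
            "test2": {k: len(v) for k, v in groups2.items()},
        },
    )
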