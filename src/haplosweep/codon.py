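"""Pairwise peptide identity and Nei-Gojobori (1986) dN/dS.

NG86 counts fractional synonymous/nonsynonymous sites per codon (changes
to stop codons count as nonsynonymous, so N + S = 3 x codons), partitions
observed codon differences over equally weighted minimal mutational
pathways (pathways passing through a stop codon are excluded unless every
pathway does), and applies the Jukes-Cantor correction
d = -(3/4) ln(1 - (4/3) p) to the proportions pN = Nd/N and pS = Sd/S.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_NUCS = "ACGT"


def _translate(codon: str) -> str | None:
    """Amino acid for a codon, or None for a stop."""
    return None if codon in _STOPS else _CODON_TABLE[codon]


@dataclass
class CodonAlignmentPair:
    """Two codon-aligned nucleotide sequences.

    Codons containing gaps or ambiguity codes in either sequence are masked
    out; internal stop codons are rejected.
    """

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        if len(a) != len(b):
            raise ValueError("sequences must have equal aligned length")
        if len(a) % 3:
            raise ValueError("aligned length must be divisible by 3")
        self.codons: list[tuple[str, str]] = []
        for i in range(0, len(a), 3):
            ca, cb = a[i : i + 3], b[i : i + 3]
            if any(n not in _NUCS for n in ca + cb):
                continue  # masked: gap or ambiguity
            if i + 3 < len(a) and (ca in _STOPS or cb in _STOPS):
                raise ValueError(f"internal stop codon at position {i + 1}")
            if ca in _STOPS or cb in _STOPS:
                continue  # terminal stop: not a comparable codon
            self.codons.append((ca, cb))


def pairwise_identity(peptide_a: str, peptide_b: str) -> float:
    """Fraction of matching positions, excluding double-gap columns.

    Columns where only one sequence is gapped count as mismatches.
    """
    if len(peptide_a) != len(peptide_b):
        raise ValueError("peptides must have equal aligned length")
    matches = comparable = 0
    for x, y in zip(peptide_a.upper(), peptide_b.upper()):
        if x == "-" and y == "-":
            continue
        comparable += 1
        if x == y and x != "-":
            matches += 1
    if comparable == 0:
        return float("nan")
    return matches / comparable


def codon_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts for one codon.

    Each of the 9 single-nucleotide changes contributes 1/3 of a site to
    the class of its effect; changes to stops are nonsynonymous.
    """
    aa = _translate(codon)
    syn = 0.0
    for i in range(3):
        for alt in _NUCS:
            if alt == codon[i]:
                continue
            mutant = codon[:i] + alt + codon[i + 1 :]
            if _translate(mutant) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def pathway_differences(ca: str, cb: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    over equally weighted minimal mutational pathways."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        syn = nonsyn = 0.0
        cur = ca
        blocked = False
        for i in order:
            nxt = cur[:i] + cb[i] + cur[i + 1 :]
            if nxt in _STOPS and nxt != cb:
                blocked = True
            if _translate(nxt) == _translate(cur) and _translate(nxt) is not None:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        paths.append((syn, nonsyn, blocked))
    valid = [p for p in paths if not p[2]]
    if not valid:  # every pathway traverses a stop; fall back to all
        valid = paths
    s = sum(p[0] for p in valid) / len(valid)
    n = sum(p[1] for p in valid) / len(valid)
    return s, n


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        warnings.warn("proportion >= 3/4; Jukes-Cantor correction undefined")
        return float("nan")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class DnDsResult:
    dn: float
    ds: float
    ratio: float
    n_sites: float  # nonsynonymous sites N
    s_sites: float  # synonymous sites S
    nd: float
    sd: float
    method: str = "NG86"


def ng86_dnds(pair: CodonAlignmentPair) -> DnDsResult:
    """Pairwise dN, dS and their ratio by the NG86 pathway estimator."""
    if not pair.codons:
        raise ValueError("no comparable codons after masking")
    N = S = Nd = Sd = 0.0
    for ca, cb in pair.codons:
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        s_d, n_d = pathway_differences(ca, cb)
        Sd += s_d
        Nd += n_d
    pn = Nd / N if N else 0.0
    ps = Sd / S if S else 0.0
    dn = _jukes_cantor(pn)
    ds = _jukes_cantor(ps)
    if ds == 0.0 or not math.isfinite(ds):
        if ds == 0.0:
            warnings.warn("dS is zero; dN/dS undefined")
        ratio = float("nan")
    else:
        ratio = dn / ds
    return DnDsResult(dn=dn, ds=ds, ratio=ratio, n_sites=N, s_sites=S, nd=Nd, sd=Sd)


def dnds_table(sequences: dict) -> "pd.DataFrame":
    """Pairwise identity and NG86 dN/dS over a dict of aligned CDS."""
    import pandas as pd

    names = list(sequences)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pair = CodonAlignmentPair(sequences[a], sequences[b])
            res = ng86_dnds(pair)
            pep_a = _translate_seq(sequences[a])
            pep_b = _translate_seq(sequences[b])
            rows.append(
                {
                    "seq_a": a,
                    "seq_b": b,
                    "identity": pairwise_identity(pep_a, pep_b),
                    "dn": res.dn,
                    "ds": res.ds,
                    "dn_ds": res.ratio,
                    "method": res.method,
                }
            )
    return pd.DataFrame(rows)


def _translate_seq(seq: str) -> str:
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3].upper()
        if any(n not in _NUCS for n in codon):
            out.append("-")
        elif codon in _STOPS:
            out.append("*")
        else:
            out.append(_CODON_TABLE[codon])
    return "".join(out)
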