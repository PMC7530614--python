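"""Tiny declarative haplotype-group expressions.

An expression is `&`-joined clauses, e.g.::

    population=BFcol & species=coluzzii & allele[2L:25429236]=1 & karyotype=INV/INV

Clauses: ``population=``, ``species=``, ``karyotype=`` (sample-level class)
and ``allele[CHROM:POS]=0|1`` (haplotype-level allele state).  A resolved
group must be non-empty or an error names the expression.
"""

from __future__ import annotations

import re

import numpy as np

from .core import HaplotypeDataset

_ALLELE_RE = re.compile(r"^allele\[([^:\]]+):(\d+)\]$")


def resolve_group(ds: HaplotypeDataset, expr: str) -> np.ndarray:
    mask = np.ones(ds.n_haplotypes, dtype=bool)
    for clause in expr.split("&"):
        clause = clause.strip()
        if not clause:
            continue
        if "=" not in clause:
            raise ValueError(f"malformed clause {clause!r} in group {expr!r}")
        key, value = clause.split("=", 1)
        key, value = key.strip(), value.strip()
        m = _ALLELE_RE.match(key)
        if m:
            vi = ds.variant_index(m.group(1), int(m.group(2)))
            mask &= ds.matrix[vi] == int(value)
        elif key == "population":
            mask &= ds.hap_population == value
        elif key == "species":
            mask &= ds.hap_species == value
        elif key == "karyotype":
            kary = ds._sample_column("karyotype")
            mask &= kary == value
        else:
            raise ValueError(f"unknown group key {key!r} in {expr!r}")
    cols = np.flatnonzero(mask)
    if cols.size == 0:
        raise ValueError(f"group expression {expr!r} resolves to zero haplotypes")
    return cols
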