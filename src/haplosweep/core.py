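"""Core data containers, VCF/metadata I/O and variant-filtering rules.

The central object is :class:`HaplotypeDataset`: a variants x haplotypes
matrix of phased alleles (0 = reference, 1 = alternate) together with the
variant table, per-haplotype sample labels and per-sample population /
species / karyotype metadata.  Every statistic in this package consumes it.

Coordinates are 1-based inclusive (VCF convention); bp windows and region
strings are half-open ``[start, end)`` where noted.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EFFECT_CLASSES = ("synonymous", "nonsynonymous", "noncoding", "unknown")

_NUC = set("ACGT")


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP.

    Attributes
    ----------
    chrom : str
        Chromosome (or chromosomal arm) name.
    pos : int
        1-based position in bp.
    ref_allele, alt_allele : str
        Single-character nucleotide codes; must differ.
    effect_class : str
        One of ``synonymous``, ``nonsynonymous``, ``noncoding``, ``unknown``.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    effect_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError("only single-nucleotide biallelic variants are supported")
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect_class!r}")


@dataclass
class WindowSpec:
    """Sliding-window definition.

    ``mode='variant_count'`` windows are blocks of consecutive variants
    (e.g. 500 variants advancing by 20% of the block); ``mode='bp'`` windows
    are genomic intervals ``[start, start+size)`` advancing by ``step`` bp.
    """

    mode: str
    size: int
    step: int

    def __post_init__(self) -> None:
        if self.mode not in ("variant_count", "bp"):
            raise ValueError(f"unknown window mode {self.mode!r}")
        if not (0 < self.step <= self.size):
            raise ValueError("require 0 < step <= size")

    def variant_windows(self, n_variants: int) -> Iterator[tuple[int, int]]:
        """Yield (start, stop) index pairs; trailing partial window dropped."""
        if self.mode != "variant_count":
            raise ValueError("variant_windows requires variant_count mode")
        start = 0
        while start + self.size <= n_variants:
            yield start, start + self.size
            start += self.step

    def bp_windows(self, region_start: int, region_end: int) -> Iterator[tuple[int, int]]:
        """Yield half-open [start, end) bp windows fully inside the region."""
        if self.mode != "bp":
            raise ValueError("bp_windows requires bp mode")
        start = region_start
        while start + self.size <= region_end:
            yield start, start + self.size
            start += self.step


@dataclass
class HaplotypeDataset:
    """Phased haplotypes for a set of biallelic SNPs.

    Attributes
    ----------
    variants : pandas.DataFrame
        Columns ``chrom, pos, ref, alt, effect_class``; positions strictly
        increasing within each chromosome.
    matrix : numpy.ndarray, shape (n_variants, n_haplotypes)
        Entries in {0, 1}; column order follows sample order with chromosome
        copy 0 before copy 1.
    haplotype_labels : list of (sample_id, copy)
        One entry per matrix column.
    sample_table : pandas.DataFrame or None
        Indexed by sample id with columns ``population, species, karyotype``
        (karyotype in {INV/INV, INV/STD, STD/STD} or NA).  Attached by
        :func:`attach_metadata`.
    accessible_bases : int
        Accessible length (bp) of the region, used for per-site
        normalisation of diversity statistics.  May exceed or trim the
        variant span but must be positive.
    drop_tally : dict
        Counts of records dropped during reading, by reason.
    """

    variants: pd.DataFrame
    matrix: np.ndarray
    haplotype_labels: list[tuple[str, int]]
    sample_table: pd.DataFrame | None = None
    accessible_bases: int = 0
    drop_tally: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (variants x haplotypes)")
        if self.matrix.shape[0] != len(self.variants):
            raise ValueError("matrix row count != number of variants")
        if self.matrix.shape[1] != len(self.haplotype_labels):
            raise ValueError("matrix column count != number of haplotype labels")
        if self.matrix.size and not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")
        if self.accessible_bases <= 0:
            # default to the spanned region so diversity stays computable
            pos = self.variants["pos"].to_numpy()
            self.accessible_bases = int(pos.max() - pos.min() + 1) if len(pos) else 1
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            p = sub["pos"].to_numpy()
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {chrom}")

    # -- basic geometry ---------------------------------------------------
    @property
    def n_variants(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for sid, _ in self.haplotype_labels:
            seen.setdefault(sid, None)
        return list(seen)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def positions(self) -> np.ndarray:
        return self.variants["pos"].to_numpy()

    # -- per-haplotype label vectors --------------------------------------
    def _sample_column(self, column: str) -> np.ndarray:
        if self.sample_table is None:
            raise ValueError("no sample metadata attached; call attach_metadata first")
        tab = self.sample_table[column]
        return np.array([tab.loc[sid] for sid, _ in self.haplotype_labels], dtype=object)

    @property
    def hap_population(self) -> np.ndarray:
        return self._sample_column("population")

    @property
    def hap_species(self) -> np.ndarray:
        return self._sample_column("species")

    # -- subsetting --------------------------------------------------------
    def take_variants(self, index: np.ndarray) -> "HaplotypeDataset":
        index = np.asarray(index)
        return replace(
            self,
            variants=self.variants.iloc[index].reset_index(drop=True),
            matrix=self.matrix[index],
        )

    def take_haplotypes(self, columns: np.ndarray) -> "HaplotypeDataset":
        columns = np.asarray(columns)
        if columns.dtype == bool:
            columns = np.flatnonzero(columns)
        labels = [self.haplotype_labels[i] for i in columns]
        return replace(self, matrix=self.matrix[:, columns], haplotype_labels=labels)

    def region(self, region: str) -> "HaplotypeDataset":
        """Subset to ``chrom`` or ``chrom:start-end`` (1-based inclusive)."""
        chrom, start, end = parse_region(region)
        mask = (self.variants["chrom"] == chrom).to_numpy()
        if start is not None:
            pos = self.positions
            mask &= (pos >= start) & (pos <= end)
        return self.take_variants(np.flatnonzero(mask))

    def variant_index(self, chrom: str, pos: int) -> int:
        hit = np.flatnonzero(
            (self.variants["chrom"] == chrom).to_numpy() & (self.positions == pos)
        )
        if len(hit) != 1:
            raise KeyError(f"variant {chrom}:{pos} not found (or not unique)")
        return int(hit[0])

    def allele_frequencies(self, columns: np.ndarray | None = None) -> np.ndarray:
        """Alternate-allele frequency per variant over the given columns."""
        m = self.matrix if columns is None else self.matrix[:, np.asarray(columns)]
        if m.shape[1] == 0:
            raise ValueError("cannot compute frequencies over zero haplotypes")
        return m.mean(axis=1)


@dataclass
class GenotypeMatrix:
    """Variants x samples matrix of alternate-allele dosages in {0, 1, 2}."""

    variants: pd.DataFrame
    matrix: np.ndarray
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]


_REGION_RE = re.compile(r"^([^:]+)(?::(\d+)-(\d+))?$")


def parse_region(region: str) -> tuple[str, int | None, int | None]:
    m = _REGION_RE.match(region)
    if not m:
        raise ValueError(f"malformed region {region!r}; expected CHROM or CHROM:START-END")
    chrom, start, end = m.group(1), m.group(2), m.group(3)
    if start is None:
        return chrom, None, None
    start_i, end_i = int(start), int(end)
    if start_i > end_i:
        raise ValueError(f"region start > end in {region!r}")
    return chrom, start_i, end_i


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_phased_vcf(path: str, region: str | None = None) -> HaplotypeDataset:
    """Read phased, biallelic SNP records from a VCF into a HaplotypeDataset.

    Records that are not biallelic SNPs, or that contain unphased or missing
    genotypes, are dropped and counted in ``drop_tally``.  Effect classes are
    taken from an ``EFF_CLASS`` INFO key when present.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    records = vcf(region) if region else vcf
    rows: list[tuple] = []
    columns: list[np.ndarray] = []
    tally = {"multiallelic_or_indel": 0, "unphased_or_missing": 0}
    for rec in records:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            tally["multiallelic_or_indel"] += 1
            continue
        if rec.REF not in _NUC or rec.ALT[0] not in _NUC:
            tally["multiallelic_or_indel"] += 1
            continue
        gts = rec.genotypes  # [allele0, allele1, phased] per sample
        ok = True
        alleles = np.empty(2 * len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            if len(g) != 3 or not g[2] or g[0] < 0 or g[1] < 0:
                ok = False
                break
            alleles[2 * i] = g[0]
            alleles[2 * i + 1] = g[1]
        if not ok:
            tally["unphased_or_missing"] += 1
            continue
        eff = rec.INFO.get("EFF_CLASS") or "unknown"
        if eff not in EFFECT_CLASSES:
            eff = "unknown"
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0], eff))
        columns.append(alleles)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "effect_class"])
    matrix = (
        np.vstack(columns) if columns else np.zeros((0, 2 * len(samples)), dtype=np.int8)
    )
    labels = [(sid, copy) for sid in samples for copy in (0, 1)]
    ds = HaplotypeDataset(variants=variants, matrix=matrix, haplotype_labels=labels)
    ds.drop_tally = tally
    return ds


def write_vcf(ds: HaplotypeDataset, path: str) -> None:
    """Write the dataset as an uncompressed phased VCF (round-trip safe)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=EFF_CLASS,Number=1,Type=String,'
            'Description="Variant effect class">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in ds.variants["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ds.sample_ids)
            + "\n"
        )
        for i, row in enumerate(ds.variants.itertuples(index=False)):
            gts = "\t".join(
                f"{ds.matrix[i, 2 * s]}|{ds.matrix[i, 2 * s + 1]}"
                for s in range(ds.n_samples)
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                f"EFF_CLASS={row.effect_class}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Metadata and effect tables
# ---------------------------------------------------------------------------

def read_metadata(path: str) -> pd.DataFrame:
    """Read a tab-separated sample table (sample_id, population, species, karyotype)."""
    tab = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "population", "species"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if "karyotype" not in tab.columns:
        tab["karyotype"] = "NA"
    return tab


def attach_metadata(ds: HaplotypeDataset, table: pd.DataFrame) -> HaplotypeDataset:
    """Attach per-sample population/species/karyotype labels.

    Every sample in the dataset must appear exactly once in the table; extra
    table rows are ignored with a warning.
    """
    dup = table["sample_id"][table["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample id(s) in metadata: {sorted(set(dup))}")
    indexed = table.set_index("sample_id")
    missing = [sid for sid in ds.sample_ids if sid not in indexed.index]
    if missing:
        raise ValueError(f"metadata missing sample id(s): {missing}")
    extra = [sid for sid in indexed.index if sid not in set(ds.sample_ids)]
    if extra:
        logger.warning("metadata contains %d sample id(s) not in the VCF; ignored", len(extra))
    sample_table = indexed.loc[ds.sample_ids, ["population", "species", "karyotype"]]
    return replace(ds, sample_table=sample_table)


def read_effect_table(path: str) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int, "effect_class": str})
    bad = set(tab["effect_class"]) - set(EFFECT_CLASSES)
    if bad:
        raise ValueError(f"unknown effect class(es): {sorted(bad)}")
    return tab


def attach_effects(ds: HaplotypeDataset, table: pd.DataFrame) -> HaplotypeDataset:
    """Overwrite variant effect classes from a (chrom, pos, effect_class) table."""
    key = table.set_index(["chrom", "pos"])["effect_class"]
    variants = ds.variants.copy()
    idx = pd.MultiIndex.from_frame(variants[["chrom", "pos"]])
    hit = idx.isin(key.index)
    variants.loc[hit, "effect_class"] = key.loc[idx[hit]].to_numpy()
    return replace(ds, variants=variants)


# ---------------------------------------------------------------------------
# Variant filters
# ---------------------------------------------------------------------------

def filter_segregating(ds: HaplotypeDataset, min_freq: float = 0.05) -> HaplotypeDataset:
    """Keep variants whose alternate-allele frequency strictly exceeds
    ``min_freq`` in at least one population."""
    pops = ds.hap_population
    keep = np.zeros(ds.n_variants, dtype=bool)
    for pop in pd.unique(pops):
        cols = np.flatnonzero(pops == pop)
        if len(cols) == 0:
            raise ValueError(f"population {pop!r} has zero haplotypes")
        keep |= ds.allele_frequencies(cols) > min_freq
    return ds.take_variants(np.flatnonzero(keep))


def filter_nonsingleton(ds: HaplotypeDataset, min_carriers: int = 3) -> HaplotypeDataset:
    """Keep variants whose minor allele is carried by >= ``min_carriers``
    haplotypes (the nonsingleton / shared-variant filter)."""
    alt = ds.matrix.sum(axis=1)
    minor = np.minimum(alt, ds.n_haplotypes - alt)
    return ds.take_variants(np.flatnonzero(minor >= min_carriers))


def genotypes_from_haplotypes(ds: HaplotypeDataset) -> GenotypeMatrix:
    """Collapse phased haplotype pairs into per-sample allele dosages."""
    if ds.n_haplotypes % 2:
        raise ValueError("odd haplotype count; columns must be paired per sample")
    for s in range(ds.n_haplotypes // 2):
        a, b = ds.haplotype_labels[2 * s], ds.haplotype_labels[2 * s + 1]
        if a[0] != b[0]:
            raise ValueError(f"columns {2*s},{2*s+1} belong to different samples")
    dosage = ds.matrix[:, 0::2].astype(np.int8) + ds.matrix[:, 1::2]
    return GenotypeMatrix(variants=ds.variants, matrix=dosage, sample_ids=ds.sample_ids)
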