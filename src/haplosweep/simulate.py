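"""Synthetic phased-cohort generator with ground truth.

Generates :class:`~haplosweep.core.HaplotypeDataset` instances carrying the
structures the analysis stack is designed to detect:

* a neutral background (shared ancestral polymorphism plus private
  per-lineage mutations),
* two deeply diverged haplotype backgrounds ("INV" vs "STD") whose fixed
  differences are confined to an inversion interval — a stand-in for a
  polymorphic chromosomal inversion that suppresses recombination,
* species-level fixed differences, so interspecific allele-frequency
  contrasts (and hence ABBA-BABA tests) are informative,
* a hard selective sweep: one founder haplotype carrying a focal resistance
  allele and perfectly linked secondary markers replaces a stated fraction
  of haplotypes, with crossover against the replaced background so
  haplotype homozygosity decays with distance from the core,
* introgression events that copy the swept haplotype between populations or
  between inversion backgrounds over a bounded tract.

Construction is forward-free (founder copying + crossover), not a
coalescent: it realises the target structures directly and keeps runtime
trivial.  Every operation is a pure function of (config, seed).
"""

from __future__ import annotations

import copy
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import HaplotypeDataset

logger = logging.getLogger(__name__)

ORIGIN_TAGS = (
    "background",
    "sweep_core",
    "linked_marker",
    "karyotype_diagnostic",
    "species_diagnostic",
)


@dataclass
class PopulationConfig:
    """One sampled population.

    inv_freq is the per-chromosome-copy probability of the inverted
    background; karyotype_counts (e.g. ``{"INV/INV": 30, "INV/STD": 30,
    "STD/STD": 30}``) overrides it with exact per-class sample counts.
    """

    name: str
    species: str
    n_samples: int
    inv_freq: float = 0.0
    karyotype_counts: dict | None = None
    is_outgroup: bool = False


@dataclass
class SweepConfig:
    core_pos: int
    carrier_fraction: dict  # population name -> fraction of haplotypes
    linked_marker_positions: list = field(default_factory=list)
    recomb_rate: float = 0.0  # crossovers per bp per copy event
    founder_karyotype: str = "STD"
    founder_scope: str = "shared"  # one founder overall, or "per_population"


@dataclass
class IntrogressionEvent:
    """Copy the swept haplotype from a source group into a target group.

    source/target select either a population by name or a karyotype
    background by class ("INV" or "STD").  Recipients carry the donor
    haplotype inside ``[core - tract_half_length, core + tract_half_length)``
    (the core variant is always included) and their own background outside.
    """

    source: str
    target: str
    n_copies: int
    tract_half_length: int
    pair_samples: bool = True


@dataclass
class CohortConfig:
    seed: int
    populations: list
    region_length: int
    n_variants: int
    chrom: str = "2L"
    mutation_sites_per_lineage: float = 10.0
    inversion_interval: tuple = (1, 1)
    karyotype_divergence: int = 0
    species_divergence: int = 0
    shared_poly_fraction: float = 0.3
    outgroup_leakage: float = 0.05
    sweep: SweepConfig | None = None
    introgression_events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.populations = [
            PopulationConfig(**p) if isinstance(p, dict) else p for p in self.populations
        ]
        if isinstance(self.sweep, dict):
            self.sweep = SweepConfig(**self.sweep)
        self.introgression_events = [
            IntrogressionEvent(**e) if isinstance(e, dict) else e
            for e in self.introgression_events
        ]
        lo, hi = self.inversion_interval
        if not (1 <= lo <= hi <= self.region_length):
            raise ValueError("inversion_interval must lie within [1, region_length]")
        if self.sweep is not None:
            if not (lo <= self.sweep.core_pos <= hi):
                raise ValueError("sweep core_pos must lie inside the inversion interval")
            for f in self.sweep.carrier_fraction.values():
                if not (0.0 <= f <= 1.0):
                    raise ValueError("carrier_fraction must be in [0, 1]")

    @classmethod
    def from_file(cls, path: str) -> "CohortConfig":
        text = open(path).read()
        if path.endswith((".yaml", ".yml")):
            import yaml

            doc = yaml.safe_load(text)
        else:
            doc = json.loads(text)
        return cls(**doc)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CohortTruth:
    """Ground truth emitted alongside a simulated dataset.

    haplotypes : per-column frame with sample_id, copy, population, species,
        karyotype (background at generation, "INV"/"STD"), sweep_carrier,
        sweep_left/sweep_right (bp bounds of the retained donor tract),
        introgression_recipient, event_id, tract_start/tract_end.
    variants : per-variant frame with pos and origin tag.
    founders : origin key -> founder haplotype vector (with sweep alleles).
    """

    haplotypes: pd.DataFrame
    variants: pd.DataFrame
    founders: dict = field(default_factory=dict)
    core_index: int | None = None

    def write(self, path: str) -> None:
        self.haplotypes.to_csv(path, sep="\t", index=False)


def _rng(cfg: CohortConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


# ---------------------------------------------------------------------------
# Stage 1: neutral background + diverged karyotype/species backgrounds
# ---------------------------------------------------------------------------

def simulate_background(cfg: CohortConfig) -> tuple[HaplotypeDataset, CohortTruth]:
    rng = _rng(cfg, 1)
    reserved: list[int] = []
    if cfg.sweep is not None:
        reserved = [cfg.sweep.core_pos] + list(cfg.sweep.linked_marker_positions)
        if len(set(reserved)) != len(reserved):
            raise ValueError("sweep positions must be distinct")

    n_free = cfg.n_variants - len(reserved)
    non_outgroup_species = [
        p.species for p in cfg.populations if not p.is_outgroup
    ]
    non_outgroup_species = list(dict.fromkeys(non_outgroup_species))
    n_special = cfg.karyotype_divergence + cfg.species_divergence * len(non_outgroup_species)
    if n_free < n_special:
        raise ValueError(
            f"n_variants={cfg.n_variants} too small to host {n_special} fixed "
            "differences plus sweep sites"
        )

    # Positions: reserved sweep sites are exact; the rest uniform without
    # replacement over the region.
    pool = np.setdiff1d(np.arange(1, cfg.region_length + 1), np.array(reserved, dtype=int))
    if n_free > len(pool):
        raise ValueError("n_variants exceeds region_length")
    free_pos = rng.choice(pool, size=n_free, replace=False)
    positions = np.sort(np.concatenate([free_pos, np.array(reserved, dtype=int)]))
    n = len(positions)
    origin = np.full(n, "background", dtype=object)
    pos_index = {p: i for i, p in enumerate(positions)}
    if cfg.sweep is not None:
        origin[pos_index[cfg.sweep.core_pos]] = "sweep_core"
        for p in cfg.sweep.linked_marker_positions:
            origin[pos_index[p]] = "linked_marker"

    # Karyotype-diagnostic sites: fixed INV/STD differences inside the interval.
    lo, hi = cfg.inversion_interval
    in_interval = np.flatnonzero(
        (positions >= lo) & (positions <= hi) & (origin == "background")
    )
    if cfg.karyotype_divergence > len(in_interval):
        raise ValueError(
            "not enough variants inside the inversion interval for the "
            f"requested karyotype_divergence={cfg.karyotype_divergence}"
        )
    kary_idx = rng.choice(in_interval, size=cfg.karyotype_divergence, replace=False)
    origin[kary_idx] = "karyotype_diagnostic"

    # Species-diagnostic sites: fixed derived in exactly one species.
    species_sites: dict[str, np.ndarray] = {}
    for sp in non_outgroup_species:
        free = np.flatnonzero(origin == "background")
        idx = rng.choice(free, size=cfg.species_divergence, replace=False)
        origin[idx] = "species_diagnostic"
        species_sites[sp] = idx

    # Background sites: shared ancestral polymorphism vs private-mutation pool.
    bg_idx = np.flatnonzero(origin == "background")
    shared_mask = rng.random(len(bg_idx)) < cfg.shared_poly_fraction
    shared_idx = bg_idx[shared_mask]
    private_pool = bg_idx[~shared_mask]
    shared_freq = rng.uniform(0.05, 0.95, size=len(shared_idx))

    # Haplotype columns.
    labels: list[tuple[str, int]] = []
    rows = []
    kary_bg: list[str] = []
    for pop in cfg.populations:
        classes: list[str]
        if pop.karyotype_counts:
            classes = []
            for cls, k in pop.karyotype_counts.items():
                classes += [cls] * k
            if len(classes) != pop.n_samples:
                raise ValueError(f"karyotype_counts do not sum to n_samples for {pop.name}")
        else:
            draws = rng.random((pop.n_samples, 2)) < pop.inv_freq
            classes = [
                {2: "INV/INV", 1: "INV/STD", 0: "STD/STD"}[int(d.sum())] for d in draws
            ]
        for s in range(pop.n_samples):
            sid = f"{pop.name}_{s:04d}"
            cls = classes[s]
            copies = {"INV/INV": ("INV", "INV"), "INV/STD": ("INV", "STD"),
                      "STD/STD": ("STD", "STD")}[cls]
            rows.append((sid, pop.name, pop.species, cls))
            for copy_i in (0, 1):
                labels.append((sid, copy_i))
                kary_bg.append(copies[copy_i])

    n_haps = len(labels)
    matrix = np.zeros((n, n_haps), dtype=np.int8)
    hap_pop = np.array([r[1] for r in rows for _ in (0, 1)], dtype=object)
    hap_species = np.array([r[2] for r in rows for _ in (0, 1)], dtype=object)
    is_outgroup_hap = np.isin(
        hap_pop, [p.name for p in cfg.populations if p.is_outgroup]
    )

    kary_arr = np.array(kary_bg, dtype=object)
    matrix[np.ix_(kary_idx, np.flatnonzero(kary_arr == "INV"))] = 1
    for sp, idx in species_sites.items():
        matrix[np.ix_(idx, np.flatnonzero(hap_species == sp))] = 1

    if len(shared_idx):
        draws = rng.random((len(shared_idx), n_haps)) < shared_freq[:, None]
        # the outgroup is near-fixed ancestral so site patterns polarise
        if is_outgroup_hap.any():
            leak = rng.random((len(shared_idx), int(is_outgroup_hap.sum())))
            draws[:, is_outgroup_hap] &= leak < cfg.outgroup_leakage
        matrix[shared_idx] = draws.astype(np.int8)

    if len(private_pool):
        n_private = rng.poisson(cfg.mutation_sites_per_lineage, size=n_haps)
        for h in range(n_haps):
            k = min(n_private[h], len(private_pool))
            if k:
                sites = rng.choice(private_pool, size=k, replace=False)
                matrix[sites, h] = 1

    variants = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "pos": positions,
            "ref": "A",
            "alt": "T",
            "effect_class": "unknown",
        }
    )
    sample_table = pd.DataFrame(
        rows, columns=["sample_id", "population", "species", "karyotype"]
    ).set_index("sample_id")
    ds = HaplotypeDataset(
        variants=variants,
        matrix=matrix,
        haplotype_labels=labels,
        sample_table=sample_table,
        accessible_bases=cfg.region_length,
    )
    hap_truth = pd.DataFrame(
        {
            "sample_id": [l[0] for l in labels],
            "copy": [l[1] for l in labels],
            "population": hap_pop,
            "species": hap_species,
            "karyotype": kary_arr,
            "sweep_carrier": False,
            "sweep_left": np.nan,
            "sweep_right": np.nan,
            "introgression_recipient": False,
            "event_id": -1,
            "tract_start": np.nan,
            "tract_end": np.nan,
        }
    )
    shared_freq_col = np.full(n, np.nan)
    shared_freq_col[shared_idx] = shared_freq
    truth = CohortTruth(
        haplotypes=hap_truth,
        variants=pd.DataFrame(
            {"pos": positions, "origin": origin, "shared_freq": shared_freq_col}
        ),
        core_index=(pos_index[cfg.sweep.core_pos] if cfg.sweep else None),
    )
    return ds, truth


# ---------------------------------------------------------------------------
# Stage 2: hard sweep
# ---------------------------------------------------------------------------

def _sample_major_pick(sample_cols: dict, k: int, rng) -> list[int]:
    """Pick k haplotype columns filling both copies of a sample before the
    next, so high-frequency alleles produce homozygous specimens."""
    order = rng.permutation(list(sample_cols))
    picked: list[int] = []
    for sid in order:
        for col in sample_cols[sid]:
            if len(picked) < k:
                picked.append(col)
        if len(picked) >= k:
            break
    return picked


def _make_founder(cfg: CohortConfig, ds, truth, pop_cols, rng) -> np.ndarray:
    """A fresh background haplotype of the founder karyotype carrying the
    core allele and every linked marker."""
    sw = cfg.sweep
    positions = ds.positions
    origin = truth.variants["origin"].to_numpy()
    founder = np.zeros(ds.n_variants, dtype=np.int8)
    if sw.founder_karyotype == "INV":
        founder[origin == "karyotype_diagnostic"] = 1
    # species backgrounds of the founding population
    sp = truth.haplotypes["species"].to_numpy()[pop_cols[0]]
    sp_cols = np.flatnonzero(truth.haplotypes["species"].to_numpy() == sp)
    sp_sites = np.flatnonzero(
        (origin == "species_diagnostic") & (ds.matrix[:, sp_cols].mean(axis=1) > 0.5)
    )
    founder[sp_sites] = 1
    # its own draw of the shared ancestral polymorphism
    shared_freq = truth.variants["shared_freq"].to_numpy()
    shared = np.flatnonzero(~np.isnan(shared_freq))
    founder[shared] = (rng.random(len(shared)) < shared_freq[shared]).astype(np.int8)
    # a private-mutation load of its own
    pool = np.flatnonzero((origin == "background") & np.isnan(shared_freq))
    k = min(rng.poisson(cfg.mutation_sites_per_lineage), len(pool))
    if k:
        founder[rng.choice(pool, size=k, replace=False)] = 1
    founder[truth.core_index] = 1
    for p in sw.linked_marker_positions:
        founder[ds.variant_index(cfg.chrom, p)] = 1
    return founder


def apply_sweep(
    ds: HaplotypeDataset, truth: CohortTruth, cfg: CohortConfig
) -> tuple[HaplotypeDataset, CohortTruth]:
    """Replace a fraction of haplotypes per population with recombined copies
    of a swept founder haplotype."""
    if cfg.sweep is None:
        raise ValueError("no sweep configured")
    sw = cfg.sweep
    rng = _rng(cfg, 2)
    ds = copy.deepcopy(ds)
    truth = copy.deepcopy(truth)
    positions = ds.positions
    core_pos = sw.core_pos
    hap_pop = truth.haplotypes["population"].to_numpy()

    shared_founder: np.ndarray | None = None
    if sw.founder_scope == "shared":
        first_pop = next(
            p for p, f in sw.carrier_fraction.items() if f > 0
        )
        cols = np.flatnonzero(hap_pop == first_pop)
        shared_founder = _make_founder(cfg, ds, truth, cols, rng)
        truth.founders["shared"] = shared_founder

    for pop_cfg in cfg.populations:
        frac = sw.carrier_fraction.get(pop_cfg.name, 0.0)
        if frac == 0.0:
            continue
        cols = np.flatnonzero(hap_pop == pop_cfg.name)
        k = int(round(frac * len(cols)))
        if k < 1:
            warnings.warn(
                f"carrier_fraction x haplotypes < 1 in {pop_cfg.name}; zero carriers"
            )
            continue
        if sw.founder_scope == "per_population":
            founder = _make_founder(cfg, ds, truth, cols, rng)
            truth.founders[pop_cfg.name] = founder
        else:
            founder = shared_founder
        sample_cols: dict[str, list[int]] = {}
        for c in cols:
            sample_cols.setdefault(truth.haplotypes["sample_id"].iloc[c], []).append(c)
        carriers = _sample_major_pick(sample_cols, k, rng)
        for col in carriers:
            if sw.recomb_rate > 0:
                d_left = rng.exponential(1.0 / sw.recomb_rate)
                d_right = rng.exponential(1.0 / sw.recomb_rate)
            else:
                d_left = d_right = np.inf
            left, right = core_pos - d_left, core_pos + d_right
            inside = (positions > left) & (positions < right)
            ds.matrix[inside, col] = founder[inside]
            truth.haplotypes.loc[col, "sweep_carrier"] = True
            truth.haplotypes.loc[col, "sweep_left"] = left
            truth.haplotypes.loc[col, "sweep_right"] = right
    return ds, truth


# ---------------------------------------------------------------------------
# Stage 3: introgression
# ---------------------------------------------------------------------------

def _group_columns(truth: CohortTruth, selector: str) -> np.ndarray:
    haps = truth.haplotypes
    if selector in ("INV", "STD"):
        return np.flatnonzero(haps["karyotype"].to_numpy() == selector)
    return np.flatnonzero(haps["population"].to_numpy() == selector)


def inject_introgression(
    ds: HaplotypeDataset, truth: CohortTruth, cfg: CohortConfig
) -> tuple[HaplotypeDataset, CohortTruth]:
    """Copy the swept donor haplotype into target haplotypes over a tract."""
    if cfg.sweep is None:
        raise ValueError("introgression requires a configured sweep")
    rng = _rng(cfg, 3)
    ds = copy.deepcopy(ds)
    truth = copy.deepcopy(truth)
    positions = ds.positions
    core_pos = cfg.sweep.core_pos
    for event_id, ev in enumerate(cfg.introgression_events):
        src_cols = _group_columns(truth, ev.source)
        carriers = truth.haplotypes["sweep_carrier"].to_numpy()
        if not carriers[src_cols].any():
            raise ValueError(f"no sweep haplotype in source group {ev.source!r}")
        if ev.source in truth.founders:
            donor = truth.founders[ev.source]
        else:
            donor = truth.founders["shared"]
        tgt_cols = _group_columns(truth, ev.target)
        recipients_flag = truth.haplotypes["introgression_recipient"].to_numpy()
        eligible = tgt_cols[~carriers[tgt_cols] & ~recipients_flag[tgt_cols]]
        if len(eligible) < ev.n_copies:
            raise ValueError(f"target group {ev.target!r} too small for n_copies")
        if ev.pair_samples:
            sample_cols: dict[str, list[int]] = {}
            for c in eligible:
                sample_cols.setdefault(truth.haplotypes["sample_id"].iloc[c], []).append(c)
            chosen = _sample_major_pick(sample_cols, ev.n_copies, rng)
        else:
            chosen = list(rng.choice(eligible, size=ev.n_copies, replace=False))
        lo = core_pos - ev.tract_half_length
        hi = core_pos + ev.tract_half_length
        inside = ((positions >= lo) & (positions < hi)) | (positions == core_pos)
        for col in chosen:
            ds.matrix[inside, col] = donor[inside]
            truth.haplotypes.loc[col, "introgression_recipient"] = True
            truth.haplotypes.loc[col, "event_id"] = event_id
            truth.haplotypes.loc[col, "tract_start"] = lo
            truth.haplotypes.loc[col, "tract_end"] = hi
    return ds, truth


def simulate_cohort(cfg: CohortConfig) -> tuple[HaplotypeDataset, CohortTruth]:
    """Run background -> sweep -> introgression as configured."""
    ds, truth = simulate_background(cfg)
    if cfg.sweep is not None:
        ds, truth = apply_sweep(ds, truth, cfg)
        if cfg.introgression_events:
            ds, truth = inject_introgression(ds, truth, cfg)
    return ds, truth


# ---------------------------------------------------------------------------
# Coding annotation and quartet allele frequencies
# ---------------------------------------------------------------------------

def simulate_coding_annotation(
    ds: HaplotypeDataset,
    truth: CohortTruth,
    fraction_nonsyn: float,
    seed: int,
) -> pd.DataFrame:
    """Assign effect classes: the stated fraction of background variants is
    nonsynonymous (uniform, seeded); sweep core and linked markers are forced
    nonsynonymous (resistance and compensatory substitutions); the rest is
    synonymous."""
    rng = np.random.default_rng(seed)
    origin = truth.variants["origin"].to_numpy()
    effect = np.full(ds.n_variants, "synonymous", dtype=object)
    forced = np.isin(origin, ("sweep_core", "linked_marker"))
    effect[forced] = "nonsynonymous"
    background = np.flatnonzero(~forced)
    k = int(round(fraction_nonsyn * len(background)))
    if k:
        effect[rng.choice(background, size=k, replace=False)] = "nonsynonymous"
    return pd.DataFrame(
        {
            "chrom": ds.variants["chrom"],
            "pos": ds.variants["pos"],
            "effect_class": effect,
        }
    )


def simulate_quartet_frequencies(
    n_sites: int,
    scenario: str = "null",
    effect: float = 0.0,
    seed: int = 0,
    n_chromosomes: int = 40,
    outgroup_freq: float = 0.02,
) -> pd.DataFrame:
    """Per-site derived-allele frequencies for populations A, B, C and
    outgroup O under a (((A,B),C),O) topology.

    ``null``: A and B are independent binomial perturbations (sample size
    ``n_chromosomes``) of a shared ancestral frequency, C an independent
    draw, O near-fixed ancestral.  ``AC_geneflow`` / ``BC_geneflow`` mix C's
    frequency into A (resp. B) with weight ``effect``.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if scenario not in ("null", "AC_geneflow", "BC_geneflow"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    anc = rng.uniform(0.05, 0.95, size=n_sites)
    pA = rng.binomial(n_chromosomes, anc) / n_chromosomes
    pB = rng.binomial(n_chromosomes, anc) / n_chromosomes
    anc_c = rng.uniform(0.05, 0.95, size=n_sites)
    pC = rng.binomial(n_chromosomes, anc_c) / n_chromosomes
    pO = rng.binomial(n_chromosomes, outgroup_freq) / n_chromosomes
    if scenario == "AC_geneflow":
        pA = (1 - effect) * pA + effect * pC
    elif scenario == "BC_geneflow":
        pB = (1 - effect) * pB + effect * pC
    return pd.DataFrame({"pA": pA, "pB": pB, "pC": pC, "pO": pO})
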