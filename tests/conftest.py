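import numpy as np
import pandas as pd
import pytest

from haplosweep import CohortConfig, HaplotypeDataset, attach_metadata, simulate_cohort


def make_dataset(matrix, positions=None, chrom="2L", populations=None, species=None,
                 karyotypes=None, effects=None, accessible=None):
    """Build a HaplotypeDataset from a literal variants x haplotypes matrix.

    Columns are paired into samples (copy 0, copy 1); per-sample labels are
    taken from the even columns.
    """
    matrix = np.asarray(matrix, dtype=np.int8)
    n_var, n_hap = matrix.shape
    assert n_hap % 2 == 0
    positions = positions if positions is not None else np.arange(1, n_var + 1) * 10
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "T",
            "effect_class": effects if effects is not None else "unknown",
        }
    )
    n_samples = n_hap // 2
    sample_ids = [f"s{i:03d}" for i in range(n_samples)]
    labels = [(sid, c) for sid in sample_ids for c in (0, 1)]
    ds = HaplotypeDataset(
        variants=variants,
        matrix=matrix,
        haplotype_labels=labels,
        accessible_bases=accessible or 0,
    )
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "population": (populations or ["pop1"] * n_samples),
            "species": (species or ["sp1"] * n_samples),
            "karyotype": (karyotypes or ["NA"] * n_samples),
        }
    )
    return attach_metadata(ds, meta)


@pytest.fixture
def tiny_ds():
    """4 variants x 6 haplotypes (3 samples) with mixed frequencies."""
    m = np.array(
        [
            [0, 1, 0, 1, 0, 1],
            [1, 1, 0, 0, 0, 0],
            [0, 0, 0, 0, 0, 1],
            [1, 1, 1, 1, 1, 1],
        ]
    )
    # last row is fixed; make it polymorphic so filters have work to do
    m[3, 0] = 0
    return make_dataset(m)


def sweep_cohort_config(seed, carrier_fraction=0.6, recomb_rate=1e-4,
                        n_variants=1200, region_length=100_000,
                        introgression=False, inv_freq=0.0):
    events = []
    if introgression:
        events = [dict(source="P2", target="P1", n_copies=10, tract_half_length=20_000)]
    return CohortConfig(
        seed=seed,
        populations=[
            dict(name="P1", species="sp1", n_samples=25, inv_freq=inv_freq),
            dict(name="P2", species="sp2", n_samples=25, inv_freq=inv_freq),
            dict(name="OUT", species="outg", n_samples=5, is_outgroup=True),
        ],
        region_length=region_length,
        n_variants=n_variants,
        inversion_interval=(1, region_length),
        species_divergence=60,
        sweep=dict(
            core_pos=50_000,
            carrier_fraction={"P2": carrier_fraction},
            linked_marker_positions=[54_000, 46_000],
            recomb_rate=recomb_rate,
        ),
        introgression_events=events,
    )


@pytest.fixture
def swept_cohort():
    return simulate_cohort(sweep_cohort_config(seed=7))


@pytest.fixture
def random_matrix():
    def _make(seed, n_var=20, n_hap=10):
        rng = np.random.default_rng(seed)
        return rng.integers(0, 2, size=(n_var, n_hap)).astype(np.int8)

    return _make
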