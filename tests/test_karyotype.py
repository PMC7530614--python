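import numpy as np
import pandas as pd
import pytest

from haplosweep import (
    CohortConfig,
    genotypes_from_haplotypes,
    karyotype_pipeline,
    patterson_pca,
    sample_inversion_snps,
    simulate_cohort,
    train_karyotype_classifier,
)
from haplosweep.karyotype import assign_karyotypes
from conftest import make_dataset


def karyotype_config(seed, n_per_class=30, n_diag=50, n_variants=1000):
    return CohortConfig(
        seed=seed,
        populations=[
            dict(
                name="P",
                species="sp1",
                n_samples=3 * n_per_class,
                karyotype_counts={
                    "INV/INV": n_per_class,
                    "INV/STD": n_per_class,
                    "STD/STD": n_per_class,
                },
            )
        ],
        region_length=200_000,
        n_variants=n_variants,
        inversion_interval=(20_000, 180_000),
        karyotype_divergence=n_diag,
        shared_poly_fraction=0.6,
        mutation_sites_per_lineage=5.0,
    )


@pytest.fixture(scope="module")
def karyotyped_cohort():
    ds, truth = simulate_cohort(karyotype_config(seed=1))
    return ds, truth


class TestSnpSampling:
    def test_clamps_with_warning_when_few_qualify(self, karyotyped_cohort):
        ds, _ = karyotyped_cohort
        with pytest.warns(UserWarning, match="using all"):
            sub = sample_inversion_snps(ds, "2L:20000-180000", n_snps=10_000, seed=0)
        assert sub.n_variants < 10_000

    def test_deterministic_and_within_interval(self, karyotyped_cohort):
        ds, _ = karyotyped_cohort
        a = sample_inversion_snps(ds, "2L:20000-180000", n_snps=100, seed=3)
        b = sample_inversion_snps(ds, "2L:20000-180000", n_snps=100, seed=3)
        np.testing.assert_array_equal(a.positions, b.positions)
        assert a.n_variants == 100
        assert ((a.positions >= 20_000) & (a.positions <= 180_000)).all()


class TestPattersonPCA:
    def test_identical_samples_score_zero(self):
        m = np.tile(np.array([[0, 1], [1, 0], [0, 1]], dtype=np.int8), (1, 4))
        ds = make_dataset(m)
        # one variant polymorphic across samples is required; duplicate samples
        gm = genotypes_from_haplotypes(ds)
        gm.matrix[0, 0] = 1  # break monomorphism minimally
        pca = patterson_pca(gm, n_components=2)
        # all but the perturbed sample coincide after centering
        assert np.allclose(pca.scores[1:, :], pca.scores[1, :], atol=1e-9)

    def test_antipodal_groups_split_on_pc1(self):
        m = np.zeros((20, 12), dtype=np.int8)
        m[:, 6:] = 1
        ds = make_dataset(m)
        pca = patterson_pca(genotypes_from_haplotypes(ds))
        assert pca.variance_explained[0] == pytest.approx(1.0)
        side = np.sign(pca.scores[:, 0])
        assert len(set(side[:3])) == 1 and side[0] != side[3]

    def test_matches_dense_eigendecomposition_oracle(self):
        rng = np.random.default_rng(7)
        dosages = rng.integers(0, 3, size=(20, 10)).astype(np.int8)
        from haplosweep.core import GenotypeMatrix

        gm = GenotypeMatrix(
            variants=pd.DataFrame({"chrom": "2L", "pos": np.arange(1, 21)}),
            matrix=dosages,
            sample_ids=[f"s{i}" for i in range(10)],
        )
        pca = patterson_pca(gm, n_components=5)
        # oracle: eigen-decompose the covariance of the scaled matrix
        x = dosages.T.astype(float)
        p = x.mean(axis=0) / 2
        keep = (p > 0) & (p < 1)
        scaled = (x[:, keep] - 2 * p[keep]) / np.sqrt(p[keep] * (1 - p[keep]))
        evals = np.linalg.eigvalsh(scaled @ scaled.T)[::-1]
        np.testing.assert_allclose(
            (pca.scores**2).sum(axis=0), evals[:5], rtol=1e-8
        )
        np.testing.assert_allclose(
            pca.variance_explained[:5], evals[:5] / evals.sum(), rtol=1e-8
        )

    def test_sample_order_invariance_up_to_sign(self, karyotyped_cohort):
        ds, _ = karyotyped_cohort
        sub = sample_inversion_snps(ds, "2L:20000-180000", n_snps=200, seed=1)
        gm = genotypes_from_haplotypes(sub)
        pca1 = patterson_pca(gm, 3)
        perm = np.random.default_rng(0).permutation(gm.n_samples)
        from haplosweep.core import GenotypeMatrix

        gm2 = GenotypeMatrix(
            variants=gm.variants,
            matrix=gm.matrix[:, perm],
            sample_ids=[gm.sample_ids[i] for i in perm],
        )
        pca2 = patterson_pca(gm2, 3)
        np.testing.assert_allclose(
            np.abs(pca1.scores[perm]), np.abs(pca2.scores), atol=1e-8
        )

    def test_all_monomorphic_errors(self):
        ds = make_dataset(np.zeros((5, 8), dtype=np.int8))
        with pytest.raises(ValueError):
            patterson_pca(genotypes_from_haplotypes(ds))


class TestClassifier:
    def test_pc1_separates_three_karyotype_clusters(self, karyotyped_cohort):
        ds, truth = karyotyped_cohort
        sub = sample_inversion_snps(ds, "2L:20000-180000", seed=0)
        pca = patterson_pca(genotypes_from_haplotypes(sub))
        labels = ds.sample_table["karyotype"]
        pc1 = {k: pca.scores[np.array(labels) == k, 0] for k in
               ("INV/INV", "INV/STD", "STD/STD")}
        lo, mid, hi = sorted(pc1.values(), key=lambda v: v.mean())
        assert lo.max() < mid.min() and mid.max() < hi.min()
        assert set(np.array(labels)[np.argsort(pca.scores[:, 0])][:30]) == {
            list(pc1)[int(np.argmin([v.mean() for v in pc1.values()]))]
        }

    def test_separable_classes_reach_perfect_training_metrics(self, karyotyped_cohort):
        ds, truth = karyotyped_cohort
        call, pca = karyotype_pipeline(
            ds, "2L:20000-180000", ds.sample_table["karyotype"], seed=0
        )
        assert call.report["accuracy"] == 1.0
        for cls in ("INV/INV", "INV/STD", "STD/STD"):
            assert call.report[cls]["precision"] == 1.0
            assert call.report[cls]["recall"] == 1.0

    def test_truth_recovery_against_simulated_karyotypes(self, karyotyped_cohort):
        ds, truth = karyotyped_cohort
        call, _ = karyotype_pipeline(
            ds, "2L:20000-180000", ds.sample_table["karyotype"], seed=0
        )
        merged = call.calls.merge(
            ds.sample_table.reset_index()[["sample_id", "karyotype"]], on="sample_id"
        )
        assert (merged["predicted_karyotype"] == merged["karyotype"]).all()

    def test_permuted_labels_give_chance_level_accuracy(self, karyotyped_cohort):
        ds, _ = karyotyped_cohort
        sub = sample_inversion_snps(ds, "2L:20000-180000", seed=0)
        pca = patterson_pca(genotypes_from_haplotypes(sub))
        rng = np.random.default_rng(5)
        labels = ds.sample_table["karyotype"].copy()
        labels[:] = rng.permutation(labels.to_numpy())
        _, report = train_karyotype_classifier(pca, labels)
        assert report["accuracy"] < 0.6  # three balanced classes -> ~1/3

    def test_single_class_errors(self, karyotyped_cohort):
        ds, _ = karyotyped_cohort
        sub = sample_inversion_snps(ds, "2L:20000-180000", n_snps=100, seed=0)
        pca = patterson_pca(genotypes_from_haplotypes(sub))
        labels = ds.sample_table["karyotype"].copy()
        labels[:] = "INV/INV"
        with pytest.raises(ValueError):
            train_karyotype_classifier(pca, labels)

    def test_unlabeled_sample_assigned_training_twin_class(self, karyotyped_cohort):
        ds, _ = karyotyped_cohort
        sub = sample_inversion_snps(ds, "2L:20000-180000", seed=0)
        pca = patterson_pca(genotypes_from_haplotypes(sub))
        labels = ds.sample_table["karyotype"].copy()
        hidden = labels.index[:5]
        expected = labels.loc[hidden].copy()
        labels.loc[hidden] = "NA"
        clf, _ = train_karyotype_classifier(pca, labels)
        call = assign_karyotypes(clf, pca, training_labels=labels)
        got = call.calls.set_index("sample_id").loc[hidden]
        assert (got["predicted_karyotype"] == expected).all()
        assert not got["was_training"].any()
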