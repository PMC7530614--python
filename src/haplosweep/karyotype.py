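"""Chromosomal-inversion karyotyping from genotype data.

Random SNP selection inside the inversion interval, Patterson-scaled PCA of
the genotype matrix, and a supervised linear maximum-margin classifier
(SVC, linear kernel, C=1) trained on reference karyotypes.  Homozygous
inverted, heterozygous and homozygous standard arrangements form three
clusters along PC1 when the backgrounds are sufficiently diverged, with
heterozygotes intermediate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics
from sklearn.svm import SVC

from .core import GenotypeMatrix, HaplotypeDataset, filter_nonsingleton, filter_segregating, genotypes_from_haplotypes, parse_region

KARYOTYPE_CLASSES = ("INV/INV", "INV/STD", "STD/STD")


@dataclass
class PCAResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # variants x components
    variance_explained: np.ndarray  # fraction per component
    sample_ids: list


@dataclass
class KaryotypeCall:
    calls: pd.DataFrame  # sample_id, predicted_karyotype, was_training
    report: dict  # accuracy + per-class precision/recall on the training set


def sample_inversion_snps(
    ds: HaplotypeDataset,
    interval: str,
    n_snps: int = 10000,
    seed: int = 0,
    min_freq: float = 0.05,
    min_carriers: int = 3,
) -> HaplotypeDataset:
    """Seeded uniform sample of qualifying SNPs inside the inversion.

    Qualifying = biallelic (by construction), minor allele on >=
    ``min_carriers`` haplotypes, and segregating above ``min_freq`` in at
    least one population.  When fewer than ``n_snps`` qualify, all are
    returned with a warning.
    """
    sub = ds.region(interval)
    sub = filter_nonsingleton(sub, min_carriers=min_carriers)
    sub = filter_segregating(sub, min_freq=min_freq)
    if sub.n_variants == 0:
        raise ValueError("no qualifying variants inside the inversion interval")
    if sub.n_variants <= n_snps:
        if sub.n_variants < n_snps:
            warnings.warn(
                f"only {sub.n_variants} qualifying variants; using all of them"
            )
        return sub
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(sub.n_variants, size=n_snps, replace=False))
    return sub.take_variants(idx)


def patterson_pca(gm: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """PCA of the dosage matrix with Patterson scaling.

    Each variant column is centred by its mean dosage and scaled by
    sqrt(p(1-p)) with p = mean/2; monomorphic variants are dropped.
    Component signs are fixed so the first retained variant's loading is
    non-negative, making outputs reproducible.
    """
    x = gm.matrix.T.astype(float)  # samples x variants
    if x.shape[0] < 2:
        raise ValueError("PCA requires >= 2 samples")
    p = x.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    if not keep.any():
        raise ValueError("all variants monomorphic in the sample set")
    x = x[:, keep]
    p = p[keep]
    scaled = (x - 2 * p) / np.sqrt(p * (1 - p))
    u, s, vt = np.linalg.svd(scaled, full_matrices=False)
    k = min(n_components, len(s))
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # sign convention: first variant loading non-negative per component
    signs = np.where(vt[:, 0] < 0, -1.0, 1.0)
    u = u * signs
    vt = vt * signs[:, None]
    total_var = (scaled**2).sum()
    return PCAResult(
        scores=u * s,
        loadings=vt.T,
        variance_explained=(s**2) / total_var,
        sample_ids=list(gm.sample_ids),
    )


@dataclass
class KaryotypeClassifier:
    model: SVC
    n_components: int


def train_karyotype_classifier(
    pca: PCAResult, labels: pd.Series, n_components: int = 10
) -> tuple[KaryotypeClassifier, dict]:
    """Fit a linear SVC (C=1) on the leading PCA scores of labelled samples.

    ``labels`` maps sample id -> karyotype class; unlabeled samples
    (missing or "NA") are excluded from training.  Returns the classifier
    and a training-set report with accuracy and per-class precision/recall.
    """
    idx = [
        i
        for i, sid in enumerate(pca.sample_ids)
        if sid in labels.index and labels.loc[sid] not in ("NA", "", None)
    ]
    if not idx:
        raise ValueError("no labelled samples to train on")
    y = labels.loc[[pca.sample_ids[i] for i in idx]].to_numpy()
    if len(set(y)) < 2:
        raise ValueError("training labels contain a single class")
    k = min(n_components, pca.scores.shape[1])
    x = pca.scores[idx, :k]
    model = SVC(kernel="linear", C=1.0)
    model.fit(x, y)
    pred = model.predict(x)
    report = metrics.classification_report(y, pred, output_dict=True, zero_division=0)
    report["accuracy"] = float(metrics.accuracy_score(y, pred))
    return KaryotypeClassifier(model=model, n_components=k), report


def assign_karyotypes(
    clf: KaryotypeClassifier,
    pca: PCAResult,
    training_labels: pd.Series | None = None,
) -> KaryotypeCall:
    """Predict a karyotype class for every sample in the PCA."""
    x = pca.scores[:, : clf.n_components]
    if x.shape[1] != clf.n_components:
        raise ValueError("score dimensionality does not match the classifier")
    pred = clf.model.predict(x)
    was_training = [
        training_labels is not None
        and sid in training_labels.index
        and training_labels.loc[sid] not in ("NA", "", None)
        for sid in pca.sample_ids
    ]
    calls = pd.DataFrame(
        {
            "sample_id": pca.sample_ids,
            "predicted_karyotype": pred,
            "was_training": was_training,
        }
    )
    return KaryotypeCall(calls=calls, report={})


def karyotype_pipeline(
    ds: HaplotypeDataset,
    interval: str,
    labels: pd.Series,
    n_snps: int = 10000,
    n_components: int = 10,
    seed: int = 0,
) -> tuple[KaryotypeCall, PCAResult]:
    """SNP sampling -> Patterson PCA -> linear SVC -> calls for all samples."""
    sub = sample_inversion_snps(ds, interval, n_snps=n_snps, seed=seed)
    gm = genotypes_from_haplotypes(sub)
    pca = patterson_pca(gm, n_components=n_components)
    clf, report = train_karyotype_classifier(pca, labels, n_components=n_components)
    call = assign_karyotypes(clf, pca, training_labels=labels)
    call.report = report
    return call, pca
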