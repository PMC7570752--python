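import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from spectrofibro.cluster import (ClusterAnnotation, annotate_clusters,
                                  area_percent, default_templates,
                                  fit_common_kmeans, fit_kmeans)
from spectrofibro.io import SpectralImage, WavenumberAxis

from conftest import small_image


def brute_force_two_means(points: np.ndarray) -> float:
    """Global optimum inertia over every bipartition (oracle, n <= ~16)."""
    n = len(points)
    best = np.inf
    for bits in range(1, 2 ** (n - 1)):  # fix point 0 in group A
        sel = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        if not sel.any() or sel.all():
            continue
        inertia = 0.0
        for grp in (points[sel], points[~sel]):
            inertia += ((grp - grp.mean(axis=0)) ** 2).sum()
        best = min(best, inertia)
    return best


@pytest.fixture(scope="module")
def axis():
    return WavenumberAxis(np.arange(1000.0, 1101.0, 2.0))


def _two_population_image(axis, n1=40, n2=20, noise=0.02, seed=0):
    rng = np.random.default_rng(seed)
    b = len(axis)
    v = axis.values
    pop1 = np.exp(-((v - 1030.0) ** 2) / (2 * 8.0**2))
    pop2 = np.exp(-((v - 1070.0) ** 2) / (2 * 8.0**2))
    spectra = np.vstack([
        pop1 + rng.normal(0, noise, (n1, b)),
        pop2 + rng.normal(0, noise, (n2, b)),
    ])
    labels_true = np.array([0] * n1 + [1] * n2)
    return small_image(spectra, axis, (n1 + n2, 1)), labels_true


class TestFitKMeans:
    def test_k1_single_class_mean_centroid(self, axis):
        img, _ = _two_population_image(axis)
        model, labels = fit_kmeans(img, 1, seed=0)
        assert (labels.labels[labels.valid] == 0).all()
        assert np.allclose(model.centroids[0],
                           img.valid_spectra().mean(axis=0))

    def test_two_populations_ari_one(self, axis):
        img, truth = _two_population_image(axis)
        _, labels = fit_kmeans(img, 2, seed=0)
        assert adjusted_rand_score(truth, labels.labels[labels.valid]) == 1.0

    def test_matches_exhaustive_bipartition_optimum(self, axis):
        rng = np.random.default_rng(3)
        img, _ = _two_population_image(axis, n1=7, n2=5, noise=0.3, seed=3)
        model, _ = fit_kmeans(img, 2, seed=0, n_init=10)
        oracle = brute_force_two_means(img.valid_spectra())
        assert model.inertia == pytest.approx(oracle, rel=1e-8)

    def test_centroids_are_class_means(self, axis):
        img, _ = _two_population_image(axis)
        model, labels = fit_kmeans(img, 3, seed=0)
        spectra = img.valid_spectra()
        flat = labels.labels[labels.valid]
        for cid in range(3):
            assert np.allclose(model.centroids[cid],
                               spectra[flat == cid].mean(axis=0), atol=1e-8)

    def test_canonical_ordering_by_size(self, axis):
        img, _ = _two_population_image(axis, n1=40, n2=20)
        model, labels = fit_kmeans(img, 2, seed=0)
        counts = labels.class_counts(2)
        assert counts[0] >= counts[1]

    def test_capacity_error(self, axis):
        img, _ = _two_population_image(axis, n1=2, n2=1)
        with pytest.raises(ValueError):
            fit_kmeans(img, 10, seed=0)

    def test_deterministic_given_seed(self, axis):
        img, _ = _two_population_image(axis)
        m1, l1 = fit_kmeans(img, 3, seed=42)
        m2, l2 = fit_kmeans(img, 3, seed=42)
        assert np.array_equal(m1.centroids, m2.centroids)
        assert np.array_equal(l1.labels, l2.labels)

    def test_random_spectra_init_mode(self, axis):
        img, truth = _two_population_image(axis)
        _, labels = fit_kmeans(img, 2, seed=0, init="random")
        assert adjusted_rand_score(truth, labels.labels[labels.valid]) == 1.0


class TestCommonKMeans:
    def test_single_image_reduces_to_fit_kmeans(self, axis):
        img, _ = _two_population_image(axis)
        m1, l1 = fit_kmeans(img, 2, seed=0)
        m2, (l2,) = fit_common_kmeans([img], 2, seed=0)
        assert np.allclose(m1.centroids, m2.centroids)
        assert np.array_equal(l1.labels, l2.labels)

    def test_pooling_order_invariant(self, axis):
        img1, _ = _two_population_image(axis, n1=30, n2=10, seed=1)
        img2, _ = _two_population_image(axis, n1=10, n2=26, seed=2)
        m_ab, _ = fit_common_kmeans([img1, img2], 2, seed=0)
        m_ba, _ = fit_common_kmeans([img2, img1], 2, seed=0)
        assert np.allclose(m_ab.centroids, m_ba.centroids, atol=1e-8)

    def test_shared_ids_and_histogram_conservation(self, axis):
        imgs = [_two_population_image(axis, seed=s)[0] for s in range(3)]
        model, labels = fit_common_kmeans(imgs, 2, seed=0)
        total = sum(lab.class_counts(model.k) for lab in labels)
        pooled = np.vstack([img.valid_spectra() for img in imgs])
        pooled_labels = model.predict(pooled)
        assert np.array_equal(total, np.bincount(pooled_labels, minlength=2))

    def test_axis_mismatch_rejected(self, axis):
        img1, _ = _two_population_image(axis)
        other_axis = WavenumberAxis(np.arange(2000.0, 2101.0, 2.0))
        img2 = SpectralImage(img1.cube.copy(), other_axis)
        with pytest.raises(ValueError, match="axis"):
            fit_common_kmeans([img1, img2], 2, seed=0)


class TestAnnotation:
    def test_template_identity(self, axis_fingerprint, endmember_spectra):
        from spectrofibro.cluster import KMeansModel

        model = KMeansModel(
            2, np.vstack([endmember_spectra["collagen_a"],
                          endmember_spectra["glycogen_nodule"]]),
            axis_fingerprint, seed=0, inertia=0.0)
        ann = annotate_clusters(model, default_templates(axis_fingerprint))
        assert ann.mapping == {0: "fibrosis", 1: "nodule"}

    def test_noisy_centroid_still_matched(self, axis_fingerprint,
                                          endmember_spectra):
        from spectrofibro.cluster import KMeansModel

        rng = np.random.default_rng(0)
        noisy = endmember_spectra["glycogen_nodule"] + rng.normal(
            0, 0.01, len(axis_fingerprint))
        model = KMeansModel(1, noisy[None, :], axis_fingerprint, 0, 0.0)
        ann = annotate_clusters(model, default_templates(axis_fingerprint))
        assert ann.mapping == {0: "nodule"}

    def test_manual_mapping_wins(self, axis_fingerprint, endmember_spectra):
        from spectrofibro.cluster import KMeansModel

        model = KMeansModel(
            2, np.vstack([endmember_spectra["collagen_a"],
                          endmember_spectra["glycogen_nodule"]]),
            axis_fingerprint, 0, 0.0)
        ann = annotate_clusters(model, manual={0: "nodule", 1: "fibrosis"})
        assert ann.mapping == {0: "nodule", 1: "fibrosis"}

    def test_tie_raises(self, axis_fingerprint, endmember_spectra):
        from spectrofibro.cluster import KMeansModel

        spec = endmember_spectra["glycogen_nodule"]
        model = KMeansModel(1, spec[None, :], axis_fingerprint, 0, 0.0)
        templates = {"fibrosis": spec, "nodule": spec.copy()}
        with pytest.raises(ValueError, match="tie"):
            annotate_clusters(model, templates)


class TestAreaPercent:
    def test_single_class_is_hundred(self, axis):
        img, _ = _two_population_image(axis)
        model, labels = fit_kmeans(img, 1, seed=0)
        ann = ClusterAnnotation({0: "fibrosis"})
        assert area_percent(labels, ann, "fibrosis") == 100.0

    def test_percentages_conserve(self, axis):
        img, _ = _two_population_image(axis)
        model, labels = fit_kmeans(img, 3, seed=0)
        ann = ClusterAnnotation({0: "fibrosis", 1: "nodule", 2: "other"})
        total = sum(area_percent(labels, ann, t)
                    for t in ("fibrosis", "nodule", "other"))
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_recovery_on_phantom(self, phantom30):
        from spectrofibro.emsc import dewax

        _, truth, cube, paraffin, _ = phantom30
        corrected, _, _ = dewax(cube, paraffin)
        model, labels = fit_kmeans(corrected, 3, seed=0)
        ann = annotate_clusters(model, default_templates(corrected.axis))
        pct = area_percent(labels, ann, "fibrosis")
        assert pct == pytest.approx(truth.fibrosis_fraction, abs=2.0)


def test_fibrosis_stays_compact_while_nodules_subdivide(phantom30):
    """Across k = 2..5 the fibrosis area occupies at most two classes."""
    from spectrofibro.emsc import dewax

    _, truth, cube, paraffin, _ = phantom30
    corrected, _, _ = dewax(cube, paraffin)
    fib = truth.fibrosis & corrected.mask
    for k in (2, 3, 4, 5):
        _, labels = fit_kmeans(corrected, k, seed=0)
        fib_labels = labels.labels[fib]
        counts = np.bincount(fib_labels[fib_labels >= 0], minlength=k)
        # classes holding >= 5% of fibrosis pixels
        assert (counts > 0.05 * counts.sum()).sum() <= 2
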