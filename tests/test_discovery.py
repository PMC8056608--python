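"""Discovery: ROI cropping, PCA+UMAP reduction, noise-cluster removal,
silhouette-guided spectral subclustering and centroid exemplars."""

import numpy as np
import pytest
from sklearn.datasets import make_blobs
from sklearn.metrics import adjusted_rand_score, silhouette_score

from maps_hcm.detection import detect_cells
from maps_hcm.discovery import (
    ReducedEmbedding,
    centroid_exemplars,
    crop_rois,
    embedding_table,
    mean_silhouette,
    reduce_features,
    silhouette_sweep,
    split_noise_cluster,
    subcluster,
)
from maps_hcm.features import RadialProfileExtractor, extract_features
from maps_hcm.synthetic import SyntheticSpec, generate_field
from maps_hcm.types import BBox, Detection

from conftest import make_garbage_rois, make_phenotype_rois


def _planted_blobs(k: int, n: int = 300, seed: int = 0):
    return make_blobs(n_samples=n, n_features=200, centers=k, cluster_std=1.0,
                      center_box=(-30.0, 30.0), random_state=seed)


class TestCropRois:
    @pytest.fixture(scope="class")
    def field_and_detections(self):
        spec = SyntheticSpec(seed=6, noise_multiplier=0.0, transfected_fraction=1.0)
        field, truth = generate_field(spec)
        dets = detect_cells(field)
        return field, truth, dets

    def test_one_roi_per_detection(self, field_and_detections):
        field, _, dets = field_and_detections
        rois = crop_rois([field], {field.field_id: dets})
        assert len(rois) == len(dets)
        assert all(r.pixels.shape[0] == 3 for r in rois)

    def test_corner_detection_clipped_not_failed(self, field_and_detections):
        field, _, _ = field_and_detections
        corner = Detection(BBox(0.0, 0.0, 0.1, 0.1), 0.9)
        rois = crop_rois([field], {field.field_id: [corner]}, pad=0.5)
        assert len(rois) == 1

    def test_resize_to_extractor_input(self, field_and_detections):
        field, _, dets = field_and_detections
        rois = crop_rois([field], {field.field_id: dets}, output_size=64)
        assert all(r.pixels.shape == (3, 64, 64) for r in rois)

    def test_nuclear_cell_crop_keeps_target_mass(self):
        """A crop of a nuclear-phenotype cell keeps >= 80% of its
        target-channel mass above background."""
        spec = SyntheticSpec(seed=12, cells_per_field=(1, 1),
                             transfected_fraction=1.0,
                             phenotype_mix=(1.0, 0.0, 0.0),
                             noise_multiplier=0.0)
        field, truth = generate_field(spec)
        bg = spec.background[2]
        signal = np.clip(field.channel("target") - bg, 0, None)
        rois = crop_rois([field], {field.field_id: [
            Detection(truth.boxes[0].bbox, 1.0)
        ]})
        crop_signal = np.clip(rois[0].pixels[2] - bg, 0, None)
        assert crop_signal.sum() >= 0.8 * signal.sum()

    def test_unknown_field_reference_rejected(self, field_and_detections):
        field, _, dets = field_and_detections
        with pytest.raises(KeyError, match="ghost"):
            crop_rois([field], {"ghost": dets})


class TestReduceFeatures:
    def test_output_shapes(self):
        X, _ = _planted_blobs(3, n=200)
        emb = reduce_features(X, seed=0)
        assert emb.coords30.shape == (200, 30)
        assert emb.coords2.shape == (200, 2)

    def test_small_input_clamps_neighbors_with_warning(self):
        X, _ = _planted_blobs(2, n=50)
        with pytest.warns(UserWarning, match="clamping"):
            emb = reduce_features(X, seed=0)
        assert emb.coords30.shape[0] == 50

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            reduce_features(np.zeros((2, 10)), seed=0)

    def test_two_blobs_separate_in_2d(self):
        """Planted 2-blob structure survives to the visualization plane."""
        X, y = _planted_blobs(2, n=200)
        emb = reduce_features(X, seed=0)
        assert silhouette_score(emb.coords2, y) > 0.5

    def test_seeded_determinism(self):
        X, _ = _planted_blobs(2, n=120)
        a = reduce_features(X, seed=3)
        b = reduce_features(X, seed=3)
        assert np.array_equal(a.coords30, b.coords30)
        assert np.array_equal(a.coords2, b.coords2)


class TestMeanSilhouette:
    def test_hand_computed_example(self):
        """{0,1} vs {10,11} on a line: mean s = 0.89975."""
        coords = np.array([0.0, 1.0, 10.0, 11.0])
        assert mean_silhouette(coords, [0, 0, 1, 1]) == pytest.approx(
            0.8997493734, abs=1e-9
        )

    def test_coincident_clusters_score_nonpositive(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(0, 1, (40, 3))
        labels = [0, 1] * 20
        assert mean_silhouette(coords, labels) <= 0.05

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(4, 30))
            coords = rng.normal(0, 1, (n, 2))
            labels = rng.integers(0, 3, n)
            if len(np.unique(labels)) < 2:
                continue
            s = mean_silhouette(coords, labels)
            assert -1.0 <= s <= 1.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            mean_silhouette(np.zeros((4, 2)), [0, 0, 0, 0])

    def test_matches_brute_force_oracle(self):
        """200 random small instances against a literal double-loop
        implementation of s = (b-a)/max(a,b)."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(4, 41))
            k = int(rng.integers(2, min(n, 5)))
            coords = rng.normal(0, 1, (n, int(rng.integers(1, 4))))
            labels = rng.integers(0, k, n)
            if len(np.unique(labels)) < 2:
                continue
            scores = []
            for i in range(n):
                own = [j for j in range(n) if labels[j] == labels[i] and j != i]
                if not own:
                    scores.append(0.0)
                    continue
                a = np.mean([np.linalg.norm(coords[i] - coords[j]) for j in own])
                b = min(
                    np.mean([np.linalg.norm(coords[i] - coords[j])
                             for j in range(n) if labels[j] == other])
                    for other in np.unique(labels) if other != labels[i]
                )
                scores.append((b - a) / max(a, b))
            assert mean_silhouette(coords, labels) == pytest.approx(
                np.mean(scores), abs=1e-9
            )

    def test_agrees_with_sklearn_when_no_singletons(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(0, 1, (60, 4))
        labels = np.repeat([0, 1, 2], 20)
        assert mean_silhouette(coords, labels) == pytest.approx(
            silhouette_score(coords, labels), abs=1e-9
        )


class TestSubclusterAndSweep:
    def test_planted_k_recovered_with_high_ari(self):
        X, y = _planted_blobs(3)
        emb = reduce_features(X, seed=0)
        sweep = silhouette_sweep(emb.coords30, range(2, 8), seed=0)
        assert sweep.chosen_k == 3
        labels = subcluster(emb.coords30, 3, seed=0)
        assert adjusted_rand_score(y, labels) > 0.9

    def test_two_blobs_split_perfectly(self):
        X, y = _planted_blobs(2, n=150)
        emb = reduce_features(X, seed=0)
        labels = subcluster(emb.coords30, 2, seed=0)
        assert adjusted_rand_score(y, labels) == pytest.approx(1.0)

    def test_labels_cover_exactly_k_clusters(self):
        X, _ = _planted_blobs(4, n=200)
        emb = reduce_features(X, seed=1)
        labels = subcluster(emb.coords30, 4, seed=1)
        assert sorted(set(labels)) == [0, 1, 2, 3]
        # stable relabeling: sizes descending
        sizes = np.bincount(labels)
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_k_out_of_range_rejected(self):
        coords = np.zeros((10, 3))
        with pytest.raises(ValueError):
            subcluster(coords, 1)
        with pytest.raises(ValueError):
            subcluster(coords, 10)

    def test_sweep_rerun_is_identical(self):
        X, _ = _planted_blobs(3, n=150)
        emb = reduce_features(X, seed=2)
        a = silhouette_sweep(emb.coords30, range(2, 6), seed=2)
        b = silhouette_sweep(emb.coords30, range(2, 6), seed=2)
        assert a.silhouettes == b.silhouettes and a.chosen_k == b.chosen_k

    def test_empty_k_range_rejected(self):
        with pytest.raises(ValueError):
            silhouette_sweep(np.zeros((10, 2)), [])


class TestSplitNoiseCluster:
    def test_planted_garbage_rois_flagged(self):
        """Random-noise patches cluster apart and are auto-discarded."""
        rois = (make_phenotype_rois("nuclear", 90, seed=20)
                + make_phenotype_rois("nuclear_excluded", 95, seed=21)
                + make_phenotype_rois("diffuse", 100, seed=22)
                + make_garbage_rois(15, seed=23))
        X = extract_features(rois, RadialProfileExtractor())
        emb = reduce_features(X, seed=0)
        retained = split_noise_cluster(emb, seed=0)
        assert (~retained[-15:]).all()  # all garbage flagged
        assert retained[:-15].mean() > 0.95  # real cells kept

    def test_balanced_split_guard_rail(self):
        """A near-even split discards nothing and warns."""
        X, _ = _planted_blobs(2, n=200)
        emb = reduce_features(X, seed=0)
        with pytest.warns(UserWarning, match="review"):
            retained = split_noise_cluster(emb, seed=0)
        assert retained.all()

    def test_flags_partition_the_data(self):
        X, _ = _planted_blobs(2, n=100)
        emb = reduce_features(X, seed=1)
        with pytest.warns(UserWarning):
            retained = split_noise_cluster(emb, seed=1)
        assert retained.sum() + (~retained).sum() == emb.n


class TestCentroidExemplars:
    @pytest.fixture(scope="class")
    def clustered_rois(self):
        rois = (make_phenotype_rois("nuclear", 40, seed=30)
                + make_phenotype_rois("nuclear_excluded", 40, seed=31)
                + make_phenotype_rois("diffuse", 40, seed=32))
        X = extract_features(rois, RadialProfileExtractor())
        emb = reduce_features(X, seed=0)
        emb.top_cluster = np.ones(emb.n, dtype=bool)
        emb.subcluster = subcluster(emb.coords30, 3, seed=0)
        return rois, emb

    def test_small_cluster_returns_all_members_with_warning(self):
        rng = np.random.default_rng(3)
        coords = np.vstack([rng.normal(0, 0.1, (5, 30)),
                            rng.normal(10, 0.1, (25, 30))])
        emb = ReducedEmbedding(coords30=coords, coords2=coords[:, :2])
        emb.top_cluster = np.ones(30, dtype=bool)
        emb.subcluster = np.array([1] * 5 + [0] * 25)
        rois = make_phenotype_rois("nuclear", 30, seed=33)
        with pytest.warns(UserWarning, match="only 5"):
            table = centroid_exemplars(emb, rois, n_neighbors=20)
        assert (table["cluster"] == 1).sum() == 5

    def test_distances_non_decreasing_within_cluster(self, clustered_rois):
        rois, emb = clustered_rois
        table = centroid_exemplars(emb, rois, n_neighbors=20)
        for _, group in table.groupby("cluster"):
            d = list(group.sort_values("rank")["distance"])
            assert all(a <= b for a, b in zip(d, d[1:]))

    def test_exemplars_share_cluster_majority_label(self, clustered_rois):
        """>= 80% of each cluster's exemplars carry the cluster's
        majority ground-truth phenotype."""
        rois, emb = clustered_rois
        table = centroid_exemplars(emb, rois, n_neighbors=20)
        by_id = {r.roi_id: r.label for r in rois}
        for _, group in table.groupby("cluster"):
            labels = [by_id[rid] for rid in group["roi"]]
            majority = max(set(labels), key=labels.count)
            assert labels.count(majority) / len(labels) >= 0.8

    def test_montages_and_csv_written(self, clustered_rois, tmp_path):
        rois, emb = clustered_rois
        centroid_exemplars(emb, rois, n_neighbors=5, out_dir=tmp_path)
        assert (tmp_path / "exemplars.csv").exists()
        assert (tmp_path / "cluster_0_exemplars.png").exists()

    def test_embedding_table_schema(self, clustered_rois):
        rois, emb = clustered_rois
        table = embedding_table(emb, rois)
        assert list(table.columns) == ["roi", "source_image", "umap1", "umap2",
                                       "noise", "subcluster"]
        assert len(table) == emb.n
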