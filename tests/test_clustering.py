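"""Two-step clustering: DBSCAN, rendering, template seeding, k-means."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from paintdenoise import (
    TwoStepClusterer,
    ValidationError,
    dbscan_cluster,
    kmeans_partition,
    median_precision,
    render_cluster,
    seed_centroids,
    simulate_nanorulers,
    two_step_cluster,
)

from conftest import make_table


# ---------------------------------------------------------------- median

def test_median_precision_convention():
    assert median_precision(make_table([0, 0, 0], [0, 0, 0], precision=[10, 12, 14])) == 12
    # lower-of-two-middles for even counts
    assert median_precision(make_table([0, 0], [0, 0], precision=[10, 20])) == 10


def test_median_precision_matches_sort_oracle(rng):
    prec = rng.uniform(5, 20, 1001)
    t = make_table(np.zeros(1001), np.zeros(1001), precision=prec)
    assert median_precision(t) == np.sort(prec)[500]


def test_median_precision_empty_table_errors():
    with pytest.raises(ValidationError):
        median_precision(make_table([], []))


# ---------------------------------------------------------------- DBSCAN

def brute_force_dbscan(xy, eps, min_pts):
    """O(n^2) reference: cores by neighbour count, clusters by core
    connectivity in first-core-index order, borders to the lowest cluster."""
    n = len(xy)
    d = cdist(xy, xy)
    neighbours = d <= eps
    core = neighbours.sum(axis=1) >= min_pts
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        # flood-fill over cores
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            for k in np.flatnonzero(neighbours[j]):
                if core[k] and labels[k] == -1:
                    labels[k] = cid
                    stack.append(k)
        cid += 1
    for i in range(n):  # borders join the lowest-id cluster with a core neighbour
        if labels[i] == -1 and not core[i]:
            owners = labels[np.flatnonzero(neighbours[i] & core)]
            if owners.size:
                labels[i] = owners.min()
    return labels


def test_dbscan_identical_points():
    t5 = make_table(np.zeros(5), np.zeros(5))
    assert set(dbscan_cluster(t5, eps_nm=1.0, min_pts=5)) == {0}
    t4 = make_table(np.zeros(4), np.zeros(4))
    assert set(dbscan_cluster(t4, eps_nm=1.0, min_pts=5)) == {-1}


def test_dbscan_two_blobs(blob_table):
    labels = dbscan_cluster(blob_table, eps_nm=15.0, min_pts=5)
    assert set(labels[labels >= 0]) == {0, 1}
    left = labels[:100][labels[:100] >= 0]
    right = labels[100:][labels[100:] >= 0]
    assert np.unique(left).size == 1 and np.unique(right).size == 1
    assert left[0] != right[0]


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_dbscan_agrees_with_brute_force(seed):
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0, 400, size=(6, 2))
    pts = np.vstack([c + rng.normal(0, 12, size=(60, 2)) for c in centers]
                    + [rng.uniform(0, 400, size=(80, 2))])
    t = make_table(pts[:, 0], pts[:, 1])
    got = dbscan_cluster(t, eps_nm=10.0, min_pts=5)
    ref = brute_force_dbscan(pts, 10.0, 5)
    np.testing.assert_array_equal(got, ref)


# ---------------------------------------------------------------- rendering

def test_render_single_and_stacked():
    t = make_table([100.0], [50.0])
    img = render_cluster(t, [0], pixel_nm=5.0)
    assert img.grid.sum() == 1
    assert (img.grid > 0).sum() == 1

    t10 = make_table(np.full(10, 100.0), np.full(10, 50.0))
    img10 = render_cluster(t10, np.arange(10), pixel_nm=5.0)
    assert img10.grid.max() == 10
    assert (img10.grid > 0).sum() == 1


def test_render_mass_conservation(rng):
    pts = rng.normal(0, 30, size=(100, 2))
    t = make_table(pts[:, 0], pts[:, 1])
    img = render_cluster(t, np.arange(100), pixel_nm=5.0)
    assert img.grid.sum() == 100


# ---------------------------------------------------------------- seeding

def _spot_table(rng, centers, n_per=120, sigma=10.0):
    pts = np.vstack([c + rng.normal(0, sigma, size=(n_per, 2)) for c in centers])
    return make_table(pts[:, 0], pts[:, 1], precision=sigma)


def test_seed_single_spot(rng):
    t = _spot_table(rng, [(0.0, 0.0)])
    img = render_cluster(t, np.arange(len(t)), pixel_nm=5.0)
    seeds = seed_centroids(img, sigma_nm=10.0)
    assert seeds.shape[0] == 1
    assert np.hypot(*seeds[0]) < 10.0  # at the spot peak (within ~1 sigma)


def test_seed_two_spots_8_sigma_apart(rng):
    t = _spot_table(rng, [(0.0, 0.0), (80.0, 0.0)])
    img = render_cluster(t, np.arange(len(t)), pixel_nm=5.0)
    seeds = seed_centroids(img, sigma_nm=10.0)
    assert seeds.shape[0] == 2


def test_seed_three_collinear_nanoruler_marks(rng):
    # nanoruler geometry: 3 marks, 80 nm apart, sigma = 10 nm
    t = _spot_table(rng, [(-80.0, 0.0), (0.0, 0.0), (80.0, 0.0)])
    img = render_cluster(t, np.arange(len(t)), pixel_nm=5.0)
    seeds = seed_centroids(img, sigma_nm=10.0)
    assert seeds.shape[0] == 3


def test_seed_all_zero_image_errors():
    from paintdenoise import RenderedImage

    with pytest.raises(ValidationError):
        seed_centroids(RenderedImage(np.zeros((4, 4)), 5.0, (0.0, 0.0)), 10.0)


# ---------------------------------------------------------------- k-means

def test_kmeans_k1_gives_mean(blob_table):
    clusters = kmeans_partition(blob_table, np.arange(100), seeds=[[0.0, 0.0]])
    assert len(clusters) == 1
    np.testing.assert_allclose(
        clusters[0].centroid_nm,
        [blob_table.x_nm[:100].mean(), blob_table.y_nm[:100].mean()],
    )


def test_kmeans_two_blobs_nearest_assignment(blob_table):
    clusters = kmeans_partition(
        blob_table, np.arange(200), seeds=[[0.0, 0.0], [500.0, 0.0]]
    )
    assert len(clusters) == 2
    assert set(clusters[0].member_indices) == set(range(100))
    assert set(clusters[1].member_indices) == set(range(100, 200))


def test_kmeans_fewer_members_than_seeds():
    t = make_table([0.0, 1.0], [0.0, 0.0])
    clusters = kmeans_partition(t, [0, 1], seeds=[[0, 0], [1, 0], [2, 0]])
    assert sum(c.member_indices.size for c in clusters) == 2


# ---------------------------------------------------------------- two-step

def test_two_step_empty_table():
    assert two_step_cluster(make_table([], [])) == []


def test_two_step_partition_property(rng):
    table, _ = simulate_nanorulers(6, seed=3)
    clusters = two_step_cluster(table)
    all_members = np.concatenate([c.member_indices for c in clusters])
    # no localization duplicated across final clusters
    assert all_members.size == np.unique(all_members).size
    # each final cluster comes from exactly one DBSCAN cluster and membership
    # is conserved within it
    from paintdenoise.clustering import dbscan_cluster as db

    labels = db(table, median_precision(table), 5)
    for c in clusters:
        assert np.unique(labels[c.member_indices]).size == 1
        assert c.parent_dbscan_id == labels[c.member_indices[0]]
    clustered = np.flatnonzero(labels >= 0)
    assert np.array_equal(np.sort(all_members), clustered)


def test_two_step_translation_invariance(rng):
    table, _ = simulate_nanorulers(4, seed=9)
    shifted = make_table(
        table.x_nm + 1234.5, table.y_nm - 987.6, frame=table.frame,
        precision=table.precision_nm, n_frames=table.n_frames,
    )
    c0 = two_step_cluster(table)
    c1 = two_step_cluster(shifted)
    assert len(c0) == len(c1)
    for a, b in zip(c0, c1):
        np.testing.assert_array_equal(a.member_indices, b.member_indices)
        np.testing.assert_allclose(
            np.asarray(b.centroid_nm) - np.asarray(a.centroid_nm),
            [1234.5, -987.6], atol=1e-6,
        )


def test_nanoruler_kmeans_mark_recovery(rng):
    table, truth = simulate_nanorulers(10, seed=4)
    clusters = two_step_cluster(table)
    # >95% of localizations assigned to a cluster dominated by their own mark
    correct = total = 0
    for c in clusters:
        marks = truth.loc_mark_id[c.member_indices] + 10 * truth.loc_cluster_id[c.member_indices]
        dominant = np.bincount(marks).argmax()
        correct += (marks == dominant).sum()
        total += marks.size
    assert correct / total > 0.95


def test_estimator_api(blob_table):
    from sklearn.base import clone

    est = TwoStepClusterer(min_pts=5)
    est2 = clone(est)
    labels = est2.fit(blob_table).labels_
    assert labels.shape == (len(blob_table),)
    assert est2.n_clusters_ == len(est2.clusters_)
    assert est2.get_params()["min_pts"] == 5
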