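"""Tests for rendering, masking, the distance metric, baselines and PCA."""

import numpy as np
import pandas as pd
import pytest

from snnclust.evaluation import (
    ClusterMap,
    accuracy,
    active_pixel_mask,
    kmeans_centers,
    mean_nearest_cluster_distance,
    neural_gas_centers,
    pca_overlay_export,
    prototype_match_distances,
    render_pseudo_pattern,
    write_pgm,
)
from snnclust.network import build_network

from conftest import tiny_config


@pytest.fixture
def net(rng):
    return build_network(tiny_config(), rng)


class TestRender:
    def test_uniform_weight_levels_map_linearly_to_blackness(self, net):
        pop = net.pops["IN->CN"]
        for g_val, z in [(0.25, 255.0), (0.0, 0.0), (0.125, 127.5)]:
            pop.W = np.where(pop.mask, g_val, 0.0)
            Z = render_pseudo_pattern(net, 0)
            assert Z.shape == net.cfg.image_shape
            assert np.allclose(Z, z)

    def test_strict_mode_divides_by_full_fanin(self, net):
        pop = net.pops["IN->CN"]
        pop.W = np.where(pop.mask, 0.25, 0.0)
        Z_conn = render_pseudo_pattern(net, 0, mode="connected")
        Z_strict = render_pseudo_pattern(net, 0, mode="strict")
        # p < 1 so the strict average over K_I*K_C is smaller
        assert np.all(Z_strict <= Z_conn)
        frac = pop.mask[:, net.layers["CN"].group_slice(0)].mean()
        assert Z_strict.mean() / Z_conn.mean() == pytest.approx(frac, rel=0.05)

    def test_hand_set_weights_closed_form(self, net):
        pop = net.pops["IN->CN"]
        pop.W = np.where(pop.mask, 0.1, 0.0)
        pop.W[:10] *= 2.0                            # pixel 0 at 0.2
        Z = render_pseudo_pattern(net, 1).ravel()
        assert Z[0] == pytest.approx(0.2 * 255 / 0.25)
        assert Z[1] == pytest.approx(0.1 * 255 / 0.25)

    def test_unknown_mode_rejected(self, net):
        with pytest.raises(ValueError):
            render_pseudo_pattern(net, 0, mode="bogus")


class TestMask:
    def test_784_pixels_mask_78(self, rng):
        imgs = rng.random((5, 28, 28)) + 0.01
        m = active_pixel_mask(imgs)
        assert m.shape == (28, 28)
        assert (~m).sum() == 78                      # floor(0.1 * 784)

    def test_always_dark_pixel_is_always_masked(self, rng):
        imgs = rng.random((10, 4, 4)) + 0.1
        imgs[:, 2, 3] = 0.0
        m = active_pixel_mask(imgs)
        assert not m[2, 3]

    def test_uniform_images_tie_break_by_pixel_index(self):
        imgs = np.full((3, 4, 4), 0.5)
        m = active_pixel_mask(imgs).ravel()
        assert not m[0]                              # floor(1.6)=1 masked, lowest index
        assert m[1:].all()


class TestDistanceMetric:
    def test_point_equal_to_center_gives_zero(self):
        x = np.array([[0.3, 0.7]])
        assert mean_nearest_cluster_distance(x, x.copy()) == 0.0

    def test_brute_force_example(self):
        data = np.array([[0.0, 0.0], [2.0, 2.0]])
        centers = np.array([[0.0, 0.0], [3.0, 3.0]])
        assert mean_nearest_cluster_distance(data, centers) == pytest.approx(1.0)

    def test_adding_a_center_never_increases_the_metric(self, rng):
        data = rng.random((30, 8))
        centers = rng.random((4, 8))
        base = mean_nearest_cluster_distance(data, centers)
        more = np.vstack([centers, rng.random((1, 8))])
        assert mean_nearest_cluster_distance(data, more) <= base

    def test_mask_restricts_the_distance(self):
        data = np.array([[1.0, 0.0]])
        centers = np.array([[0.0, 0.0]])
        mask = np.array([False, True])
        assert mean_nearest_cluster_distance(data, centers, mask) == 0.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mean_nearest_cluster_distance(np.ones((2, 3)), np.ones((1, 4)))


class TestBaselines:
    def test_kmeans_with_k_equal_n_memorizes(self, rng):
        data = rng.random((6, 5))
        centers = kmeans_centers(data, 6, rng)
        assert mean_nearest_cluster_distance(data, centers) == pytest.approx(0.0, abs=1e-9)

    # k-means converges to the blob means; neural gas keeps a residual pull
    # toward the global mean from its soft neighborhood (final lambda 0.5).
    @pytest.mark.parametrize("fit,tol", [(kmeans_centers, 0.03),
                                         (neural_gas_centers, 0.30)])
    def test_two_blob_centers_recovered(self, fit, tol, rng):
        n = 60
        blobs = np.vstack([
            rng.normal(0.0, 0.05, (n, 2)),
            rng.normal(1.0, 0.05, (n, 2)),
        ])
        centers = fit(blobs, 2, rng)
        centers = centers[np.argsort(centers[:, 0])]
        assert np.allclose(centers[0], [0.0, 0.0], atol=tol)
        assert np.allclose(centers[1], [1.0, 1.0], atol=tol)

    @pytest.mark.parametrize("fit", [kmeans_centers, neural_gas_centers])
    def test_same_seed_is_deterministic(self, fit, rng):
        data = np.random.default_rng(4).random((40, 6))
        a = fit(data, 5, np.random.default_rng(9))
        b = fit(data, 5, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_too_many_centers_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_centers(np.ones((3, 2)), 4, rng)
        with pytest.raises(ValueError):
            neural_gas_centers(np.ones((3, 2)), 4, rng)


class TestAccuracy:
    def test_extremes(self):
        df = pd.DataFrame({"true": [0, 1, 0, 1], "predicted": [0, 1, 0, 1]})
        assert accuracy(df)[0] == 100.0
        df2 = pd.DataFrame({"true": [0] * 200 + [1] * 200,
                            "predicted": [0] * 200 + [0] * 200})
        assert accuracy(df2)[0] == 50.0

    def test_hand_built_confusion_matrix(self):
        true = [0, 0, 0, 1, 1, 2, 2, 2, 2, 1]
        pred = [0, 1, -1, 1, 1, 2, 0, 2, 2, 0]
        pct, conf = accuracy(pd.DataFrame({"true": true, "predicted": pred}))
        # brute force
        expect = {}
        for t, p in zip(true, pred):
            expect[(t, p)] = expect.get((t, p), 0) + 1
        for (t, p), n in expect.items():
            assert conf.loc[t, p] == n
        assert conf.to_numpy().sum() == 10
        assert pct == pytest.approx(100.0 * 6 / 10)

    def test_no_decision_counts_as_incorrect(self):
        df = pd.DataFrame({"true": [0, 1], "predicted": [0, -1]})
        assert accuracy(df)[0] == 50.0


class TestPrototypeMatch:
    def test_perfect_prototypes_have_zero_distance(self):
        tpl = np.zeros((2, 4, 4))
        tpl[0, :2] = 1.0
        tpl[1, 2:] = 1.0
        cmap = ClusterMap(pseudo_patterns=tpl * 255.0,
                          active_mask=np.ones((4, 4), bool))
        d = prototype_match_distances(cmap, tpl)
        assert np.allclose(d, 0.0)

    def test_masked_pixels_do_not_contribute(self):
        tpl = np.ones((1, 2, 2))
        patterns = np.zeros((1, 2, 2))
        mask = np.zeros((2, 2), bool)
        mask[0, 0] = True
        cmap = ClusterMap(pseudo_patterns=patterns, active_mask=mask)
        assert prototype_match_distances(cmap, tpl)[0] == pytest.approx(1.0)


class TestPCA:
    def test_data_mean_projects_to_origin(self, rng):
        data = rng.random((20, 6))
        df = pca_overlay_export(data, data.mean(axis=0, keepdims=True))
        center = df[df.kind == "center"]
        assert abs(center.pc1.iloc[0]) < 1e-9 and abs(center.pc2.iloc[0]) < 1e-9

    def test_projected_variance_bounded_by_total(self, rng):
        data = rng.random((40, 8))
        df = pca_overlay_export(data, data[:1])
        pts = df[df.kind == "data"][["pc1", "pc2"]].to_numpy()
        assert pts.var(axis=0).sum() <= data.var(axis=0).sum() + 1e-9

    def test_two_dimensional_input_is_a_rotation(self, rng):
        data = rng.random((25, 2))
        df = pca_overlay_export(data, data[:0].reshape(0, 2) if False else data[:1])
        pts = df[df.kind == "data"][["pc1", "pc2"]].to_numpy()
        from scipy.spatial.distance import pdist
        assert np.allclose(pdist(pts), pdist(data - data.mean(0)), atol=1e-8)


def test_pgm_writer_produces_plain_text(tmp_path):
    img = np.arange(6).reshape(2, 3) * 40.0
    path = tmp_path / "p.pgm"
    write_pgm(img, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "P2" and lines[1] == "3 2" and lines[2] == "255"
    vals = [int(v) for line in lines[3:] for v in line.split()]
    assert vals == [0, 40, 80, 120, 160, 200]
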