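"""Image quantification: region measurement, probe detection, neighbors,
background estimation and the full scene pipeline."""

import math

import numpy as np
import pytest

import couplekit as ck
from couplekit.errors import (
    InsufficientNeighborsError,
    NoProbeFoundError,
    SceneError,
)
from couplekit.imaging import CellRecord


def square_scene(values, size=10, gap=5, probe_values=None, pixel_size=2.0):
    """Scene of constant-value square cells laid out left to right."""
    n = len(values)
    W = n * (size + gap) + gap
    H = size + 2 * gap
    tracer = np.zeros((H, W))
    probe = np.zeros((H, W))
    mask = np.zeros((H, W), dtype=np.int32)
    for i, v in enumerate(values):
        c0 = gap + i * (size + gap)
        sl = (slice(gap, gap + size), slice(c0, c0 + size))
        tracer[sl] = v
        probe[sl] = 0.0 if probe_values is None else probe_values[i]
        mask[sl] = i + 1
    return ck.LabeledScene(tracer_channel=tracer, probe_channel=probe,
                           label_mask=mask, pixel_size=pixel_size)


class TestMeasureCells:
    def test_constant_region_mean(self):
        scene = square_scene([7.0])
        recs = ck.measure_cells(scene)
        assert len(recs) == 1
        assert recs[0].mean_tracer == pytest.approx(7.0)

    def test_means_match_per_pixel_oracle(self):
        scene = square_scene([3.0, 9.0])
        rng = np.random.default_rng(0)
        noisy = scene.tracer_channel + rng.normal(0, 0.5, scene.tracer_channel.shape)
        scene = ck.LabeledScene(noisy, scene.probe_channel, scene.label_mask,
                                scene.pixel_size)
        recs = {r.cell_id: r for r in ck.measure_cells(scene)}
        for lbl in (1, 2):
            oracle = noisy[scene.label_mask == lbl].mean()
            assert recs[lbl].mean_tracer == pytest.approx(oracle, abs=1e-12)

    def test_area_in_square_micrometers(self):
        scene = square_scene([1.0], size=10, pixel_size=2.0)
        assert ck.measure_cells(scene)[0].area == pytest.approx(100 * 4.0)

    def test_empty_mask_warns_and_returns_nothing(self):
        scene = ck.LabeledScene(np.zeros((5, 5)), np.zeros((5, 5)),
                                np.zeros((5, 5), dtype=int))
        with pytest.warns(UserWarning):
            assert ck.measure_cells(scene) == []


class TestIdentifyProbes:
    def _records(self, probe_means):
        return [CellRecord(cell_id=i + 1, centroid=(float(i), 0.0),
                           mean_tracer=1.0, mean_probe=m, area=1.0)
                for i, m in enumerate(probe_means)]

    def test_bimodal_marker_finds_single_probe(self):
        recs = ck.identify_probes(self._records([1.0, 1.0, 1.0, 100.0]))
        assert [r.is_probe for r in recs] == [False, False, False, True]

    def test_uniform_marker_is_an_error(self):
        with pytest.raises(NoProbeFoundError):
            ck.identify_probes(self._records([5.0] * 8))

    def test_sparsity_guard_rejects_half_bright(self):
        with pytest.raises(NoProbeFoundError):
            ck.identify_probes(self._records([1.0] * 5 + [100.0] * 5))

    def test_numeric_threshold_rule(self):
        recs = ck.identify_probes(self._records([1.0] * 6 + [50.0]),
                                  threshold_rule=25.0)
        assert sum(r.is_probe for r in recs) == 1

    def test_noisy_marker_cluster_split_exactly(self):
        rng = np.random.default_rng(1)
        means = list(rng.normal(5.0, 0.1, 300)) + list(rng.normal(95.0, 2.0, 3))
        recs = ck.identify_probes(self._records(means))
        assert sum(r.is_probe for r in recs) == 3
        assert all(r.is_probe == (r.mean_probe > 50) for r in recs)


class TestSixNearestNeighbors:
    def test_perfect_hexagon(self):
        recs = [CellRecord(0, (0.0, 0.0), 1, 100, 1, is_probe=True)]
        for k in range(6):
            ang = k * math.pi / 3
            recs.append(CellRecord(k + 1, (math.cos(ang), math.sin(ang)),
                                   1, 0, 1))
        for k in range(6):  # a farther ring
            ang = k * math.pi / 3 + 0.3
            recs.append(CellRecord(k + 7, (3 * math.cos(ang), 3 * math.sin(ang)),
                                   1, 0, 1))
        q = ck.six_nearest_neighbors(recs, 0)
        assert sorted(q.neighbor_ids) == [1, 2, 3, 4, 5, 6]
        assert not q.probe_excluded

    def test_cells_on_a_line(self):
        recs = [CellRecord(0, (0.0, 0.0), 1, 100, 1, is_probe=True)]
        recs += [CellRecord(i, (float(i), 0.0), 1, 0, 1) for i in range(1, 9)]
        q = ck.six_nearest_neighbors(recs, 0)
        assert sorted(q.neighbor_ids) == [1, 2, 3, 4, 5, 6]

    def test_matches_brute_force_sort_on_jittered_mosaic(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 100, (40, 2))
        recs = [CellRecord(i, tuple(p), 1, 0, 1) for i, p in enumerate(pts)]
        probe = recs[0] = CellRecord(0, tuple(pts[0]), 1, 100, 1, is_probe=True)
        q = ck.six_nearest_neighbors(recs, 0)
        dist = np.linalg.norm(pts - pts[0], axis=1)
        oracle = sorted(range(1, 40), key=lambda i: (dist[i], i))[:6]
        assert sorted(q.neighbor_ids) == sorted(oracle)

    def test_other_probe_excluded_and_flagged(self):
        recs = [CellRecord(0, (0.0, 0.0), 1, 100, 1, is_probe=True),
                CellRecord(1, (1.0, 0.0), 1, 100, 1, is_probe=True)]
        recs += [CellRecord(i, (float(i), 5.0), 1, 0, 1) for i in range(2, 10)]
        q = ck.six_nearest_neighbors(recs, 0)
        assert 1 not in q.neighbor_ids
        assert len(q.neighbor_ids) == 6
        assert q.probe_excluded

    def test_too_few_candidates(self):
        recs = [CellRecord(0, (0.0, 0.0), 1, 100, 1, is_probe=True)]
        recs += [CellRecord(i, (float(i), 0.0), 1, 0, 1) for i in range(1, 5)]
        with pytest.raises(InsufficientNeighborsError):
            ck.six_nearest_neighbors(recs, 0)


class TestEstimateBackground:
    def test_uniform_background(self):
        scene = square_scene([9.0])
        scene = ck.LabeledScene(
            np.where(scene.label_mask > 0, scene.tracer_channel, 5.0),
            scene.probe_channel, scene.label_mask, scene.pixel_size)
        assert ck.estimate_background(scene) == pytest.approx(5.0)

    def test_bright_halo_around_cells_is_ignored(self):
        """A 1-pixel bleed halo around each cell must not shift the estimate
        (the cell mask is dilated before background pixels are sampled)."""
        from scipy import ndimage
        scene = square_scene([50.0])
        tracer = np.full(scene.label_mask.shape, 5.0)
        cells = scene.label_mask > 0
        halo = ndimage.binary_dilation(cells) & ~cells
        tracer[halo] = 40.0
        tracer[cells] = 50.0
        scene = ck.LabeledScene(tracer, scene.probe_channel, scene.label_mask)
        assert ck.estimate_background(scene) == pytest.approx(5.0)

    def test_poisson_noise_background_close_to_truth(self):
        rng = np.random.default_rng(3)
        scene = square_scene([50.0])
        tracer = rng.poisson(5.0, scene.label_mask.shape).astype(float)
        tracer[scene.label_mask > 0] = 50.0
        scene = ck.LabeledScene(tracer, scene.probe_channel, scene.label_mask)
        n_bg = (scene.label_mask == 0).sum()
        se = math.sqrt(5.0 / n_bg) * math.sqrt(math.pi / 2)  # SE of the median
        assert ck.estimate_background(scene) == pytest.approx(5.0, abs=max(3 * se, 0.5))

    def test_no_background_pixels_is_an_error(self):
        full = np.ones((6, 6), dtype=np.int32)
        scene = ck.LabeledScene(np.ones((6, 6)), np.zeros((6, 6)), full)
        with pytest.raises(SceneError):
            ck.estimate_background(scene)


class TestQuantifyScene:
    def test_noiseless_scene_recovers_strength(self):
        lam = 0.5
        sc = ck.generate_scene(lam, noise=ck.NoiseSpec.none())
        ms = ck.quantify_scene(sc.scene)
        assert len(ms) == len(sc.probe_ids)
        for m in ms:
            s = ck.neighbor_ratio_strength(m)
            assert s.S == pytest.approx(math.exp(-lam), rel=0.05)

    def test_adjacent_probes_are_flagged(self):
        lat = ck.generate_mosaic(ck.MosaicSpec(n_cells=200, jitter_sd=0.0,
                                               probe_fraction=0.005, seed=0))
        # force two probes one hop apart in the interior
        probe = lat.probe_cells[0]
        neighbor = int(lat.neighbors(probe)[0])
        lat = lat.with_probes([probe, neighbor])
        conc = 10.0 + 90.0 * np.exp(-0.5 * np.where(
            np.isfinite(lat.graph_distance), lat.graph_distance, 10.0))
        sc = ck.render_scene(lat, conc, noise=ck.NoiseSpec.none(),
                             background_level=10.0)
        ms = ck.quantify_scene(sc.scene)
        assert len(ms) == 2
        assert all("overlapping_neighbors" in m.flags for m in ms)

    def test_constant_offset_leaves_strength_unchanged(self):
        sc = ck.generate_scene(0.7, noise=ck.NoiseSpec.none())
        base = {m.probe_id: ck.neighbor_ratio_strength(m).S
                for m in ck.quantify_scene(sc.scene)}
        shifted = ck.LabeledScene(sc.scene.tracer_channel + 11.0,
                                  sc.scene.probe_channel + 11.0,
                                  sc.scene.label_mask, sc.scene.pixel_size)
        for m in ck.quantify_scene(shifted):
            assert ck.neighbor_ratio_strength(m).S == pytest.approx(
                base[m.probe_id], abs=1e-6)

    def test_removing_distant_cells_leaves_strength_unchanged(self):
        """Deleting a random 10% of cells outside every probe neighborhood
        does not move any probe's S."""
        sc = ck.generate_scene(0.7, noise=ck.NoiseSpec.none())
        ms = ck.quantify_scene(sc.scene)
        base = {m.probe_id: ck.neighbor_ratio_strength(m).S for m in ms}
        keep_ids = {int(m.probe_id) for m in ms}
        for m in ms:
            recs = ck.identify_probes(ck.measure_cells(sc.scene))
            keep_ids |= set(ck.six_nearest_neighbors(recs, int(m.probe_id)).neighbor_ids)
        rng = np.random.default_rng(0)
        all_ids = np.unique(sc.scene.label_mask)
        all_ids = all_ids[all_ids > 0]
        removable = np.array([i for i in all_ids if i not in keep_ids])
        drop = set(rng.choice(removable, size=len(removable) // 10,
                              replace=False).tolist())
        mask = np.where(np.isin(sc.scene.label_mask, list(drop)), 0,
                        sc.scene.label_mask)
        pruned = ck.LabeledScene(sc.scene.tracer_channel,
                                 sc.scene.probe_channel, mask,
                                 sc.scene.pixel_size)
        for m in ck.quantify_scene(pruned):
            assert ck.neighbor_ratio_strength(m).S == pytest.approx(
                base[m.probe_id], abs=1e-6)


class TestSegmentationFallback:
    def test_recovers_disjoint_bright_cells(self):
        img = np.zeros((60, 60))
        img[10:20, 10:20] = 50.0
        img[35:45, 35:45] = 60.0
        labels = ck.segment_cells(img)
        assert labels.max() == 2
        assert (labels[12:18, 12:18] > 0).all()
        assert (labels[37:43, 37:43] > 0).all()
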