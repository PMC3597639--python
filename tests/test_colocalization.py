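import numpy as np
import pytest

from cxplaque.colocalization import (ALL_CLASSES, PARENCHYMAL, VASCULAR,
                                     CombinationClass, GeometryMismatchError,
                                     assign_compartment, assign_compartments,
                                     merge_channels)
from cxplaque.segmentation import segment_channel

from oracles import pairwise_overlap_components

VOX = (8.2, 0.25, 0.25)


def channel_from_blobs(name, blobs, shape=(2, 12, 12), voxel_size=VOX):
    vol = np.zeros(shape)
    for blob in blobs:
        for v in blob:
            vol[v] = 1.0
    return segment_channel(vol, channel=name, threshold=0.5, min_size=1,
                           voxel_size=voxel_size)


class TestCombinationClass:
    def test_exactly_fifteen_classes(self):
        assert len(ALL_CLASSES) == 15
        orders = [c.order for c in ALL_CLASSES]
        assert orders.count(1) == 4 and orders.count(2) == 6
        assert orders.count(3) == 4 and orders.count(4) == 1

    def test_label_round_trip_and_canonical_order(self):
        c = CombinationClass(["Cx45", "Cx26"])
        assert c.label == "Cx26/Cx45"
        assert CombinationClass.from_label("Cx26/Cx45") == c

    def test_empty_and_unknown_rejected(self):
        with pytest.raises(ValueError):
            CombinationClass([])
        with pytest.raises(ValueError):
            CombinationClass(["Cx36"])


class TestMergeChannels:
    def test_overlapping_pair_merges_into_one_plaque(self):
        chans = {
            "Cx26": channel_from_blobs("Cx26", [[(0, 2, 2), (0, 2, 3)]]),
            "Cx45": channel_from_blobs("Cx45", [[(0, 2, 3), (0, 2, 4)]]),
        }
        plaques = merge_channels(chans)
        assert len(plaques) == 1
        assert plaques[0].members.label == "Cx26/Cx45"
        assert plaques[0].voxel_count == 3  # union of voxels

    def test_four_mutually_overlapping_objects_form_quadruple(self):
        chans = {cx: channel_from_blobs(cx, [[(0, 5, 5 + j) for j in range(i + 1)]])
                 for i, cx in enumerate(["Cx26", "Cx30", "Cx43", "Cx45"], 1)}
        plaques = merge_channels(chans)
        assert len(plaques) == 1
        assert plaques[0].members.label == "Cx26/Cx30/Cx43/Cx45"

    def test_disjoint_objects_stay_singletons(self):
        chans = {
            "Cx26": channel_from_blobs("Cx26", [[(0, 1, 1)]]),
            "Cx30": channel_from_blobs("Cx30", [[(0, 5, 5)]]),
            "Cx43": channel_from_blobs("Cx43", [[(1, 9, 9)]]),
        }
        plaques = merge_channels(chans)
        assert sorted(p.members.label for p in plaques) == ["Cx26", "Cx30", "Cx43"]

    def test_partition_every_object_in_exactly_one_plaque(self, rng):
        chans = {}
        for cx in ("Cx26", "Cx30", "Cx43", "Cx45"):
            blobs = []
            for _ in range(6):
                y, x = rng.integers(0, 10, 2)
                blobs.append([(0, int(y), int(x)), (0, int(y), int(x) + 1)])
            chans[cx] = channel_from_blobs(cx, blobs, shape=(1, 12, 12))
        plaques = merge_channels(chans)
        n_objects = sum(len(chans[c].objects) for c in chans)
        # union of per-plaque member multiplicity must cover every object once
        assert sum(1 for p in plaques for _ in p.members) <= n_objects
        total_object_voxels = {(c, o.id) for c in chans for o in chans[c].objects}
        assert len(total_object_voxels) == n_objects

    def test_merge_symmetric_in_channel_order(self):
        a = {
            "Cx26": channel_from_blobs("Cx26", [[(0, 2, 2)]]),
            "Cx30": channel_from_blobs("Cx30", [[(0, 2, 2)], [(0, 8, 8)]]),
        }
        b = dict(reversed(list(a.items())))
        pa = merge_channels(a)
        pb = merge_channels(b)
        assert [(p.members.label, p.voxel_count) for p in pa] == \
            [(p.members.label, p.voxel_count) for p in pb]

    def test_agrees_with_brute_force_overlap_oracle(self, rng):
        for trial in range(10):
            chans = {}
            objects = {}
            for cx in ("Cx26", "Cx30", "Cx43", "Cx45"):
                blobs = []
                for _ in range(4):
                    y, x = int(rng.integers(0, 8)), int(rng.integers(0, 8))
                    blobs.append([(0, y, x), (0, y, x + 1)])
                ch = channel_from_blobs(cx, blobs, shape=(1, 10, 10))
                chans[cx] = ch
                for o in ch.objects:
                    objects[(cx, o.id)] = set(map(tuple, o.voxels))
            plaques = merge_channels(chans)
            want = pairwise_overlap_components(objects)
            got_voxels = {frozenset((int(a), int(b), int(c)) for a, b, c in p.voxels)
                          for p in plaques}
            want_voxels = {frozenset(v for k in grp for v in objects[k])
                           for grp in want}
            assert got_voxels == want_voxels

    def test_centroid_distance_rule(self):
        chans = {
            "Cx26": channel_from_blobs("Cx26", [[(0, 2, 2)]]),
            "Cx30": channel_from_blobs("Cx30", [[(0, 2, 4)]]),  # 0.5 um apart
        }
        near = merge_channels(chans, rule="centroid_distance", max_distance_um=1.0)
        far = merge_channels(chans, rule="centroid_distance", max_distance_um=0.1)
        assert len(near) == 1 and len(far) == 2

    def test_geometry_mismatch_rejected(self):
        chans = {
            "Cx26": channel_from_blobs("Cx26", [[(0, 1, 1)]], shape=(1, 12, 12)),
            "Cx30": channel_from_blobs("Cx30", [[(0, 1, 1)]], shape=(2, 12, 12)),
        }
        with pytest.raises(GeometryMismatchError):
            merge_channels(chans)


class TestAssignCompartment:
    def _plaque(self, voxels):
        from cxplaque.colocalization import Plaque
        return Plaque(1, CombinationClass(["Cx30"]),
                      np.array(voxels, dtype=int), VOX)

    def test_plaque_inside_vessel_shell_is_vascular(self):
        mask = np.zeros((1, 10, 10), dtype=bool)
        mask[0, 4:6, 4:6] = True
        p = self._plaque([(0, 4, 4), (0, 4, 5)])
        assert assign_compartment(p, mask, VOX) == VASCULAR

    def test_distant_plaque_is_parenchymal(self):
        mask = np.zeros((1, 20, 20), dtype=bool)
        mask[0, 0, 0] = True
        p = self._plaque([(0, 19, 19)])   # ~6.7 um away
        assert assign_compartment(p, mask, VOX, max_distance_um=2.0) == PARENCHYMAL

    def test_empty_vessel_mask_defaults_to_parenchymal(self, caplog):
        p = self._plaque([(0, 1, 1)])
        mask = np.zeros((1, 5, 5), dtype=bool)
        with caplog.at_level("WARNING"):
            assert assign_compartment(p, mask, VOX) == PARENCHYMAL
        assert "empty vessel mask" in caplog.text

    def test_recovery_matches_planted_labels_on_synthetic_scene(self):
        from cxplaque.scene import build_scene
        from conftest import make_scene_config

        cfg = make_scene_config(seed=21)
        truth = build_scene(cfg)
        from cxplaque.colocalization import Plaque
        plaques = [Plaque(p.id, p.members, p.voxels, cfg.voxel_size)
                   for p in truth.plaques]
        assign_compartments(plaques, truth.vessel_mask, cfg.voxel_size,
                            max_distance_um=cfg.vascular_distance_um,
                            fraction=cfg.vascular_fraction)
        for got, planted in zip(plaques, truth.plaques):
            assert got.compartment == planted.compartment
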