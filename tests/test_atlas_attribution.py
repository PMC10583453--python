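import numpy as np
import pytest

from gliocam.atlas_attribution import (BinaryMap, RegionOverlap, binarize,
                                       overlay_atlas, region_report,
                                       region_sets)
from gliocam.io_formats import LabelTable
from gliocam.preprocessing import SurvivalLabel


def _overlap(cls, counts, th=0.2):
    return RegionOverlap(target_class=cls, threshold=th, counts=dict(counts))


class TestBinarize:
    def test_threshold_zero_keeps_strictly_positive(self):
        data = np.array([0.0, 0.1, 0.0, 0.7]).reshape(4, 1, 1)
        out = binarize(data, 0.0)
        np.testing.assert_array_equal(out.data.ravel(), [0, 1, 0, 1])

    def test_threshold_one_gives_all_zeros(self, rng):
        assert np.all(binarize(rng.random((3, 3, 3)), 1.0).data == 0)

    def test_elementwise_comparison(self):
        data = np.array([0.15, 0.25, 0.35]).reshape(3, 1, 1)
        out = binarize(data, 0.2)
        np.testing.assert_array_equal(out.data.ravel(), [0, 1, 1])

    @pytest.mark.parametrize("th", [-0.1, 1.5])
    def test_threshold_out_of_range(self, th, rng):
        with pytest.raises(ValueError, match="threshold"):
            binarize(rng.random((2, 2, 2)), th)

    def test_monotone_in_threshold(self, rng):
        data = rng.random((6, 6, 6))
        previous = None
        for th in (0.1, 0.2, 0.3, 0.4, 0.5, 0.6):
            current = binarize(data, th).data
            if previous is not None:
                assert np.all(current <= previous)  # voxels only disappear
            previous = current


class TestOverlayAtlas:
    def _toy_atlas(self):
        atlas = np.zeros((6, 6, 2), dtype=int)
        atlas[:2] = 1
        atlas[2:4] = 2
        atlas[4:] = 3
        return atlas

    def test_empty_binary_map(self):
        atlas = self._toy_atlas()
        binary = BinaryMap(np.zeros_like(atlas, dtype=np.uint8), 0.2)
        assert overlay_atlas(binary, atlas).counts == {}

    def test_single_parcel_mask(self):
        atlas = self._toy_atlas()
        binary = BinaryMap((atlas == 3).astype(np.uint8), 0.2)
        assert overlay_atlas(binary, atlas).counts == {3: int((atlas == 3).sum())}

    def test_matches_exhaustive_tally(self, rng):
        atlas = self._toy_atlas()
        binary = BinaryMap((rng.random(atlas.shape) > 0.5).astype(np.uint8), 0.2)
        counts = overlay_atlas(binary, atlas).counts
        # oracle: voxel-by-voxel loop
        expected: dict[int, int] = {}
        for idx in np.ndindex(atlas.shape):
            if binary.data[idx] and atlas[idx] > 0:
                expected[int(atlas[idx])] = expected.get(int(atlas[idx]), 0) + 1
        assert counts == expected

    def test_min_voxels_filters_speckle(self):
        atlas = self._toy_atlas()
        binary = np.zeros_like(atlas, dtype=np.uint8)
        binary[0, 0, 0] = 1           # one voxel in parcel 1
        binary[2:4, :3, :] = 1        # many voxels in parcel 2
        ov = overlay_atlas(BinaryMap(binary, 0.2), atlas, min_voxels=2)
        assert 1 not in ov.counts and 2 in ov.counts

    def test_grid_mismatch(self):
        binary = BinaryMap(np.zeros((2, 2, 2), dtype=np.uint8), 0.2)
        with pytest.raises(ValueError, match="grid"):
            overlay_atlas(binary, np.zeros((3, 3, 3), dtype=int))


class TestRegionSets:
    def test_worked_example(self):
        sets = region_sets(
            _overlap(SurvivalLabel.SHORT, {1: 5, 2: 5}),
            _overlap(SurvivalLabel.MEDIUM, {2: 5, 3: 5}),
            _overlap(SurvivalLabel.LONG, {2: 5, 4: 5}))
        assert sets.common == {2}
        assert sets.unique_short == {1}
        assert sets.unique_medium == {3}
        assert sets.unique_long == {4}

    def test_identical_presence_sets(self):
        ovs = [_overlap(c, {1: 3, 7: 2}) for c in SurvivalLabel]
        sets = region_sets(*ovs)
        assert sets.common == {1, 7}
        for c in SurvivalLabel:
            assert sets.unique_by_class(c) == frozenset()

    def test_matches_exhaustive_membership(self, rng):
        labels = range(1, 21)
        for _ in range(30):
            presence = [frozenset(l for l in labels if rng.random() < 0.4)
                        for _ in range(3)]
            ovs = [_overlap(c, {l: 1 for l in p})
                   for c, p in zip(SurvivalLabel, presence)]
            sets = region_sets(*ovs)
            p_s, p_m, p_l = presence
            for lab in labels:
                assert (lab in sets.common) == (
                    lab in p_s and lab in p_m and lab in p_l)
                assert (lab in sets.unique_short) == (
                    lab in p_s and lab not in p_m and lab not in p_l)
                assert (lab in sets.unique_medium) == (
                    lab in p_m and lab not in p_l and lab not in p_s)
                assert (lab in sets.unique_long) == (
                    lab in p_l and lab not in p_s and lab not in p_m)

    def test_unique_sets_disjoint_from_common_and_each_other(self, rng):
        for _ in range(20):
            ovs = [_overlap(c, {int(l): 1 for l in
                                rng.choice(20, size=rng.integers(0, 12),
                                           replace=False) + 1})
                   for c in SurvivalLabel]
            sets = region_sets(*ovs)
            groups = [sets.common, sets.unique_short, sets.unique_medium,
                      sets.unique_long]
            for i in range(4):
                for j in range(i + 1, 4):
                    assert not (groups[i] & groups[j])

    def test_relabeling_equivariance(self, rng):
        presence = [{1: 4, 2: 1}, {2: 2, 3: 9}, {2: 7, 4: 3}]
        perm = {1: 10, 2: 20, 3: 30, 4: 40}
        ovs = [_overlap(c, p) for c, p in zip(SurvivalLabel, presence)]
        ovs_perm = [_overlap(c, {perm[k]: v for k, v in p.items()})
                    for c, p in zip(SurvivalLabel, presence)]
        sets, sets_perm = region_sets(*ovs), region_sets(*ovs_perm)
        assert sets_perm.common == {perm[l] for l in sets.common}
        for c in SurvivalLabel:
            assert sets_perm.unique_by_class(c) == {
                perm[l] for l in sets.unique_by_class(c)}

    def test_threshold_mismatch_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            region_sets(_overlap(SurvivalLabel.SHORT, {1: 1}, th=0.2),
                        _overlap(SurvivalLabel.MEDIUM, {1: 1}, th=0.3),
                        _overlap(SurvivalLabel.LONG, {1: 1}, th=0.2))


class TestRegionReport:
    TABLE = LabelTable([(i, f"Parcel_{i:02d}") for i in range(1, 6)])

    def test_empty_sets(self):
        ovs = {c: _overlap(c, {}) for c in SurvivalLabel}
        sets = region_sets(*[ovs[c] for c in SurvivalLabel])
        report = region_report(sets, ovs, self.TABLE)
        assert report.common == []
        assert all(v == [] for v in report.unique.values())

    def test_single_region_fraction_one(self):
        ovs = {SurvivalLabel.SHORT: _overlap(SurvivalLabel.SHORT, {1: 50}),
               SurvivalLabel.MEDIUM: _overlap(SurvivalLabel.MEDIUM, {2: 10}),
               SurvivalLabel.LONG: _overlap(SurvivalLabel.LONG, {3: 10})}
        sets = region_sets(*[ovs[c] for c in SurvivalLabel])
        report = region_report(sets, ovs, self.TABLE)
        (row,) = report.unique["short"]
        assert row["region_name"] == "Parcel_01"
        assert row["fraction_of_class_volume"] == pytest.approx(1.0)

    def test_fractions_normalize_by_class_volume(self):
        ovs = {SurvivalLabel.SHORT: _overlap(SurvivalLabel.SHORT,
                                             {1: 30, 2: 70}),
               SurvivalLabel.MEDIUM: _overlap(SurvivalLabel.MEDIUM, {3: 4}),
               SurvivalLabel.LONG: _overlap(SurvivalLabel.LONG, {4: 4})}
        sets = region_sets(*[ovs[c] for c in SurvivalLabel])
        report = region_report(sets, ovs, self.TABLE)
        fractions = {r["label"]: r["fraction_of_class_volume"]
                     for r in report.unique["short"]}
        assert fractions == {1: pytest.approx(0.3), 2: pytest.approx(0.7)}

    def test_unknown_label_rejected(self):
        ovs = {c: _overlap(c, {9: 1}) for c in SurvivalLabel}
        sets = region_sets(*[ovs[c] for c in SurvivalLabel])
        with pytest.raises(KeyError, match="9"):
            region_report(sets, ovs, self.TABLE)
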