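import numpy as np
import pytest

from neoseg import imageops, phantom, postfix
from neoseg.labels import (
    DEFAULT_REGIONS,
    DEFAULT_SCHEME,
    SENTINEL_LH_WM,
    SENTINEL_RH_WM,
    LabelScheme,
)
from neoseg.types import InvalidArgumentError, LabelVolume

import oracles

sch = DEFAULT_SCHEME
rc = DEFAULT_REGIONS


def _lv(data):
    return LabelVolume(data=np.asarray(data, dtype=np.int32), table=sch.names())


class TestApplySentinels:
    def test_all_sentinels_rewritten_and_protected(self):
        lv = _lv(np.full((4, 4, 4), SENTINEL_LH_WM))
        out, prot = postfix.apply_sentinels(lv)
        assert np.all(out.data == sch.wm_left) and prot.all()

    def test_no_sentinels_is_identity(self):
        lv = _lv(np.full((4, 4, 4), sch.csf))
        out, prot = postfix.apply_sentinels(lv)
        assert np.array_equal(out.data, lv.data) and not prot.any()

    def test_mixed_only_sentinels_change(self):
        data = np.full((4, 4, 4), sch.gm_left)
        data[1, 1, 1] = SENTINEL_RH_WM
        out, prot = postfix.apply_sentinels(_lv(data))
        assert out.data[1, 1, 1] == sch.wm_right
        assert prot.sum() == 1 and prot[1, 1, 1]
        changed = out.data != data
        assert changed.sum() == 1


class TestReassignCsfIslands:
    def test_enclosed_pocket_becomes_wm(self):
        data = np.full((8, 8, 8), sch.wm_left)
        data[3, 3, 3:6] = sch.csf
        out = postfix.reassign_csf_islands(_lv(data))
        assert np.all(out.data == sch.wm_left)

    def test_component_touching_no_wm_unchanged(self):
        data = np.zeros((8, 8, 8), dtype=np.int32)
        data[0:2, 0:2, 0:2] = sch.wm_left
        data[6:8, 6:8, 6:8] = sch.csf
        out = postfix.reassign_csf_islands(_lv(data))
        assert np.all(out.data[6:8, 6:8, 6:8] == sch.csf)

    def test_bridge_between_hemispheres_split_by_chessboard(self):
        data = np.zeros((9, 5, 5), dtype=np.int32)
        data[0:2] = sch.wm_left
        data[7:9] = sch.wm_right
        data[2:7, 2, 2] = sch.csf  # bridge touching both main components
        out = postfix.reassign_csf_islands(_lv(data))
        dl = oracles.chessboard(data == sch.wm_left)
        dr = oracles.chessboard(data == sch.wm_right)
        for x in range(2, 7):
            want = sch.wm_left if dl[x, 2, 2] <= dr[x, 2, 2] else sch.wm_right
            assert out.data[x, 2, 2] == want

    def test_no_wm_is_noop(self):
        data = np.full((5, 5, 5), sch.csf)
        out = postfix.reassign_csf_islands(_lv(data))
        assert np.array_equal(out.data, data)

    def test_protected_voxels_untouched(self):
        data = np.full((6, 6, 6), sch.wm_left)
        data[2, 2, 2] = sch.csf
        prot = np.zeros((6, 6, 6), bool)
        prot[2, 2, 2] = True
        out = postfix.reassign_csf_islands(_lv(data), protected=prot)
        assert out.data[2, 2, 2] == sch.csf


class TestSplitSulcalBanks:
    def _wall_scene(self):
        # two parcels separated by a 1-voxel WM wall
        data = np.full((9, 5, 5), sch.csf)
        data[1:4] = sch.superior_temporal_left
        data[4] = sch.wm_left
        data[5:8] = sch.supramarginal_left
        return data

    def test_wall_reset_to_csf(self):
        out = postfix.split_sulcal_banks(_lv(self._wall_scene()), dilate_mm=1.0)
        assert np.all(out.data[4] == sch.csf)

    def test_distant_parcels_unchanged(self):
        data = np.full((12, 5, 5), sch.csf)
        data[0:2] = sch.superior_temporal_left
        data[10:12] = sch.supramarginal_left
        data[5] = sch.wm_left
        out = postfix.split_sulcal_banks(_lv(data), dilate_mm=1.0)
        assert np.all(out.data[5] == sch.wm_left)

    def test_protected_wall_voxel_stays_wm(self):
        data = self._wall_scene()
        prot = np.zeros(data.shape, bool)
        prot[4, 2, 2] = True
        out = postfix.split_sulcal_banks(_lv(data), dilate_mm=1.0, protected=prot)
        assert out.data[4, 2, 2] == sch.wm_left
        assert out.data[4, 0, 0] == sch.csf


class TestBuildRegionsImage:
    def _ribbon(self, shape, split_at):
        data = np.zeros(shape, dtype=np.int32)
        data[:split_at] = sch.wm_left
        data[split_at:] = sch.wm_right
        return _lv(data)

    def test_midline_closure_and_hemisphere_split(self):
        data = np.zeros((10, 7, 7), dtype=np.int32)
        data[1:3] = sch.wm_left
        data[7:9] = sch.wm_right
        data[4:6, 3, 3] = sch.cc  # midline bridge, closed into the composite
        lv = _lv(data)
        out = postfix.build_regions_image(lv, self._ribbon((10, 7, 7), 5), close_iters=3)
        assert (out.data[:5] != rc.wm_right).all()
        assert (out.data[5:] != rc.wm_left).all()
        assert out.data[4, 3, 3] == rc.wm_left and out.data[5, 3, 3] == rc.wm_right

    def test_equidistant_voxel_goes_left(self):
        data = np.zeros((7, 5, 5), dtype=np.int32)
        data[3, 2, 2] = sch.thalamus_left  # absorbed into the composite
        rib = np.zeros((7, 5, 5), dtype=np.int32)
        rib[2] = sch.wm_left
        rib[4] = sch.wm_right
        out = postfix.build_regions_image(_lv(data), _lv(rib), close_iters=1)
        assert out.data[3, 2, 2] == rc.wm_left

    def test_subcortical_absorption_and_passthroughs(self, truth):
        out = postfix.build_regions_image(truth.labels, truth.ribbon)
        thal = truth.labels.mask(sch.thalamus_left, sch.thalamus_right)
        assert np.all(np.isin(out.data[thal], (rc.wm_left, rc.wm_right)))
        assert np.all(out.data[truth.labels.data == sch.gm_left] == rc.cortical_gm)
        assert np.all(out.data[truth.labels.data == sch.brainstem] == rc.brainstem_cerebellum)
        lv_l = truth.labels.data == sch.ventricle_left
        assert np.all(out.data[lv_l] == rc.ventricle_left)

    def test_partition_matches_brute_force_chessboard(self, rng):
        shape = (10, 10, 10)
        data = np.zeros(shape, dtype=np.int32)
        data[(rng.random(shape) < 0.3)] = sch.wm_left
        data[(rng.random(shape) < 0.2) & (data == 0)] = sch.wm_right
        rib = np.zeros(shape, dtype=np.int32)
        rib[:4] = sch.wm_left
        rib[6:] = sch.wm_right
        out = postfix.build_regions_image(_lv(data), _lv(rib), close_iters=1)
        dl = oracles.chessboard(rib == sch.wm_left)
        dr = oracles.chessboard(rib == sch.wm_right)
        comp = np.isin(out.data, (rc.wm_left, rc.wm_right))
        want = np.where(dl <= dr, rc.wm_left, rc.wm_right)
        assert np.array_equal(out.data[comp], want[comp])

    def test_missing_ribbon_rejected(self, truth):
        bad = truth.ribbon.with_data(np.zeros(truth.ribbon.shape, dtype=np.int32))
        with pytest.raises(InvalidArgumentError):
            postfix.build_regions_image(truth.labels, bad)


class TestRoundTrips:
    def test_csf_island_round_trip(self, truth):
        corr, planted = phantom.corrupt_labels(truth, "csf_island", seed=5)
        fixed = postfix.reassign_csf_islands(corr)
        assert planted.any()
        assert np.array_equal(fixed.data, truth.labels.data)

    def test_sulcal_bridge_round_trip(self, truth):
        corr, planted = phantom.corrupt_labels(truth, "sulcal_bridge", seed=5)
        fixed = postfix.split_sulcal_banks(corr, dilate_mm=2.0)
        assert planted.any()
        assert np.array_equal(fixed.data, truth.labels.data)

    def test_pial5_sentinel_round_trip(self, truth):
        corr, planted = phantom.corrupt_labels(truth, "pial5_occlusion", seed=5)
        edited = corr.data.copy()
        lh = truth.labels.data == sch.wm_left
        edited[planted & lh] = SENTINEL_LH_WM
        edited[planted & ~lh] = SENTINEL_RH_WM
        restored, prot = postfix.apply_sentinels(corr.with_data(edited))
        assert np.array_equal(restored.data, truth.labels.data)
        assert np.array_equal(prot, planted)

    def test_full_postfix_idempotent_and_protecting(self, truth):
        corr, planted = phantom.corrupt_labels(truth, "pial5_occlusion", seed=5)
        edited = corr.data.copy()
        lh = truth.labels.data == sch.wm_left
        edited[planted & lh] = SENTINEL_LH_WM
        edited[planted & ~lh] = SENTINEL_RH_WM
        lv = corr.with_data(edited)
        fixed1, regions1, prot = postfix.run_postfix(lv, truth.ribbon)
        fixed2, regions2, _ = postfix.run_postfix(fixed1, truth.ribbon)
        assert np.array_equal(fixed1.data, fixed2.data)
        assert np.array_equal(regions1.data, regions2.data)
        # sentinel-derived voxels bit-identical through the whole stage
        assert np.all(fixed1.data[prot] == truth.labels.data[prot])

    def test_voxel_conservation_outside_fix_domain(self, truth):
        corr, _ = phantom.corrupt_labels(truth, "csf_island", seed=5)
        fixed, _, _ = postfix.run_postfix(corr, truth.ribbon)
        changeable = np.isin(corr.data, (sch.csf,) + sch.wm_codes)
        assert np.array_equal(fixed.data[~changeable], corr.data[~changeable])
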