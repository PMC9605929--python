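"""Isocontour delineation and lesion metrics with fallback rules."""

import numpy as np
import pytest

from gliodx import (
    PerfusionMaps,
    PetLesionSpec,
    VoiMask,
    compute_lesion_metrics,
    delineate_bv_volume,
    delineate_fet_volume,
    make_pet_phantom,
    sphere_mask,
)

SHAPE = (16, 16, 8)
VSZ = (2.0, 2.0, 2.0)
VVOL = 0.008  # mL per voxel


def make_maps(bv):
    z = np.zeros_like(bv)
    return PerfusionMaps(f=z + 20.0, bv=bv, ki=z + 2.0, ve=z + 20.0,
                         residual=z, valid=np.ones_like(bv, bool))


def bg_mask():
    m = np.zeros(SHAPE, bool)
    m[0:3, 0:3, 0:3] = True
    return m


class TestDelineateFet:
    def test_threshold_is_strictly_above_1p6_background(self):
        pet = np.full(SHAPE, 1000.0)
        pet[8, 8, 4] = 2000.0   # above 1600 -> included
        pet[9, 8, 4] = 1500.0   # below 1600 -> excluded
        voi = delineate_fet_volume(pet, bg_mask(), VVOL)
        assert voi.mask[8, 8, 4]
        assert not voi.mask[9, 8, 4]

    def test_uniform_background_yields_empty_mask(self):
        voi = delineate_fet_volume(np.full(SHAPE, 1000.0), bg_mask(), VVOL)
        assert voi.empty and voi.volume_ml == 0.0

    def test_volume_matches_independent_voxel_count(self):
        pet, _ = make_pet_phantom(1000.0, [PetLesionSpec((8, 8, 4), 10.0, 2.0)],
                                  shape=SHAPE, voxel_size_mm=VSZ)
        voi = delineate_fet_volume(pet, bg_mask(), VVOL)
        assert voi.mask.sum() == int((pet > 1600.0).sum() - bg_mask().sum() * 0)
        assert voi.volume_ml == pytest.approx(voi.mask.sum() * VVOL)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            delineate_fet_volume(np.ones(SHAPE), np.zeros(SHAPE, bool), VVOL)

    def test_seed_selects_connected_component(self):
        pet = np.full(SHAPE, 1000.0)
        pet[2:4, 8:10, 4] = 2000.0     # distractor component
        pet[10:12, 8:10, 4] = 2000.0   # lesion component
        seed = np.zeros(SHAPE, bool)
        seed[10, 8, 4] = True
        voi = delineate_fet_volume(pet, bg_mask(), VVOL, seed=seed)
        assert voi.mask[10, 8, 4] and not voi.mask[2, 8, 4]


class TestDelineateBv:
    def test_all_below_threshold_is_bv_negative(self):
        bv = np.full(SHAPE, 1.5)
        voi = delineate_bv_volume(bv, nawm_reference=1.5, voxel_volume_ml=VVOL,
                                  vessel_mask=np.zeros(SHAPE, bool))
        assert voi.empty

    def test_vessel_voxels_never_included(self):
        bv = np.full(SHAPE, 1.5)
        bv[8, 8, 4] = 50.0
        vessels = np.zeros(SHAPE, bool)
        vessels[8, 8, 4] = True
        voi = delineate_bv_volume(bv, 1.5, VVOL, vessel_mask=vessels)
        assert not voi.mask[8, 8, 4]

    def test_missing_vessel_mask_warns_but_proceeds(self):
        bv = np.full(SHAPE, 1.5)
        with pytest.warns(UserWarning, match="vessel"):
            delineate_bv_volume(bv, 1.5, VVOL)

    def test_phantom_lesion_recovered_exactly_at_zero_noise(self):
        truth = sphere_mask(SHAPE, (8, 8, 4), VSZ, volume_ml=4.0)
        bv = np.where(truth, 4.5, 1.5)  # 3 x NAWM inside, factor 2 threshold
        voi = delineate_bv_volume(bv, 1.5, VVOL, vessel_mask=np.zeros(SHAPE, bool),
                                  threshold_factor=2.0)
        inter = (voi.mask & truth).sum()
        dice = 2 * inter / (voi.mask.sum() + truth.sum())
        assert dice > 0.95


class TestLesionMetrics:
    def _setup(self, pet_ratio=2.4, bv_lesion=10.0):
        pet, masks = make_pet_phantom(
            1000.0, [PetLesionSpec((8, 8, 4), 8.0, pet_ratio)], shape=SHAPE,
            voxel_size_mm=VSZ,
        )
        lesion = masks["lesion0"]
        bv = np.where(lesion, bv_lesion, 2.0)
        nawm = np.zeros(SHAPE, bool)
        nawm[12:15, 1:4, 1:4] = True
        return pet, make_maps(bv), lesion, nawm

    def test_ratio_definitions(self):
        pet, maps, lesion, nawm = self._setup()
        fet = delineate_fet_volume(pet, bg_mask(), VVOL)
        bv = delineate_bv_volume(maps.bv, 2.0, VVOL, vessel_mask=np.zeros(SHAPE, bool))
        rec = compute_lesion_metrics(
            pet, maps, VoiMask(lesion, VVOL), fet, bv, bg_mask(), nawm,
            enhancing=True, voxel_size_mm=VSZ,
        )
        assert rec.tbr_max == pytest.approx(2.4, rel=1e-6)
        assert rec.bv_max == pytest.approx(10.0)
        assert rec.nbv_max == pytest.approx(10.0 / 2.0)  # BV_max / NAWM mean
        assert rec.tbr_med <= rec.tbr_max
        assert rec.bv_med <= rec.bv_max

    def test_bv_negative_enhancing_falls_back_to_ce(self):
        pet, maps, lesion, nawm = self._setup(bv_lesion=3.4)
        fet = delineate_fet_volume(pet, bg_mask(), VVOL)
        bv = delineate_bv_volume(maps.bv, 2.0, VVOL, threshold_factor=2.0,
                                 vessel_mask=np.zeros(SHAPE, bool))
        assert bv.empty  # 3.4 < 2 x 2.0
        rec = compute_lesion_metrics(
            pet, maps, VoiMask(lesion, VVOL), fet, bv, bg_mask(), nawm,
            enhancing=True, voxel_size_mm=VSZ,
        )
        assert rec.bv_max == pytest.approx(3.4)
        assert rec.bv_max_basis == "vol_ce"

    def test_fet_negative_mirrors_fallback_chain(self):
        pet, maps, lesion, nawm = self._setup(pet_ratio=1.4)
        fet = delineate_fet_volume(pet, bg_mask(), VVOL)
        assert fet.empty
        bv = delineate_bv_volume(maps.bv, 2.0, VVOL, vessel_mask=np.zeros(SHAPE, bool))
        rec = compute_lesion_metrics(
            pet, maps, VoiMask(lesion, VVOL), fet, bv, bg_mask(), nawm,
            enhancing=True, voxel_size_mm=VSZ,
        )
        assert rec.tbr_max == pytest.approx(1.4, rel=1e-6)
        assert rec.tbr_max < 1.6 and rec.tbr_max_basis == "vol_ce"

    def test_non_enhancing_fet_negative_uses_flair_sphere(self):
        pet = np.full(SHAPE, 1000.0)
        maps = make_maps(np.full(SHAPE, 2.0))
        nawm = np.zeros(SHAPE, bool)
        nawm[12:15, 1:4, 1:4] = True
        empty = VoiMask(np.zeros(SHAPE, bool), VVOL)
        rec = compute_lesion_metrics(
            pet, maps, None, empty, empty, bg_mask(), nawm,
            enhancing=False, flair_centre=(8, 8, 4), voxel_size_mm=VSZ,
        )
        assert rec.tbr_max == pytest.approx(1.0)
        assert rec.tbr_max_basis == "sphere"
        assert rec.bv_max_basis == "sphere"

    def test_all_fallbacks_empty_flags_missing(self):
        pet = np.full(SHAPE, 1000.0)
        maps = make_maps(np.full(SHAPE, 2.0))
        nawm = np.zeros(SHAPE, bool)
        nawm[12:15, 1:4, 1:4] = True
        empty = VoiMask(np.zeros(SHAPE, bool), VVOL)
        rec = compute_lesion_metrics(
            pet, maps, None, empty, empty, bg_mask(), nawm,
            enhancing=False, flair_centre=None, voxel_size_mm=VSZ,
        )
        assert np.isnan(rec.bv_max) and np.isnan(rec.tbr_max)
        assert rec.bv_max_basis == "missing"

    def test_tbr_invariant_to_global_pet_rescaling(self):
        pet, maps, lesion, nawm = self._setup()
        out = []
        for k in (1.0, 7.3):
            fet = delineate_fet_volume(pet * k, bg_mask(), VVOL)
            bvm = delineate_bv_volume(maps.bv, 2.0, VVOL, vessel_mask=np.zeros(SHAPE, bool))
            rec = compute_lesion_metrics(
                pet * k, maps, VoiMask(lesion, VVOL), fet, bvm, bg_mask(), nawm,
                enhancing=True, voxel_size_mm=VSZ,
            )
            out.append((rec.tbr_max, rec.tbr_med, rec.vol_fet_ml))
        assert out[0] == pytest.approx(out[1], rel=1e-9)

    def test_sphere_mask_volume_is_one_ml(self):
        m = sphere_mask((32, 32, 32), (16, 16, 16), (1.0, 1.0, 1.0), volume_ml=1.0)
        assert m.sum() * 0.001 == pytest.approx(1.0, rel=0.1)
        assert m[16, 16, 16]  # centre-inclusive
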