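"""Segmentation, SIFT/RANSAC registration, patch grids and filtering."""

import numpy as np
import pytest

from virtstain.errors import ConfigurationError, InputError, RegistrationError
from virtstain.fixtures import (
    SyntheticTissueSpec,
    apply_stain_oracle,
    generate_unstained_image,
    perturb_geometry,
    random_misalignment,
)
from virtstain.geometry import HomographyTransform
from virtstain.preprocess import (
    extract_patches,
    filter_background_patches,
    plan_grid,
    register_pair,
    segment_foreground,
)
from virtstain.utils import load_image


class TestSegmentForeground:
    def test_uniform_white_has_no_foreground(self):
        img = np.full((128, 128, 3), 250, np.uint8)
        assert segment_foreground(img).foreground_fraction < 0.01

    def test_recovers_label_map_fraction(self, oracle):
        spec = SyntheticTissueSpec(height=192, width=192, cytoplasm_fraction=0.30, seed=5)
        unstained, labels = generate_unstained_image(spec)
        stained = apply_stain_oracle(unstained, labels, oracle)
        # neighborhood must exceed the ~25 px blob scale of the fixtures
        mask = segment_foreground(stained, block_size=101)
        assert abs(mask.foreground_fraction - (labels > 0).mean()) < 0.05

    def test_mask_matches_image_shape(self, tissue_pair):
        _, stained, _ = tissue_pair
        assert segment_foreground(stained).mask.shape == stained.shape[:2]

    def test_even_block_size_rejected(self, tissue_pair):
        with pytest.raises(ConfigurationError):
            segment_foreground(tissue_pair[1], block_size=50)


class TestRegisterPair:
    def test_self_registration_is_identity(self, tissue_pair):
        _, stained, _ = tissue_pair
        transform, _ = register_pair(stained, stained)
        assert np.abs(transform.matrix - np.eye(3)).max() < 1e-2

    def test_recovers_known_misalignment(self, tissue_pair):
        unstained, stained, _ = tissue_pair
        h, w = unstained.shape[:2]
        true = HomographyTransform.from_params(rotation_deg=3.0, dx=10, dy=-5,
                                               center=(w / 2, h / 2))
        moving = perturb_geometry(unstained, true)
        estimated, warped = register_pair(moving, stained)
        # estimated should invert the perturbation: est o true ~ identity
        comp = estimated.compose(true)
        corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], float)
        err = np.linalg.norm(comp.apply(corners) - corners, axis=1)
        assert err.mean() < 2.0
        assert warped.shape == stained.shape

    def test_blank_pair_raises_registration_error(self):
        blank = np.full((128, 128, 3), 250, np.uint8)
        with pytest.raises(RegistrationError):
            register_pair(blank, blank)

    def test_small_images_rejected(self):
        small = np.zeros((64, 64, 3), np.uint8)
        with pytest.raises(InputError):
            register_pair(small, small)

    def test_median_recovery_over_many_random_homographies(self, oracle):
        """Median corner reprojection error stays below 2 px over 20 pairs."""
        errs = []
        for seed in range(20):
            spec = SyntheticTissueSpec(height=192, width=192, seed=300 + seed,
                                       cytoplasm_fraction=0.45)
            unstained, labels = generate_unstained_image(spec)
            stained = apply_stain_oracle(unstained, labels, oracle)
            rng = np.random.default_rng(9000 + seed)
            true = random_misalignment(rng, labels.shape, max_rotation_deg=5.0,
                                       max_shift_px=20.0)
            moving = perturb_geometry(unstained, true, fill=oracle.background_rgb)
            estimated, _ = register_pair(moving, stained, pair_id=str(seed))
            comp = estimated.compose(true)
            corners = np.array([[0, 0], [191, 0], [0, 191], [191, 191]], float)
            errs.append(np.linalg.norm(comp.apply(corners) - corners, axis=1).mean())
        assert float(np.median(errs)) < 2.0


class TestPatchGrid:
    def test_counts_at_reference_geometry(self):
        grid = plan_grid((1024, 1024), patch_size=512, stride=256)
        assert len(grid.origins) == 9
        assert grid.padded_shape == (1024, 1024)

    def test_single_tile_when_patch_covers_canvas(self):
        grid = plan_grid((512, 512), patch_size=512, stride=256)
        assert grid.origins == [(0, 0)]

    def test_interior_pixels_covered_four_times_at_half_overlap(self):
        grid = plan_grid((256, 256), patch_size=64, stride=32)
        cover = np.zeros(grid.padded_shape, int)
        for r, c in grid.origins:
            cover[r : r + 64, c : c + 64] += 1
        assert (cover >= 1).all()
        assert (cover[32:-32, 32:-32] == 4).all()

    def test_stride_larger_than_patch_rejected(self):
        with pytest.raises(ConfigurationError):
            plan_grid((256, 256), patch_size=64, stride=128)

    def test_pairs_share_the_grid_and_padding(self, tmp_path, tissue_pair):
        unstained, stained, _ = tissue_pair
        records = extract_patches(unstained, stained, "pairX", tmp_path,
                                  patch_size=64, stride=32)
        assert len(records) == 25  # ((192-64)/32+1)^2
        rec = records[7]
        tile_u = load_image(rec.unstained_patch_path)
        tile_s = load_image(rec.stained_patch_path)
        r, c = rec.origin
        np.testing.assert_array_equal(tile_u, unstained[r : r + 64, c : c + 64])
        np.testing.assert_array_equal(tile_s, stained[r : r + 64, c : c + 64])


class TestFilterBackground:
    def _records(self, labels, patch=64, stride=32):
        grid = plan_grid(labels.shape, patch, stride)
        from virtstain.preprocess import PatchRecord

        return [PatchRecord(pair_id="p", origin=o, foreground_fraction=1.0)
                for o in grid.origins]

    def test_all_background_slide_keeps_nothing(self):
        from virtstain.preprocess import ForegroundMask

        mask = ForegroundMask(np.zeros((128, 128), bool))
        recs = self._records(np.zeros((128, 128)))
        assert filter_background_patches(recs, mask, patch_size=64) == []

    def test_all_tissue_slide_keeps_everything(self):
        from virtstain.preprocess import ForegroundMask

        mask = ForegroundMask(np.ones((128, 128), bool))
        recs = self._records(np.zeros((128, 128)))
        kept = filter_background_patches(recs, mask, patch_size=64)
        assert len(kept) == len(recs)
        assert all(r.foreground_fraction == 1.0 for r in kept)

    def test_keeps_exactly_patches_over_threshold(self):
        """The survivors are exactly the tiles the label map says have tissue."""
        from virtstain.fixtures import SyntheticTissueSpec, generate_unstained_image
        from virtstain.preprocess import ForegroundMask

        spec = SyntheticTissueSpec(height=192, width=192, cytoplasm_fraction=0.15,
                                   nucleus_density=3.0, seed=10)
        _, labels = generate_unstained_image(spec)
        mask = ForegroundMask(labels > 0)
        recs = self._records(labels)
        expected = {
            r.origin
            for r in recs
            if (labels > 0)[r.origin[0] : r.origin[0] + 64,
                            r.origin[1] : r.origin[1] + 64].mean() >= 0.05
        }
        kept = filter_background_patches(recs, mask, min_fraction=0.05, patch_size=64)
        assert {r.origin for r in kept} == expected
        assert 0 < len(kept) < len(recs)

    def test_idempotent_and_order_independent(self, tissue_pair):
        from virtstain.preprocess import ForegroundMask

        _, _, labels = tissue_pair
        mask = ForegroundMask(labels > 0)
        recs = self._records(labels)
        once = filter_background_patches(recs, mask, patch_size=64)
        twice = filter_background_patches(once, mask, patch_size=64)
        assert [r.origin for r in once] == [r.origin for r in twice]
        shuffled = list(reversed(recs))
        kept_rev = filter_background_patches(shuffled, mask, patch_size=64)
        assert {r.origin for r in kept_rev} == {r.origin for r in once}
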