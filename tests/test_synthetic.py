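"""Synthetic fixtures and simulated lesions: exactness, determinism, controls."""

import numpy as np
import pytest

from lesionfd.synthetic import (
    DEFAULT_GROUP_SIZES,
    FixtureKind,
    FractalFixtureSpec,
    Illumination,
    SyntheticLesionParams,
    boundary_radius,
    generate_cohort,
    lesion_mask_for,
    render_fixture,
    render_lesion,
    render_lesion_rgb,
)
from .conftest import SMALL


def brute_force_carpet_count(depth: int) -> int:
    """Digit-rule oracle: foreground iff no base-3 digit pair equals (1, 1)."""
    side = 3**depth
    count = 0
    for y in range(side):
        for x in range(side):
            yy, xx, fg = y, x, True
            for _ in range(depth):
                if yy % 3 == 1 and xx % 3 == 1:
                    fg = False
                    break
                yy //= 3
                xx //= 3
            count += fg
    return count


class TestFixtures:
    def test_constant_field(self):
        img = render_fixture(
            FractalFixtureSpec(FixtureKind.CONSTANT_FIELD, side=64, foreground=128)
        )
        assert img.pixels.shape == (64, 64)
        assert (img.pixels == 128).all()

    def test_carpet_depth1_base_case(self):
        img = render_fixture(
            FractalFixtureSpec(
                FixtureKind.SIERPINSKI_CARPET, side=3, depth=1,
                foreground=0, background=255,
            )
        )
        expected = np.zeros((3, 3), dtype=np.uint8)
        expected[1, 1] = 255
        assert (img.pixels == expected).all()

    def test_carpet_depth3_foreground_count(self):
        img = render_fixture(
            FractalFixtureSpec(FixtureKind.SIERPINSKI_CARPET, side=27, depth=3)
        )
        assert (img.pixels == 0).sum() == 512  # 8^3
        assert (img.pixels == 0).sum() == brute_force_carpet_count(3)

    def test_carpet_wrong_side_rejected(self):
        with pytest.raises(ValueError, match="3\\^depth"):
            FractalFixtureSpec(FixtureKind.SIERPINSKI_CARPET, side=30, depth=3)

    def test_fbm_texture_deterministic_and_two_valued_extremes(self):
        spec = FractalFixtureSpec(FixtureKind.FBM_TEXTURE, side=64, hurst=0.5, seed=3)
        a, b = render_fixture(spec), render_fixture(spec)
        assert (a.pixels == b.pixels).all()
        assert a.pixels.min() == 0 and a.pixels.max() == 255

    def test_checkerboard_alternates(self):
        img = render_fixture(
            FractalFixtureSpec(FixtureKind.CHECKERBOARD, side=4, foreground=0, background=255)
        )
        assert img.pixels[0, 0] == 0 and img.pixels[0, 1] == 255


class TestRenderLesion:
    def test_circular_when_unperturbed(self):
        p = SyntheticLesionParams(
            seed=1, irregularity_amplitude=0.0, specular_noise_density=0.0,
            texture_sd=0.0, **SMALL,
        )
        mask = lesion_mask_for(p)
        assert abs(mask.sum() - np.pi * p.base_radius**2) / (np.pi * p.base_radius**2) < 0.02

    def test_same_seed_bit_identical(self, small_lesion_params):
        a = render_lesion(small_lesion_params)
        b = render_lesion(small_lesion_params)
        assert (a.pixels == b.pixels).all()

    def test_pl_npl_share_mask_and_differ_in_contrast(self, small_lesion_params):
        from dataclasses import replace

        pl = small_lesion_params
        npl = replace(pl, illumination=Illumination.NPL)
        assert (lesion_mask_for(pl) == lesion_mask_for(npl)).all()
        pl_img, npl_img = render_lesion(pl), render_lesion(npl)
        mask = lesion_mask_for(pl)
        contrast_pl = pl_img.pixels[~mask].mean() - pl_img.pixels[mask].mean()
        contrast_npl = npl_img.pixels[~mask].mean() - npl_img.pixels[mask].mean()
        assert contrast_npl < contrast_pl

    def test_npl_has_specular_speckles(self, small_lesion_params):
        from dataclasses import replace

        npl = render_lesion(replace(small_lesion_params, illumination=Illumination.NPL))
        assert (npl.pixels == 255).sum() > 0

    def test_boundary_perimeter_monotone_in_amplitude(self):
        theta = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        lengths = []
        for amp in (0.0, 0.05, 0.15, 0.25, 0.35):
            p = SyntheticLesionParams(seed=5, irregularity_amplitude=amp, **SMALL)
            r = boundary_radius(p, theta)
            pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
            seg = np.diff(np.vstack([pts, pts[:1]]), axis=0)
            lengths.append(float(np.hypot(seg[:, 0], seg[:, 1]).sum()))
        assert all(a < b for a, b in zip(lengths, lengths[1:]))

    def test_self_intersection_rejected(self):
        p = SyntheticLesionParams(seed=5, irregularity_amplitude=1.5, **SMALL)
        with pytest.raises(ValueError, match="self-intersect"):
            lesion_mask_for(p)

    def test_lesion_darker_than_background_enforced(self):
        with pytest.raises(ValueError, match="darker"):
            SyntheticLesionParams(lesion_mean_intensity=220, background_mean_intensity=200)

    def test_rgb_variant_shape(self, small_lesion_params):
        rgb = render_lesion_rgb(small_lesion_params)
        assert rgb.shape == (320, 320, 3) and rgb.dtype == np.uint8


class TestCohort:
    def test_counts_and_ids(self):
        presets = {
            g: SyntheticLesionParams(**SMALL, irregularity_amplitude=a)
            for g, a in (("BN", 0.05), ("DN", 0.15), ("MM", 0.30))
        }
        entries = generate_cohort(2, presets, seed=9)
        assert len(entries) == 6
        assert sum(e.pl_image is not None and e.npl_image is not None for e in entries) == 6
        assert len({e.lesion_id for e in entries}) == 6

    def test_master_seed_reproducible(self):
        presets = {"BN": SyntheticLesionParams(**SMALL)}
        a = generate_cohort(2, presets, seed=11)
        b = generate_cohort(2, presets, seed=11)
        for ea, eb in zip(a, b):
            assert (ea.pl_image.pixels == eb.pl_image.pixels).all()
            assert (ea.npl_image.pixels == eb.npl_image.pixels).all()

    def test_study_group_sizes_give_97_pairs(self):
        # counting only: tiny canvas keeps the render trivial
        tiny = {
            g: SyntheticLesionParams(
                image_width=64, image_height=64, base_radius=20.0, harmonics=6
            )
            for g in DEFAULT_GROUP_SIZES
        }
        entries = generate_cohort(DEFAULT_GROUP_SIZES, tiny, seed=1)
        assert len(entries) == 97
        assert sum(e.group == "MM" for e in entries) == 20
        assert sum(e.group == "DN" for e in entries) == 23
        assert sum(e.group == "BN" for e in entries) == 54
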