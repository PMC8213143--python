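"""Synthetic phantom cohort: determinism, stationarity, geometry."""

import numpy as np
import pytest

from mritexture.synthetic import (
    GROUP_PRESETS,
    CohortDesign,
    ImageVolume,
    SubjectSpec,
    TextureParams,
    generate_cohort,
    generate_subject,
    generate_subject_volume,
)


def _spec(background, lesion, seed=11, centers=((12.0, 16.0, 16.0),),
          radii=((7.0, 7.0, 7.0),)):
    return SubjectSpec(
        subject_id="S0", disease_group="TU", n_lesions=len(centers),
        lesion_radii=radii, lesion_centers=centers,
        background_params=background, lesion_params={"T1": lesion},
        seed=seed,
    )


GRID = (48, 32, 32)
SPACING = (1.0, 1.0, 1.0)


class TestSubjectVolume:
    def test_zero_variance_fields_are_piecewise_constant(self):
        spec = _spec(TextureParams(100.0, 0.0), TextureParams(200.0, 0.0))
        vol, masks = generate_subject_volume(spec, "T1", GRID, SPACING)
        assert np.all(vol.voxels[~masks[0]] == 100.0)
        assert np.all(vol.voxels[masks[0]] == 200.0)

    def test_determinism_same_inputs_bit_identical(self):
        spec = _spec(TextureParams(100.0, 10.0, 1.5, 0.5),
                     TextureParams(200.0, 20.0, 2.0, 0.5))
        v1, m1 = generate_subject_volume(spec, "T1", GRID, SPACING)
        v2, m2 = generate_subject_volume(spec, "T1", GRID, SPACING)
        assert np.array_equal(v1.voxels, v2.voxels)
        assert np.array_equal(m1[0], m2[0])

    def test_lesion_interior_mean_matches_target(self):
        # white noise, no blur: interior sample mean ~ N(200, 10/sqrt(n))
        spec = _spec(TextureParams(100.0, 10.0), TextureParams(200.0, 10.0))
        vol, masks = generate_subject_volume(spec, "T1", GRID, SPACING)
        inner = vol.voxels[masks[0]]
        se = 10.0 / np.sqrt(inner.size)
        assert abs(inner.mean() - 200.0) < 3 * se

    def test_blur_smooths_boundary_but_preserves_far_field(self):
        spec = _spec(TextureParams(100.0, 0.0, 0.0, 1.0),
                     TextureParams(200.0, 0.0, 0.0, 1.0))
        vol, masks = generate_subject_volume(spec, "T1", GRID, SPACING)
        # far from the lesion the field stays at the background mean
        assert vol.voxels[45, 2, 2] == pytest.approx(100.0, abs=1e-6)
        # boundary shell holds intermediate (partial-volume) values
        assert ((vol.voxels > 110) & (vol.voxels < 190)).any()

    def test_outputs_strictly_positive_after_clamp(self):
        spec = _spec(TextureParams(5.0, 30.0), TextureParams(200.0, 10.0))
        vol, _ = generate_subject_volume(spec, "T1", GRID, SPACING)
        assert vol.voxels.min() >= 1.0

    def test_lesion_outside_grid_raises(self):
        spec = _spec(TextureParams(100.0, 1.0), TextureParams(200.0, 1.0),
                     centers=((3.0, 16.0, 16.0),))
        with pytest.raises(ValueError, match="outside"):
            generate_subject_volume(spec, "T1", GRID, SPACING)

    def test_nonpositive_spacing_raises(self):
        spec = _spec(TextureParams(100.0, 1.0), TextureParams(200.0, 1.0))
        with pytest.raises(ValueError):
            generate_subject_volume(spec, "T1", GRID, (1.0, 0.0, 1.0))


class TestStationarity:
    def test_no_lesion_field_matches_texture_params(self):
        """Empirical mean/sd of the background converge to the targets."""
        design = CohortDesign(grid_shape=(40, 40, 40))
        spec = SubjectSpec(
            subject_id="bg", disease_group="TU", n_lesions=1,
            lesion_radii=((2.0, 2.0, 2.0),),
            lesion_centers=((8.0, 20.0, 20.0),),
            background_params=TextureParams(100.0, 10.0, 1.5, 0.0),
            lesion_params={"T1": TextureParams(100.0, 10.0, 1.5, 0.0)},
            seed=5,
        )
        vol, _ = generate_subject_volume(spec, "T1", (40, 40, 40), SPACING)
        n = vol.voxels.size
        assert abs(vol.voxels.mean() - 100.0) < 3 * 10.0 / np.sqrt(n) + 1e-9
        assert abs(vol.voxels.std() - 10.0) < 0.5


class TestCohort:
    def test_default_design_has_71_subjects(self):
        design = CohortDesign()
        assert design.n_subjects == 71
        assert (design.n_is, design.n_ms, design.n_tu) == (22, 22, 27)

    def test_minimal_cohort_counts(self):
        design = CohortDesign(n_is=1, n_ms=1, n_tu=1, master_seed=3)
        records = generate_cohort(design)
        assert len(records) == 3
        assert sum(len(r.volumes) for r in records) == 6
        assert {r.spec.disease_group for r in records} == {"IS", "MS", "TU"}

    def test_cohort_determinism(self):
        design = CohortDesign(n_is=1, n_ms=1, n_tu=1, master_seed=9)
        r1 = generate_cohort(design)
        r2 = generate_cohort(design)
        for a, b in zip(r1, r2):
            assert a.spec == b.spec
            for contrast in a.volumes:
                assert np.array_equal(
                    a.volumes[contrast].voxels, b.volumes[contrast].voxels
                )

    def test_lesion_geometry_shared_across_contrasts(self):
        design = CohortDesign(n_is=1, n_ms=1, n_tu=1, master_seed=2)
        for rec in generate_cohort(design):
            _, masks_t1 = generate_subject_volume(
                rec.spec, "T1", design.grid_shape, design.spacing
            )
            _, masks_t2 = generate_subject_volume(
                rec.spec, "T2", design.grid_shape, design.spacing
            )
            for a, b in zip(masks_t1, masks_t2):
                assert np.array_equal(a, b)
            # contrasts differ in their noise realisation
            assert not np.array_equal(
                rec.volumes["T1"].voxels, rec.volumes["T2"].voxels
            )

    def test_group_resizing_preserves_other_subjects(self):
        """Seed substreams: growing one group never perturbs another."""
        small = generate_cohort(CohortDesign(n_is=1, n_ms=1, n_tu=1, master_seed=4))
        large = generate_cohort(CohortDesign(n_is=2, n_ms=1, n_tu=1, master_seed=4))
        by_id_small = {r.spec.subject_id: r for r in small}
        by_id_large = {r.spec.subject_id: r for r in large}
        for sid, rec in by_id_small.items():
            other = by_id_large[sid]
            assert rec.spec == other.spec
            for contrast in rec.volumes:
                assert np.array_equal(
                    rec.volumes[contrast].voxels,
                    other.volumes[contrast].voxels,
                )

    def test_lesions_and_mirrors_disjoint_and_inside(self):
        design = CohortDesign(n_is=2, n_ms=2, n_tu=2, master_seed=8)
        for rec in generate_cohort(design):
            total = np.zeros(design.grid_shape, dtype=int)
            for mask in rec.lesion_masks:
                total += mask
                mirrored = mask[::-1]  # reflection across (X-1)/2
                total += mirrored
            assert total.max() <= 1  # no lesion/control overlap anywhere


class TestValidation:
    def test_image_volume_requires_positive_intensities(self):
        with pytest.raises(ValueError):
            ImageVolume(np.zeros((4, 4, 4)), (1, 1, 1))

    def test_texture_params_validation(self):
        with pytest.raises(ValueError):
            TextureParams(mean_intensity=0.0)
        with pytest.raises(ValueError):
            TextureParams(mean_intensity=10.0, intensity_sd=-1.0)

    def test_group_presets_cover_all_groups(self):
        assert set(GROUP_PRESETS) == {"IS", "MS", "TU"}
        for preset in GROUP_PRESETS.values():
            assert set(preset["lesion_params"]) == {"T1", "T2"}
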