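import numpy as np
import pytest
import trimesh

from volsurf.errors import ValidationError
from volsurf.formats_io import TriangleMesh, VolumeImage
from volsurf.fusion import (
    SubjectBundle,
    SurfToVolMapping,
    average_partial,
    build_affine_baseline,
    build_single_registration_baseline,
    build_surf2vol,
    build_vol2surf,
    dilate_mapping,
    finalize_surf2vol,
    load_surf2vol,
    load_vol2surf,
    per_subject_vertex_coords,
    save_surf2vol,
    save_vol2surf,
)
from volsurf.surfaces import SphericalRegistration
from volsurf.transforms import AffineTransform, TransformChain


def translation(d):
    m = np.eye(4)
    m[:3, 3] = d
    return AffineTransform(m)


@pytest.fixture(scope="module")
def sphere():
    ico = trimesh.creation.icosphere(subdivisions=1, radius=1.0)
    return TriangleMesh(np.asarray(ico.vertices, float), np.asarray(ico.faces))


def identity_bundle(sphere, radius=3.0, grid=12, shift=(0, 0, 0), sid="s0"):
    """A subject that IS the template: identity transforms, optional
    anatomy translation realized through affine chains."""
    anat = TriangleMesh(sphere.vertices * radius + np.array(shift, float), sphere.faces)
    affine = np.eye(4)
    affine[:3, 3] = -(grid - 1) / 2.0
    idx = np.indices((grid,) * 3).reshape(3, -1).T
    centers = idx + affine[:3, 3]
    r = np.linalg.norm(centers - np.array(shift, float), axis=1).reshape((grid,) * 3)
    ribbon = ((r >= radius - 1) & (r <= radius + 1)).astype(np.uint8)
    return SubjectBundle(
        subject_id=sid,
        vol_chain=TransformChain([translation(shift)]),
        inverse_vol_chain=TransformChain([translation(-np.array(shift, float))]),
        reg=SphericalRegistration(anat, sphere.vertices, sphere),
        ribbon_mask=VolumeImage(ribbon, affine),
    ), affine


class TestVol2Surf:
    def test_single_identity_subject_recovers_template_vertices(self, sphere):
        bundle, _ = identity_bundle(sphere)
        m = build_vol2surf([bundle], sphere)
        assert np.allclose(m.coords, sphere.vertices * 3.0, atol=1e-9)
        assert m.n_subjects == 1

    def test_opposite_translations_cancel_in_the_mean(self, sphere):
        d = np.array([0.7, -0.3, 0.2])
        anat = TriangleMesh(sphere.vertices * 3.0, sphere.faces)
        rib = identity_bundle(sphere)[0].ribbon_mask
        bundles = []
        for s, sid in ((1.0, "plus"), (-1.0, "minus")):
            bundles.append(
                SubjectBundle(
                    subject_id=sid,
                    vol_chain=TransformChain([translation(-s * d)]),
                    inverse_vol_chain=TransformChain([translation(s * d)]),
                    reg=SphericalRegistration(anat, sphere.vertices, sphere),
                    ribbon_mask=rib,
                )
            )
        m = build_vol2surf(bundles, sphere)
        assert np.allclose(m.coords, anat.vertices, atol=1e-9)

    def test_empty_cohort_rejected(self, sphere):
        with pytest.raises(ValidationError):
            build_vol2surf([], sphere)

    def test_zero_jitter_cohort_matches_ground_truth(self, zero_template, zero_cohort):
        cohort, truth = zero_cohort
        m = build_vol2surf(cohort, zero_template.sphere)
        err = np.linalg.norm(m.coords - truth.vol2surf.coords, axis=1)
        assert err.max() < 0.5 * zero_template.spec.voxel_size

    def test_jittered_error_shrinks_with_cohort_size(self):
        # zero-mean jitter: error from 2 subjects should beat 1 subject
        # in most seeds; checked in depth by the acceptance suite
        from volsurf.synthetic import PhantomSpec, make_cohort, make_template

        spec = PhantomSpec(
            grid_shape=(36,) * 3, r_in=10, r_out=14, n_parcels=8, n_subjects=6,
            amplitude=1.0, jitter_deg=3.0, seed=3, subdivisions=2,
        )
        template = make_template(spec)
        cohort, truth = make_cohort(spec, template)
        errs = []
        for n in (1, 6):
            m = average_partial(cohort, template.sphere, list(range(n)))
            errs.append(np.linalg.norm(m.coords - truth.vol2surf.coords, axis=1).mean())
        assert errs[1] < errs[0]


class TestAveragePartial:
    def test_full_subset_equals_batch_build(self, small_template, small_cohort):
        cohort, _ = small_cohort
        full = build_vol2surf(cohort, small_template.sphere)
        part = average_partial(cohort, small_template.sphere, range(len(cohort)))
        np.testing.assert_array_equal(full.coords, part.coords)

    def test_singleton_subset_is_that_subject(self, small_template, small_cohort):
        cohort, _ = small_cohort
        part = average_partial(cohort, small_template.sphere, [1])
        solo = build_vol2surf([cohort[1]], small_template.sphere)
        np.testing.assert_array_equal(part.coords, solo.coords)

    def test_streaming_mean_equals_batch_mean(self, small_template, small_cohort, rng):
        cohort, _ = small_cohort
        per = [per_subject_vertex_coords(b, small_template.sphere) for b in cohort]
        order = rng.permutation(len(per))
        stream = np.zeros_like(per[0])
        for k, i in enumerate(order, start=1):
            stream += (per[i] - stream) / k
        batch = np.mean(per, axis=0)
        assert np.abs(stream - batch).max() < 1e-12

    def test_empty_subset_rejected(self, small_template, small_cohort):
        with pytest.raises(ValidationError):
            average_partial(small_cohort[0], small_template.sphere, [])


class TestSurf2Vol:
    def test_coverage_counts_subjects(self, sphere):
        # 4 identical subjects, one with a decimated ribbon: voxels kept by
        # 3 of 4 subjects get coverage 0.75 and join both masks
        b_full, affine = identity_bundle(sphere)
        rib = b_full.ribbon_mask.data.copy()
        hole = tuple(np.argwhere(rib > 0)[0])
        rib_holed = rib.copy()
        rib_holed[hole] = 0
        bundles = []
        for i in range(4):
            b, _ = identity_bundle(sphere, sid=f"s{i}")
            if i == 3:
                b.ribbon_mask = VolumeImage(rib_holed, affine)
            bundles.append(b)
        m = build_surf2vol(bundles, (12,) * 3, affine)
        assert m.coverage[hole] == pytest.approx(0.75)
        assert m.tight_mask[hole] and m.loose_mask[hole]

    def test_threshold_arithmetic_with_default_masks(self, sphere):
        # coverage 1.0 / 0.5 / 0.25 / 0.0 across four probe voxels
        b0, affine = identity_bundle(sphere)
        probes = [tuple(p) for p in np.argwhere(b0.ribbon_mask.data > 0)[:3]]
        bundles = []
        for i in range(4):
            b, _ = identity_bundle(sphere, sid=f"s{i}")
            rib = b.ribbon_mask.data.copy()
            if i >= 2:
                rib[probes[1]] = 0
            if i >= 1:
                rib[probes[2]] = 0
            b.ribbon_mask = VolumeImage(rib, affine)
            bundles.append(b)
        outside = tuple(np.argwhere(b0.ribbon_mask.data == 0)[0])
        m = build_surf2vol(bundles, (12,) * 3, affine)
        assert m.coverage[probes[0]] == 1.0
        assert m.coverage[probes[1]] == 0.5
        assert m.coverage[probes[2]] == 0.25
        assert m.coverage[outside] == 0.0
        assert m.tight_mask[probes[0]] and m.tight_mask[probes[1]]
        assert not m.tight_mask[probes[2]]
        assert m.loose_mask[probes[2]]
        assert not m.loose_mask[outside]

    def test_identical_subjects_make_tight_equal_loose(self, sphere):
        bundles = [identity_bundle(sphere, sid=f"s{i}")[0] for i in range(3)]
        affine = bundles[0].ribbon_mask.affine
        m = build_surf2vol(bundles, (12,) * 3, affine)
        footprint = bundles[0].ribbon_mask.data > 0
        np.testing.assert_array_equal(m.tight_mask, footprint)
        np.testing.assert_array_equal(m.tight_mask, m.loose_mask)

    def test_invalid_thresholds_rejected(self, sphere):
        b, affine = identity_bundle(sphere)
        with pytest.raises(ValidationError):
            build_surf2vol([b], (12,) * 3, affine, tight_thresh=0.5, loose_thresh=0.8)

    def test_tight_subset_of_loose_for_any_threshold_pair(self, small_template, small_cohort):
        cohort, _ = small_cohort
        for tight, loose in [(0.9, 0.1), (0.5, 0.5), (1.0, 0.2), (0.34, 0.33)]:
            m = build_surf2vol(
                cohort, small_template.shape, small_template.affine, tight, loose
            )
            assert not np.any(m.tight_mask & ~m.loose_mask)


def _random_mapping(rng, shape):
    n = int(np.prod(shape))
    coverage = rng.random(shape)
    tight = coverage >= 0.6
    loose = coverage >= 0.3
    if not tight.any():
        tight.ravel()[0] = True
        loose.ravel()[0] = True
    sphere = rng.standard_normal(shape + (3,))
    sphere /= np.linalg.norm(sphere, axis=-1, keepdims=True)
    sphere[~loose] = np.nan
    affine = np.diag([1.0, 1.3, 0.7, 1.0])  # anisotropic: distances in mm
    return SurfToVolMapping(
        shape=shape, affine=affine, sphere_coords=sphere, coverage=coverage,
        tight_mask=tight, loose_mask=loose, tight_thresh=0.6, loose_thresh=0.3,
        n_subjects=5,
    )


class TestDilate:
    def test_matches_exhaustive_search_on_random_grids(self, rng):
        for shape in [(6, 6, 6), (8, 7, 6), (12, 12, 12)]:
            m = _random_mapping(rng, shape)
            out = dilate_mapping(m)
            centers = m.voxel_centers()
            tight_lin = np.nonzero(m.tight_mask.ravel(order="F"))[0]
            grow_lin = np.nonzero(
                (m.loose_mask & ~m.tight_mask).ravel(order="F")
            )[0]
            sphere_flat = np.array(
                [m.sphere_coords[..., c].ravel(order="F") for c in range(3)]
            ).T
            out_flat = np.array(
                [out.sphere_coords[..., c].ravel(order="F") for c in range(3)]
            ).T
            for g in grow_lin:
                d = np.linalg.norm(centers[tight_lin] - centers[g], axis=1)
                # geometric ties reached via different float paths differ by
                # an ulp; the tie set uses a relative tolerance accordingly
                ties = d <= d.min() * (1 + 1e-9) + 1e-12
                best = tight_lin[ties].min()  # lowest linear index wins
                np.testing.assert_array_equal(out_flat[g], sphere_flat[best])

    def test_equidistant_tie_goes_to_lower_linear_index(self):
        shape = (3, 1, 1)
        sphere = np.full(shape + (3,), np.nan)
        sphere[0, 0, 0] = [1, 0, 0]
        sphere[2, 0, 0] = [0, 1, 0]
        tight = np.zeros(shape, bool)
        tight[0, 0, 0] = tight[2, 0, 0] = True
        loose = np.ones(shape, bool)
        m = SurfToVolMapping(
            shape=shape, affine=np.eye(4), sphere_coords=sphere,
            coverage=tight.astype(float), tight_mask=tight, loose_mask=loose,
            tight_thresh=0.5, loose_thresh=0.15, n_subjects=2,
        )
        out = dilate_mapping(m)
        np.testing.assert_array_equal(out.sphere_coords[1, 0, 0], [1, 0, 0])

    def test_empty_tight_mask_rejected(self, rng):
        m = _random_mapping(rng, (5, 5, 5))
        m.tight_mask[:] = False
        with pytest.raises(ValidationError):
            dilate_mapping(m)


class TestFinalize:
    def test_exact_vertex_coordinate_maps_to_that_vertex(self, sphere, rng):
        m = _random_mapping(rng, (6, 6, 6))
        lin = np.argwhere(m.loose_mask)
        m.sphere_coords[tuple(lin[0])] = sphere.vertices[12]
        out = finalize_surf2vol(dilate_mapping(m), sphere)
        assert out.vertex_index[tuple(lin[0])] == 12

    def test_matches_exhaustive_vertex_scan(self, sphere, rng):
        m = finalize_surf2vol(dilate_mapping(_random_mapping(rng, (8, 8, 8))), sphere)
        loose = np.argwhere(m.loose_mask)[:500]
        for ijk in loose:
            coord = m.sphere_coords[tuple(ijk)]
            d = np.linalg.norm(sphere.vertices - coord, axis=1)
            assert m.vertex_index[tuple(ijk)] == d.argmin()

    def test_degenerate_average_excluded_with_warning(self, sphere, rng):
        m = _random_mapping(rng, (6, 6, 6))
        bad = tuple(np.argwhere(m.loose_mask & ~m.tight_mask)[0])
        m.sphere_coords[bad] = np.nan  # antipodal cancellation marker
        with pytest.warns(UserWarning, match="degenerate"):
            out = finalize_surf2vol(m, sphere)
        assert not out.loose_mask[bad]
        assert out.vertex_index[bad] == -1


class TestBaselines:
    def test_identity_affine_reproduces_supplied_table(self, sphere):
        b, affine = identity_bundle(sphere)
        v2s, s2v = build_affine_baseline(
            AffineTransform(np.eye(4)), b.reg.subject_mesh, sphere,
            b.ribbon_mask, (12,) * 3, affine,
        )
        assert np.allclose(v2s.coords, b.reg.subject_mesh.vertices, atol=1e-9)
        np.testing.assert_array_equal(s2v.tight_mask, b.ribbon_mask.data > 0)

    def test_translation_affine_shifts_every_coordinate(self, sphere):
        b, affine = identity_bundle(sphere)
        t = np.array([1.5, 0.0, -1.0])
        v2s, _ = build_affine_baseline(
            translation(t), b.reg.subject_mesh, sphere, b.ribbon_mask, (12,) * 3, affine
        )
        assert np.allclose(v2s.coords, b.reg.subject_mesh.vertices - t, atol=1e-9)

    def test_single_registration_equals_one_subject_fusion(self, small_template, small_cohort):
        cohort, _ = small_cohort
        v2s, s2v = build_single_registration_baseline(
            cohort[0], small_template.sphere, small_template.shape, small_template.affine
        )
        ref = build_vol2surf([cohort[0]], small_template.sphere)
        np.testing.assert_array_equal(v2s.coords, ref.coords)
        footprint_cov = build_surf2vol(
            [cohort[0]], small_template.shape, small_template.affine
        ).coverage
        np.testing.assert_array_equal(s2v.coverage, footprint_cov)
        np.testing.assert_array_equal(s2v.tight_mask, s2v.loose_mask)


class TestSerialization:
    def test_vol2surf_round_trip(self, tmp_path, small_template, small_cohort):
        cohort, _ = small_cohort
        m = build_vol2surf(cohort, small_template.sphere)
        save_vol2surf(m, tmp_path, subject_ids=[b.subject_id for b in cohort])
        back = load_vol2surf(tmp_path)
        np.testing.assert_array_equal(back.coords, m.coords)
        assert back.n_subjects == m.n_subjects

    def test_surf2vol_round_trip(self, tmp_path, small_template, small_cohort):
        cohort, _ = small_cohort
        m = build_surf2vol(cohort, small_template.shape, small_template.affine)
        m = finalize_surf2vol(dilate_mapping(m), small_template.sphere)
        save_surf2vol(m, tmp_path)
        back = load_surf2vol(tmp_path)
        np.testing.assert_array_equal(back.vertex_index, m.vertex_index)
        np.testing.assert_array_equal(back.tight_mask, m.tight_mask)
        np.testing.assert_array_equal(back.loose_mask, m.loose_mask)
        assert back.tight_thresh == m.tight_thresh
        assert back.n_subjects == m.n_subjects
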