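import json

import numpy as np
import pytest

from volsurf.errors import ValidationError
from volsurf.evaluation import dice
from volsurf.synthetic import (
    PhantomSpec,
    load_cohort,
    make_cohort,
    make_evaluation_data,
    make_subject,
    make_subject_parcellations,
    make_template,
    write_cohort,
)
from volsurf.transforms import resample_volume


class TestSpec:
    def test_shell_must_fit_inside_grid(self):
        with pytest.raises(ValidationError):
            PhantomSpec(grid_shape=(20, 20, 20), r_in=14, r_out=18)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValidationError):
            PhantomSpec(amplitude=-1.0)

    def test_parcel_minimum(self):
        with pytest.raises(ValidationError):
            PhantomSpec(n_parcels=1)


class TestTemplate:
    def test_ribbon_volume_matches_analytic_shell(self):
        spec = PhantomSpec(n_subjects=1)  # default 48^3, radii 14-18
        template = make_template(spec)
        count = int(template.ribbon.data.sum()) * spec.voxel_size**3
        analytic = 4 / 3 * np.pi * (spec.r_out**3 - spec.r_in**3)
        assert abs(count - analytic) / analytic < 0.05

    def test_parcels_partition_the_ribbon(self, small_template):
        ribbon = small_template.ribbon.data.astype(bool)
        parc = small_template.parc.data
        assert np.all(parc[ribbon] > 0)
        assert np.all(parc[~ribbon] == 0)
        assert set(np.unique(parc[ribbon])) == set(small_template.label_ids)

    def test_vertex_labels_cover_all_parcels(self, small_template):
        assert set(np.unique(small_template.vertex_labels)) == set(
            small_template.label_ids
        )

    def test_parcels_respect_hemispheres(self, small_template):
        # every parcel's vertices lie in the parcel's own half-shell
        for i, label in enumerate(small_template.label_ids):
            hemis = small_template.vertex_hemi[small_template.vertex_labels == label]
            assert np.all(hemis == small_template.parcel_hemi[i])

    def test_deterministic_for_identical_seed(self, small_spec):
        a = make_template(small_spec)
        b = make_template(small_spec)
        np.testing.assert_array_equal(a.parc.data, b.parc.data)
        np.testing.assert_array_equal(a.mid_surface.vertices, b.mid_surface.vertices)
        np.testing.assert_array_equal(a.seed_directions, b.seed_directions)


class TestSubject:
    def test_zero_amplitude_zero_jitter_is_identity(self, zero_spec, zero_template):
        bundle, forward = make_subject(zero_spec, 0, template=zero_template)
        assert np.abs(forward.field.vectors).max() == 0
        np.testing.assert_array_equal(
            bundle.ribbon_mask.data, zero_template.ribbon.data
        )
        np.testing.assert_array_equal(
            bundle.reg.sphere_coords, zero_template.sphere.vertices
        )
        assert np.allclose(
            bundle.reg.subject_mesh.vertices, zero_template.mid_surface.vertices
        )

    def test_max_displacement_bounded_by_amplitude(self, small_spec, small_template):
        _, forward = make_subject(small_spec, 2, template=small_template)
        norms = np.linalg.norm(forward.field.vectors, axis=-1)
        assert norms.max() <= small_spec.amplitude + 1e-9
        assert norms.max() == pytest.approx(small_spec.amplitude)

    def test_warped_ribbon_round_trip_overlap(self, small_template):
        spec = PhantomSpec(
            grid_shape=(36,) * 3, r_in=10, r_out=14, n_parcels=8, n_subjects=1,
            amplitude=2.0, jitter_deg=0.0, seed=5, subdivisions=2,
        )
        bundle, forward = make_subject(spec, 0, template=small_template)
        back = resample_volume(
            bundle.ribbon_mask, bundle.vol_chain, interp="nearest"
        )
        overlap = dice(
            back.data.astype(np.int32), small_template.ribbon.data.astype(np.int32), 1
        )
        assert overlap > 0.95


class TestCohort:
    def test_deterministic_for_identical_seed(self, small_spec, small_template):
        a, _ = make_cohort(small_spec, small_template)
        b, _ = make_cohort(small_spec, small_template)
        for ba, bb in zip(a, b):
            np.testing.assert_array_equal(
                ba.vol_chain.steps[0].field.vectors, bb.vol_chain.steps[0].field.vectors
            )
            np.testing.assert_array_equal(ba.reg.sphere_coords, bb.reg.sphere_coords)

    def test_prefix_stable_without_recentering(self):
        kw = dict(
            grid_shape=(36,) * 3, r_in=10, r_out=14, n_parcels=8, amplitude=1.0,
            jitter_deg=2.0, seed=9, subdivisions=2, recenter=False,
        )
        template = make_template(PhantomSpec(n_subjects=2, **kw))
        short, _ = make_cohort(PhantomSpec(n_subjects=2, **kw), template)
        long, _ = make_cohort(PhantomSpec(n_subjects=4, **kw), template)
        for a, b in zip(short, long):
            np.testing.assert_array_equal(
                a.vol_chain.steps[0].field.vectors, b.vol_chain.steps[0].field.vectors
            )
            np.testing.assert_array_equal(a.reg.sphere_coords, b.reg.sphere_coords)

    def test_recentering_shrinks_the_cohort_mean_field(self):
        kw = dict(
            grid_shape=(36,) * 3, r_in=10, r_out=14, n_parcels=8, n_subjects=6,
            amplitude=1.0, jitter_deg=0.0, seed=13, subdivisions=2,
        )
        template = make_template(PhantomSpec(**kw))
        def mean_field(recenter):
            cohort, truth = make_cohort(PhantomSpec(recenter=recenter, **kw), template)
            stack = np.stack([t.field.vectors for t in truth.true_fields])
            return np.linalg.norm(stack.mean(axis=0), axis=-1).max()
        assert mean_field(True) < 0.35 * mean_field(False)

    def test_ground_truth_self_consistency(self, small_template, small_cohort):
        # forward then recorded inverse returns the mid-surface vertices
        # within twice the inversion tolerance (0.005 mm)
        cohort, _ = small_cohort
        verts = small_template.mid_surface.vertices
        for bundle in cohort[:2]:
            fwd = bundle.vol_chain.map_points(verts, oob="clamp")
            back = bundle.inverse_vol_chain.map_points(fwd, oob="clamp")
            assert np.linalg.norm(back - verts, axis=1).max() < 2 * 0.005

    def test_ground_truth_vertex_voxel_round_trip(self, small_template, small_cohort):
        # template vertex -> its voxel -> assigned vertex is the identity
        _, truth = small_cohort
        s2v = truth.surf2vol
        verts = small_template.mid_surface.vertices
        inv_aff = np.linalg.inv(small_template.affine)
        vox = np.round(verts @ inv_aff[:3, :3].T + inv_aff[:3, 3]).astype(int)
        hits = s2v.vertex_index[vox[:, 0], vox[:, 1], vox[:, 2]]
        assert (hits == np.arange(len(verts))).mean() > 0.95


class TestSubjectParcellations:
    def test_identity_cohort_reproduces_template(self, zero_template, zero_cohort):
        parcs = make_subject_parcellations(zero_template, zero_cohort[0])
        for p in parcs:
            np.testing.assert_array_equal(p.data, zero_template.parc.data)

    def test_label_set_preserved(self, small_template, small_cohort):
        parcs = make_subject_parcellations(small_template, small_cohort[0])
        allowed = set(small_template.label_ids) | {0}
        for p in parcs:
            assert set(np.unique(p.data)) <= allowed

    def test_subject_agreement_decreases_with_amplitude(self):
        kw = dict(
            grid_shape=(36,) * 3, r_in=10, r_out=14, n_parcels=8, n_subjects=3,
            jitter_deg=0.0, seed=21, subdivisions=2, recenter=False,
        )
        mean_dice = {}
        for a in (0.5, 2.0):
            spec = PhantomSpec(amplitude=a, **kw)
            template = make_template(spec)
            cohort, _ = make_cohort(spec, template)
            parcs = make_subject_parcellations(template, cohort)
            vals = []
            for i in range(len(parcs)):
                for j in range(i + 1, len(parcs)):
                    for label in template.label_ids:
                        vals.append(
                            dice(parcs[i].data, parcs[j].data, int(label), on_empty="nan")
                        )
            mean_dice[a] = np.nanmean(vals)
        assert mean_dice[2.0] < mean_dice[0.5]


class TestEvaluationData:
    def test_shapes_and_label_preservation(self, small_template, small_cohort):
        ed = make_evaluation_data(small_template, small_cohort[0])
        n_labels = len(small_template.label_ids)
        assert ed.vol_probs.probs.shape == (n_labels,) + small_template.shape
        assert ed.surf_truth.probs.shape == (
            n_labels,
            small_template.sphere.n_vertices,
        )
        assert set(np.unique(ed.vol_truth.labels)) <= set(small_template.label_ids) | {0}
        assert set(np.unique(ed.surf_parc.labels)) <= set(small_template.label_ids) | {0}


class TestOnDiskCohort:
    def test_round_trip_and_manifest_determinism(self, tmp_path):
        spec = PhantomSpec(
            grid_shape=(24,) * 3, r_in=6, r_out=9, n_parcels=4, n_subjects=2,
            amplitude=1.0, jitter_deg=2.0, seed=3, subdivisions=1,
        )
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_cohort(d1, spec)
        write_cohort(d2, spec)
        assert (d1 / "manifest.sha256").read_text() == (d2 / "manifest.sha256").read_text()
        manifest = json.loads((d1 / "manifest.json").read_text())
        assert len(manifest["subjects"]) == 2

        spec2, template, cohort, truth = load_cohort(d1)
        assert spec2.to_dict() == spec.to_dict()
        fresh_template = make_template(spec)
        fresh_cohort, _ = make_cohort(spec, fresh_template)
        for loaded, fresh in zip(cohort, fresh_cohort):
            np.testing.assert_allclose(
                loaded.vol_chain.steps[0].field.vectors,
                fresh.vol_chain.steps[0].field.vectors,
            )
            np.testing.assert_allclose(
                loaded.reg.sphere_coords, fresh.reg.sphere_coords, atol=1e-12
            )
        np.testing.assert_array_equal(template.parc.data, fresh_template.parc.data)
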