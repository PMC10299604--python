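"""Synthetic humerus generator: geometry, populations, fractures, cohorts."""

import numpy as np
import pytest

import phf3d as p


class TestGenerate:
    def test_watertight_and_positive_volume(self, humerus):
        tm = humerus.mesh.to_trimesh()
        assert tm.is_watertight
        assert tm.volume > 0

    def test_head_and_shaft_fits_round_trip(self, humerus):
        sphere = p.fit_sphere(humerus.mesh.vertices[humerus.cap_mask])
        assert abs(sphere.radius - 24.0) < 0.2
        assert np.linalg.norm(sphere.center - humerus.landmarks["head_center"]) < 0.2
        cyl = p.fit_cylinder_axis(
            humerus.mesh.vertices[humerus.shaft_mask], orientation_hint=[0, 0, 1]
        )
        assert abs(cyl.radius - 12.0) < 0.2
        assert abs(np.dot(cyl.direction, [0, 0, 1])) > np.cos(np.deg2rad(0.5))

    def test_neck_points_on_neck_plane(self, humerus):
        plane = humerus.frame.neck_plane
        d = plane.signed_distance(humerus.landmarks["neck_points"])
        assert np.abs(d).max() < 1e-9
        assert len(humerus.landmarks["neck_points"]) == 10

    def test_inclination_round_trip(self):
        h = p.generate_humerus(p.HumerusParams(inclination=135.0), resolution=36)
        measure = p.make_anatomy_measurer(h)
        assert measure(h.mesh).inclination == pytest.approx(135.0, abs=1.0)

    def test_deterministic(self):
        a = p.generate_humerus(seed=7, resolution=32)
        b = p.generate_humerus(seed=7, resolution=32)
        assert np.array_equal(a.mesh.vertices, b.mesh.vertices)
        assert np.array_equal(a.mesh.faces, b.mesh.faces)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            p.HumerusParams(inclination=100.0)
        with pytest.raises(ValueError):
            p.HumerusParams(shaft_length=50.0)

    def test_left_side_mirrored_watertight(self):
        h = p.generate_humerus(p.HumerusParams(side="left"), resolution=32)
        tm = h.mesh.to_trimesh()
        assert tm.is_watertight and tm.volume > 0
        # medial is -x for a left humerus
        assert h.landmarks["glenoid_hint"][0] < 0


class TestPopulation:
    def test_zero_size_errors(self):
        with pytest.raises(ValueError):
            p.sample_population(n=0)

    def test_zero_dispersion_identical(self):
        pop = p.sample_population(dispersions={"head_radius": 0.0}, n=5, seed=1, resolution=32)
        for h in pop[1:]:
            assert np.allclose(h.mesh.vertices, pop[0].mesh.vertices, atol=1e-12)

    def test_head_radius_sample_mean(self):
        pop = p.sample_population(
            dispersions={"head_radius": 2.0}, n=50, seed=13, resolution=32, linearize=False
        )
        radii = [p.fit_sphere(h.mesh.vertices[h.cap_mask]).radius for h in pop]
        sem = 2.0 / np.sqrt(50)
        assert abs(np.mean(radii) - 24.0) < 2 * sem + 0.05

    def test_fixed_topology(self):
        pop = p.sample_population(n=12, seed=3, resolution=32)
        for h in pop[1:]:
            assert np.array_equal(h.mesh.faces, pop[0].mesh.faces)


class TestSimulateFracture:
    def test_ground_truth_consistency(self, humerus):
        """Displacement composed with its stored reduction is the identity
        (before noise)."""
        spec = p.FractureSpec(
            pattern=("surgical_neck", "greater_tuberosity", "lesser_tuberosity"),
            displacements={
                "head": p.FragmentDisplacement((1, 2, 3), (0, 1, 0), 12.0),
                "greater_tuberosity": p.FragmentDisplacement((5, 0, -2), (1, 0, 0), 5.0),
            },
        )
        fx = p.simulate_fracture(humerus, spec)
        for label, frag in fx.fragments.items():
            back = frag.transformed(fx.ground_truth[label])
            assert np.abs(back.vertices - fx.anatomic_fragments[label].vertices).max() < 1e-9

    def test_fragments_partition_faces(self, humerus):
        spec = p.FractureSpec(
            pattern=("surgical_neck", "greater_tuberosity", "lesser_tuberosity")
        )
        fx = p.simulate_fracture(humerus, spec)
        assert set(fx.fragments) == {
            "shaft",
            "head",
            "greater_tuberosity",
            "lesser_tuberosity",
        }
        assert sum(f.n_faces for f in fx.fragments.values()) == humerus.mesh.n_faces

    def test_full_pipeline_varus(self, humerus, humerus_frame):
        spec = p.FractureSpec(
            displacements={
                "head": p.FragmentDisplacement(axis=tuple(humerus.frame.coro), angle_deg=30.0)
            }
        )
        fx = p.simulate_fracture(humerus, spec)
        rep = p.measure_displacement(
            fx.fragments["head"], fx.ground_truth["head"], humerus_frame
        )
        assert rep.rotation.coronal_angle == pytest.approx(30.0, abs=0.1)

    def test_translated_12mm_bin(self, humerus, humerus_frame):
        rng = np.random.default_rng(5)
        direction = rng.normal(size=3)
        direction = 12.0 * direction / np.linalg.norm(direction)
        spec = p.FractureSpec(
            pattern=("greater_tuberosity",),
            displacements={"greater_tuberosity": p.FragmentDisplacement(tuple(direction))},
        )
        fx = p.simulate_fracture(humerus, spec)
        rep = p.measure_displacement(
            fx.fragments["greater_tuberosity"],
            fx.ground_truth["greater_tuberosity"],
            humerus_frame,
        )
        assert rep.translation.norm_3d == pytest.approx(12.0, abs=1e-9)
        assert rep.neer.displaced is True
        assert rep.neer.translation_fine_bin == "10-15"

    def test_zero_displacement_one_part(self, humerus, humerus_frame):
        fx = p.simulate_fracture(
            humerus, p.FractureSpec(pattern=("surgical_neck", "greater_tuberosity"))
        )
        assessments = [
            p.measure_displacement(frag, fx.ground_truth[label], humerus_frame).neer
            for label, frag in fx.fragments.items()
            if label != "shaft"
        ]
        assert all(not a.displaced for a in assessments)
        assert p.count_neer_parts(assessments) == 1

    def test_noise_recorded_and_bounded(self, humerus):
        spec = p.FractureSpec(noise_sigma=0.2, seed=9)
        fx = p.simulate_fracture(humerus, spec)
        assert fx.seed == 9
        back = fx.fragments["head"].transformed(fx.ground_truth["head"])
        d = np.linalg.norm(back.vertices - fx.anatomic_fragments["head"].vertices, axis=1)
        assert 0.05 < d.std() < 0.6

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            p.FractureSpec(pattern=())


class TestCohort:
    def test_deterministic(self):
        a = p.sample_cohort(5, seed=11, resolution=32)
        b = p.sample_cohort(5, seed=11, resolution=32)
        for fa, fb in zip(a, b):
            assert fa.spec.pattern == fb.spec.pattern
            for label in fa.fragments:
                assert np.array_equal(
                    fa.fragments[label].vertices, fb.fragments[label].vertices
                )

    def test_small_rotation_cohort_all_neutral(self, humerus_frame):
        dist = p.CohortDistributions(
            head_coronal_mean=0.0,
            head_coronal_sd=1.0,
            head_sagittal_mean=0.0,
            head_sagittal_sd=1.0,
            head_axial_mean=0.0,
            head_axial_sd=1.0,
            head_translation_sd=0.5,
            gt_translation_sd=0.5,
            lt_translation_sd=0.5,
            tuberosity_rotation_sd=0.5,
        )
        cohort = p.sample_cohort(20, dist=dist, seed=17, resolution=32)
        for fx in cohort:
            for label, frag in fx.fragments.items():
                if label == "shaft":
                    continue
                rep = p.measure_displacement(frag, fx.ground_truth[label], fx.intact.frame)
                assert rep.neer.coronal_rotation_class == "<5"

    def test_pattern_frequencies_binomial(self):
        n = 120
        cohort = p.sample_cohort(n, seed=23, resolution=24)
        dist = p.CohortDistributions()
        freq = {
            "surgical_neck": 0,
            "greater_tuberosity": 0,
            "lesser_tuberosity": 0,
        }
        for fx in cohort:
            for name in fx.spec.pattern:
                freq[name] += 1
        # resampling of all-empty patterns slightly inflates frequencies;
        # stay within 3 sigma of the Bernoulli draw
        for name, prob in (
            ("surgical_neck", dist.p_surgical_neck),
            ("greater_tuberosity", dist.p_greater_tuberosity),
            ("lesser_tuberosity", dist.p_lesser_tuberosity),
        ):
            sigma = np.sqrt(prob * (1 - prob) / n)
            assert abs(freq[name] / n - prob) < 3 * sigma + 0.01, name
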