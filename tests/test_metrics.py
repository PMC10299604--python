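"""Displacement decomposition, per-plane angles, Neer logic, cohorts."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import phf3d as p
from phf3d.geometry import NotRigidError
from phf3d.metrics import (
    NeerAssessment,
    TRANSLATION_FINE_BINS,
    _rotation_class,
    _translation_bin,
    _translation_fine_bin,
    assess_neer,
    twist_angle_deg,
)
from conftest import brute_force_neer, quaternion_twist_deg, random_frame


def _fake_translation(norm, projections=None):
    projections = projections or {}
    v = np.array([norm, 0.0, 0.0])
    return p.TranslationReport(
        GP=np.zeros(3),
        GR=v,
        trans_vector=v,
        norm_3d=norm,
        proj_coronal=projections.get("coronal", 0.0),
        proj_sagittal=projections.get("sagittal", 0.0),
        proj_axial=projections.get("axial", 0.0),
    )


def _fake_rotation(coronal=0.0, sagittal=0.0, axial=0.0):
    return p.RotationReport(
        axis=np.array([0.0, 0.0, 1.0]),
        angle_3d=max(abs(coronal), abs(sagittal), abs(axial)),
        coronal_angle=coronal,
        sagittal_angle=sagittal,
        axial_angle=axial,
    )


class TestDecompose:
    def test_identity(self):
        t, axis, angle = p.decompose_transform(p.RigidTransform.identity())
        assert np.allclose(t, 0)
        assert angle == 0.0
        assert np.allclose(axis, (0, 0, 1))

    def test_constructed_case(self):
        M = p.RigidTransform.from_axis_angle((0, 0, 1), 45.0, translation=(10, 0, 0))
        t, axis, angle = p.decompose_transform(M)
        assert np.allclose(t, (10, 0, 0))
        assert np.allclose(axis, (0, 0, 1))
        assert angle == pytest.approx(45.0, abs=1e-9)

    def test_scaled_matrix_rejected(self):
        m = np.eye(4)
        m[:3, :3] *= 1.1
        with pytest.raises(NotRigidError):
            p.decompose_transform(m)

    def test_half_turn(self):
        M = p.RigidTransform.from_axis_angle((1, 1, 0), 180.0)
        _, axis, angle = p.decompose_transform(M)
        assert angle == pytest.approx(180.0, abs=1e-6)
        assert abs(abs(np.dot(axis, np.array([1, 1, 0]) / np.sqrt(2))) - 1) < 1e-6

    def test_round_trip_random(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = rng.uniform(1e-3, 179.9)
            trans = rng.normal(0, 20, 3)
            M = p.RigidTransform.from_axis_angle(axis, angle, translation=trans)
            t, a, ang = p.decompose_transform(M)
            assert np.allclose(t, trans, atol=1e-9)
            assert ang == pytest.approx(angle, abs=1e-9)
            assert abs(abs(np.dot(a, axis)) - 1) < 1e-9


class TestSwingTwist:
    def test_agrees_with_quaternion_oracle(self):
        rng = np.random.default_rng(32)
        for _ in range(300):
            R = Rotation.random(random_state=int(rng.integers(1 << 31))).as_matrix()
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            assert twist_angle_deg(R, axis) == pytest.approx(
                quaternion_twist_deg(R, axis), abs=1e-6
            )

    def test_twist_of_inverse_negates(self):
        R = Rotation.from_rotvec([0.3, -0.2, 0.8]).as_matrix()
        a = np.array([0.0, 0.0, 1.0])
        assert twist_angle_deg(R.T, a) == pytest.approx(-twist_angle_deg(R, a), abs=1e-12)

    def test_twist_never_exceeds_total_angle(self):
        rng = np.random.default_rng(33)
        for _ in range(500):
            rv = rng.normal(size=3)
            rv = rv / np.linalg.norm(rv) * np.deg2rad(rng.uniform(0, 179))
            R = Rotation.from_rotvec(rv).as_matrix()
            total = np.rad2deg(np.linalg.norm(rv))
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            assert abs(twist_angle_deg(R, axis)) <= total + 1e-9


class TestRotationReport:
    def test_pure_varus_round_trip(self, humerus_frame):
        """A 33-degree varus head displacement reports coronal 33, other
        planes zero."""
        frame = humerus_frame
        disp = p.RigidTransform.from_axis_angle(frame.coro, 33.0)
        M = disp.inverse()  # reduction transform
        rot = p.rotation_report(M, frame)
        assert rot.coronal_angle == pytest.approx(33.0, abs=1e-9)
        assert rot.sagittal_angle == pytest.approx(0.0, abs=1e-9)
        assert rot.axial_angle == pytest.approx(0.0, abs=1e-9)
        assert rot.angle_3d == pytest.approx(33.0, abs=1e-9)

    def test_identity_all_zero(self, humerus_frame):
        rot = p.rotation_report(p.RigidTransform.identity(), humerus_frame)
        assert rot.angle_3d == 0.0
        assert (rot.coronal_angle, rot.sagittal_angle, rot.axial_angle) == (0, 0, 0)

    def test_composed_twists_match_oracle(self, humerus_frame):
        frame = humerus_frame
        disp = p.RigidTransform.from_axis_angle(frame.coro, 20.0).compose(
            p.RigidTransform.from_axis_angle(frame.axial, 20.0)
        )
        rot = p.rotation_report(disp.inverse(), frame)
        R_disp = disp.rotation
        assert rot.coronal_angle == pytest.approx(
            quaternion_twist_deg(R_disp, frame.coro), abs=1e-6
        )
        assert rot.axial_angle == pytest.approx(
            quaternion_twist_deg(R_disp, frame.axial), abs=1e-6
        )

    def test_plane_angle_bounded_by_3d_angle(self, humerus_frame):
        rng = np.random.default_rng(34)
        for _ in range(300):
            M = p.RigidTransform.from_axis_angle(
                rng.normal(size=3), rng.uniform(0, 179), translation=rng.normal(0, 5, 3)
            )
            rot = p.rotation_report(M, humerus_frame)
            for a in rot.plane_angles().values():
                assert abs(a) <= rot.angle_3d + 1e-6


class TestTranslationReport:
    def test_pythagorean_case(self, humerus):
        frame = p.ReferenceFrame(
            origin_O=(0, 0, 0),
            axial=(0, 0, 1),
            anatneck=(1, 0, 0),
            coro=(0, 1, 0),
            sag=(-1, 0, 0),
        )
        M = p.RigidTransform.from_rotation_translation(np.eye(3), (-3, -4, -12))
        rep = p.translation_report(humerus.mesh, M, frame)
        assert rep.norm_3d == pytest.approx(13.0, abs=1e-9)
        # plane with normal sag = (-1,0,0): drops the x component
        assert rep.proj_sagittal == pytest.approx(np.sqrt(16 + 144), abs=1e-9)

    def test_identity_zero(self, humerus, humerus_frame):
        rep = p.translation_report(humerus.mesh, p.RigidTransform.identity(), humerus_frame)
        assert rep.norm_3d == 0.0
        assert rep.proj_coronal == rep.proj_sagittal == rep.proj_axial == 0.0

    def test_projection_inequality_random(self, humerus):
        rng = np.random.default_rng(35)
        for _ in range(200):
            frame = random_frame(rng)
            M = p.RigidTransform.from_axis_angle(
                rng.normal(size=3), rng.uniform(0, 60), translation=rng.normal(0, 10, 3)
            )
            rep = p.translation_report(humerus.mesh, M, frame)
            for proj in rep.projections().values():
                assert proj <= rep.norm_3d + 1e-12


class TestNeer:
    @pytest.mark.parametrize(
        "norm,coronal,displaced,tbin",
        [
            (12.0, 30.0, True, ">=10"),
            (9.9, 30.0, False, "5-9.9"),
            (0.0, 45.0, True, "<5"),
            (10.0, 0.0, True, ">=10"),
            (4.99, 44.99, False, "<5"),
        ],
    )
    def test_threshold_cases(self, norm, coronal, displaced, tbin):
        a = assess_neer(_fake_translation(norm), _fake_rotation(coronal=coronal))
        assert a.displaced is displaced
        assert a.translation_bin == tbin

    def test_valgus_class(self):
        a = assess_neer(_fake_translation(0.0), _fake_rotation(coronal=-50.0))
        assert a.coronal_rotation_class == "valgus>45"
        assert a.displaced

    def test_matches_brute_force_on_grid(self):
        """Classification equals literal threshold evaluation on a dense
        grid including every boundary value."""
        values = np.concatenate(
            [np.linspace(0, 60, 18), [4.999, 5.0, 9.9, 9.95, 10.0, 44.999, 45.0]]
        )
        rng = np.random.default_rng(36)
        count = 0
        for norm in values:
            for cor in rng.choice(np.concatenate([values, -values]), 5, replace=False):
                for sag in rng.choice(np.concatenate([values, -values]), 2, replace=False):
                    ax = float(rng.choice(np.concatenate([values, -values])))
                    a = assess_neer(
                        _fake_translation(norm),
                        _fake_rotation(coronal=cor, sagittal=sag, axial=ax),
                    )
                    assert a.displaced == brute_force_neer(norm, cor, sag, ax)
                    count += 1
        assert count >= 200

    def test_monotonicity(self):
        rng = np.random.default_rng(37)
        for _ in range(300):
            norm = rng.uniform(0, 20)
            angles = rng.uniform(-60, 60, 3)
            base = assess_neer(
                _fake_translation(norm), _fake_rotation(*angles)
            ).displaced
            grown = assess_neer(
                _fake_translation(norm + rng.uniform(0, 10)),
                _fake_rotation(*(angles * rng.uniform(1.0, 1.5))),
            ).displaced
            assert not (base and not grown)

    def test_bins_partition(self):
        for value in np.linspace(0, 30, 601):
            assert sum(_translation_bin(value) == b for b in ("<5", "5-9.9", ">=10")) == 1
            assert sum(_translation_fine_bin(value) == b for b in TRANSLATION_FINE_BINS) == 1
        assert _translation_fine_bin(15.0) == "10-15"
        assert _translation_fine_bin(15.0001) == ">15"
        assert _translation_bin(9.95) == "5-9.9"  # no display rounding-up

    def test_rotation_class_boundaries(self):
        assert _rotation_class(45.0, "coronal") == "varus>45"
        assert _rotation_class(44.999, "coronal") == "varus 5-45"
        assert _rotation_class(5.0, "coronal") == "varus 5-45"
        assert _rotation_class(4.999, "coronal") == "<5"
        assert _rotation_class(-45.0, "axial") == "anteversion>45"
        assert _rotation_class(50.0, "sagittal") == "posterior_tilt>45"


class TestPartCount:
    def _assessment(self, displaced):
        return NeerAssessment(
            displaced=displaced,
            translation_bin="<5",
            translation_fine_bin="<5",
            coronal_rotation_class="<5",
            sagittal_rotation_class="<5",
            axial_rotation_class="<5",
        )

    def test_matches_enumeration_oracle(self):
        """Part count equals 1 + displaced flags (capped at 4) over every
        flag subset of the four classic fragments."""
        import itertools

        for flags in itertools.product([False, True], repeat=4):
            expected = min(1 + sum(flags), 4)
            got = p.count_neer_parts([self._assessment(f) for f in flags])
            assert got == expected

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            p.count_neer_parts([])


@pytest.fixture(scope="module")
def cohort_reports():
    cohort = p.sample_cohort(77, seed=42, resolution=32)
    reports = []
    for fx in cohort:
        for label, frag in fx.fragments.items():
            if label == "shaft":
                continue
            reports.append(
                p.measure_displacement(frag, fx.ground_truth[label], fx.intact.frame)
            )
    return reports


class TestCohortSummary:
    def test_marginals_conserved(self, cohort_reports):
        reports = cohort_reports[:77]
        summary = p.summarize_cohort(reports)
        assert summary.n == 77
        assert summary.crosstab_axial.loc["Total", "Total"] == 77
        assert summary.crosstab_axial["Total"].iloc[:-1].sum() == 77
        assert summary.crosstab_axial.loc["Total"].iloc[:-1].sum() == 77
        assert summary.crosstab_sagittal.loc["Total", "Total"] == 77

    def test_identity_cohort(self, humerus, humerus_frame):
        reports = [
            p.measure_displacement(humerus.mesh, p.RigidTransform.identity(), humerus_frame)
            for _ in range(5)
        ]
        summary = p.summarize_cohort(reports)
        assert summary.coronal_class_counts["<5"] == 5
        assert summary.translation_fine_counts["<5"] == 5
        assert summary.underestimation["mean_diff_mm"].abs().max() == 0.0
        assert summary.displaced_fraction == 0.0

    def test_underestimation_positive_with_ci(self, cohort_reports):
        """2D projections systematically shorten 3D translations: mean
        difference positive with the 95% CI excluding zero."""
        moved = [r for r in cohort_reports if r.translation.norm_3d > 1e-9][:77]
        summary = p.summarize_cohort(moved)
        for plane in ("coronal", "sagittal", "axial"):
            row = summary.underestimation.loc[plane]
            assert row["mean_diff_mm"] > 0
            assert row["ci95_low"] > 0
            assert row["p_value"] < 0.05

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            p.summarize_cohort([])
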