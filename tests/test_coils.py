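import numpy as np
import pytest

from gradsafe.coils import (
    MU0,
    CoilModel,
    ComplianceVolume,
    DriveSpec,
    Loop,
    SingularEvaluationError,
    _circle,
    biot_savart_B,
    compliance_peak_dBdt,
    gradient_efficiency,
    make_axis_coil,
    make_ideal_field,
    maxwell_pair_efficiency,
    vector_potential_A,
)

ORIGIN = np.array([[0.0, 0.0, 0.0]])


def single_loop(radius=0.3, z=0.0, current=1.0, n=720):
    return CoilModel(
        loops=[Loop(_circle(radius, z, n), current)],
        axis="Z",
        inner_diameter=2 * radius,
        length=1.2,
        name="loop",
    )


class TestBiotSavart:
    def test_loop_center_closed_form(self):
        # mu0 I / 2R for a unit-current circular loop
        b = biot_savart_B(single_loop(), ORIGIN).values[0]
        assert b[2] == pytest.approx(MU0 / (2 * 0.3), rel=1e-4)
        assert abs(b[0]) < 1e-12 and abs(b[1]) < 1e-12

    def test_current_linearity(self):
        c1 = single_loop(current=1.0)
        c2 = single_loop(current=2.0)
        p = np.array([[0.05, 0.07, 0.1]])
        np.testing.assert_allclose(
            biot_savart_B(c2, p).values, 2 * biot_savart_B(c1, p).values, rtol=1e-13
        )

    def test_opposed_coaxial_pair_cancels_on_midplane_axis(self):
        coil = CoilModel(
            loops=[Loop(_circle(0.3, 0.2, 360), 1.0), Loop(_circle(0.3, -0.2, 360), -1.0)],
            axis="Z",
            inner_diameter=0.6,
            length=0.4,
            name="pair",
        )
        b = biot_savart_B(coil, ORIGIN).values[0]
        assert np.linalg.norm(b) < 1e-15

    def test_far_field_dipole_decay(self):
        coil = single_loop(n=360)
        rs = 3.0 * 2 ** np.arange(0, 4)  # a decade of distances
        pts = np.column_stack([np.zeros_like(rs), np.zeros_like(rs), rs])
        mags = np.linalg.norm(biot_savart_B(coil, pts).values, axis=1)
        ratios = mags[:-1] / mags[1:]
        np.testing.assert_allclose(ratios, 8.0, rtol=0.02)  # 1/r^3 halving steps

    def test_singular_point_rejected_with_loop_index(self):
        coil = single_loop()
        on_wire = np.array([[0.3, 0.0, 0.0]])
        with pytest.raises(SingularEvaluationError, match="loop 0"):
            biot_savart_B(coil, on_wire)


class TestVectorPotential:
    def test_curl_matches_B(self, maxwell_z):
        h = 1e-4
        p = np.array([0.03, -0.02, 0.05])

        def A(pt):
            return vector_potential_A(maxwell_z, pt[None, :]).values[0]

        e = np.eye(3) * h
        dA = [(A(p + e[k]) - A(p - e[k])) / (2 * h) for k in range(3)]
        curl = np.array(
            [dA[1][2] - dA[2][1], dA[2][0] - dA[0][2], dA[0][1] - dA[1][0]]
        )
        b = biot_savart_B(maxwell_z, p[None, :]).values[0]
        np.testing.assert_allclose(curl, b, rtol=5e-3)

    def test_negated_current_negates_A(self):
        c1, c2 = single_loop(current=1.0), single_loop(current=-1.0)
        p = np.array([[0.1, 0.05, 0.02]])
        np.testing.assert_allclose(
            vector_potential_A(c2, p).values, -vector_potential_A(c1, p).values, rtol=1e-13
        )

    def test_translation_invariance(self):
        c1 = single_loop()
        shift = np.array([0.3, -0.2, 0.5])
        c2 = CoilModel(
            loops=[Loop(c1.loops[0].vertices + shift, 1.0)],
            axis="Z",
            inner_diameter=0.6,
            length=1.2,
        )
        p = np.array([[0.04, 0.06, -0.03]])
        np.testing.assert_allclose(
            vector_potential_A(c1, p).values,
            vector_potential_A(c2, p + shift).values,
            rtol=1e-12,
        )


class TestAxisCoils:
    def test_maxwell_pair_efficiency_closed_form(self, maxwell_z):
        R = 0.35
        d = np.sqrt(3) / 2 * R
        expected = maxwell_pair_efficiency(R, d)
        assert gradient_efficiency(maxwell_z) == pytest.approx(expected, rel=1e-3)

    def test_closed_form_reference_value(self):
        # 3 mu0 I R^2 d / (R^2+d^2)^(5/2) at R=0.35, d=0.303
        assert maxwell_pair_efficiency(0.35, 0.303) == pytest.approx(6.66e-6, rel=0.02)

    def test_primary_gradient_direction(self, maxwell_z, golay_x):
        h = 1e-3
        for coil, k in ((maxwell_z, 2), (golay_x, 0)):
            pts = np.zeros((2, 3))
            pts[0, k], pts[1, k] = h, -h
            bz = biot_savart_B(coil, pts).values[:, 2]
            g_axis = (bz[0] - bz[1]) / (2 * h)
            assert abs(g_axis) > 1e-7
            # other derivatives vanish at isocenter
            for j in range(3):
                if j == k:
                    continue
                q = np.zeros((2, 3))
                q[0, j], q[1, j] = h, -h
                bzq = biot_savart_B(coil, q).values[:, 2]
                assert abs((bzq[0] - bzq[1]) / (2 * h)) < 1e-9 * abs(g_axis) / 1e-3

    def test_y_coil_is_rotated_x_coil(self, golay_x):
        golay_y = make_axis_coil("Y", 0.70, 1.40)
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        p = np.array([[0.04, 0.03, 0.06], [-0.02, 0.08, -0.1]])
        bx = biot_savart_B(golay_x, p).values
        by = biot_savart_B(golay_y, (rot @ p.T).T).values
        np.testing.assert_allclose((rot @ bx.T).T, by, rtol=1e-10, atol=1e-16)

    def test_shielded_z_reduces_external_field(self, maxwell_z):
        shielded = make_axis_coil("Z", 0.70, 1.40, shielded=True)
        theta = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        pts = np.column_stack(
            [0.70 * np.cos(theta), 0.70 * np.sin(theta), np.full(16, 0.3)]
        )
        b_s = np.linalg.norm(biot_savart_B(shielded, pts).values, axis=1)
        b_u = np.linalg.norm(biot_savart_B(maxwell_z, pts).values, axis=1)
        assert (b_s < b_u).all()

    def test_shield_radius_must_exceed_primary(self):
        with pytest.raises(ValueError, match="shield radius"):
            make_axis_coil("Z", 0.70, 1.40, shielded=True, shield_radius_factor=0.9)

    def test_realistic_range_enforced(self):
        with pytest.raises(ValueError, match="realistic"):
            make_axis_coil("Z", inner_diameter=0.30, length=1.40)
        coil = make_axis_coil("Z", inner_diameter=0.30, length=1.40, allow_unrealistic=True)
        assert coil.inner_diameter == 0.30

    def test_minimum_segments_enforced(self):
        with pytest.raises(ValueError, match="72"):
            make_axis_coil("Z", 0.70, 1.40, n_segments=32)


class TestGradientEfficiency:
    def test_current_scaling(self, maxwell_z):
        scaled = maxwell_z.scaled(3.0)
        assert gradient_efficiency(scaled) == pytest.approx(
            3 * gradient_efficiency(maxwell_z), rel=1e-12
        )

    def test_ideal_gradient_exact(self):
        src = make_ideal_field("uniform_gradient", 0.0123)
        assert gradient_efficiency(src) == 0.0123

    def test_degenerate_coil_rejected(self, maxwell_z):
        dead = maxwell_z.scaled(0.0)
        with pytest.raises(ValueError, match="degenerate"):
            gradient_efficiency(dead)


class TestIdealFields:
    def test_uniform_b_curl_exact(self):
        src = make_ideal_field("uniform_B", 2.5)
        h = 1e-5
        p = np.array([0.1, -0.2, 0.3])
        e = np.eye(3) * h

        def A(pt):
            return src.A(pt[None, :]).values[0]

        dA = [(A(p + e[k]) - A(p - e[k])) / (2 * h) for k in range(3)]
        curl = np.array([dA[1][2] - dA[2][1], dA[2][0] - dA[0][2], dA[0][1] - dA[1][0]])
        np.testing.assert_allclose(curl, [0, 0, 2.5], atol=1e-9)

    def test_uniform_gradient_zero_A_at_zero_G(self):
        src = make_ideal_field("uniform_gradient", 0.0)
        pts = np.random.default_rng(0).normal(size=(5, 3))
        assert (src.A(pts).values == 0).all()

    def test_rim_E_oracle_value(self):
        # uniform B at 100 T/s over r=0.2: analytic rim E = (r/2) dB/dt
        assert 0.2 / 2 * 100.0 == pytest.approx(10.0)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            make_ideal_field("spiral", 1.0)


class TestCompliancePeakDBdt:
    def test_ideal_gradient_half_meter(self):
        src = make_ideal_field("uniform_gradient", 1.0)
        cv = ComplianceVolume(radius=0.20, z_extent=(-0.5, 0.5))
        peak = compliance_peak_dBdt(src, DriveSpec(slew=100.0), cv)
        assert peak == pytest.approx(100.0 * 0.5, rel=1e-12)

    def test_uniform_b_returns_rate(self):
        src = make_ideal_field("uniform_B", 1.0, rate=100.0)
        cv = ComplianceVolume(radius=0.15, z_extent=(-0.2, 0.2))
        assert compliance_peak_dBdt(src, DriveSpec(slew=42.0), cv) == 100.0

    def test_slew_linearity(self, maxwell_z):
        cv = ComplianceVolume(z_extent=(-0.4, 0.4))
        p1 = compliance_peak_dBdt(maxwell_z, DriveSpec(slew=100.0), cv)
        p2 = compliance_peak_dBdt(maxwell_z, DriveSpec(slew=200.0), cv)
        assert p2 == pytest.approx(2 * p1, rel=1e-12)

    def test_current_amplitude_cancels(self, maxwell_z):
        cv = ComplianceVolume(z_extent=(-0.4, 0.4))
        p1 = compliance_peak_dBdt(maxwell_z, DriveSpec(slew=100.0), cv)
        p2 = compliance_peak_dBdt(maxwell_z.scaled(7.0), DriveSpec(slew=100.0), cv)
        assert p2 == pytest.approx(p1, rel=1e-10)

    def test_axis_combination_rss_split(self, maxwell_z):
        cv = ComplianceVolume(z_extent=(-0.4, 0.4))
        single = compliance_peak_dBdt([maxwell_z], DriveSpec(slew=100.0), cv)
        assert single == pytest.approx(
            compliance_peak_dBdt(maxwell_z, DriveSpec(slew=100.0), cv)
        )


class TestValidation:
    def test_compliance_volume_invariants(self):
        with pytest.raises(ValueError):
            ComplianceVolume(radius=-0.1)
        with pytest.raises(ValueError):
            ComplianceVolume(z_extent=(0.5, -0.5))
        with pytest.raises(ValueError):
            ComplianceVolume(spacing=0.05)  # > 1 cm

    def test_drive_spec_invariants(self):
        with pytest.raises(ValueError):
            DriveSpec(slew=-1.0)
        with pytest.raises(ValueError):
            DriveSpec(frequency=0.0)
        assert DriveSpec(axis_combination=("X", "Y", "Z")).per_axis_slew() == pytest.approx(
            100.0 / np.sqrt(3)
        )

    def test_loop_needs_three_vertices(self):
        with pytest.raises(ValueError):
            Loop(np.zeros((2, 3)), 1.0)

    def test_coil_axis_validation(self):
        with pytest.raises(ValueError):
            CoilModel(loops=[Loop(_circle(0.3, 0, 72), 1.0)], axis="Q", inner_diameter=0.6, length=1.2)
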