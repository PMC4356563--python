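"""Forward-model physics: series solution, Sarvas field, leadfield assembly."""

import numpy as np
import pytest

from emegscan.errors import ConfigurationError, GeometryError
from emegscan.forward import (
    ConductivityProfile,
    HeadModelSpec,
    build_leadfield,
    eeg_sphere_potential,
    meg_sphere_field,
)
from emegscan.phantom import SensorArray, SourceSpace

MU0_OVER_4PI = 1e-7


def random_electrodes(n, radius, seed=0):
    rng = np.random.default_rng(seed)
    e = rng.standard_normal((n, 3))
    e /= np.linalg.norm(e, axis=1, keepdims=True)
    return e * radius


def homogeneous_sphere_potential(r0_mm, m_nAm, elec_mm, radius_mm, sigma):
    """Independent closed-form surface potential of a homogeneous sphere.

    Derived by summing the interior Legendre expansion in closed form
    (infinite-medium term plus the boundary correction); average-referenced.
    Units: SI internally, returns µV for nAm moments.
    """
    r0 = np.asarray(r0_mm, float) * 1e-3
    m = np.asarray(m_nAm, float) * 1e-9
    R = radius_mm * 1e-3
    b = np.linalg.norm(r0)
    rhat0 = r0 / b
    t = b / R
    out = []
    for e in np.asarray(elec_mm, float) * 1e-3:
        ehat = e / np.linalg.norm(e)
        c = float(ehat @ rhat0)
        d = e - r0
        dn = np.linalg.norm(d)
        D = dn / R
        m_r = m @ rhat0
        m_t = m @ (ehat - c * rhat0)
        v = 2 * (m @ d) / dn**3 + (m_r * (1 / D - 1)) / (b * R)
        if abs(1 - c**2) > 1e-14:
            v += m_t * ((t - c) / D + c) / ((1 - c**2) * b * R)
        out.append(v / (4 * np.pi * sigma))
    out = np.asarray(out) * 1e6
    return out - out.mean()


def sarvas_field_sympy(r0_mm, q_nAm, pos_mm):
    """Independent symbolic re-derivation of the spherical-conductor field.

    F is written symbolically and its gradient obtained by differentiation
    rather than from the hand-coded closed form.
    """
    import sympy as sy

    x, y, z = sy.symbols("x y z", real=True)
    r = sy.Matrix([x, y, z])
    r0 = sy.Matrix(np.asarray(r0_mm, float) * 1e-3)
    q = sy.Matrix(np.asarray(q_nAm, float) * 1e-9)
    a = r - r0
    a_n = sy.sqrt(a.dot(a))
    r_n = sy.sqrt(r.dot(r))
    F = a_n * (r_n * a_n + r_n**2 - r0.dot(r))
    gradF = sy.Matrix([sy.diff(F, v) for v in (x, y, z)])
    qxr0 = q.cross(r0)
    B = (MU0_OVER_4PI / F**2) * (F * qxr0 - qxr0.dot(r) * gradF)
    out = []
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DeprecationWarning)  # mpmath bitcount noise
        for p in np.asarray(pos_mm, float) * 1e-3:
            subs = {x: p[0], y: p[1], z: p[2]}
            out.append([float(B[i].evalf(subs=subs)) for i in range(3)])
    return np.asarray(out) * 1e15  # fT


class TestEEGSpherePotential:
    def test_matches_homogeneous_closed_form(self):
        """With equal shell conductivities the 4-shell series must collapse to
        the homogeneous-sphere closed form."""
        sigma = 0.33
        head = HeadModelSpec(conductivity=ConductivityProfile(sigma, sigma, sigma, sigma))
        elec = random_electrodes(40, head.scalp_radius, seed=3)
        rng = np.random.default_rng(4)
        for _ in range(5):
            r0 = rng.standard_normal(3)
            r0 *= rng.uniform(10, 75) / np.linalg.norm(r0)
            m = rng.standard_normal(3) * 20
            got = eeg_sphere_potential(r0, m, elec, head)
            want = homogeneous_sphere_potential(r0, m, elec, head.scalp_radius, sigma)
            assert np.max(np.abs(got - want)) <= 1e-6 * np.max(np.abs(want))

    def test_average_reference(self, head):
        elec = random_electrodes(30, head.scalp_radius)
        v = eeg_sphere_potential([20, -30, 40], [5, -3, 7], elec, head)
        assert abs(v.sum()) < 1e-9 * np.linalg.norm(v)

    def test_skull_conductivity_attenuates_eeg_only(self, head):
        elec = random_electrodes(30, head.scalp_radius)
        sens = random_electrodes(30, head.scalp_radius + 25, seed=7)
        ori = sens / np.linalg.norm(sens, axis=1, keepdims=True)
        r0, m = np.array([0.0, 0.0, 70.0]), np.array([30.0, 0.0, 0.0])
        v_hi = eeg_sphere_potential(r0, m, elec, head)
        low = head.with_conductivity(head.conductivity.with_skull(head.conductivity.sigma_skull / 2))
        v_lo = eeg_sphere_potential(r0, m, elec, low)
        assert np.abs(v_hi - v_lo).max() > 0
        b_hi = meg_sphere_field(r0, m, sens, ori, head)
        b_lo = meg_sphere_field(r0, m, sens, ori, low)
        np.testing.assert_array_equal(b_hi, b_lo)

    def test_attenuation_monotone_in_skull_conductivity(self, head):
        elec = random_electrodes(60, head.scalp_radius)
        r0, m = np.array([0.0, 0.0, 70.0]), np.array([30.0, 0.0, 0.0])
        tenth = head.with_conductivity(head.conductivity.with_skull(head.conductivity.sigma_skull / 10))
        v = eeg_sphere_potential(r0, m, elec, head)
        v10 = eeg_sphere_potential(r0, m, elec, tenth)
        assert np.abs(v10).max() < np.abs(v).max()

    def test_geometry_errors(self, head):
        elec = random_electrodes(10, head.scalp_radius)
        with pytest.raises(GeometryError):
            eeg_sphere_potential([0, 0, 85.0], [1, 0, 0], elec, head)
        with pytest.raises(GeometryError):
            eeg_sphere_potential([0, 0, 40.0], [1, 0, 0], elec * 0.9, head)
        with pytest.raises(ConfigurationError):
            HeadModelSpec(shell_radii=(79, 82, 82, 92))


class TestMEGSphereField:
    def test_radial_dipole_silent(self, head):
        sens = random_electrodes(50, head.scalp_radius + 20, seed=2)
        ori = sens / np.linalg.norm(sens, axis=1, keepdims=True)
        r0 = np.array([25.0, -35.0, 40.0])
        b = meg_sphere_field(r0, 4.0 * r0 / np.linalg.norm(r0), sens, ori, head)
        tangential = meg_sphere_field(r0, [10.0, 10.0, 0.0], sens, ori, head)
        assert np.abs(b).max() < 1e-12 * np.abs(tangential).max()

    def test_dipole_at_origin_silent(self, head):
        sens = random_electrodes(10, head.scalp_radius + 20)
        ori = sens / np.linalg.norm(sens, axis=1, keepdims=True)
        b = meg_sphere_field([0, 0, 0], [10, 5, -3], sens, ori, head)
        np.testing.assert_array_equal(b, 0)

    def test_matches_symbolic_rederivation(self, head):
        sens = random_electrodes(5, head.scalp_radius + 25, seed=9)
        ori = sens / np.linalg.norm(sens, axis=1, keepdims=True)
        r0, q = np.array([20.0, -30.0, 40.0]), np.array([5.0, -3.0, 7.0])
        got = meg_sphere_field(r0, q, sens, ori, head)
        want = np.einsum("ij,ij->i", sarvas_field_sympy(r0, q, sens), ori)
        assert np.max(np.abs(got - want)) <= 1e-9 * np.max(np.abs(want))

    def test_radial_component_equals_primary_field(self, head):
        """Volume currents contribute no radial field over a spherical
        conductor, so B·r̂ must equal the infinite-medium dipole term."""
        sens = random_electrodes(20, head.scalp_radius + 30, seed=5)
        rhat = sens / np.linalg.norm(sens, axis=1, keepdims=True)
        r0, q = np.array([-30.0, 10.0, 35.0]), np.array([8.0, 2.0, -5.0])
        got = meg_sphere_field(r0, q, sens, rhat, head)
        a = (sens - r0) * 1e-3
        an = np.linalg.norm(a, axis=1)
        expected = (
            MU0_OVER_4PI
            * (np.cross(r0 * 1e-3, q * 1e-9) @ rhat.T)
            / an**3
            * 1e15
        )
        assert np.max(np.abs(got - expected)) <= 1e-9 * np.max(np.abs(expected))

    def test_sensor_inside_scalp_rejected(self, head):
        sens = random_electrodes(5, head.scalp_radius - 5)
        ori = sens / np.linalg.norm(sens, axis=1, keepdims=True)
        with pytest.raises(GeometryError):
            meg_sphere_field([0, 0, 40.0], [1, 0, 0], sens, ori, head)


class TestLeadfield:
    @pytest.fixture()
    def small_space(self, head):
        rng = np.random.default_rng(8)
        pos = rng.standard_normal((12, 3))
        pos = pos / np.linalg.norm(pos, axis=1, keepdims=True) * rng.uniform(30, 70, (12, 1))
        normals = rng.standard_normal((12, 3))
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        return SourceSpace(pos, normals, spacing=10.0)

    def test_columns_match_single_dipole_ops(self, head, small_space):
        elec = random_electrodes(20, head.scalp_radius)
        eeg = SensorArray("eeg", elec)
        lf = build_leadfield(small_space, eeg, head)
        for i in (0, 5, 11):
            for k in range(3):
                unit = np.eye(3)[k]
                v = eeg_sphere_potential(small_space.positions[i], unit, elec, head)
                np.testing.assert_allclose(lf.gain[:, 3 * i + k], v, rtol=0, atol=1e-9)

    def test_linearity(self, head, small_space):
        elec = random_electrodes(20, head.scalp_radius)
        lf = build_leadfield(small_space, SensorArray("eeg", elec), head)
        m = np.zeros((12, 3))
        m[4] = [3.0, -1.0, 2.0]
        np.testing.assert_allclose(lf.predict(2 * m), 2 * lf.predict(m), rtol=1e-12)

    def test_meg_gain_conductivity_independent(self, head, small_space):
        sens = random_electrodes(25, head.scalp_radius + 20, seed=4)
        ori = sens / np.linalg.norm(sens, axis=1, keepdims=True)
        meg = SensorArray("meg", sens, orientations=ori)
        other = head.with_conductivity(ConductivityProfile(0.2, 1.0, 0.01, 0.5))
        lf_a = build_leadfield(small_space, meg, head)
        lf_b = build_leadfield(small_space, meg, other)
        assert np.max(np.abs(lf_a.gain - lf_b.gain)) == 0.0

    def test_deeper_dipole_weaker_in_both_modalities(self, head):
        """Same tangential moment at 30 mm vs 10 mm below the brain surface:
        the deeper source produces smaller peak EEG and MEG amplitudes."""
        elec = random_electrodes(60, head.scalp_radius, seed=6)
        sens = random_electrodes(60, head.scalp_radius + 20, seed=7)
        ori = sens / np.linalg.norm(sens, axis=1, keepdims=True)
        m = np.array([20.0, 0.0, 0.0])
        shallow = np.array([0.0, 0.0, head.brain_radius - 10.0])
        deep = np.array([0.0, 0.0, head.brain_radius - 30.0])
        assert np.abs(eeg_sphere_potential(deep, m, elec, head)).max() < np.abs(
            eeg_sphere_potential(shallow, m, elec, head)
        ).max()
        assert np.abs(meg_sphere_field(deep, m, sens, ori, head)).max() < np.abs(
            meg_sphere_field(shallow, m, sens, ori, head)
        ).max()

    def test_source_outside_shell_reports_index(self, head, small_space):
        bad = small_space.positions.copy()
        bad[3] = [0, 0, 100.0]
        space = SourceSpace(bad, small_space.normals, 10.0)
        elec = random_electrodes(10, head.scalp_radius)
        with pytest.raises(GeometryError, match="3"):
            build_leadfield(space, SensorArray("eeg", elec), head)
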