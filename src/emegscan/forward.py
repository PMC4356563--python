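"""Analytic spherical-head EEG and MEG forward solutions.

The head is modeled as four concentric spherical shells (brain, CSF, skull,
scalp).  EEG scalp potentials come from the exact Legendre-series solution of
the concentric-multishell volume conductor: for each harmonic order ``n`` the
radial interface conditions (continuity of potential and of radial current
density, insulating exterior) are solved as a small linear system, giving a
geometry coefficient ``c_n`` that multiplies the standard interior dipole
expansion.  MEG fields use the closed-form solution of a current dipole in a
spherically symmetric conductor (Sarvas), which is independent of the
conductivity profile and exactly silent for radial dipoles.

Units at the interface: positions in mm, dipole moments in nAm, EEG in µV
(average reference), MEG in fT along each sensor's orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, GeometryError

_MU0_OVER_4PI = 1e-7  # T·m/A

#: series truncation: stop once the next term falls below this relative size
SERIES_RTOL = 1e-10
SERIES_MAX_TERMS = 200


@dataclass(frozen=True)
class ConductivityProfile:
    """Per-shell conductivities in S/m, innermost first."""

    sigma_brain: float = 0.33
    sigma_csf: float = 1.79
    sigma_skull: float = 0.0024
    sigma_scalp: float = 0.43

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if value <= 0:
                raise ConfigurationError(f"conductivity {name} must be > 0, got {value}")

    def as_dict(self) -> dict:
        return {
            "sigma_brain": self.sigma_brain,
            "sigma_csf": self.sigma_csf,
            "sigma_skull": self.sigma_skull,
            "sigma_scalp": self.sigma_scalp,
        }

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.sigma_brain, self.sigma_csf, self.sigma_skull, self.sigma_scalp]
        )

    def with_skull(self, sigma_skull: float) -> "ConductivityProfile":
        return ConductivityProfile(
            self.sigma_brain, self.sigma_csf, sigma_skull, self.sigma_scalp
        )


@dataclass(frozen=True)
class HeadModelSpec:
    """Four concentric shells: radii in mm (brain, CSF, skull, scalp outer)."""

    shell_radii: tuple = (79.0, 82.0, 87.0, 92.0)
    conductivity: ConductivityProfile = field(default_factory=ConductivityProfile)

    def __post_init__(self) -> None:
        r = np.asarray(self.shell_radii, dtype=float)
        if r.shape != (4,):
            raise ConfigurationError("shell_radii must have exactly four entries")
        if not np.all(np.diff(r) > 0):
            raise ConfigurationError(f"shell radii must be strictly increasing, got {tuple(r)}")
        if r[0] <= 0:
            raise ConfigurationError("innermost radius must be positive")

    @property
    def brain_radius(self) -> float:
        return float(self.shell_radii[0])

    @property
    def scalp_radius(self) -> float:
        return float(self.shell_radii[3])

    def with_conductivity(self, profile: ConductivityProfile) -> "HeadModelSpec":
        return HeadModelSpec(self.shell_radii, profile)


@dataclass
class Leadfield:
    """Sensor gain matrix: (n_sensors, n_sources * 3), unit dipoles along x/y/z.

    EEG gains are µV/nAm in average reference; MEG gains are fT/nAm along the
    sensor orientation.
    """

    gain: np.ndarray
    kind: str  # "eeg" | "meg"
    source_space_id: str = ""
    sensor_array_id: str = ""
    conductivity_id: str = ""

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1] // 3

    def predict(self, moments: np.ndarray) -> np.ndarray:
        """Sensor data for per-source moment vectors (n_sources, 3) in nAm."""
        return self.gain @ np.asarray(moments, float).reshape(-1)


def _multishell_coefficients(head: HeadModelSpec, n_max: int) -> np.ndarray:
    """Scalp-surface geometry coefficients c_n for harmonic orders 1..n_max.

    Solved per order from the interface conditions in radii normalized by the
    scalp radius; c_n multiplies the interior expansion term (b/R)^(n-1) and
    reduces to (2n+1)/n when all four conductivities are equal.
    """
    radii = np.asarray(head.shell_radii, float) / head.scalp_radius  # u1..u4=1
    sig = head.conductivity.as_array()
    out = np.empty(n_max)
    for n in range(1, n_max + 1):
        # unknowns: a1, a2, b2, a3, b3, a4, b4 (b1 = 1 is the source term)
        A = np.zeros((7, 7))
        rhs = np.zeros(7)
        col_a = {1: 0, 2: 1, 3: 3, 4: 5}
        col_b = {2: 2, 3: 4, 4: 6}
        row = 0
        for k in (1, 2, 3):
            u = radii[k - 1]
            up, um = u**n, u ** -(n + 1)
            dup, dum = n * u ** (n - 1), -(n + 1) * u ** -(n + 2)
            # potential continuity at interface k | k+1
            A[row, col_a[k]] = up
            if k > 1:
                A[row, col_b[k]] = um
            else:
                rhs[row] = -um  # b1 = 1
            A[row, col_a[k + 1]] = -up
            A[row, col_b[k + 1]] = -um
            row += 1
            # radial current continuity
            A[row, col_a[k]] = sig[k - 1] * dup
            if k > 1:
                A[row, col_b[k]] = sig[k - 1] * dum
            else:
                rhs[row] = -sig[k - 1] * dum
            A[row, col_a[k + 1]] = -sig[k] * dup
            A[row, col_b[k + 1]] = -sig[k] * dum
            row += 1
        # insulating outer surface at u = 1
        A[row, col_a[4]] = n
        A[row, col_b[4]] = -(n + 1)
        x = np.linalg.solve(A, rhs)
        out[n - 1] = x[col_a[4]] + x[col_b[4]]  # scalp value at u = 1
    return out


def _check_electrodes_on_scalp(electrodes: np.ndarray, head: HeadModelSpec) -> None:
    radii = np.linalg.norm(electrodes, axis=1)
    if np.any(np.abs(radii - head.scalp_radius) > 1e-3):
        raise GeometryError("EEG electrodes must lie on the scalp shell")


def _eeg_series_coefficients(
    dipole_radii_mm: np.ndarray, cos_alpha: np.ndarray, head: HeadModelSpec
) -> tuple:
    """Accumulated angular coefficient maps (A, B) for the EEG series.

    A multiplies the radial moment component, B the tangential one (through the
    derivative Legendre polynomials); shapes follow ``cos_alpha``
    (n_electrodes, n_dipoles).
    """
    R = head.scalp_radius
    beta = np.asarray(dipole_radii_mm, float) / R
    if np.any(beta >= head.brain_radius / R + 1e-12):
        raise GeometryError("dipole outside the innermost shell")
    c = _multishell_coefficients(head, SERIES_MAX_TERMS)
    x = np.asarray(cos_alpha, float)
    coefA = np.zeros_like(x)
    coefB = np.zeros_like(x)
    # Legendre recursion in P_n(x) and dP_n/dx
    p_nm1 = np.ones_like(x)  # P_0
    p_n = x.copy()  # P_1
    dp_nm1 = np.zeros_like(x)  # P_0'
    dp_n = np.ones_like(x)  # P_1'
    beta_pow = np.ones_like(beta)  # beta^(n-1), n = 1
    running_max = 0.0
    for n in range(1, SERIES_MAX_TERMS + 1):
        kn = c[n - 1] * beta_pow  # per-dipole radial factor
        termA = kn * n * p_n
        termB = kn * dp_n
        coefA += termA
        coefB += termB
        term_size = max(np.max(np.abs(termA)), np.max(np.abs(termB)))
        running_max = max(running_max, term_size)
        if term_size < SERIES_RTOL * running_max and n > 2:
            break
        # advance recursions to order n+1
        p_np1 = ((2 * n + 1) * x * p_n - n * p_nm1) / (n + 1)
        dp_np1 = dp_nm1 + (2 * n + 1) * p_n
        p_nm1, p_n = p_n, p_np1
        dp_nm1, dp_n = dp_n, dp_np1
        beta_pow = beta_pow * beta
    return coefA, coefB


def eeg_sphere_potential(
    dipole_pos_mm: np.ndarray,
    moment_nAm: np.ndarray,
    electrodes_mm: np.ndarray,
    head: HeadModelSpec,
) -> np.ndarray:
    """Average-referenced scalp potentials (µV) of one dipole.

    Parameters
    ----------
    dipole_pos_mm : (3,) position inside the innermost shell.
    moment_nAm : (3,) dipole moment.
    electrodes_mm : (n, 3) electrode positions on the scalp shell.
    """
    r0 = np.asarray(dipole_pos_mm, float)
    m = np.asarray(moment_nAm, float)
    elec = np.atleast_2d(np.asarray(electrodes_mm, float))
    _check_electrodes_on_scalp(elec, head)
    b = np.linalg.norm(r0)
    if b >= head.brain_radius:
        raise GeometryError(
            f"dipole at radius {b:.2f} mm is outside the innermost shell "
            f"({head.brain_radius:.2f} mm)"
        )
    rhat0 = r0 / b if b > 1e-12 else np.array([0.0, 0.0, 1.0])
    ehat = elec / np.linalg.norm(elec, axis=1, keepdims=True)
    cosa = np.clip(ehat @ rhat0, -1.0, 1.0)[:, None]  # (n_elec, 1)
    coefA, coefB = _eeg_series_coefficients(np.array([b]), cosa, head)
    m_r = m @ rhat0
    m_tang = ehat @ m - cosa[:, 0] * m_r  # m · (ê − cosα r̂0)
    R_m = head.scalp_radius * 1e-3
    scale = 1.0 / (4.0 * np.pi * head.conductivity.sigma_brain * R_m**2)
    v_volts_per_Am = scale * (coefA[:, 0] * m_r + coefB[:, 0] * m_tang)
    v_uV = v_volts_per_Am * 1e-3  # (V per A·m) → (µV per nAm), moments in nAm
    return v_uV - v_uV.mean()


def meg_sphere_field(
    dipole_pos_mm: np.ndarray,
    moment_nAm: np.ndarray,
    sensor_pos_mm: np.ndarray,
    sensor_ori: np.ndarray,
    head: HeadModelSpec,
) -> np.ndarray:
    """Magnetic field (fT) along each sensor orientation for one dipole.

    Implements the closed-form field of a current dipole in a spherically
    symmetric conductor; the output does not depend on the conductivity profile
    and is exactly zero for radial dipoles and for a dipole at the origin.
    """
    r0 = np.asarray(dipole_pos_mm, float) * 1e-3
    q = np.asarray(moment_nAm, float) * 1e-9
    pos = np.atleast_2d(np.asarray(sensor_pos_mm, float)) * 1e-3
    ori = np.atleast_2d(np.asarray(sensor_ori, float))
    b = np.linalg.norm(r0) * 1e3
    if b >= head.brain_radius:
        raise GeometryError("dipole outside the innermost shell")
    sensor_radii = np.linalg.norm(pos, axis=1) * 1e3
    if np.any(sensor_radii <= head.scalp_radius):
        raise GeometryError("MEG sensors must lie outside the scalp shell")
    B = _sarvas_field(r0, q, pos)
    return np.einsum("ij,ij->i", B, ori) * 1e15  # T → fT


def _sarvas_field(r0: np.ndarray, q: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Vector field (T) at positions ``pos`` (m) for dipole q (A·m) at r0 (m)."""
    a_vec = pos - r0
    a = np.linalg.norm(a_vec, axis=1)
    r = np.linalg.norm(pos, axis=1)
    ar = np.einsum("ij,j->i", a_vec, r0)  # a · r0 not needed; use a·r below
    adotr = np.einsum("ij,ij->i", a_vec, pos)
    F = a * (r * a + r**2 - pos @ r0)
    gradF = (
        (a**2 / r + adotr / a + 2 * a + 2 * r)[:, None] * pos
        - (a + 2 * r + adotr / a)[:, None] * r0[None, :]
    )
    qxr0 = np.cross(q, r0)
    # radial dipole or dipole at origin: spherical conductor is silent
    if np.linalg.norm(qxr0) <= 1e-15 * np.linalg.norm(q) * max(np.linalg.norm(r0), 1e-300):
        return np.zeros_like(pos)
    B = _MU0_OVER_4PI / (F**2)[:, None] * (
        F[:, None] * qxr0[None, :] - (pos @ qxr0)[:, None] * gradF
    )
    del ar
    return B


def build_leadfield(source_space, sensors, head: HeadModelSpec) -> Leadfield:
    """Assemble the gain matrix for a source space and one sensor array.

    Column (3*i + k) is the forward solution of a unit dipole along axis k at
    source i (µV/nAm for EEG, fT/nAm for MEG).
    """
    positions = np.asarray(source_space.positions, float)
    n_src = positions.shape[0]
    if sensors.kind == "eeg":
        gain = _eeg_gain(positions, np.asarray(sensors.positions, float), head)
    elif sensors.kind == "meg":
        gain = _meg_gain(
            positions,
            np.asarray(sensors.positions, float),
            np.asarray(sensors.orientations, float),
            head,
        )
    else:
        raise ConfigurationError(f"unknown sensor kind {sensors.kind!r}")
    return Leadfield(
        gain=gain,
        kind=sensors.kind,
        source_space_id=getattr(source_space, "space_id", ""),
        sensor_array_id=getattr(sensors, "array_id", ""),
        conductivity_id=repr(head.conductivity.as_dict()),
    )


def _eeg_gain(positions: np.ndarray, electrodes: np.ndarray, head: HeadModelSpec) -> np.ndarray:
    _check_electrodes_on_scalp(electrodes, head)
    b = np.linalg.norm(positions, axis=1)
    if np.any(b >= head.brain_radius):
        bad = int(np.argmax(b >= head.brain_radius))
        raise GeometryError(f"source {bad} lies outside the innermost shell")
    safe_b = np.where(b > 1e-12, b, 1.0)
    rhat0 = positions / safe_b[:, None]
    rhat0[b <= 1e-12] = [0.0, 0.0, 1.0]
    ehat = electrodes / np.linalg.norm(electrodes, axis=1, keepdims=True)
    cosa = np.clip(ehat @ rhat0.T, -1.0, 1.0)  # (n_elec, n_src)
    coefA, coefB = _eeg_series_coefficients(b, cosa, head)
    R_m = head.scalp_radius * 1e-3
    scale = 1.0 / (4.0 * np.pi * head.conductivity.sigma_brain * R_m**2) * 1e-3
    # V = scale * (coefA (m·r̂0) + coefB (m·ê − cosα m·r̂0)) per electrode/source
    radial = (coefA - coefB * cosa)[:, :, None] * rhat0[None, :, :]
    tangential = coefB[:, :, None] * ehat[:, None, :]
    gain = scale * (radial + tangential)  # (n_elec, n_src, 3)
    gain -= gain.mean(axis=0, keepdims=True)  # average reference
    return gain.reshape(gain.shape[0], -1)


def _meg_gain(
    positions: np.ndarray, sensor_pos: np.ndarray, sensor_ori: np.ndarray, head: HeadModelSpec
) -> np.ndarray:
    if np.any(np.linalg.norm(sensor_pos, axis=1) <= head.scalp_radius):
        raise GeometryError("MEG sensors must lie outside the scalp shell")
    b = np.linalg.norm(positions, axis=1)
    if np.any(b >= head.brain_radius):
        bad = int(np.argmax(b >= head.brain_radius))
        raise GeometryError(f"source {bad} lies outside the innermost shell")
    pos_m = sensor_pos * 1e-3
    src_m = positions * 1e-3
    n_sens, n_src = pos_m.shape[0], src_m.shape[0]
    # geometry terms: sensors × sources
    a_vec = pos_m[:, None, :] - src_m[None, :, :]
    a = np.linalg.norm(a_vec, axis=2)
    r = np.linalg.norm(pos_m, axis=1)[:, None]
    adotr = np.einsum("stk,sk->st", a_vec, pos_m)
    rdotr0 = pos_m @ src_m.T
    F = a * (r * a + r**2 - rdotr0)
    c1 = a**2 / r + adotr / a + 2 * a + 2 * r
    c2 = a + 2 * r + adotr / a
    gradF = c1[:, :, None] * pos_m[:, None, :] - c2[:, :, None] * src_m[None, :, :]
    gain = np.empty((n_sens, n_src, 3))
    eye = np.eye(3)
    for k in range(3):
        qxr0 = np.cross(eye[k], src_m)  # (n_src, 3), unit A·m along axis k
        rdotqx = np.einsum("sk,tk->st", pos_m, qxr0)
        B = (
            _MU0_OVER_4PI
            / F[:, :, None] ** 2
            * (F[:, :, None] * qxr0[None, :, :] - rdotqx[:, :, None] * gradF)
        )
        gain[:, :, k] = np.einsum("stk,sk->st", B, sensor_ori)
    # unit moment above is 1 A·m; convert to fT per nAm: 1e-9 * 1e15
    gain *= 1e6
    # interleave axes: (n_sens, n_src*3) with per-source xyz blocks
    out = np.empty((n_sens, n_src * 3))
    for k in range(3):
        out[:, k::3] = gain[:, :, k]
    return out
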