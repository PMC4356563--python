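"""Single-dipole deviation scan, EEG/MEG fusion and skull calibration.

The deviation scan fits, at every source-space position independently, a free
3-vector dipole moment to the sensor data by least squares on the local
3-column gain, reports the goodness of fit

    GOF_i = 1 − ||d − G_i m_i||² / ||d||²

for every position, and returns the position with the highest GOF (lowest
index on ties).  MEG scans use Tikhonov regularization on the local fit to
stabilize the near-silent radial moment direction; the winning moment is
always re-solved unregularized.

EEG and MEG enter a combined (EMEG) scan in a unitless common space: every
channel (data row and leadfield row alike) is divided by its baseline noise
standard deviation, so each fused channel carries unit noise variance and the
two modalities are weighted by their per-channel amplitude SNRs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InputError
from .forward import Leadfield
from .phantom import Phantom, SensorArray

#: relative Tikhonov weight: lambda = MEG_LAMBDA_REL * trace(G^T G) per source
MEG_LAMBDA_REL = 1e-3
_PINV_RCOND = 1e-10


@dataclass
class ScanResult:
    best_index: int
    location_mm: np.ndarray
    moment_nAm: np.ndarray
    gof: float
    gof_map: np.ndarray
    modality: str = ""
    time_ms: float = 0.0
    rank_deficient: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def residual_variance(self) -> float:
        return 1.0 - self.gof

    @property
    def strength_nAm(self) -> float:
        return float(np.linalg.norm(self.moment_nAm))

    @property
    def orientation(self) -> np.ndarray:
        s = self.strength_nAm
        return self.moment_nAm / s if s > 0 else np.zeros(3)


@dataclass
class FusedData:
    """Noise-normalized EEG+MEG data vector and matching row-scaled leadfield."""

    data: np.ndarray  # (n_fused,)
    gain: np.ndarray  # (n_fused, n_sources*3)
    channel_kinds: list
    dropped: list = field(default_factory=list)


@dataclass
class CalibrationResult:
    sigma_grid: np.ndarray
    scores: np.ndarray  # EEG GOF at the MEG-determined location per candidate
    best_sigma: float
    meg_location_index: int
    meg_gof: float
    reliable: bool = True


def deviation_scan(
    data_vector: np.ndarray,
    leadfield: Leadfield,
    source_positions: np.ndarray,
    regularization: str = "none",
    modality: str = "",
    time_ms: float = 0.0,
) -> ScanResult:
    """Exhaustive single-dipole scan over all source positions.

    ``regularization`` is "none" or "tikhonov" (relative weight
    ``MEG_LAMBDA_REL`` times the local normal-matrix trace).
    """
    d = np.asarray(data_vector, float)
    d_ss = float(d @ d)
    if d_ss == 0:
        raise InputError("zero data vector: GOF undefined")
    if regularization not in ("none", "tikhonov"):
        raise ConfigurationError(f"unknown regularization {regularization!r}")
    G = leadfield.gain.reshape(leadfield.n_sensors, -1, 3)
    if G.shape[0] != d.size:
        raise ConfigurationError("data and leadfield dimensions do not match")
    A = np.einsum("cik,cil->ikl", G, G)  # (n_src, 3, 3) normal matrices
    b = np.einsum("cik,c->ik", G, d)  # (n_src, 3)
    A_solve = A
    if regularization == "tikhonov":
        lam = MEG_LAMBDA_REL * np.trace(A, axis1=1, axis2=2)
        A_solve = A + lam[:, None, None] * np.eye(3)[None, :, :]
    eig = np.linalg.eigvalsh(A_solve)
    bad = np.flatnonzero(eig[:, 0] <= _PINV_RCOND * np.maximum(eig[:, -1], 1e-300))
    if bad.size:
        moments = np.empty_like(b)
        ok = np.setdiff1d(np.arange(A.shape[0]), bad)
        if ok.size:
            moments[ok] = np.linalg.solve(A_solve[ok], b[ok][..., None])[..., 0]
        for i in bad:
            moments[i] = np.linalg.pinv(A_solve[i], rcond=_PINV_RCOND) @ b[i]
    else:
        moments = np.linalg.solve(A_solve, b[..., None])[..., 0]
    resid = d_ss - 2 * np.einsum("ik,ik->i", moments, b) + np.einsum(
        "ik,ikl,il->i", moments, A, moments
    )
    gof_map = 1.0 - resid / d_ss
    best = int(np.argmax(gof_map))
    # winning moment re-solved without regularization; the pseudo-inverse
    # keeps the near-silent direction (e.g. radial in MEG) out of the moment
    m_best = np.linalg.pinv(A[best], rcond=_PINV_RCOND) @ b[best]
    eig_best = np.linalg.eigvalsh(A[best])
    if eig_best[0] <= _PINV_RCOND * max(eig_best[-1], 1e-300) and best not in bad:
        bad = np.sort(np.append(bad, best))
    r_best = d_ss - 2 * m_best @ b[best] + m_best @ A[best] @ m_best
    gof_best = 1.0 - r_best / d_ss
    gof_map = gof_map.copy()
    gof_map[best] = gof_best
    return ScanResult(
        best_index=best,
        location_mm=np.asarray(source_positions, float)[best].copy(),
        moment_nAm=m_best,
        gof=float(gof_best),
        gof_map=gof_map,
        modality=modality,
        time_ms=time_ms,
        rank_deficient=bad,
    )


def select_meg_left(sensors: SensorArray) -> np.ndarray:
    """Indices of MEG channels over the left hemisphere (x < 0, strict)."""
    x = np.asarray(sensors.positions, float)[:, 0]
    picks = np.flatnonzero(x < 0)
    if picks.size == 0:
        warnings.warn("no MEG channels on the left hemisphere", stacklevel=2)
    return picks


def emeg_fuse(
    eeg_data: np.ndarray,
    meg_data: np.ndarray,
    eeg_baseline: np.ndarray,
    meg_baseline: np.ndarray,
    eeg_gain: np.ndarray,
    meg_gain: np.ndarray,
) -> FusedData:
    """Stack EEG then MEG after dividing every row by its baseline noise SD.

    ``*_data`` are per-channel values at the scan instant, ``*_baseline`` are
    (n_channels, n_baseline_samples) windows from which the per-channel SD is
    estimated.  Channels with zero baseline SD are dropped with a warning.
    """
    rows_d, rows_g, kinds, dropped = [], [], [], []
    for kind, dat, base, gain in (
        ("eeg", eeg_data, eeg_baseline, eeg_gain),
        ("meg", meg_data, meg_baseline, meg_gain),
    ):
        dat = np.asarray(dat, float)
        sd = np.asarray(base, float).std(axis=1)
        for c in range(dat.size):
            if sd[c] == 0:
                dropped.append((kind, c))
                continue
            rows_d.append(dat[c] / sd[c])
            rows_g.append(gain[c] / sd[c])
            kinds.append(kind)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} zero-noise channels from fusion", stacklevel=2)
    if not rows_d:
        raise InputError("no channels left after fusion")
    return FusedData(
        data=np.asarray(rows_d),
        gain=np.asarray(rows_g),
        channel_kinds=kinds,
        dropped=dropped,
    )


def calibrate_skull(
    sep_eeg_epoch: np.ndarray,
    sef_meg_epoch: np.ndarray,
    n20_sample: int,
    phantom: Phantom,
    sigma_grid,
    baseline_slice: slice | None = None,
) -> CalibrationResult:
    """Skull-conductivity calibration from averaged N20 responses.

    The conductivity-independent MEG scan fixes the source location; each
    candidate skull conductivity is then scored by the EEG goodness of fit of
    the local 3-column gain (rebuilt at that conductivity) at the fixed
    location, and the best-scoring candidate wins.
    """
    sigma_grid = np.asarray(sigma_grid, float)
    if sigma_grid.size == 0:
        raise ConfigurationError("empty conductivity grid")
    if np.any(np.diff(sigma_grid) <= 0):
        raise ConfigurationError("conductivity grid must be strictly increasing")
    d_meg = np.asarray(sef_meg_epoch, float)[:, n20_sample]
    meg_scan = deviation_scan(
        d_meg,
        phantom.leadfield("meg"),
        phantom.source_space.positions,
        regularization="tikhonov",
        modality="meg",
    )
    reliable = meg_scan.gof >= 0.5
    if not reliable:
        warnings.warn(
            f"MEG calibration scan GOF {meg_scan.gof:.2f} < 0.5: calibration unreliable",
            stacklevel=2,
        )
    loc = phantom.source_space.positions[meg_scan.best_index]
    sep = np.asarray(sep_eeg_epoch, float)
    # score over the whole N20 lobe (samples with >= half the peak spatial
    # rms), not a single instant: the component shape carries the skull-
    # conductivity information and the extra samples suppress noise
    rms = np.sqrt(np.mean(sep**2, axis=0))
    window = np.flatnonzero(rms >= 0.5 * rms[n20_sample])
    D = sep[:, window]
    d_ss = float(np.sum(D**2))
    if d_ss == 0:
        raise InputError("zero EEG data in the N20 window")
    elec = np.asarray(phantom.eeg.positions, float)
    scores = np.empty(sigma_grid.size)
    from .forward import eeg_sphere_potential  # local import avoids cycle at module load

    for i, sig in enumerate(sigma_grid):
        head = phantom.head.with_conductivity(phantom.head.conductivity.with_skull(float(sig)))
        G = np.column_stack(
            [eeg_sphere_potential(loc, axis, elec, head) for axis in np.eye(3)]
        )
        M, *_ = np.linalg.lstsq(G, D, rcond=None)
        resid = D - G @ M
        scores[i] = 1.0 - float(np.sum(resid**2)) / d_ss
    best = int(np.argmax(scores))
    return CalibrationResult(
        sigma_grid=sigma_grid,
        scores=scores,
        best_sigma=float(sigma_grid[best]),
        meg_location_index=meg_scan.best_index,
        meg_gof=meg_scan.gof,
        reliable=reliable,
    )
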