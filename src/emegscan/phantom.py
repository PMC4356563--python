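"""Digital phantom: geometry, sensors, sEEG contacts and simulated recordings.

The phantom stands in for a patient: a four-shell spherical head, an EEG cap
on the scalp shell, a whole-head MEG array outside it, a cortical-band source
space, depth-electrode contacts with ictal/interictal/inactive labels, and an
irritative zone consisting of a deep patch (seizure-onset analogue) and a
lateral patch (temporal-pole analogue) toward which spike activity propagates.

Coordinate frame: head-centered RAS in millimetres, origin at the sphere
center, left hemisphere at x < 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .errors import ConfigurationError, GeometryError
from .forward import HeadModelSpec, Leadfield, build_leadfield

DEFAULT_SFREQ = 250.0  # Hz


@dataclass
class SourceSpace:
    """Candidate dipole positions with nominal cortical orientations."""

    positions: np.ndarray  # (n, 3) mm, strictly inside the innermost shell
    normals: np.ndarray  # (n, 3) unit vectors
    spacing: float  # nominal grid resolution, mm
    space_id: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.normals = np.asarray(self.normals, float)

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]


@dataclass
class SensorArray:
    kind: str  # "eeg" | "meg"
    positions: np.ndarray  # (n, 3) mm
    orientations: np.ndarray | None = None  # (n, 3), MEG sensing directions
    names: list = field(default_factory=list)
    hemisphere: list = field(default_factory=list)  # "left" | "right" | "midline"
    array_id: str = ""

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]


@dataclass
class SEEGContactTable:
    """Depth-electrode contacts used as geometric validation points."""

    electrode_names: list
    contact_numbers: list
    positions: np.ndarray  # (n, 3) mm
    labels: list  # "ictal" | "interictal" | "inactive"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)

    def select(self, label: str) -> np.ndarray:
        """Positions of all contacts carrying ``label``.

        ``interictal`` returns the full interictal-measuring set, which by
        construction includes every ictal contact.
        """
        if label == "interictal":
            keep = [lab in ("interictal", "ictal") for lab in self.labels]
        else:
            keep = [lab == label for lab in self.labels]
        return self.positions[np.asarray(keep, bool)]

    def names_for(self, label: str) -> list:
        if label == "interictal":
            keep = [lab in ("interictal", "ictal") for lab in self.labels]
        else:
            keep = [lab == label for lab in self.labels]
        return [
            f"{e}{c}"
            for e, c, k in zip(self.electrode_names, self.contact_numbers, keep)
            if k
        ]


@dataclass
class IrritativeZoneSpec:
    """Two disjoint source patches with deep-to-lateral propagation."""

    deep_patch: np.ndarray  # source indices, seizure-onset analogue
    lateral_patch: np.ndarray  # source indices, temporal-pole analogue
    propagation_delay_ms: float = 30.0
    origin_jitter_mm: float = 10.0
    amplitude_median_nAm: float = 200.0
    amplitude_sigma_log: float = 0.4
    lateral_gain: float = 2.0  # lateral activity stronger → EEG peak late

    def __post_init__(self) -> None:
        self.deep_patch = np.asarray(self.deep_patch, int)
        self.lateral_patch = np.asarray(self.lateral_patch, int)
        if self.propagation_delay_ms < 0:
            raise ConfigurationError("propagation delay must be >= 0")
        if np.intersect1d(self.deep_patch, self.lateral_patch).size:
            raise ConfigurationError("deep and lateral patches must be disjoint")


@dataclass
class SpikeEvent:
    """Ground-truth bookkeeping for one simulated spike."""

    onset_sample: int
    origin_index: int
    amplitude_nAm: float
    waveform_id: str = "biphasic"
    peak_sample: int = -1  # sample of maximal lateral (EEG-dominant) activity
    lateral_index: int = -1


@dataclass
class ContinuousRecording:
    """Multichannel time series; EEG rows in µV, MEG rows in fT."""

    data: np.ndarray  # (n_channels, n_samples)
    sfreq: float
    channel_names: list
    channel_kinds: list  # "eeg" | "meg" per channel
    ground_truth: list = field(default_factory=list)  # SpikeEvent, synthetic runs

    def __post_init__(self) -> None:
        if self.sfreq <= 0:
            raise ConfigurationError("sfreq must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ConfigurationError("recording contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def picks(self, kind: str) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.channel_kinds) if k == kind])


@dataclass
class Phantom:
    """Bundle of everything `make_phantom` builds, plus cached leadfields."""

    head: HeadModelSpec
    source_space: SourceSpace
    eeg: SensorArray
    meg: SensorArray
    contacts: SEEGContactTable
    zone: IrritativeZoneSpec
    _leadfields: dict = field(default_factory=dict, repr=False)

    def leadfield(self, kind: str) -> Leadfield:
        if kind not in self._leadfields:
            sensors = self.eeg if kind == "eeg" else self.meg
            self._leadfields[kind] = build_leadfield(self.source_space, sensors, self.head)
        return self._leadfields[kind]


def _fibonacci_directions(n: int, z_min: float, rng_phase: float = 0.0) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors with z >= z_min (cap coverage)."""
    i = np.arange(n) + 0.5
    z = z_min + (1.0 - z_min) * (1.0 - i / n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i + rng_phase
    s = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _hemisphere_labels(positions: np.ndarray, tol: float = 1e-9) -> list:
    out = []
    for x in positions[:, 0]:
        out.append("midline" if abs(x) < tol else ("left" if x < 0 else "right"))
    return out


def _cortical_band_grid(head: HeadModelSpec, spacing: float, band: tuple) -> np.ndarray:
    lo, hi = band
    if not (0 < lo < hi < head.brain_radius):
        raise ConfigurationError("cortical band must lie inside the innermost shell")
    edge = np.arange(-hi, hi + spacing / 2, spacing)
    gx, gy, gz = np.meshgrid(edge, edge, edge, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    r = np.linalg.norm(pts, axis=1)
    return pts[(r >= lo) & (r <= hi)]


def _tilted_normals(positions: np.ndarray, tilt_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Radial directions tilted by a fixed angle about a random tangent axis.

    A purely radial orientation would make every source silent in MEG; real
    cortical normals mix radial and tangential components, which the fixed
    tilt emulates.
    """
    r = np.linalg.norm(positions, axis=1, keepdims=True)
    radial = positions / r
    rand = rng.standard_normal(positions.shape)
    tangent = rand - (np.einsum("ij,ij->i", rand, radial))[:, None] * radial
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    t = np.deg2rad(tilt_deg)
    normals = np.cos(t) * radial + np.sin(t) * tangent
    return normals / np.linalg.norm(normals, axis=1, keepdims=True)


def _patch_indices(
    positions: np.ndarray,
    seed_point: np.ndarray,
    n_members: int,
    radius_mm: float = 14.0,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Up to ``n_members`` sources nearest the seed, capped at ``radius_mm``.

    The radius cap keeps the patch a compact piece of cortex on coarse grids
    instead of spreading over the whole band.
    """
    d = np.linalg.norm(positions - seed_point, axis=1)
    order = np.argsort(d, kind="stable")
    if exclude is not None:
        order = order[~np.isin(order, exclude)]
    if n_members > positions.shape[0]:
        raise ConfigurationError("patch request exceeds available source count")
    order = order[: n_members]
    order = order[d[order] <= radius_mm]
    if order.size == 0:
        raise ConfigurationError("no source within the patch radius")
    return np.sort(order)


def _default_electrode_specs(brain_radius: float) -> list:
    """Five left-temporal depth electrodes plus two distant inactive ones.

    Each spec: (name, entry direction unit vector, target point, n_contacts).
    Contacts are spaced 5 mm along the insertion line from the target outward.
    """
    deep_dir = np.array([-0.75, 0.35, -0.35])
    lat_dir = np.array([-0.80, 0.55, -0.22])
    deep_dir /= np.linalg.norm(deep_dir)
    lat_dir /= np.linalg.norm(lat_dir)
    deep_target = deep_dir * 0.72 * brain_radius
    lat_target = lat_dir * 0.91 * brain_radius
    mid = 0.5 * (deep_target + lat_target)
    specs = [
        ("A", deep_target + np.array([0.0, 6.0, -3.0]), 9),
        ("HA", deep_target + np.array([0.0, -4.0, 3.0]), 12),
        ("HP", deep_target + np.array([0.0, -14.0, 6.0]), 8),
        ("TA", lat_target + np.array([0.0, 3.0, 0.0]), 8),
        ("E", mid + np.array([0.0, 0.0, 8.0]), 8),
        ("F", np.array([-30.0, 55.0, 25.0]), 8),  # frontal, inactive
        ("P", np.array([-35.0, -50.0, 20.0]), 8),  # posterior, inactive
    ]
    return specs


def _make_contacts(
    head: HeadModelSpec,
    deep_centroid: np.ndarray,
    lateral_centroid: np.ndarray,
    n_interictal: int,
    n_ictal: int,
) -> SEEGContactTable:
    names, numbers, positions = [], [], []
    for name, target, n_contacts in _default_electrode_specs(head.brain_radius):
        direction = target / np.linalg.norm(target)
        for k in range(n_contacts):
            pos = target - direction * 5.0 * k  # retract toward the center
            if np.linalg.norm(pos) >= head.brain_radius - 1.0:
                pos = direction * (head.brain_radius - 1.5)
            names.append(name)
            numbers.append(k + 1)
            positions.append(pos)
    positions = np.asarray(positions)

    # activity labels by proximity quotas: the n_ictal contacts nearest the
    # deep patch (on the two deep-most electrodes) are ictal; the interictal
    # set extends by proximity to either patch up to n_interictal contacts.
    d_deep = np.linalg.norm(positions - deep_centroid, axis=1)
    d_any = np.minimum(d_deep, np.linalg.norm(positions - lateral_centroid, axis=1))
    elec = np.asarray(names)
    deep_electrodes = ("A", "HA")
    ictal_pool = np.flatnonzero(np.isin(elec, deep_electrodes))
    ictal = ictal_pool[np.argsort(d_deep[ictal_pool], kind="stable")[:n_ictal]]
    active_pool = np.flatnonzero(np.isin(elec, ("A", "HA", "HP", "TA", "E")))
    remaining = active_pool[~np.isin(active_pool, ictal)]
    extra = remaining[np.argsort(d_any[remaining], kind="stable")[: n_interictal - n_ictal]]
    labels = ["inactive"] * len(names)
    for i in extra:
        labels[i] = "interictal"
    for i in ictal:
        labels[i] = "ictal"
    return SEEGContactTable(list(names), numbers, positions, labels)


def make_phantom(
    head: HeadModelSpec | None = None,
    *,
    n_eeg: int = 80,
    n_meg: int = 275,
    spacing_mm: float = 8.0,
    cortical_band: tuple = (55.0, 74.0),
    patch_size: int = 20,
    n_interictal_contacts: int = 24,
    n_ictal_contacts: int = 8,
    normal_tilt_deg: float = 40.0,
    deep_tilt_deg: float = 35.0,
    lateral_tilt_deg: float = 15.0,
    seed: int = 0,
) -> Phantom:
    """Build the full synthetic measurement setup.

    Deterministic for a fixed seed.  Default sensor counts follow an 80-channel
    EEG cap and a 275-channel whole-head MEG; the source space is a regular
    grid restricted to a cortical shell band, with normals tilted away from
    radial so every source is visible to both modalities.
    """
    head = head or HeadModelSpec()
    rng = np.random.default_rng(seed)
    if n_ictal_contacts > n_interictal_contacts:
        raise ConfigurationError("ictal contacts must be a subset of interictal contacts")

    positions = _cortical_band_grid(head, spacing_mm, cortical_band)
    if positions.shape[0] < 2 * patch_size:
        raise ConfigurationError("patch requests exceed the source count")
    normals = _tilted_normals(positions, normal_tilt_deg, rng)
    space = SourceSpace(positions, normals, spacing_mm, space_id=f"band{cortical_band}@{spacing_mm}mm")

    eeg_dirs = _fibonacci_directions(n_eeg, z_min=-0.35)
    eeg_pos = eeg_dirs * head.scalp_radius
    eeg = SensorArray(
        kind="eeg",
        positions=eeg_pos,
        names=[f"EEG{i:03d}" for i in range(1, n_eeg + 1)],
        hemisphere=_hemisphere_labels(eeg_pos),
        array_id=f"eeg{n_eeg}",
    )
    meg_dirs = _fibonacci_directions(n_meg, z_min=-0.45)
    meg_pos = meg_dirs * (head.scalp_radius + 20.0)
    meg = SensorArray(
        kind="meg",
        positions=meg_pos,
        orientations=meg_dirs,  # radial magnetometers
        names=[f"MEG{i:03d}" for i in range(1, n_meg + 1)],
        hemisphere=_hemisphere_labels(meg_pos),
        array_id=f"meg{n_meg}",
    )

    lo, hi = cortical_band
    deep_dir = np.array([-0.75, 0.35, -0.35])
    deep_dir /= np.linalg.norm(deep_dir)
    lat_dir = np.array([-0.80, 0.55, -0.22])
    lat_dir /= np.linalg.norm(lat_dir)
    deep_seed = deep_dir * (lo + 0.15 * (hi - lo))
    lat_seed = lat_dir * (lo + 0.90 * (hi - lo))
    deep_patch = _patch_indices(positions, deep_seed, patch_size)
    lateral_patch = _patch_indices(positions, lat_seed, patch_size, exclude=deep_patch)
    if deep_patch.size + lateral_patch.size > positions.shape[0]:
        raise ConfigurationError("patch requests exceed the source count")
    zone = IrritativeZoneSpec(deep_patch=deep_patch, lateral_patch=lateral_patch)
    # orientation profile of the irritative zone: the deep (mesial) patch is
    # predominantly tangential, the lateral (temporal-pole) patch mostly
    # radial, so EEG gains more than MEG as activity propagates laterally
    normals[deep_patch] = _tilted_normals(positions[deep_patch], deep_tilt_deg, rng)
    normals[lateral_patch] = _tilted_normals(positions[lateral_patch], lateral_tilt_deg, rng)

    deep_centroid = positions[deep_patch].mean(axis=0)
    lat_centroid = positions[lateral_patch].mean(axis=0)
    scalp = head.scalp_radius
    if scalp - np.linalg.norm(deep_centroid) <= scalp - np.linalg.norm(lat_centroid):
        raise ConfigurationError("deep patch must lie deeper than the lateral patch")
    contacts = _make_contacts(
        head, deep_centroid, lat_centroid, n_interictal_contacts, n_ictal_contacts
    )
    if np.any(np.linalg.norm(contacts.positions, axis=1) >= head.brain_radius):
        raise GeometryError("sEEG contact outside the innermost shell")
    return Phantom(head, space, eeg, meg, contacts, zone)


# ---------------------------------------------------------------------------
# noise model
# ---------------------------------------------------------------------------


@dataclass
class NoiseModel:
    """Spatially structured sensor noise.

    A fraction ``spatial_correlation`` of each channel's variance comes from
    random dipolar fields (deep brain dipoles projected through the leadfield,
    temporally low-passed), the rest from white sensor noise; per-channel SD is
    normalized to the requested value in expectation.
    """

    spatial_correlation: float = 0.6
    eeg_sd_uV: float = 5.0
    meg_sd_fT: float = 300.0
    n_noise_dipoles: int = 60
    lowpass_hz: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eeg_sd_uV < 0 or self.meg_sd_fT < 0:
            raise ConfigurationError("noise SDs must be >= 0")
        if not 0 <= self.spatial_correlation <= 1:
            raise ConfigurationError("spatial_correlation must lie in [0, 1]")

    def _mixing(self, phantom: Phantom, kind: str, rng: np.random.Generator) -> np.ndarray:
        """Row-normalized topography matrix of random brain dipoles."""
        lf = phantom.leadfield(kind)
        n_src = lf.n_sources
        idx = rng.integers(0, n_src, size=self.n_noise_dipoles)
        ori = rng.standard_normal((self.n_noise_dipoles, 3))
        ori /= np.linalg.norm(ori, axis=1, keepdims=True)
        cols = lf.gain.reshape(lf.n_sensors, n_src, 3)
        topo = np.einsum("cnk,nk->cn", cols[:, idx, :], ori)
        norms = np.linalg.norm(topo, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return topo / norms

    def generate(self, phantom: Phantom, kind: str, n_samples: int, sfreq: float) -> np.ndarray:
        """Noise matrix (n_channels, n_samples) in µV (EEG) or fT (MEG)."""
        sd = self.eeg_sd_uV if kind == "eeg" else self.meg_sd_fT
        sensors = phantom.eeg if kind == "eeg" else phantom.meg
        n_ch = sensors.n_channels
        if sd == 0:
            return np.zeros((n_ch, n_samples))
        rng = np.random.default_rng((self.seed, {"eeg": 0, "meg": 1}[kind]))
        alpha = self.spatial_correlation
        white = rng.standard_normal((n_ch, n_samples))
        if alpha == 0:
            return sd * white
        mix = self._mixing(phantom, kind, rng)
        drive = rng.standard_normal((self.n_noise_dipoles, n_samples))
        if self.lowpass_hz < sfreq / 2:
            sos = sp_signal.butter(4, self.lowpass_hz, btype="low", fs=sfreq, output="sos")
            drive = sp_signal.sosfiltfilt(sos, drive, axis=1)
        drive /= drive.std(axis=1, keepdims=True)
        structured = mix @ drive
        structured /= np.sqrt(np.mean(structured**2, axis=1, keepdims=True))
        return sd * (np.sqrt(alpha) * structured + np.sqrt(1 - alpha) * white)


# ---------------------------------------------------------------------------
# spike and SEP simulation
# ---------------------------------------------------------------------------


def spike_waveform(sfreq: float, rise_ms: float = 20.0, fall_ms: float = 30.0) -> np.ndarray:
    """Fixed biphasic spike template, peak value 1 at the end of the rise."""
    n_rise = max(2, int(round(rise_ms * sfreq / 1000.0)))
    n_fall = max(2, int(round(fall_ms * sfreq / 1000.0)))
    rise = 0.5 - 0.5 * np.cos(np.linspace(0, np.pi, n_rise, endpoint=False))
    t = np.linspace(0, 1, n_fall)
    fall = np.cos(0.5 * np.pi * t) * (1 - 0.35 * np.sin(np.pi * t))
    return np.concatenate([rise, fall])


def _draw_origin(
    positions: np.ndarray, patch: np.ndarray, jitter_mm: float, rng: np.random.Generator
) -> int:
    """Patch member within ``jitter_mm`` of the patch seed (its first member)."""
    seedpos = positions[patch].mean(axis=0)
    d = np.linalg.norm(positions[patch] - seedpos, axis=1)
    candidates = patch[d <= jitter_mm]
    if candidates.size == 0:
        candidates = patch
    return int(rng.choice(candidates))


def simulate_spike_run(
    phantom: Phantom,
    zone: IrritativeZoneSpec | None = None,
    n_spikes: int = 200,
    noise_model: NoiseModel | None = None,
    duration_s: float | None = None,
    sfreq: float = DEFAULT_SFREQ,
    seed: int = 0,
) -> ContinuousRecording:
    """Continuous EEG+MEG with embedded stochastic propagating spikes.

    Each spike: a deep-patch origin drawn within the origin jitter of the patch
    seed fires a biphasic waveform at onset; after the propagation delay a
    lateral-patch source ramps up with ``lateral_gain`` times the amplitude, so
    the late (EEG-dominant) peak sits over the lateral patch as in mesial
    temporal spikes that propagate to the temporal pole.
    """
    zone = zone or phantom.zone
    noise_model = noise_model if noise_model is not None else NoiseModel(seed=seed + 1)
    if n_spikes < 1:
        raise ConfigurationError("n_spikes must be >= 1")
    rng = np.random.default_rng(seed)
    # the deep (onset) source rises slowly, the lateral one sharply after the
    # propagation delay, so the pre-peak instants sample a genuine low-SNR
    # onset phase while the late EEG peak sits over the lateral patch
    wave_deep = spike_waveform(sfreq, rise_ms=35.0, fall_ms=30.0)
    wave = spike_waveform(sfreq, rise_ms=20.0, fall_ms=30.0)
    delay = int(round(zone.propagation_delay_ms * sfreq / 1000.0))
    span = delay + max(wave.size, wave_deep.size - delay)
    gap = int(round(1.0 * sfreq))  # inter-spike spacing: 1 s
    margin = int(round(0.4 * sfreq))
    needed = margin + n_spikes * gap + span + margin
    if duration_s is None:
        n_samples = needed
    else:
        n_samples = int(round(duration_s * sfreq))
        if n_samples < needed:
            raise ConfigurationError(
                f"duration {duration_s} s too short for {n_spikes} non-overlapping spikes"
            )
    positions = phantom.source_space.positions
    lf_eeg = phantom.leadfield("eeg")
    lf_meg = phantom.leadfield("meg")
    normals = phantom.source_space.normals
    cols_eeg = lf_eeg.gain.reshape(lf_eeg.n_sensors, -1, 3)
    cols_meg = lf_meg.gain.reshape(lf_meg.n_sensors, -1, 3)

    eeg_sig = np.zeros((lf_eeg.n_sensors, n_samples))
    meg_sig = np.zeros((lf_meg.n_sensors, n_samples))
    events: list[SpikeEvent] = []
    for k in range(n_spikes):
        onset = margin + k * gap + int(rng.integers(0, max(1, gap // 4)))
        origin = _draw_origin(positions, zone.deep_patch, zone.origin_jitter_mm, rng)
        lateral = _draw_origin(positions, zone.lateral_patch, zone.origin_jitter_mm, rng)
        amp = zone.amplitude_median_nAm * np.exp(
            zone.amplitude_sigma_log * rng.standard_normal()
        )
        deep_m = amp * normals[origin]
        lat_m = zone.lateral_gain * amp * normals[lateral]
        topo_e = cols_eeg[:, origin, :] @ deep_m
        topo_m = cols_meg[:, origin, :] @ deep_m
        sl = slice(onset, onset + wave_deep.size)
        eeg_sig[:, sl] += topo_e[:, None] * wave_deep[None, :]
        meg_sig[:, sl] += topo_m[:, None] * wave_deep[None, :]
        lat_on = onset + delay
        sl2 = slice(lat_on, lat_on + wave.size)
        topo_e2 = cols_eeg[:, lateral, :] @ lat_m
        topo_m2 = cols_meg[:, lateral, :] @ lat_m
        eeg_sig[:, sl2] += topo_e2[:, None] * wave[None, :]
        meg_sig[:, sl2] += topo_m2[:, None] * wave[None, :]
        peak = lat_on + int(np.argmax(wave))
        events.append(
            SpikeEvent(
                onset_sample=onset,
                origin_index=origin,
                amplitude_nAm=float(amp),
                peak_sample=peak,
                lateral_index=lateral,
            )
        )
    eeg_sig += noise_model.generate(phantom, "eeg", n_samples, sfreq)
    meg_sig += noise_model.generate(phantom, "meg", n_samples, sfreq)
    data = np.vstack([eeg_sig, meg_sig])
    return ContinuousRecording(
        data=data,
        sfreq=sfreq,
        channel_names=list(phantom.eeg.names) + list(phantom.meg.names),
        channel_kinds=["eeg"] * lf_eeg.n_sensors + ["meg"] * lf_meg.n_sensors,
        ground_truth=events,
    )


def simulate_sep_run(
    phantom: Phantom,
    n20_location_mm: np.ndarray,
    n20_moment_nAm: np.ndarray,
    n_trials: int = 300,
    noise_model: NoiseModel | None = None,
    sfreq: float = DEFAULT_SFREQ,
    seed: int = 0,
) -> tuple:
    """Trial-averaged somatosensory (N20-like) EEG and MEG epochs.

    Returns ``(eeg_epoch, meg_epoch, n20_sample)`` with epochs of 200 ms
    (−100…+100 ms around the component peak).  Averaging over trials shrinks
    the noise SD as 1/sqrt(n_trials).
    """
    loc = np.asarray(n20_location_mm, float)
    if np.linalg.norm(loc) >= phantom.head.brain_radius:
        raise GeometryError("N20 source outside the innermost shell")
    noise_model = noise_model if noise_model is not None else NoiseModel(seed=seed + 1)
    # snap to nearest source-space point so the scan can recover it exactly
    idx = int(np.argmin(np.linalg.norm(phantom.source_space.positions - loc, axis=1)))
    m = np.asarray(n20_moment_nAm, float)
    n_samp = int(round(0.2 * sfreq))
    n20_sample = n_samp // 2
    wave = np.zeros(n_samp)
    half = sp_signal.windows.hann(int(round(0.02 * sfreq)) * 2 + 1)
    lo = n20_sample - half.size // 2
    wave[lo : lo + half.size] = half
    lf_eeg = phantom.leadfield("eeg")
    lf_meg = phantom.leadfield("meg")
    topo_e = lf_eeg.gain.reshape(lf_eeg.n_sensors, -1, 3)[:, idx, :] @ m
    topo_m = lf_meg.gain.reshape(lf_meg.n_sensors, -1, 3)[:, idx, :] @ m
    clean_e = topo_e[:, None] * wave[None, :]
    clean_m = topo_m[:, None] * wave[None, :]
    # one long noise stream cut into trials; the average shrinks as 1/sqrt(n)
    noise_e = noise_model.generate(phantom, "eeg", n_samp * n_trials, sfreq)
    noise_m = noise_model.generate(phantom, "meg", n_samp * n_trials, sfreq)
    avg_e = clean_e + noise_e.reshape(len(topo_e), n_trials, n_samp).mean(axis=1)
    avg_m = clean_m + noise_m.reshape(len(topo_m), n_trials, n_samp).mean(axis=1)
    return avg_e, avg_m, n20_sample


def noise_free_sensor_data(phantom: Phantom, moments: np.ndarray) -> np.ndarray:
    """Leadfield applied to a full per-source moment field (n_sources, 3)."""
    lf_e = phantom.leadfield("eeg")
    lf_m = phantom.leadfield("meg")
    flat = np.asarray(moments, float).reshape(-1)
    return np.concatenate([lf_e.gain @ flat, lf_m.gain @ flat])
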