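"""Spike detection, epoching, SNR statistics and bootstrap subaveraging.

The analysis chain mirrors standard interictal-spike practice: band-pass the
continuous data, build a template from a handful of reviewer-style seed
events, find further spikes by normalized sliding cross-correlation, cut
400 ms epochs aligned to the EEG spike peak, and draw bootstrap subaverages
(Av1, Av5 … Av50) whose SNR decides inclusion in source analysis.

The SNR of an epoch at a time point is the channel-mean instantaneous signal
power there divided by the channel-mean baseline noise variance, the baseline
being −200…−70 ms before the spike peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .errors import ConfigurationError, InputError
from .phantom import ContinuousRecording

BASELINE_MS = (-200.0, -70.0)
EPOCH_MS = (-200.0, 200.0)
DEFAULT_GROUP_SIZES = (1, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50)


@dataclass
class Epoch:
    """One 400 ms window, time 0 at the EEG spike peak."""

    data: np.ndarray  # (n_channels, n_samples)
    sfreq: float
    channel_kinds: list
    spike_ids: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def zero_sample(self) -> int:
        return int(round(-EPOCH_MS[0] * self.sfreq / 1000.0))

    def sample_at(self, time_ms: float) -> int:
        s = self.zero_sample + int(round(time_ms * self.sfreq / 1000.0))
        if not 0 <= s < self.n_samples:
            raise InputError(f"time {time_ms} ms outside the epoch")
        return s

    def picks(self, kind: str) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.channel_kinds) if k == kind])


@dataclass
class SNRRecord:
    value: float
    time_ms: float
    modality: str  # "eeg" | "meg" | "emeg"
    baseline_ms: tuple = BASELINE_MS

    def __post_init__(self) -> None:
        if self.value < 0:
            raise InputError("SNR cannot be negative")


@dataclass
class SubaverageSpec:
    group_sizes: tuple = DEFAULT_GROUP_SIZES
    realizations_per_group: int = 200
    seed: int = 0


@dataclass
class SubaverageRealization:
    group_size: int
    member_indices: np.ndarray
    epoch: Epoch

    def __post_init__(self) -> None:
        self.member_indices = np.asarray(self.member_indices, int)
        if len(set(self.member_indices.tolist())) != self.group_size:
            raise InputError("realization must draw distinct spikes")


def bandpass(recording: ContinuousRecording, low_hz: float, high_hz: float) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass of all channels."""
    nyq = recording.sfreq / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ConfigurationError(
            f"band ({low_hz}, {high_hz}) Hz invalid for Nyquist {nyq} Hz"
        )
    sos = sp_signal.butter(4, [low_hz, high_hz], btype="band", fs=recording.sfreq, output="sos")
    out = sp_signal.sosfiltfilt(sos, recording.data, axis=1)
    return ContinuousRecording(
        data=out,
        sfreq=recording.sfreq,
        channel_names=list(recording.channel_names),
        channel_kinds=list(recording.channel_kinds),
        ground_truth=list(recording.ground_truth),
    )


def _extract(data: np.ndarray, center: int, half_before: int, half_after: int) -> np.ndarray | None:
    lo, hi = center - half_before, center + half_after
    if lo < 0 or hi > data.shape[1]:
        return None
    return data[:, lo:hi]


def make_template(
    recording: ContinuousRecording,
    seed_event_samples,
    n_seed: int = 10,
    channel_picks: np.ndarray | None = None,
    half_width_ms: float = 100.0,
) -> np.ndarray:
    """Average of seed epochs on the detection channel subset.

    Emulates the reviewer workflow of marking a few clear spikes and averaging
    them into a search template.
    """
    seed_event_samples = np.asarray(seed_event_samples, int)
    if seed_event_samples.size < n_seed or n_seed < 1:
        raise InputError(f"need at least {n_seed} marked events, got {seed_event_samples.size}")
    picks = channel_picks if channel_picks is not None else np.arange(recording.data.shape[0])
    half = int(round(half_width_ms * recording.sfreq / 1000.0))
    segs = []
    for s in seed_event_samples[:n_seed]:
        seg = _extract(recording.data[picks], int(s), half, half)
        if seg is not None:
            segs.append(seg)
    if not segs:
        raise InputError("no seed event yields a full window")
    return np.mean(segs, axis=0)


def detect_spikes(
    recording: ContinuousRecording,
    template: np.ndarray,
    correlation_threshold: float = 0.8,
    channel_picks: np.ndarray | None = None,
    refractory_ms: float = 200.0,
) -> np.ndarray:
    """Event samples where the normalized sliding correlation peaks above threshold.

    The correlation is computed jointly over the detection channels (the
    template and each data window are compared as flattened vectors), is
    invariant to amplitude scaling, and a refractory lockout suppresses
    secondary maxima closer than ``refractory_ms``.
    """
    template = np.atleast_2d(np.asarray(template, float))
    if template.size == 0:
        raise ConfigurationError("empty template")
    if not 0 < correlation_threshold <= 1:
        raise ConfigurationError("threshold must lie in (0, 1]")
    picks = channel_picks if channel_picks is not None else np.arange(recording.data.shape[0])
    data = recording.data[picks]
    n_ch, n_t = template.shape
    if n_t >= data.shape[1]:
        raise ConfigurationError("template longer than recording")
    if data.shape[0] != n_ch:
        raise ConfigurationError("template channel count does not match picks")
    tc = template - template.mean()
    tnorm = np.linalg.norm(tc)
    if tnorm == 0:
        raise ConfigurationError("template has zero variance")
    # numerator: sum over channels of valid-mode cross-correlation
    num = np.zeros(data.shape[1] - n_t + 1)
    for c in range(n_ch):
        num += np.correlate(data[c], tc[c], mode="valid")
    # denominator: sliding L2 norm of the (mean-corrected) data windows
    sq = np.sum(data**2, axis=0)
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    win_energy = csum[n_t:] - csum[:-n_t]
    tot = np.sum(data, axis=0)
    csum1 = np.concatenate([[0.0], np.cumsum(tot)])
    win_sum = csum1[n_t:] - csum1[:-n_t]
    win_energy = win_energy - win_sum**2 / (n_ch * n_t)
    denom = np.sqrt(np.clip(win_energy, 1e-30, None)) * tnorm
    corr = num / denom
    lockout = int(round(refractory_ms * recording.sfreq / 1000.0))
    peaks, _ = sp_signal.find_peaks(corr, height=correlation_threshold, distance=max(1, lockout))
    centers = peaks + n_t // 2
    return np.sort(centers)


def align_to_eeg_peak(
    recording: ContinuousRecording, event_samples, search_ms: float = 60.0
) -> np.ndarray:
    """Shift each event to the local EEG global-field-power maximum.

    Defines 'spike peak' channel-independently: the sample of maximal spatial
    variance across EEG channels within ±``search_ms`` of the detection.
    """
    eeg = recording.data[recording.picks("eeg")]
    gfp = eeg.var(axis=0)
    half = int(round(search_ms * recording.sfreq / 1000.0))
    out = []
    for s in np.asarray(event_samples, int):
        lo, hi = max(0, s - half), min(recording.n_samples, s + half + 1)
        out.append(lo + int(np.argmax(gfp[lo:hi])))
    return np.asarray(out, int)


def epoch_around(recording: ContinuousRecording, peak_samples) -> list:
    """Cut 400 ms epochs (−200…+200 ms) around each EEG spike peak."""
    before = int(round(-EPOCH_MS[0] * recording.sfreq / 1000.0))
    after = int(round(EPOCH_MS[1] * recording.sfreq / 1000.0))
    epochs = []
    for i, p in enumerate(np.asarray(peak_samples, int)):
        seg = _extract(recording.data, p, before, after)
        if seg is None:
            continue
        epochs.append(
            Epoch(
                data=seg.copy(),
                sfreq=recording.sfreq,
                channel_kinds=list(recording.channel_kinds),
                spike_ids=[i],
            )
        )
    return epochs


def compute_snr(epoch: Epoch, time_ms: float, channel_picks, modality: str = "eeg") -> SNRRecord:
    """Power SNR at one time point against the −200…−70 ms baseline."""
    picks = np.asarray(channel_picks, int)
    if picks.size == 0:
        raise ConfigurationError("empty channel set")
    s = epoch.sample_at(time_ms)
    b0 = epoch.sample_at(BASELINE_MS[0])
    b1 = epoch.sample_at(BASELINE_MS[1])
    sub = epoch.data[picks]
    signal_power = float(np.mean(sub[:, s] ** 2))
    noise_var = float(np.mean(np.var(sub[:, b0:b1], axis=1)))
    if noise_var == 0:
        raise InputError("zero baseline variance; SNR undefined")
    return SNRRecord(value=signal_power / noise_var, time_ms=time_ms, modality=modality)


def make_subaverages(epochs: list, spec: SubaverageSpec) -> dict:
    """Bootstrap subaverage realizations per group size.

    Av1 is the identity list of single epochs; for k > 1 each realization
    averages k distinct randomly drawn epochs (no repeats within one
    realization; repeats across realizations are allowed).  Deterministic for
    a fixed spec seed: realization r of group k uses a counter-derived
    sub-seed.
    """
    n = len(epochs)
    if n == 0:
        raise InputError("no epochs to subaverage")
    out: dict[int, list] = {}
    for k in spec.group_sizes:
        if k > n:
            raise ConfigurationError(f"group size {k} exceeds {n} epochs")
        reals = []
        if k == 1:
            for i, ep in enumerate(epochs):
                reals.append(SubaverageRealization(1, np.array([i]), ep))
        else:
            for r in range(spec.realizations_per_group):
                rng = np.random.default_rng((spec.seed, k, r))
                idx = rng.choice(n, size=k, replace=False)
                avg = np.mean([epochs[i].data for i in idx], axis=0)
                ep = Epoch(
                    data=avg,
                    sfreq=epochs[0].sfreq,
                    channel_kinds=list(epochs[0].channel_kinds),
                    spike_ids=sorted(int(i) for i in idx),
                )
                reals.append(SubaverageRealization(k, idx, ep))
        out[k] = reals
    return out


def snr_gate(
    realizations: list,
    channel_picks,
    time_ms: float,
    threshold: float = 3.0,
    modality: str = "eeg",
) -> list:
    """Keep realizations whose SNR at ``time_ms`` is strictly above threshold.

    Returns ``(realization, SNRRecord)`` pairs for the survivors.
    """
    if threshold <= 0:
        raise ConfigurationError("threshold must be positive")
    out = []
    for real in realizations:
        rec = compute_snr(real.epoch, time_ms, channel_picks, modality)
        if rec.value > threshold:
            out.append((real, rec))
    return out
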