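"""Preprocessing of multichannel intracranial EEG recordings.

Turns raw depth-electrode (SEEG) traces into clean, z-scored, band-limited
interictal segments:

* a zero-phase frequency-domain band-pass filter (pass band 5–50 Hz, stops at
  DC and 60 Hz, raised-cosine upper transition) that removes mains noise and
  slow drift while leaving the physiological band untouched;
* per-channel z-scoring, so amplitudes are in standard-deviation units;
* hard amplitude clipping of residual interictal spikes at ±k SD;
* selection of non-overlapping interictal segments that end at least 30
  minutes before the first annotated seizure and dodge spike-dense stretches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "REGIONS",
    "ChannelInfo",
    "Recording",
    "SegmentWindow",
    "FilterSpec",
    "FlatChannelError",
    "SegmentSelectionError",
    "UnknownRegionError",
    "amplitude_response",
    "bandpass_filter",
    "zscore_channels",
    "clip_artifacts",
    "select_segments",
    "preprocess_segment",
]

#: The 9-region temporal-lobe parcellation used as channel labels:
#: hippocampus head/tail, amygdala, superior/middle/inferior temporal gyri,
#: fusiform gyrus, parahippocampal gyrus, temporal pole.
REGIONS = ("HH", "HT", "A", "STG", "MTG", "ITG", "FG", "PHG", "TP")


class UnknownRegionError(ValueError):
    """Raised when a channel carries a region label outside the 9-label scheme."""

    def __init__(self, region: str):
        super().__init__(
            f"unknown region label {region!r}; valid labels are {', '.join(REGIONS)}"
        )
        self.region = region


class FlatChannelError(ValueError):
    """Raised when a zero-variance channel makes z-scoring undefined."""


class SegmentSelectionError(ValueError):
    """Raised when a recording cannot accommodate the requested segments."""


@dataclass(frozen=True)
class ChannelInfo:
    """One electrode contact: its identifier and anatomical region."""

    contact_id: str
    region: str

    def __post_init__(self):
        if self.region not in REGIONS:
            raise UnknownRegionError(self.region)


@dataclass
class Recording:
    """A multichannel intracranial EEG recording.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal traces, arbitrary amplitude units.
    sampling_rate : float
        Sampling rate in Hz.
    channels : list of ChannelInfo
        Per-channel contact id and region label.
    seizure_onsets : list of int
        Ascending sample indices of annotated seizure onsets (may be empty).
    patient_id, outcome
        Optional provenance carried along for cohort-level analyses;
        ``outcome=True`` means seizure freedom after surgery.
    """

    samples: np.ndarray
    sampling_rate: float
    channels: list[ChannelInfo]
    seizure_onsets: list[int] = field(default_factory=list)
    patient_id: str | None = None
    outcome: bool | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (n_channels, n_samples) array")
        n_ch, n_samp = self.samples.shape
        if n_ch < 2:
            raise ValueError("a recording needs at least 2 channels")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channels) != n_ch:
            raise ValueError(
                f"{len(self.channels)} channel descriptions for {n_ch} signal rows"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain NaN or Inf")
        onsets = list(self.seizure_onsets)
        if any(not (0 <= o < n_samp) for o in onsets):
            raise ValueError("seizure onset index outside the recording")
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("seizure onsets must be strictly ascending")
        self.seizure_onsets = onsets

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def contact_ids(self) -> list[str]:
        return [c.contact_id for c in self.channels]


@dataclass(frozen=True)
class SegmentWindow:
    """Half-open sample-index window [start, end)."""

    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid window [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FilterSpec:
    """Amplitude response of the interictal band-pass filter.

    Gain is 0 at DC and below ``pass_low``, 1 on [``pass_low``, ``pass_high``],
    follows a raised cosine from 1 to 0 on (``pass_high``, ``stop_high``), and
    is 0 at and above ``stop_high``.  Defaults give the 5–50 Hz pass band with
    stops at 0 and 60 Hz.
    """

    pass_low: float = 5.0
    pass_high: float = 50.0
    stop_high: float = 60.0

    def validate(self, sampling_rate: float) -> None:
        if not (0.0 < self.pass_low < self.pass_high < self.stop_high):
            raise ValueError(
                f"need 0 < pass_low < pass_high < stop_high, got "
                f"({self.pass_low}, {self.pass_high}, {self.stop_high})"
            )
        if self.stop_high >= sampling_rate / 2.0:
            raise ValueError(
                f"stop_high={self.stop_high} Hz not below the Nyquist frequency "
                f"{sampling_rate / 2.0} Hz"
            )


def amplitude_response(freqs: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Real, non-negative filter gain evaluated at frequencies ``freqs`` (Hz)."""
    f = np.asarray(freqs, dtype=float)
    h = np.zeros_like(f)
    h[(f >= spec.pass_low) & (f <= spec.pass_high)] = 1.0
    trans = (f > spec.pass_high) & (f < spec.stop_high)
    h[trans] = 0.5 * (
        1.0 + np.cos(np.pi * (f[trans] - spec.pass_high) / (spec.stop_high - spec.pass_high))
    )
    return h


def bandpass_filter(
    samples: np.ndarray,
    sampling_rate: float,
    filter_spec: FilterSpec | None = None,
) -> np.ndarray:
    """Zero-phase frequency-domain band-pass filter, applied per channel.

    The whole segment is Fourier transformed, multiplied by the purely real
    amplitude response of ``filter_spec``, and transformed back.  A real
    response means no phase distortion; a zeroed DC bin means the output is
    exactly zero-mean per channel.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples) or (n_samples,)
    sampling_rate : float, Hz
    filter_spec : FilterSpec, optional

    Raises
    ------
    ValueError
        If the segment is shorter than 2 s (the 5 Hz edge would not be
        resolvable) or ``filter_spec`` is inconsistent with the sampling rate.
    """
    spec = filter_spec or FilterSpec()
    spec.validate(sampling_rate)
    x = np.asarray(samples, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    n = x.shape[1]
    if n < 2 * sampling_rate:
        raise ValueError(
            f"segment of {n} samples is shorter than 2 s at {sampling_rate} Hz; "
            "the lower band edge cannot be resolved"
        )
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    h = amplitude_response(freqs, spec)
    y = np.fft.irfft(np.fft.rfft(x, axis=1) * h, n=n, axis=1)
    return y[0] if squeeze else y


def zscore_channels(
    samples: np.ndarray, contact_ids: Sequence[str] | None = None
) -> np.ndarray:
    """Z-score each channel to mean 0 and SD 1 (population SD).

    Raises
    ------
    FlatChannelError
        Naming the offending contact (or row index) if a channel has zero
        variance.
    """
    x = np.asarray(samples, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0.0)
    if flat.size:
        names = [
            contact_ids[i] if contact_ids is not None else f"channel {i}" for i in flat
        ]
        raise FlatChannelError(f"zero-variance channel(s): {', '.join(map(str, names))}")
    z = (x - mu) / sd
    return z[0] if squeeze else z


def clip_artifacts(zscored_samples: np.ndarray, threshold_k: float = 5.0) -> np.ndarray:
    """Hard-limit z-scored samples to ±``threshold_k`` standard deviations.

    The most literal reading of spike "clipping": values inside the bounds are
    untouched, values beyond are set to the bound with sign preserved.  The
    operation is idempotent.
    """
    if threshold_k <= 0:
        raise ValueError("threshold_k must be positive")
    return np.clip(np.asarray(zscored_samples, dtype=float), -threshold_k, threshold_k)


def _window_density(cumsum: np.ndarray, start: int, end: int) -> float:
    return float(cumsum[end] - cumsum[start]) / (end - start)


def select_segments(
    recording: Recording,
    n_segments: int = 3,
    segment_duration: float = 90.0,
    preictal_exclusion_s: float = 1800.0,
    threshold_k: float = 5.0,
    max_spike_density: float = 0.01,
) -> list[SegmentWindow]:
    """Pick non-overlapping interictal windows before the first seizure.

    The eligible span runs from the start of the recording to
    ``preictal_exclusion_s`` seconds (default 30 minutes) before the first
    annotated seizure onset — or the whole recording if no seizure is
    annotated.  The span is divided into ``n_segments`` equal slots and one
    window of nominally ``segment_duration`` seconds is placed in each, as
    centred as possible; within a slot the placement (and, if necessary, the
    length, down to 80% of nominal) is adjusted to minimise spike density,
    the fraction of samples whose per-channel z-score magnitude exceeds
    ``threshold_k`` on any channel.

    Raises
    ------
    SegmentSelectionError
        If the eligible span is shorter than ``n_segments × 0.8 ×
        segment_duration``, reporting the available span.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be ≥ 1")
    fs = recording.sampling_rate
    n_total = recording.n_samples
    if recording.seizure_onsets:
        eligible_end = recording.seizure_onsets[0] - int(round(preictal_exclusion_s * fs))
    else:
        eligible_end = n_total
    nominal = int(round(segment_duration * fs))
    min_len = int(math.ceil(0.8 * nominal))
    if eligible_end < n_segments * min_len:
        avail = max(eligible_end, 0) / fs
        raise SegmentSelectionError(
            f"eligible interictal span is {avail:.1f} s; need at least "
            f"{n_segments * min_len / fs:.1f} s for {n_segments} segments of "
            f"≥ {min_len / fs:.1f} s"
        )

    seg = recording.samples[:, :eligible_end]
    sd = seg.std(axis=1, keepdims=True)
    sd[sd == 0.0] = 1.0  # flat channels carry no spikes; caught later by z-scoring
    z = np.abs(seg - seg.mean(axis=1, keepdims=True)) / sd
    spikey = (z > threshold_k).any(axis=0)
    csum = np.concatenate([[0.0], np.cumsum(spikey, dtype=float)])

    windows: list[SegmentWindow] = []
    slot = eligible_end / n_segments
    for i in range(n_segments):
        s0 = int(round(i * slot))
        s1 = int(round((i + 1) * slot))
        width = min(nominal, s1 - s0)
        starts = np.unique(
            np.linspace(s0, s1 - width, num=33).round().astype(int)
        )
        dens = np.array([_window_density(csum, a, a + width) for a in starts])
        centred = s0 + (s1 - s0 - width) // 2
        near_best = starts[dens <= dens.min() + 1e-12]
        start = int(near_best[np.argmin(np.abs(near_best - centred))])
        end = start + width
        best = (start, end, _window_density(csum, start, end))
        if best[2] > max_spike_density and width > min_len:
            # shrink from either end, in small steps, to dodge spike bursts
            step = max(1, nominal // 100)
            for new_w in range(width - step, min_len - 1, -step):
                for a in (start, end - new_w):
                    d = _window_density(csum, a, a + new_w)
                    if d < best[2]:
                        best = (a, a + new_w, d)
                if best[2] <= max_spike_density:
                    break
        windows.append(SegmentWindow(best[0], best[1]))
    return windows


def preprocess_segment(
    recording: Recording,
    window: SegmentWindow,
    filter_spec: FilterSpec | None = None,
    threshold_k: float = 5.0,
) -> np.ndarray:
    """Extract a window and run the full cleaning chain.

    Stages: extract → band-pass filter → z-score → clip at ±k SD → re-z-score
    (so clipping cannot leave SD < 1).  Returns a channels × window-length
    array in standard-deviation units.
    """
    if window.end > recording.n_samples:
        raise ValueError("window extends past the end of the recording")
    x = recording.samples[:, window.start : window.end]
    x = bandpass_filter(x, recording.sampling_rate, filter_spec)
    ids = recording.contact_ids
    x = zscore_channels(x, ids)
    x = clip_artifacts(x, threshold_k)
    return zscore_channels(x, ids)
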