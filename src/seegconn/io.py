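"""On-disk formats: recording bundles (CSV signal + JSON sidecar) and EDF.

The canonical exchange format is a human-readable, diffable pair of files:
``<stem>.signal.csv`` holding the channels × samples matrix (one row per
channel, no header) and ``<stem>.meta.json`` holding the sidecar metadata
(sampling rate, contact ids, region labels, seizure onset sample indices,
patient id and outcome).  Sample indices are 0-based and times are expressed
in samples so that no rounding drifts across the supported sampling rates.
European Data Format ingestion is optional and backed by MNE.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preprocessing import REGIONS, ChannelInfo, Recording

__all__ = [
    "BundleValidationError",
    "ChannelCountMismatchError",
    "UnmappedChannelError",
    "MixedSamplingRateError",
    "write_recording_bundle",
    "read_recording_bundle",
    "read_edf",
]


class BundleValidationError(ValueError):
    """A recording bundle's files are missing or mutually inconsistent."""


class ChannelCountMismatchError(BundleValidationError):
    """Sidecar channel count does not match the signal matrix."""


class UnmappedChannelError(ValueError):
    """An EDF channel has no entry in the channel→region map."""


class MixedSamplingRateError(ValueError):
    """An EDF file records channels at different sampling rates."""


def write_recording_bundle(recording: Recording, stem: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>.signal.csv`` and ``<stem>.meta.json``; returns both paths."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    signal_path = stem.with_suffix(".signal.csv")
    meta_path = stem.with_suffix(".meta.json")
    # %.17g makes the text round-trip bit-exact for float64
    np.savetxt(signal_path, recording.samples, delimiter=",", fmt="%.17g")
    meta = {
        "sampling_rate_hz": recording.sampling_rate,
        "contacts": [
            {"contact_id": c.contact_id, "region": c.region} for c in recording.channels
        ],
        "seizure_onset_samples": list(recording.seizure_onsets),
        "patient_id": recording.patient_id,
        "outcome": recording.outcome,
        "signal_file": signal_path.name,
    }
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return signal_path, meta_path


def read_recording_bundle(meta_path: str | Path) -> Recording:
    """Load and validate a recording bundle from its sidecar path.

    Raises
    ------
    ChannelCountMismatchError
        If the sidecar's channel count differs from the signal row count.
    UnknownRegionError
        If a region label is outside the 9-label parcellation.
    BundleValidationError
        For missing files or non-finite samples.
    """
    meta_path = Path(meta_path)
    if not meta_path.exists():
        raise BundleValidationError(f"sidecar not found: {meta_path}")
    meta = json.loads(meta_path.read_text())
    signal_path = meta_path.parent / meta["signal_file"]
    if not signal_path.exists():
        raise BundleValidationError(f"signal file not found: {signal_path}")
    samples = np.loadtxt(signal_path, delimiter=",", ndmin=2)
    contacts = meta["contacts"]
    if len(contacts) != samples.shape[0]:
        raise ChannelCountMismatchError(
            f"sidecar lists {len(contacts)} channels but the signal file has "
            f"{samples.shape[0]} rows"
        )
    channels = [ChannelInfo(c["contact_id"], c["region"]) for c in contacts]
    if not np.all(np.isfinite(samples)):
        raise BundleValidationError("signal file contains NaN or Inf samples")
    return Recording(
        samples=samples,
        sampling_rate=float(meta["sampling_rate_hz"]),
        channels=channels,
        seizure_onsets=[int(i) for i in meta["seizure_onset_samples"]],
        patient_id=meta.get("patient_id"),
        outcome=meta.get("outcome"),
    )


def _edf_channel_rates(path: Path) -> dict[str, float]:
    """Per-channel sampling rates read directly from the EDF header.

    MNE silently resamples mixed-rate files, so uniformity is checked here
    before loading.
    """
    with open(path, "rb") as f:
        header = f.read(256)
        duration = float(header[244:252].decode("ascii").strip())
        ns = int(header[252:256].decode("ascii").strip())
        sig = f.read(ns * 256)
    labels = [
        sig[16 * i : 16 * (i + 1)].decode("ascii").strip() for i in range(ns)
    ]
    offset = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    nsamp = [
        int(sig[offset + 8 * i : offset + 8 * (i + 1)].decode("ascii").strip())
        for i in range(ns)
    ]
    return {lab: n / duration for lab, n in zip(labels, nsamp) if lab.upper() != "EDF ANNOTATIONS"}


def read_edf(path: str | Path, channel_region_map: dict[str, str]) -> Recording:
    """Read a European Data Format file into a Recording.

    Every signal channel in the file must appear in ``channel_region_map``
    (channel name → region label); channels are loaded in file order.

    Raises
    ------
    UnmappedChannelError
        If the file contains a channel absent from the map.
    MixedSamplingRateError
        If channels are stored at different sampling rates.
    """
    import mne

    path = Path(path)
    rates = _edf_channel_rates(path)
    unmapped = [ch for ch in rates if ch not in channel_region_map]
    if unmapped:
        raise UnmappedChannelError(
            f"channels with no region mapping: {', '.join(unmapped)}"
        )
    if len(set(rates.values())) > 1:
        raise MixedSamplingRateError(
            f"per-channel sampling rates differ: {sorted(set(rates.values()))}"
        )
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    channels = [
        ChannelInfo(ch, channel_region_map[ch]) for ch in raw.ch_names
    ]
    return Recording(
        samples=raw.get_data(),
        sampling_rate=float(raw.info["sfreq"]),
        channels=channels,
    )
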