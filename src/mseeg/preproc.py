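"""Reading, filtering, referencing and segmenting multichannel EEG.

The pipeline operates on :class:`Recording` objects — a channels x samples
amplitude matrix in microvolts with a sampling rate and channel labels.
Preprocessing here is deliberately simple and fully automatic: a zero-phase
Butterworth band-pass, average referencing, artifact-scored segment
selection, fixed-length epoching, and the 22-region scalp parcellation used
for region-level statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal

from ._edf import read_edf

__all__ = [
    "BANDS",
    "ANALYSIS_BAND_NAMES",
    "Recording",
    "RegionScheme",
    "EpochSet",
    "read_recording",
    "bandpass",
    "average_reference",
    "select_clean_segments",
    "make_epochs",
    "build_region_scheme",
    "default_region_scheme",
    "REGION_BASES",
]

# Named frequency bands (Hz, half-open [lo, hi) for power integration).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha1": (8.0, 10.0),
    "alpha2": (10.0, 13.0),
    "beta": (13.0, 30.0),
    "broadband": (0.5, 70.0),
}

#: The five bands entering relative-power analysis; they tile [1, 30) Hz.
ANALYSIS_BAND_NAMES = ("delta", "theta", "alpha1", "alpha2", "beta")

#: Base names of the 11 regions per hemisphere: frontal-polar, frontal
#: midline/lateral, central midline/lateral, temporal anterior/posterior,
#: parietal lateral/midline, parieto-occipital and occipital.
REGION_BASES = ("FP", "FM", "FL", "CM", "CL", "TA", "TP", "PL", "PM", "PO", "O")


@dataclass
class Recording:
    """Channels x samples EEG amplitude matrix (microvolts)."""

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)
    reference: str = "original"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class RegionScheme:
    """Partition of scalp channels into 22 regions (11 per hemisphere)."""

    region_labels: list[str]
    channel_to_region: dict[str, str]
    excluded_channels: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.region_labels) != 22:
            raise ValueError(f"expected 22 regions, got {len(self.region_labels)}")
        per_hemi = {"L": 0, "R": 0}
        for name in self.region_labels:
            hemi = name.rsplit("_", 1)[-1]
            if hemi not in per_hemi:
                raise ValueError(f"region {name!r} lacks an _L/_R hemisphere suffix")
            per_hemi[hemi] += 1
        if per_hemi["L"] != 11 or per_hemi["R"] != 11:
            raise ValueError(f"need 11 regions per hemisphere, got {per_hemi}")
        overlap = self.excluded_channels & set(self.channel_to_region)
        if overlap:
            raise ValueError(f"channels both excluded and region-mapped: {sorted(overlap)}")
        bad = set(self.channel_to_region.values()) - set(self.region_labels)
        if bad:
            raise ValueError(f"channels map to unknown regions: {sorted(bad)}")

    def region_channels(self, region: str) -> list[str]:
        return [c for c, r in self.channel_to_region.items() if r == region]

    def validate_channels(self, channel_labels: list[str]) -> None:
        """Every non-excluded channel must map to exactly one region."""
        unmapped = [
            c
            for c in channel_labels
            if c not in self.excluded_channels and c not in self.channel_to_region
        ]
        if unmapped:
            raise ValueError(f"unmapped non-excluded channels: {unmapped}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "region_labels": self.region_labels,
            "channel_to_region": self.channel_to_region,
            "excluded_channels": sorted(self.excluded_channels),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionScheme":
        payload = json.loads(Path(path).read_text())
        return cls(
            region_labels=list(payload["region_labels"]),
            channel_to_region=dict(payload["channel_to_region"]),
            excluded_channels=set(payload.get("excluded_channels", [])),
        )


@dataclass
class EpochSet:
    """Equal-length, non-overlapping channels x samples blocks."""

    epochs: np.ndarray  # (n_epochs, n_channels, n_samples)
    epoch_length: float  # seconds
    sampling_rate: float
    channel_labels: list[str]
    offsets: list[int] = field(default_factory=list)  # sample offsets in source

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


# ---------------------------------------------------------------------------
# Reading


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read an EDF file or a delimited channels x samples matrix.

    Delimited matrices require a JSON sidecar ``<path>.json`` with at least
    ``sampling_rate`` and optionally ``channel_labels``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        data, fs, labels = read_edf(path)
        rec = Recording(data=data, sampling_rate=fs, channel_labels=labels)
    elif format == "delimited":
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"missing sidecar {sidecar} (sampling_rate required)")
        meta = json.loads(sidecar.read_text())
        data = np.loadtxt(path, delimiter=meta.get("delimiter"))
        data = np.atleast_2d(data)
        labels = meta.get("channel_labels") or []
        rec = Recording(data=data, sampling_rate=float(meta["sampling_rate"]),
                        channel_labels=list(labels))
    else:
        raise ValueError(f"unknown format {format!r}")
    bad = [rec.channel_labels[i] for i in np.flatnonzero(~np.isfinite(rec.data).all(axis=1))]
    if bad:
        raise ValueError(f"non-finite samples in channel(s): {bad}")
    return rec


# ---------------------------------------------------------------------------
# Filtering and referencing


def _band_edges(band: str | tuple[float, float]) -> tuple[float, float]:
    if isinstance(band, str):
        try:
            return BANDS[band]
        except KeyError:
            raise ValueError(f"unknown band {band!r}; known: {sorted(BANDS)}") from None
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError(f"invalid band edges ({lo}, {hi})")
    return float(lo), float(hi)


def bandpass(recording: Recording, band: str | tuple[float, float], order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass (applied forward-backward).

    Zero-phase filtering preserves the inter-channel phase relations that
    the phase-lag index downstream depends on.
    """
    lo, hi = _band_edges(band)
    nyq = recording.sampling_rate / 2.0
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=recording.sampling_rate,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, recording.data, axis=1)
    return replace(recording, data=filtered)


def average_reference(recording: Recording) -> Recording:
    """Re-reference to the instantaneous mean over channels."""
    if recording.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = recording.data - recording.data.mean(axis=0, keepdims=True)
    return replace(recording, data=data, reference="average")


# ---------------------------------------------------------------------------
# Segment selection and epoching


def select_clean_segments(
    recording: Recording,
    min_total: float = 180.0,
    seg_bounds: tuple[float, float] = (25.0, 200.0),
    z_threshold: float = 5.0,
) -> Recording:
    """Concatenate the lowest-artifact segments into >= ``min_total`` seconds.

    The recording is tiled into candidate segments of ``seg_bounds[0]``
    seconds.  Each segment's artifact score is the 95th percentile of
    per-channel robustly z-scored absolute amplitude (median/MAD, so the
    scale is not inflated by the artifacts themselves), maximised over
    channels — a simple stand-in for visual artifact marking that flags
    high-amplitude bursts.  Segments scoring above ``z_threshold`` are
    rejected; the lowest-scoring survivors are kept (in temporal order)
    until the total reaches ``min_total``.
    """
    if recording.duration <= min_total:
        raise ValueError(
            f"recording of {recording.duration:.1f} s cannot yield {min_total:.0f} s"
        )
    fs = recording.sampling_rate
    seg_len = int(round(seg_bounds[0] * fs))
    n_seg = recording.n_samples // seg_len
    med = np.median(recording.data, axis=1, keepdims=True)
    mad = np.median(np.abs(recording.data - med), axis=1, keepdims=True)
    sd = 1.4826 * mad  # Gaussian-consistent robust scale
    sd[sd == 0] = 1.0
    z = np.abs((recording.data - med) / sd)
    scores = np.empty(n_seg)
    for s in range(n_seg):
        block = z[:, s * seg_len:(s + 1) * seg_len]
        scores[s] = np.percentile(block, 95, axis=1).max()
    ok = scores <= z_threshold
    rejected = [
        (s * seg_len / fs, (s + 1) * seg_len / fs) for s in np.flatnonzero(~ok)
    ]
    need = int(round(min_total * fs))
    order = np.argsort(scores[ok], kind="stable")
    idx_ok = np.flatnonzero(ok)[order]
    chosen: list[int] = []
    total = 0
    for s in idx_ok:
        chosen.append(int(s))
        total += seg_len
        if total >= need:
            break
    if total < need:
        raise ValueError(
            f"only {total / fs:.1f} s of clean data (< {min_total:.0f} s); "
            f"rejected spans (s): {[(round(a, 1), round(b, 1)) for a, b in rejected]}"
        )
    chosen.sort()
    data = np.concatenate(
        [recording.data[:, s * seg_len:(s + 1) * seg_len] for s in chosen], axis=1
    )
    return replace(recording, data=data)


def make_epochs(recording: Recording, n: int = 12, length: float = 4.0) -> EpochSet:
    """Cut the earliest ``n`` non-overlapping epochs of ``length`` seconds."""
    fs = recording.sampling_rate
    samp = int(round(length * fs))
    if n * samp > recording.n_samples:
        raise ValueError(
            f"recording of {recording.n_samples} samples too short for "
            f"{n} epochs of {samp} samples"
        )
    epochs = np.stack(
        [recording.data[:, k * samp:(k + 1) * samp] for k in range(n)], axis=0
    )
    return EpochSet(
        epochs=epochs,
        epoch_length=length,
        sampling_rate=fs,
        channel_labels=list(recording.channel_labels),
        offsets=[k * samp for k in range(n)],
    )


# ---------------------------------------------------------------------------
# Region scheme


def default_region_scheme() -> RegionScheme:
    """Bundled 214-channel scheme: 170 channels in 22 regions of 7-8.

    Channels E1..E170 are assigned in blocks to the 22 regions (the first 16
    regions get 8 channels, the rest 7); E171..E214 stand for the midline,
    face and neck electrodes excluded from region analysis.
    """
    regions = [f"{base}_{hemi}" for base in REGION_BASES for hemi in ("L", "R")]
    sizes = [8] * 16 + [7] * 6
    mapping: dict[str, str] = {}
    ch = 1
    for region, size in zip(regions, sizes):
        for _ in range(size):
            mapping[f"E{ch}"] = region
            ch += 1
    excluded = {f"E{i}" for i in range(ch, 215)}
    return RegionScheme(region_labels=regions, channel_to_region=mapping,
                        excluded_channels=excluded)


def build_region_scheme(montage_spec=None) -> RegionScheme:
    """Build a :class:`RegionScheme` from a montage specification.

    ``montage_spec`` may be ``None``/``"default"`` for the bundled
    214-channel scheme, a path to a region-scheme JSON, or a mapping
    ``{region: [channel, ...]}`` with an optional ``"excluded"`` entry.
    """
    if montage_spec is None or montage_spec == "default":
        return default_region_scheme()
    if isinstance(montage_spec, (str, Path)):
        return RegionScheme.from_json(montage_spec)
    spec = dict(montage_spec)
    excluded = set(spec.pop("excluded", []))
    mapping: dict[str, str] = {}
    for region, channels in spec.items():
        for c in channels:
            if c in mapping:
                raise ValueError(f"channel {c!r} assigned to multiple regions")
            mapping[c] = region
    return RegionScheme(region_labels=list(spec), channel_to_region=mapping,
                        excluded_channels=excluded)
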