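"""Phase-lag-index (PLI) connectivity, standard and microstate-segmented.

The PLI between two signals is the asymmetry of their phase-difference
distribution,

    PLI = (1/k) | sum_i sign[ sin(dPhi(i)) ] |,

which is 0 for perfectly synchronous (zero-lag) coupling — making it robust
against volume conduction — and 1 for a constant nonzero lag.

Two estimation routes are provided:

* ``pli_standard`` — per-epoch Hilbert phases on 12 epochs of 4 s, one PLI
  matrix per epoch, averaged;
* ``mspli`` — phases from a sliding-window Hilbert transform of the
  full-length band-filtered recording; for every microstate class the
  phase samples carrying that class's label are stitched in temporal
  order, cut into 4 periods of 4000 samples, a PLI matrix is computed per
  period, and the class and subject averages are formed (20 matrices for
  5 classes).  Restricting estimation to one microstate's time frames
  isolates the subnetwork active in that state.

Channel-space matrices can be reduced to the 22-region scheme by averaging
all electrode pairs spanning two regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert
from scipy.signal.windows import hann

from .preproc import EpochSet, Recording, RegionScheme, bandpass

__all__ = [
    "PhaseSeries",
    "ConnectivityMatrix",
    "instantaneous_phase",
    "pli",
    "pli_matrix",
    "pli_standard",
    "mspli",
    "reduce_to_regions",
]


@dataclass
class PhaseSeries:
    """Per-channel instantaneous phase (radians, wrapped to (-pi, pi])."""

    phases: np.ndarray  # (n_channels, n_samples)
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)


@dataclass
class ConnectivityMatrix:
    """Symmetric, zero-diagonal weight matrix with entries in [0, 1]."""

    weights: np.ndarray
    band: str
    scope: str = "global"  # "global" or "microstate:<c>"
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.abs(np.diag(w)).max() > 1e-12:
            raise ValueError("diagonal must be zero")
        if w.min() < -1e-12 or w.max() > 1 + 1e-12:
            raise ValueError("weights must lie in [0, 1]")
        self.weights = w
        if not self.node_labels:
            self.node_labels = [f"ch{i:02d}" for i in range(w.shape[0])]


# ---------------------------------------------------------------------------
# Phase extraction


def instantaneous_phase(
    band_filtered_recording: Recording,
    window: float = 4.0,
) -> PhaseSeries:
    """Sliding-window Hilbert phases of the full-length recording.

    Windows of ``window`` seconds advance in half-window steps and are
    Hanning-tapered; each output sample is taken from the central half of
    its window, where the taper is flattest, except at the recording edges
    where the outer halves of the first/last windows are used.
    """
    rec = band_filtered_recording
    n = rec.n_samples
    win = int(round(window * rec.sampling_rate))
    if n < win:
        raise ValueError(f"recording of {n} samples shorter than one {win}-sample window")
    step = win // 2
    starts = list(range(0, n - win + 1, step))
    if starts[-1] != n - win:
        starts.append(n - win)
    taper = hann(win)
    q = win // 4
    phases = np.empty_like(rec.data)
    for idx, s in enumerate(starts):
        analytic = hilbert(rec.data[:, s:s + win] * taper, axis=1)
        ph = np.angle(analytic)
        lo = 0 if idx == 0 else q
        hi = win if idx == len(starts) - 1 else win - q
        phases[:, s + lo:s + hi] = ph[:, lo:hi]
    return PhaseSeries(phases=phases, sampling_rate=rec.sampling_rate,
                       channel_labels=list(rec.channel_labels))


# ---------------------------------------------------------------------------
# PLI


def pli(delta_phi_samples: np.ndarray) -> float:
    """PLI = (1/k) |sum sign(sin dPhi)|; sign(0) counts as 0."""
    dphi = np.asarray(delta_phi_samples, dtype=float)
    if dphi.size == 0:
        raise ValueError("empty phase-difference series")
    return float(np.abs(np.sum(np.sign(np.sin(dphi)))) / dphi.size)


def pli_matrix(phases: np.ndarray) -> np.ndarray:
    """Pairwise PLI of a (n_channels, k) phase array."""
    n_ch, k = phases.shape
    w = np.zeros((n_ch, n_ch))
    for i in range(n_ch - 1):
        s = np.sign(np.sin(phases[i + 1:] - phases[i]))
        w[i, i + 1:] = np.abs(s.sum(axis=1)) / k
    return w + w.T


def pli_standard(
    epoch_set: EpochSet, band: str, n_epochs: int = 12
) -> ConnectivityMatrix:
    """Standard PLI: per-epoch Hilbert phases, one matrix per epoch, averaged.

    Each epoch is band-filtered before phase extraction.
    """
    if epoch_set.n_epochs < n_epochs:
        raise ValueError(f"{epoch_set.n_epochs} epochs < required {n_epochs}")
    mats = []
    for e in range(n_epochs):
        rec = Recording(data=epoch_set.epochs[e],
                        sampling_rate=epoch_set.sampling_rate,
                        channel_labels=list(epoch_set.channel_labels))
        filtered = bandpass(rec, band)
        phases = np.angle(hilbert(filtered.data, axis=1))
        mats.append(pli_matrix(phases))
    return ConnectivityMatrix(weights=np.mean(mats, axis=0), band=band,
                              scope="global",
                              node_labels=list(epoch_set.channel_labels))


def mspli(
    recording: Recording,
    labels: np.ndarray,
    band: str,
    periods_per_state: int = 4,
    samples_per_period: int = 4000,
) -> tuple[list[ConnectivityMatrix], ConnectivityMatrix]:
    """Microstate-segmented PLI.

    Phases are computed once on the band-filtered full-length recording and
    indexed by the microstate label vector.  For each class the earliest
    ``periods_per_state * samples_per_period`` labelled samples are
    stitched in temporal order, split into fixed periods, and a PLI matrix
    is computed per period.  Returns the per-class average matrices and the
    subject average over all class-period matrices.
    """
    labels = np.asarray(labels)
    if labels.size != recording.n_samples:
        raise ValueError("labels must cover every sample of the recording")
    filtered = bandpass(recording, band)
    phases = instantaneous_phase(filtered).phases
    classes = np.arange(labels.max() + 1)
    need = periods_per_state * samples_per_period
    class_mats: list[ConnectivityMatrix] = []
    all_period_mats = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if idx.size < need:
            raise ValueError(
                f"microstate class {c} has {idx.size} labelled samples; "
                f"{need} required ({periods_per_state} x {samples_per_period})"
            )
        sel = phases[:, idx[:need]]
        period_mats = [
            pli_matrix(sel[:, p * samples_per_period:(p + 1) * samples_per_period])
            for p in range(periods_per_state)
        ]
        all_period_mats.extend(period_mats)
        class_mats.append(
            ConnectivityMatrix(weights=np.mean(period_mats, axis=0), band=band,
                               scope=f"microstate:{int(c)}",
                               node_labels=list(recording.channel_labels))
        )
    subject = ConnectivityMatrix(weights=np.mean(all_period_mats, axis=0),
                                 band=band, scope="global",
                                 node_labels=list(recording.channel_labels))
    return class_mats, subject


# ---------------------------------------------------------------------------
# Region reduction


def reduce_to_regions(
    matrix: ConnectivityMatrix, region_scheme: RegionScheme
) -> ConnectivityMatrix:
    """22 x 22 region matrix: mean of all electrode pairs spanning two regions."""
    region_scheme.validate_channels(matrix.node_labels)
    idx = {c: i for i, c in enumerate(matrix.node_labels)}
    members = {}
    for region in region_scheme.region_labels:
        chans = [idx[c] for c in region_scheme.region_channels(region) if c in idx]
        if not chans:
            raise ValueError(f"region {region!r} has no surviving channels")
        members[region] = np.asarray(chans)
    n_r = len(region_scheme.region_labels)
    out = np.zeros((n_r, n_r))
    w = matrix.weights
    for a in range(n_r):
        ia = members[region_scheme.region_labels[a]]
        for b in range(a + 1, n_r):
            ib = members[region_scheme.region_labels[b]]
            out[a, b] = out[b, a] = w[np.ix_(ia, ib)].mean()
    return ConnectivityMatrix(weights=out, band=matrix.band, scope=matrix.scope,
                              node_labels=list(region_scheme.region_labels))
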