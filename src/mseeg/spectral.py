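"""Region-level spectral analysis: multitaper PSD, relative band power,
logit transform, and peak/median frequency.

Power spectra are computed per channel with the Thomson multitaper method
(time-bandwidth product 4, seven tapers on 4-s epochs) and summarised as
the median across epochs.  Regional spectra are the median over a region's
channels.  Relative power in the five analysis bands (delta 1-4, theta 4-8,
alpha1 8-10, alpha2 10-13, beta 13-30 Hz; half-open bins [lo, hi)) is band
power divided by total 1-30 Hz power, so the five values of a region sum to
one by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .preproc import ANALYSIS_BAND_NAMES, BANDS, EpochSet, RegionScheme

__all__ = [
    "BandDefinition",
    "Spectrum",
    "SpectralSummary",
    "multitaper_psd",
    "relative_band_power",
    "logit_power",
    "median_peak_frequency",
    "summarize",
    "ANALYSIS_BANDS",
]

#: Thomson multitaper settings: time-bandwidth product and taper count.
MT_NW = 4.0
MT_N_TAPERS = 7

_LOGIT_EPS = 1e-6


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not 0 < self.lo < self.hi:
            raise ValueError(f"invalid band {self.name}: [{self.lo}, {self.hi})")


ANALYSIS_BANDS: tuple[BandDefinition, ...] = tuple(
    BandDefinition(name, *BANDS[name]) for name in ANALYSIS_BAND_NAMES
)


class Spectrum(NamedTuple):
    """Per-channel power spectral density on a fixed frequency grid."""

    freqs: np.ndarray          # (n_freqs,) Hz
    psd: np.ndarray            # (n_channels, n_freqs)
    channel_labels: list[str]


@dataclass
class SpectralSummary:
    rel_power: pd.DataFrame    # region x band, rows sum to 1
    logit_power: pd.DataFrame  # region x band
    median_frequency: float    # Hz, median over parieto-occipital channels
    peak_frequency: float      # Hz


def multitaper_psd(epoch_set: EpochSet) -> Spectrum:
    """Median-across-epochs multitaper PSD per channel."""
    from mne.time_frequency import psd_array_multitaper

    epochs = np.asarray(epoch_set.epochs, dtype=float)
    if epochs.ndim != 3 or epochs.shape[0] < 1:
        raise ValueError("need at least one epoch (n_epochs, n_channels, n_samples)")
    n_times = epochs.shape[2]
    if n_times < 2 * MT_N_TAPERS:
        raise ValueError(f"epoch of {n_times} samples shorter than taper support")
    fs = epoch_set.sampling_rate
    # mne's `bandwidth` is the full smoothing width: NW = bandwidth * T / 2.
    bandwidth = 2.0 * MT_NW * fs / n_times
    psd, freqs = psd_array_multitaper(
        epochs, sfreq=fs, bandwidth=bandwidth, adaptive=False,
        normalization="full", verbose="error",
    )
    return Spectrum(freqs=freqs, psd=np.median(psd, axis=0),
                    channel_labels=list(epoch_set.channel_labels))


def _band_mask(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (freqs >= lo) & (freqs < hi)


def relative_band_power(
    spectrum: Spectrum,
    region_scheme: RegionScheme,
    bands: tuple[BandDefinition, ...] = ANALYSIS_BANDS,
) -> pd.DataFrame:
    """Region x band relative power (band power / total 1-30 Hz power)."""
    freqs, psd, labels = spectrum
    if freqs[0] > 1.0 or freqs[-1] < 30.0:
        raise ValueError("spectrum grid must cover [1, 30] Hz")
    region_scheme.validate_channels(labels)
    idx = {c: i for i, c in enumerate(labels)}
    total_mask = _band_mask(freqs, 1.0, 30.0)
    rows = {}
    for region in region_scheme.region_labels:
        chans = [idx[c] for c in region_scheme.region_channels(region) if c in idx]
        if not chans:
            raise ValueError(f"region {region!r} has no surviving channels")
        reg_spec = np.median(psd[chans], axis=0)
        total = reg_spec[total_mask].sum()
        if total <= 0:
            raise ValueError(f"region {region!r} has zero 1-30 Hz power")
        rows[region] = {
            b.name: reg_spec[_band_mask(freqs, b.lo, b.hi)].sum() / total for b in bands
        }
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[b.name for b in bands])


def logit_power(p, eps: float = _LOGIT_EPS):
    """log(p / (1-p)) with inputs clipped to [eps, 1-eps]."""
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    return np.log(p / (1.0 - p))


def _median_frequency(freqs: np.ndarray, spec: np.ndarray) -> float:
    """Frequency splitting the 1-30 Hz power in half (linear interpolation)."""
    mask = _band_mask(freqs, 1.0, 30.0)
    f, s = freqs[mask], spec[mask]
    cum = np.cumsum(s)
    half = cum[-1] / 2.0
    k = int(np.searchsorted(cum, half))
    if k == 0:
        return float(f[0])
    # interpolate within bin k between cum[k-1] and cum[k]
    frac = (half - cum[k - 1]) / (cum[k] - cum[k - 1]) if cum[k] > cum[k - 1] else 0.0
    lo = f[k - 1] if k > 0 else f[0]
    return float(lo + frac * (f[k] - lo))


def median_peak_frequency(
    spectrum: Spectrum, region_scheme: RegionScheme
) -> tuple[float, float]:
    """(median frequency, peak frequency) over parieto-occipital electrodes.

    Per PO electrode the peak is the 1-30 Hz argmax and the median frequency
    splits the cumulative 1-30 Hz power in half; the medians across those
    electrodes are returned.
    """
    freqs, psd, labels = spectrum
    po_regions = [r for r in region_scheme.region_labels if r.split("_")[0] == "PO"]
    po_channels = [c for r in po_regions for c in region_scheme.region_channels(r)]
    idx = {c: i for i, c in enumerate(labels)}
    chans = [idx[c] for c in po_channels if c in idx]
    if not chans:
        raise ValueError("no parieto-occipital channels present")
    mask = _band_mask(freqs, 1.0, 30.0)
    peaks, medians = [], []
    for c in chans:
        spec = psd[c]
        peaks.append(freqs[mask][int(np.argmax(spec[mask]))])
        medians.append(_median_frequency(freqs, spec))
    return float(np.median(medians)), float(np.median(peaks))


def summarize(epoch_set: EpochSet, region_scheme: RegionScheme) -> SpectralSummary:
    """Full spectral summary of one subject's epochs."""
    spectrum = multitaper_psd(epoch_set)
    rel = relative_band_power(spectrum, region_scheme)
    med, peak = median_peak_frequency(spectrum, region_scheme)
    return SpectralSummary(
        rel_power=rel,
        logit_power=rel.apply(logit_power),
        median_frequency=med,
        peak_frequency=peak,
    )
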