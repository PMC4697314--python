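"""EEG microstate segmentation.

Spontaneous EEG is modelled as a sequence of a few recurring quasi-stable
scalp topographies (microstates).  The segmentation here follows the
classic recipe:

1. global field power (GFP) — the spatial standard deviation of the
   average-referenced map at each time point;
2. maps at local GFP maxima are clustered with a polarity-invariant
   ("modified") k-means using squared spatial correlation as similarity;
3. the number of clusters is chosen over k = 2..20 by the Krzanowski-Lai
   criterion on the within-cluster dispersion curve;
4. every sample is competitively labelled with the best-correlating
   template and the label sequence is smoothed with a 12-ms majority window.

Polarity invariance matters: a topography and its negation belong to the
same microstate class, which squared correlation encodes for free.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preproc import Recording, average_reference

__all__ = [
    "MicrostateModel",
    "gfp",
    "find_gfp_peaks",
    "cluster_topographies",
    "krzanowski_lai",
    "select_k",
    "fit_labels",
    "fit_microstates",
]

_K_RANGE_DEFAULT = (2, 20)
_N_RESTARTS = 20
_MAX_ITER = 100
#: GFP-peak maps are deterministically subsampled to this many before
#: clustering; more adds cost without changing the recovered templates.
_MAX_MAPS = 1000


@dataclass
class MicrostateModel:
    """Fitted microstate segmentation of one recording."""

    templates: np.ndarray            # (k, n_channels), unit-norm rows
    k: int
    labels: np.ndarray               # per-sample class index
    smoothing_window: float | None   # ms
    gfp: np.ndarray | None = None
    peak_indices: np.ndarray | None = None
    kl_curve: dict[int, float] = field(default_factory=dict)
    gev: float | None = None

    def to_json(self, path: str | Path) -> None:
        runs = _rle_encode(self.labels)
        payload = {
            "k": int(self.k),
            "templates": np.asarray(self.templates).tolist(),
            "labels_rle": runs,
            "kl_curve": {str(k): float(v) for k, v in self.kl_curve.items()},
            "smoothing_window": self.smoothing_window,
            "gev": self.gev,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "MicrostateModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            templates=np.asarray(payload["templates"], dtype=float),
            k=int(payload["k"]),
            labels=_rle_decode(payload["labels_rle"]),
            smoothing_window=payload.get("smoothing_window"),
            kl_curve={int(k): v for k, v in payload.get("kl_curve", {}).items()},
            gev=payload.get("gev"),
        )


def _rle_encode(labels: np.ndarray) -> list[list[int]]:
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [[int(labels[s]), int(e - s)] for s, e in zip(starts, ends)]


def _rle_decode(runs: list[list[int]]) -> np.ndarray:
    if not runs:
        return np.empty(0, dtype=np.int64)
    vals, counts = zip(*runs)
    return np.repeat(np.asarray(vals, dtype=np.int64), counts)


# ---------------------------------------------------------------------------
# GFP


def gfp(recording: Recording) -> np.ndarray:
    """Per-sample global field power: sqrt(sum_i u_i^2 / n).

    Requires average-referenced data (then the formula equals the spatial
    standard deviation); non-referenced input is re-referenced with a
    warning.
    """
    if recording.reference != "average":
        scale = np.sqrt(np.mean(recording.data ** 2)) or 1.0
        offsets = np.abs(recording.data.mean(axis=0)).max()
        if offsets > 1e-9 * scale:
            warnings.warn("input not average-referenced; re-referencing for GFP",
                          stacklevel=2)
        recording = average_reference(recording)
    return np.sqrt(np.mean(recording.data ** 2, axis=0))


def find_gfp_peaks(gfp_trace: np.ndarray) -> np.ndarray:
    """Indices t with gfp[t-1] < gfp[t] > gfp[t+1] (strict local maxima)."""
    g = np.asarray(gfp_trace, dtype=float)
    if g.size < 3:
        raise ValueError("GFP trace must have at least 3 samples")
    inner = np.arange(1, g.size - 1)
    keep = (g[inner] > g[inner - 1]) & (g[inner] > g[inner + 1])
    return inner[keep]


# ---------------------------------------------------------------------------
# Modified k-means (polarity-invariant)


def _principal_map(X: np.ndarray) -> np.ndarray:
    """First principal component of a set of maps, unit norm."""
    s = X.T @ X
    vals, vecs = np.linalg.eigh(s)
    v = vecs[:, -1]
    return v / np.linalg.norm(v)


def _kmeans_once(
    maps_n: np.ndarray, weights: np.ndarray, k: int, rng: np.random.Generator,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """One run of polarity-invariant k-means on unit-norm maps.

    Returns (templates, assignment, GEV, mean within-cluster 1-r^2).
    """
    m = maps_n.shape[0]
    if init is None:
        templates = maps_n[rng.choice(m, size=k, replace=False)].copy()
    else:
        templates = init.copy()
    assign = np.full(m, -1)
    for _ in range(_MAX_ITER):
        corr = maps_n @ templates.T          # (m, k); maps and templates unit-norm
        new_assign = np.argmax(corr ** 2, axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            members = assign == j
            if not members.any():
                # re-seed an empty cluster at the worst-explained map
                r2best = np.max(corr ** 2, axis=1)
                templates[j] = maps_n[int(np.argmin(r2best))]
                continue
            t = _principal_map(maps_n[members])
            # fix sign by majority polarity of member correlations
            if (maps_n[members] @ t).sum() < 0:
                t = -t
            templates[j] = t
    corr = maps_n @ templates.T
    r2 = corr[np.arange(m), assign] ** 2
    gev_val = float(np.sum(weights * r2) / np.sum(weights))
    dispersion = float(np.mean(1.0 - r2))
    return templates, assign, gev_val, dispersion


def _prepare_maps(peak_maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    maps = np.asarray(peak_maps, dtype=float)
    norms = np.linalg.norm(maps, axis=1)
    keep = norms > 0
    maps_n = maps[keep] / norms[keep, None]
    return maps_n, norms[keep] ** 2  # GEV weights ~ GFP^2 at the peak


def cluster_topographies(
    peak_maps: np.ndarray, k: int, seed: int = 0,
    n_restarts: int = _N_RESTARTS,
) -> tuple[np.ndarray, float]:
    """Best-of-``n_restarts`` modified k-means; returns (templates, GEV)."""
    maps_n, weights = _prepare_maps(peak_maps)
    if k < 1 or k > maps_n.shape[0]:
        raise ValueError(f"k={k} outside [1, {maps_n.shape[0]}]")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        templates, _, gev_val, _ = _kmeans_once(maps_n, weights, k, rng)
        if best is None or gev_val > best[1]:
            best = (templates, gev_val)
    return best


def krzanowski_lai(
    w_values: np.ndarray, k_values: np.ndarray, p: int,
    floor_frac: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Krzanowski-Lai curve from a within-cluster dispersion curve W(k).

    DIFF(k) = (k-1)^(2/p) W(k-1) - k^(2/p) W(k);
    KL(k) = |DIFF(k)| / |DIFF(k+1)|, so KL is defined on the interior
    k-values (``k_values[1:-1]``); ``p`` is the map dimensionality
    (channel count).

    Beyond the true cluster count the DIFF values hover around zero, and a
    raw ratio of two near-zero noisy numbers can spike arbitrarily.  The
    denominator is therefore floored at ``floor_frac`` of the largest
    |DIFF|: a genuine elbow (numerator at the scale of the largest drop)
    keeps a large KL, while noise-over-noise ratios are damped to O(1).
    """
    w = np.asarray(w_values, dtype=float)
    kv = np.asarray(k_values, dtype=float)
    if w.shape != kv.shape or w.size < 3:
        raise ValueError("need aligned W(k) over at least 3 consecutive k")
    scaled = kv ** (2.0 / p) * w
    diff = scaled[:-1] - scaled[1:]      # DIFF at k = kv[1:]
    floor = floor_frac * np.abs(diff).max()
    with np.errstate(divide="ignore", invalid="ignore"):
        kl = np.abs(diff[:-1]) / np.maximum(np.abs(diff[1:]), floor)
    kl = np.where(np.isfinite(kl), kl, np.inf)
    return kv[1:-1].astype(int), kl


def select_k(
    peak_maps: np.ndarray,
    k_range: tuple[int, int] = _K_RANGE_DEFAULT,
    seed: int = 0,
    n_restarts: int = _N_RESTARTS,
) -> tuple[int, dict[int, float]]:
    """Choose the cluster count by the Krzanowski-Lai criterion.

    Dispersion W(k) is evaluated for k_min-1 .. k_max+1 so the KL statistic
    covers the whole search range; the global KL maximum is returned.  One
    restart per k is warm-started from the previous k's templates plus one
    extra map, which keeps the W(k) curve close to monotone.
    """
    k_min, k_max = k_range
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    maps_n, weights = _prepare_maps(peak_maps)
    m, p = maps_n.shape
    if m < k_max + 1:
        raise ValueError(f"{m} maps insufficient for k_max={k_max}")
    rng = np.random.default_rng(seed)
    ks = np.arange(k_min - 1, k_max + 2)
    w_curve = np.empty(ks.size)
    prev_templates = None
    for i, k in enumerate(ks):
        best = None
        inits: list[np.ndarray | None] = [None] * n_restarts
        if prev_templates is not None:
            extra = maps_n[rng.integers(m)][None, :]
            inits[0] = np.vstack([prev_templates, extra])[:k]
        for init in inits:
            templates, _, _, disp = _kmeans_once(maps_n, weights, int(k), rng, init=init)
            if best is None or disp < best[1]:
                best = (templates, disp)
        prev_templates, w_curve[i] = best
    if np.all(w_curve < 1e-12):
        warnings.warn("degenerate dispersion (all maps identical); returning k_min",
                      stacklevel=2)
        return k_min, {}
    kl_k, kl = krzanowski_lai(w_curve, ks, p)
    curve = {int(k): float(v) for k, v in zip(kl_k, kl)}
    k_star = int(kl_k[int(np.argmax(kl))])
    return k_star, curve


# ---------------------------------------------------------------------------
# Back-fitting


def _majority_smooth(labels: np.ndarray, k: int, window: int,
                     max_passes: int = 10) -> np.ndarray:
    """Sliding-window majority relabeling iterated to a fixed point.

    Ties keep the current label (the current label gets a half-count bonus).
    """
    half = max(window // 2, 1)
    n = labels.size
    labels = labels.copy()
    pos = np.arange(n)
    lo = np.maximum(pos - half, 0)
    hi = np.minimum(pos + half + 1, n)
    for _ in range(max_passes):
        onehot = np.zeros((k, n + 1))
        onehot[labels, pos + 1] = 1.0
        csum = np.cumsum(onehot, axis=1)
        counts = csum[:, hi] - csum[:, lo]
        counts[labels, pos] += 0.5
        new = np.argmax(counts, axis=0)
        if np.array_equal(new, labels):
            break
        labels = new
    return labels


def fit_labels(
    recording: Recording,
    templates: np.ndarray,
    smoothing_window: float | None = 12.0,
) -> np.ndarray:
    """Label every sample with its best-squared-correlation template.

    ``smoothing_window`` is in milliseconds (None disables smoothing); the
    window in samples is round(window/1000 * fs) and must be >= 1.
    """
    templates = np.asarray(templates, dtype=float)
    if templates.shape[1] != recording.n_channels:
        raise ValueError("templates and recording have different channel spaces")
    tn = templates / np.linalg.norm(templates, axis=1, keepdims=True)
    proj = tn @ recording.data               # (k, n_samples)
    labels = np.argmax(proj ** 2, axis=0)
    if smoothing_window is not None:
        window = int(round(smoothing_window / 1000.0 * recording.sampling_rate))
        if window < 1:
            raise ValueError(
                f"smoothing window of {smoothing_window} ms is < 1 sample at "
                f"{recording.sampling_rate} Hz"
            )
        labels = _majority_smooth(labels, templates.shape[0], window)
    return labels


def fit_microstates(
    recording: Recording,
    k: int | str = "auto",
    smoothing_window: float | None = 12.0,
    seed: int = 0,
    k_range: tuple[int, int] = _K_RANGE_DEFAULT,
    n_restarts: int = _N_RESTARTS,
    max_maps: int = _MAX_MAPS,
) -> MicrostateModel:
    """Full segmentation: GFP peaks -> clustering -> (optional) k selection
    -> per-sample labels."""
    if recording.reference != "average":
        recording = average_reference(recording)
    trace = gfp(recording)
    peaks = find_gfp_peaks(trace)
    maps = recording.data[:, peaks].T
    if maps.shape[0] > max_maps:
        sel = np.linspace(0, maps.shape[0] - 1, max_maps).astype(int)
        maps = maps[sel]
    kl_curve: dict[int, float] = {}
    if k == "auto":
        k, kl_curve = select_k(maps, k_range=k_range, seed=seed, n_restarts=n_restarts)
    templates, gev_val = cluster_topographies(maps, int(k), seed=seed,
                                              n_restarts=n_restarts)
    labels = fit_labels(recording, templates, smoothing_window=smoothing_window)
    return MicrostateModel(
        templates=templates, k=int(k), labels=labels,
        smoothing_window=smoothing_window, gfp=trace, peak_indices=peaks,
        kl_curve=kl_curve, gev=gev_val,
    )
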