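"""Band decomposition and entropy-weighted ROI aggregation.

Each hemoglobin channel is decomposed into five physiological frequency
bands with a zero-phase Chebyshev type-I band-pass filter, then the
channels of each region of interest are fused into a single regional time
series by the entropy-weight method: channels whose (min-max normalised)
amplitude distribution over time is far from uniform carry more
information and receive a larger weight.

For a filtered channel submatrix X (N time points x M channels of one ROI):

    z_ij = (x_ij - min_i x_ij) / (max_i x_ij - min_i x_ij)     min-max rescale
    p_ij = z_ij / sum_i z_ij                                   amplitude distribution
    e_j  = -(1 / ln N) * sum_i p_ij ln p_ij                    normalised entropy
    w_j  = (1 - e_j) / sum_k (1 - e_k)                         entropy weight
    y_i  = sum_j X_ij w_j                                      ROI series

A constant channel carries no information: its amplitude distribution is
taken as uniform (e = 1), so it receives weight 0. If every channel in an
ROI is constant the weights fall back to uniform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .data_model import BandSpec, ChannelRecording, DEFAULT_BANDS, Montage

__all__ = [
    "FILTER_ORDER",
    "FILTER_RIPPLE_DB",
    "EntropyWeights",
    "BandRoiSeries",
    "bandpass",
    "bandpass_matrix",
    "entropy_weights",
    "roi_aggregate",
]

# Chebyshev type-I band-pass design; applied forward-backward for zero phase.
FILTER_ORDER = 4
FILTER_RIPPLE_DB = 0.5


@dataclass(frozen=True)
class EntropyWeights:
    """Per-channel fusion weights for one ROI, with entropy diagnostics."""

    weights: np.ndarray  # (M,), nonnegative, sums to 1
    entropy: np.ndarray  # (M,), normalised Shannon entropy per channel


@dataclass
class BandRoiSeries:
    """ROI-level time series for one (species, band) pair.

    ``y`` has one column per ROI in montage order.
    """

    y: np.ndarray  # (time, n_rois)
    roi_order: tuple[str, ...]
    species: str
    band: BandSpec
    fs: float


def _design_sos(band: BandSpec, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if band.high >= nyq:
        raise ValueError(
            f"band {band.name!r} upper edge {band.high} Hz requires fs > {2 * band.high} Hz "
            f"(got fs = {fs} Hz)"
        )
    return sps.cheby1(
        FILTER_ORDER,
        FILTER_RIPPLE_DB,
        [band.low / nyq, band.high / nyq],
        btype="bandpass",
        output="sos",
    )


def _min_padlen(sos: np.ndarray) -> int:
    # same default scipy.signal.sosfiltfilt uses
    return 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum()))


def bandpass(x: np.ndarray, band: BandSpec, fs: float) -> np.ndarray:
    """Zero-phase Chebyshev band-pass of a 1-D signal (or each column of a 2-D one)."""
    x = np.asarray(x, dtype=float)
    sos = _design_sos(band, fs)
    if x.shape[0] <= _min_padlen(sos):
        raise ValueError(
            f"signal too short for band {band.name!r}: {x.shape[0]} samples, "
            f"need > {_min_padlen(sos)}"
        )
    return sps.sosfiltfilt(sos, x, axis=0)


def bandpass_matrix(X: np.ndarray, band: BandSpec, fs: float) -> np.ndarray:
    """Column-wise :func:`bandpass` of a (time x channel) matrix."""
    return bandpass(np.atleast_2d(X.T).T, band, fs)


def entropy_weights(X: np.ndarray) -> EntropyWeights:
    """Entropy-weight method over the channels (columns) of ``X``."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (time x channels)")
    n, m = X.shape
    if n < 2:
        raise ValueError(f"need at least 2 time points, got {n}")
    if m < 1:
        raise ValueError("need at least 1 channel")

    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    entropy = np.empty(m)
    for j in range(m):
        if rng[j] == 0.0:
            entropy[j] = 1.0  # constant channel: uniform distribution convention
            continue
        z = (X[:, j] - lo[j]) / rng[j]
        p = z / z.sum()
        nz = p > 0
        entropy[j] = -(p[nz] * np.log(p[nz])).sum() / np.log(n)
    divergence = 1.0 - entropy
    total = divergence.sum()
    if total <= 0.0:
        weights = np.full(m, 1.0 / m)
    else:
        weights = divergence / total
    return EntropyWeights(weights=weights, entropy=entropy)


def roi_aggregate(
    recording: ChannelRecording,
    montage: Montage,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
) -> list[BandRoiSeries]:
    """Filter every channel into each band, then fuse channels per ROI.

    Weights are computed per band on the *filtered* channel submatrix, so a
    channel that is informative in one band but flat in another is weighted
    accordingly.
    """
    out: list[BandRoiSeries] = []
    for band in bands:
        filtered = bandpass_matrix(recording.samples, band, recording.fs)
        y = np.empty((recording.n_samples, montage.n_rois))
        for k, roi in enumerate(montage.roi_order):
            idx = montage.channel_indices(roi, recording.channel_ids)
            sub = filtered[:, idx]
            w = entropy_weights(sub).weights
            y[:, k] = sub @ w
        out.append(
            BandRoiSeries(
                y=y,
                roi_order=montage.roi_order,
                species=recording.species,
                band=band,
                fs=recording.fs,
            )
        )
    return out
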