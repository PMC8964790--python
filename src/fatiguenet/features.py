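"""Per-session feature vector: connectivity, network metrics, time-domain.

Each session yields 2,250 features over 3 hemoglobin species x 5 bands:

* 28 signed inter-ROI Pearson correlations per (species, band) -> 420;
* characteristic path length L and clustering coefficient C of the
  weighted network per (species, band) -> 30;
* 15 time-domain descriptors per (species, band, ROI) -> 1,800.

The 15 descriptors, in order: mean, standard deviation (population),
coefficient of variation, energy, range, skewness, excess kurtosis, peak
(max |x|), Hjorth mobility, Shannon entropy of the 64-bin amplitude
histogram (nats), root mean square, kurtosis factor (mean x^4 / RMS^4),
waveform factor (RMS / mean |x|), pulse factor (peak / mean |x|) and
margin factor (peak / mean(sqrt |x|)^2). The factor definitions follow
the usual condition-monitoring conventions. Descriptors whose denominator
vanishes on a degenerate (constant or zero) signal are reported as 0 so
tree models never see missing values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sstats

from .data_model import DEFAULT_BANDS, SPECIES
from .data_model import ROI_ORDER as _ROI_ORDER
from .network import ConnectivityNetwork, NetworkMetrics
from .preprocess import BandRoiSeries

__all__ = [
    "TIME_DOMAIN_NAMES",
    "FeatureVector",
    "time_domain_features",
    "assemble_features",
    "feature_names",
    "N_FEATURES",
]

TIME_DOMAIN_NAMES = (
    "mean",
    "std",
    "cv",
    "energy",
    "range",
    "skewness",
    "kurtosis",
    "peak",
    "mobility",
    "entropy",
    "rms",
    "kurtosis_factor",
    "waveform_factor",
    "pulse_factor",
    "margin_factor",
)

ENTROPY_BINS = 64
_EPS = 1e-12

N_FEATURES = 3 * 5 * 28 + 3 * 5 * 2 + 3 * 5 * 8 * 15  # 2250


@dataclass
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values and names must have equal length")


def time_domain_features(x: np.ndarray) -> np.ndarray:
    """The 15 time-domain descriptors of a 1-D signal, in documented order."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("need a 1-D signal with at least 4 samples")
    n = x.size
    mean = x.mean()
    std = x.std()  # population, divisor N
    cv = std / (abs(mean) + _EPS)
    energy = float(np.sum(x * x))
    rng = float(x.max() - x.min())
    if std > 0:
        skew = float(sstats.skew(x, bias=True))
        kurt = float(sstats.kurtosis(x, fisher=True, bias=True))
    else:
        skew = kurt = 0.0
    peak = float(np.abs(x).max())
    var = std * std
    mobility = float(np.sqrt(np.diff(x).var() / var)) if var > 0 else 0.0
    if rng > 0:
        hist, _ = np.histogram(x, bins=ENTROPY_BINS, range=(x.min(), x.max()))
        p = hist / n
        nz = p > 0
        entropy = float(-(p[nz] * np.log(p[nz])).sum())
    else:
        entropy = 0.0
    rms = float(np.sqrt(np.mean(x * x)))
    abs_mean = np.abs(x).mean()
    sqrt_mean = np.mean(np.sqrt(np.abs(x)))
    kurtosis_factor = float(np.mean(x**4) / rms**4) if rms > 0 else 0.0
    waveform_factor = rms / abs_mean if abs_mean > 0 else 0.0
    pulse_factor = peak / abs_mean if abs_mean > 0 else 0.0
    margin_factor = peak / sqrt_mean**2 if sqrt_mean > 0 else 0.0
    return np.array(
        [
            mean, std, cv, energy, rng, skew, kurt, peak, mobility, entropy,
            rms, kurtosis_factor, waveform_factor, pulse_factor, margin_factor,
        ]
    )


def _roi_pairs(roi_order: tuple[str, ...]) -> list[tuple[str, str]]:
    return list(combinations(roi_order, 2))


def feature_names(
    species: tuple[str, ...] = SPECIES,
    bands: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS),
    roi_order: tuple[str, ...] = _ROI_ORDER,
) -> tuple[str, ...]:
    """The fixed, documented feature-name ordering.

    Blocks: all fc features, then all network metrics, then all
    time-domain features; within a block species vary slowest, then band,
    then pair / metric / (ROI, descriptor).
    """
    names: list[str] = []
    for sp in species:
        for b in bands:
            for a, c in _roi_pairs(roi_order):
                names.append(f"{sp}|{b}|fc|{a}~{c}")
    for sp in species:
        for b in bands:
            names.append(f"{sp}|{b}|net|L")
            names.append(f"{sp}|{b}|net|C")
    for sp in species:
        for b in bands:
            for roi in roi_order:
                for td in TIME_DOMAIN_NAMES:
                    names.append(f"{sp}|{b}|td|{roi}|{td}")
    return tuple(names)


def assemble_features(
    networks: dict[tuple[str, str], ConnectivityNetwork],
    metrics: dict[tuple[str, str], NetworkMetrics],
    series: dict[tuple[str, str], BandRoiSeries],
    species: tuple[str, ...] = SPECIES,
    bands: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS),
    signed_fc: bool = True,
) -> FeatureVector:
    """Concatenate per-(species, band) artifacts into one feature vector.

    ``networks``/``metrics``/``series`` are keyed by (species, band name).
    """
    for sp in species:
        for b in bands:
            for store, label in ((networks, "network"), (metrics, "metrics"), (series, "series")):
                if (sp, b) not in store:
                    raise KeyError(f"missing {label} for species {sp!r}, band {b!r}")

    values: list[float] = []
    roi_order = networks[(species[0], bands[0])].roi_order
    idx = {roi: i for i, roi in enumerate(roi_order)}
    for sp in species:
        for b in bands:
            net = networks[(sp, b)]
            mat = net.r if signed_fc else net.w
            for a, c in _roi_pairs(roi_order):
                values.append(float(mat[idx[a], idx[c]]))
    for sp in species:
        for b in bands:
            m = metrics[(sp, b)]
            values.append(m.L)
            values.append(m.C)
    for sp in species:
        for b in bands:
            y = series[(sp, b)].y
            for k in range(y.shape[1]):
                values.extend(time_domain_features(y[:, k]))
    names = feature_names(species, bands, roi_order)
    return FeatureVector(values=np.array(values), names=names)
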