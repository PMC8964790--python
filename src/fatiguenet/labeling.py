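"""Fatigue-level definition from MFI-20 and n-back behavioral scores.

Sessions are first split into non-fatigue (L1) and fatigue by 1-D k-means
(k = 2) on the mean MFI-20 item score; the data-driven threshold is the
smallest score in the upper cluster, so "score below threshold" means
non-fatigue. The fatigue group is then split into moderate (L2) and
severe (L3) by scanning a candidate threshold over the remaining score
range and keeping the candidate that maximises the statistical contrast
(absolute Welch t) between the two groups' behavioral scores. The
behavioral score is mean correct-trial reaction time divided by accuracy,
so larger means worse performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from sklearn.cluster import KMeans

from .data_model import NBackTrial

__all__ = [
    "FatigueLabeling",
    "ScanStep",
    "mfi_score",
    "behavior_score",
    "kmeans_split",
    "severe_threshold_scan",
    "assign_levels",
    "label_study",
]

SCAN_LO = 2.57
SCAN_HI = 5.00
SCAN_STEP = 0.01
MIN_GROUP = 3


@dataclass(frozen=True)
class ScanStep:
    threshold: float
    statistic: float
    n_moderate: int
    n_severe: int


@dataclass
class FatigueLabeling:
    """Scores, data-driven thresholds and per-session fatigue levels."""

    mfi_scores: np.ndarray
    behavior_scores: np.ndarray
    threshold_nonfatigue: float
    threshold_severe: float
    levels: tuple[str, ...]
    scan_trace: tuple[ScanStep, ...]


def mfi_score(items) -> float:
    """Mean of the 20 MFI items (1..5 scale, pre-oriented: higher = more fatigued)."""
    items = np.asarray(items)
    if items.size != 20:
        raise ValueError(f"expected exactly 20 MFI items, got {items.size}")
    if np.any((items < 1) | (items > 5)):
        raise ValueError("MFI items must lie in 1..5")
    return float(items.mean())


def behavior_score(nback: tuple[NBackTrial, ...]) -> float:
    """Mean correct-trial reaction time divided by accuracy (higher = worse)."""
    if not nback:
        raise ValueError("need at least one n-back trial")
    correct = [t.reaction_time for t in nback if t.correct]
    if not correct:
        raise ValueError("no correct trials: behavioral score undefined")
    accuracy = len(correct) / len(nback)
    return float(np.mean(correct) / accuracy)


def kmeans_split(scores, seed: int = 0) -> float:
    """Two-cluster 1-D k-means threshold: the smallest score in the upper cluster."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 4:
        raise ValueError("need at least 4 scores")
    if np.unique(scores).size < 2:
        raise ValueError("all scores identical: no two-cluster structure")
    km = KMeans(n_clusters=2, n_init=20, random_state=seed).fit(scores.reshape(-1, 1))
    upper = int(np.argmax(km.cluster_centers_.ravel()))
    return float(scores[km.labels_ == upper].min())


def severe_threshold_scan(
    mfi: np.ndarray,
    behavior: np.ndarray,
    lo: float = SCAN_LO,
    hi: float = SCAN_HI,
    step: float = SCAN_STEP,
    min_group: int = MIN_GROUP,
) -> tuple[float, tuple[ScanStep, ...]]:
    """Scan thresholds over [lo, hi]; maximise |Welch t| of behavior scores.

    Inputs are the fatigue-class sessions only (mfi >= lo). For each
    candidate t the group below t is moderate, at or above is severe;
    candidates leaving a group below ``min_group`` are skipped. Returns
    the maximising threshold (smallest on ties) and the full scan trace.
    """
    mfi = np.asarray(mfi, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    if mfi.shape != behavior.shape:
        raise ValueError("mfi and behavior must have equal length")
    grid = np.round(np.arange(lo, hi + step / 2, step), 10)
    trace: list[ScanStep] = []
    best_t, best_stat = None, -np.inf
    for t in grid:
        severe = mfi >= t
        n_sev, n_mod = int(severe.sum()), int((~severe).sum())
        if n_sev < min_group or n_mod < min_group:
            continue
        stat = abs(
            sstats.ttest_ind(behavior[severe], behavior[~severe], equal_var=False).statistic
        )
        trace.append(ScanStep(float(t), float(stat), n_mod, n_sev))
        if stat > best_stat + 1e-12:  # strictly larger: smallest t wins ties
            best_stat, best_t = stat, float(t)
    if best_t is None:
        raise ValueError("no candidate threshold produced two groups of sufficient size")
    return best_t, tuple(trace)


def assign_levels(
    mfi: np.ndarray, threshold_nonfatigue: float, threshold_severe: float
) -> tuple[str, ...]:
    """Deterministic level assignment from the two thresholds."""
    if not threshold_nonfatigue < threshold_severe <= 5.0:
        raise ValueError("need threshold_nonfatigue < threshold_severe <= 5")
    out = []
    for s in np.asarray(mfi, dtype=float):
        if s < threshold_nonfatigue:
            out.append("L1")
        elif s < threshold_severe:
            out.append("L2")
        else:
            out.append("L3")
    return tuple(out)


def label_study(sessions, seed: int = 0) -> FatigueLabeling:
    """Full labeling of a list of ParticipantSessions."""
    mfi = np.array([mfi_score(s.mfi_items) for s in sessions])
    behavior = np.array([behavior_score(s.nback) for s in sessions])
    t1 = kmeans_split(mfi, seed=seed)
    fatigue = mfi >= t1
    t2, trace = severe_threshold_scan(mfi[fatigue], behavior[fatigue], lo=max(SCAN_LO, t1))
    levels = assign_levels(mfi, t1, t2)
    return FatigueLabeling(
        mfi_scores=mfi,
        behavior_scores=behavior,
        threshold_nonfatigue=t1,
        threshold_severe=t2,
        levels=levels,
        scan_trace=trace,
    )
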