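"""Synthetic study generator: band-limited coupled ROI signals plus scores.

The generator emulates the structure the downstream analysis assumes, so
the whole pipeline is testable without recordings:

* per frequency band, 8 regional latent signals with a prescribed
  inter-ROI correlation matrix, built by band-pass filtering independent
  white noise and mixing with the matrix square root of the target;
* a modular default coupling: three physiological modules (prefrontal,
  frontal eye fields, sensorimotor) with strong within-module coupling,
  a few strong long-range links (homologous/hub connections), and weak
  background coupling — the clustered-plus-shortcuts organisation that
  gives cortical networks their small-world character;
* channels of an ROI share its latent signal plus independent sensor
  noise; deoxyhemoglobin mirrors oxyhemoglobin with coefficient kappa
  (HbR latent = -kappa * HbO latent) and HbT = HbO + HbR exactly;
* fatigue-level effects expressed as multiplicative modifiers on the
  per-band coupling (moderate fatigue: stronger right-hemisphere coupling
  in the neurogenic band II, weaker myogenic band III; severe fatigue:
  globally weaker bands III/IV), and level-dependent questionnaire (MFI-20)
  and n-back reaction-time/accuracy distributions.

Magnitudes of all level effects are generator parameters with documented
defaults, not measured quantities.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    BandSpec,
    ChannelRecording,
    DEFAULT_BANDS,
    FATIGUE_LEVELS,
    Montage,
    NBackTrial,
    ParticipantSession,
    TASKS,
    default_montage,
    write_montage,
    write_recording,
)
from .preprocess import bandpass

__all__ = [
    "CouplingSpec",
    "LevelEffect",
    "ScoreModel",
    "StudyDesign",
    "default_coupling_spec",
    "default_level_effects",
    "default_score_models",
    "generate_band_signals",
    "generate_session",
    "generate_study",
    "draw_mfi_items",
    "draw_nback",
    "cell_seed",
]


@dataclass(frozen=True)
class CouplingSpec:
    """Per-band inter-ROI correlation targets and signal/noise amplitudes."""

    targets: dict[str, np.ndarray]  # band name -> (8, 8) correlation target
    amplitudes: dict[str, float]  # band name -> latent amplitude
    noise_sd: float  # per-channel sensor noise s.d.
    kappa: float  # HbR latent = -kappa * HbO latent

    def __post_init__(self) -> None:
        for name, t in self.targets.items():
            _validate_target(t, name)
        if not (0.0 <= self.kappa <= 1.0):
            raise ValueError(f"kappa must lie in [0, 1], got {self.kappa}")
        if self.noise_sd < 0 or any(a < 0 for a in self.amplitudes.values()):
            raise ValueError("amplitudes and noise_sd must be nonnegative")


@dataclass(frozen=True)
class LevelEffect:
    """Multiplicative coupling modifiers for one fatigue level.

    ``global_scale`` multiplies all off-diagonal couplings of a band;
    ``right_scale`` additionally multiplies couplings between two
    right-hemisphere ROIs.
    """

    global_scale: dict[str, float] = field(default_factory=dict)  # band -> factor
    right_scale: dict[str, float] = field(default_factory=dict)  # band -> factor


@dataclass(frozen=True)
class ScoreModel:
    """MFI-20 and n-back generative parameters for one fatigue level."""

    mfi_center: float  # mean item score on the 1..5 scale
    mfi_item_sd: float
    rt_mean: float  # seconds
    rt_sd: float
    accuracy: float  # probability of a correct trial
    n_trials: int = 30


@dataclass(frozen=True)
class StudyDesign:
    """Full factorial synthetic study: task x fatigue level cells."""

    n_per_cell: int = 8
    duration: float = 1200.0  # seconds, a typical task-block length
    fs: float = 16.0
    seed: int = 0
    coupling: CouplingSpec | None = None
    level_effects: dict[str, LevelEffect] | None = None
    score_models: dict[str, ScoreModel] | None = None
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        if self.duration * self.fs < 512:
            raise ValueError("need duration * fs >= 512 samples")

    def resolved(self) -> "StudyDesign":
        """Fill unset model components with the documented defaults."""
        return replace(
            self,
            coupling=self.coupling or default_coupling_spec(),
            level_effects=self.level_effects or default_level_effects(),
            score_models=self.score_models or default_score_models(),
        )


# ---------------------------------------------------------------------------
# defaults
# ---------------------------------------------------------------------------

# ROI modules for the default coupling, indices in data_model.ROI_ORDER:
#   prefrontal {L-PFC, M-PFC, R-PFC}, eye fields {L-FEF, R-FEF},
#   sensorimotor {SMA, L-PMC, R-PMC}
_MODULES = ((0, 1, 2), (3, 4), (5, 6, 7))
# strong long-range links: PFC->FEF within hemisphere and M-PFC->SMA hub
_SHORTCUTS = ((0, 3), (2, 4), (1, 5))
_WITHIN, _SHORTCUT, _BETWEEN = 0.60, 0.45, 0.15
#: latent amplitude per band: connectivity strength declines with frequency
_DEFAULT_AMPLITUDES = {"I": 1.0, "II": 0.9, "III": 0.8, "IV": 0.6, "V": 0.5}
_RIGHT_ROIS = (2, 4, 7)  # R-PFC, R-FEF, R-PMC


def _modular_target(n: int = 8) -> np.ndarray:
    t = np.full((n, n), _BETWEEN)
    for module in _MODULES:
        for i in module:
            for j in module:
                t[i, j] = _WITHIN
    for i, j in _SHORTCUTS:
        t[i, j] = t[j, i] = _SHORTCUT
    np.fill_diagonal(t, 1.0)
    return t


def default_coupling_spec() -> CouplingSpec:
    """Modular small-world-like coupling, identical across bands; band
    amplitudes decline with frequency as hemodynamic power does."""
    base = _modular_target()
    return CouplingSpec(
        targets={b.name: base.copy() for b in DEFAULT_BANDS},
        amplitudes=dict(_DEFAULT_AMPLITUDES),
        noise_sd=0.25,
        kappa=0.6,
    )


def default_level_effects() -> dict[str, LevelEffect]:
    """Qualitative fatigue signatures: moderate fatigue strengthens
    right-hemisphere band-II coupling and weakens band III; severe fatigue
    weakens bands III and IV globally."""
    return {
        "L1": LevelEffect(),
        "L2": LevelEffect(global_scale={"III": 0.30}, right_scale={"II": 1.40}),
        "L3": LevelEffect(global_scale={"III": 0.15, "IV": 0.70}),
    }


def default_score_models() -> dict[str, ScoreModel]:
    return {
        "L1": ScoreModel(mfi_center=1.8, mfi_item_sd=1.0, rt_mean=0.45, rt_sd=0.05, accuracy=0.95),
        "L2": ScoreModel(mfi_center=3.0, mfi_item_sd=1.0, rt_mean=0.55, rt_sd=0.06, accuracy=0.88),
        "L3": ScoreModel(mfi_center=4.0, mfi_item_sd=1.0, rt_mean=0.70, rt_sd=0.08, accuracy=0.78),
    }


#: the boundary between the L2 and L3 MFI item-score centers; the severe
#: threshold scan should recover approximately this value
TRUE_SEVERE_BOUNDARY = 3.5


# ---------------------------------------------------------------------------
# signal generation
# ---------------------------------------------------------------------------

def _validate_target(t: np.ndarray, name: str = "") -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError(f"coupling target {name!r} must be square")
    if not np.allclose(t, t.T):
        raise ValueError(f"coupling target {name!r} must be symmetric")
    if not np.allclose(np.diag(t), 1.0):
        raise ValueError(f"coupling target {name!r} must have unit diagonal")
    if np.linalg.eigvalsh(t).min() < -1e-10:
        raise ValueError(f"coupling target {name!r} is not positive semidefinite")
    return t


def _psd_sqrt(t: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(t)
    return vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T


def _nearest_correlation(t: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and restore the unit diagonal."""
    vals, vecs = np.linalg.eigh(t)
    if vals.min() >= -1e-10:
        return t
    fixed = vecs @ np.diag(np.clip(vals, 1e-8, None)) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def apply_level_effect(target: np.ndarray, band: str, effect: LevelEffect) -> np.ndarray:
    """Scale a band's off-diagonal couplings per the level's modifiers."""
    t = np.array(target, dtype=float)
    off = ~np.eye(t.shape[0], dtype=bool)
    g = effect.global_scale.get(band, 1.0)
    t[off] *= g
    r = effect.right_scale.get(band, 1.0)
    if r != 1.0:
        for i in _RIGHT_ROIS:
            for j in _RIGHT_ROIS:
                if i != j:
                    t[i, j] *= r
    t = np.clip(t, -0.99, 0.99)
    np.fill_diagonal(t, 1.0)
    return _nearest_correlation(t)


def generate_band_signals(
    target: np.ndarray,
    band: BandSpec,
    n_samples: int,
    fs: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Band-limited ROI signals with the given target correlation matrix.

    Independent white-noise columns are band-pass filtered, standardised,
    mixed with the symmetric matrix square root of the target, and
    re-standardised; sample correlations converge to the target with
    growing ``n_samples``.
    """
    target = _validate_target(target)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal((n_samples, target.shape[0]))
    filtered = bandpass(white, band, fs)
    filtered = (filtered - filtered.mean(axis=0)) / filtered.std(axis=0)
    mixed = filtered @ _psd_sqrt(target)
    sd = mixed.std(axis=0)
    sd[sd == 0] = 1.0
    return (mixed - mixed.mean(axis=0)) / sd


def draw_mfi_items(model: ScoreModel, rng: np.random.Generator) -> tuple[int, ...]:
    """20 questionnaire items around the level's center, clipped to 1..5."""
    raw = rng.normal(model.mfi_center, model.mfi_item_sd, size=20)
    return tuple(int(v) for v in np.clip(np.rint(raw), 1, 5))


def draw_nback(model: ScoreModel, rng: np.random.Generator) -> tuple[NBackTrial, ...]:
    """n-back trials: truncated-normal reaction times, Bernoulli accuracy."""
    rts = np.clip(rng.normal(model.rt_mean, model.rt_sd, size=model.n_trials), 0.15, None)
    correct = rng.random(model.n_trials) < model.accuracy
    if not correct.any():
        correct[int(np.argmin(rts))] = True  # a session always has >= 1 correct trial
    return tuple(NBackTrial(float(rt), bool(c)) for rt, c in zip(rts, correct))


_LEVEL_SESSION = {"L1": "morning", "L2": "afternoon", "L3": "evening"}


def cell_seed(master_seed: int, participant_id: str, task: str, level: str) -> int:
    """Stable per-cell seed: changing the study size never reshuffles
    existing participants."""
    key = f"{master_seed}|{participant_id}|{task}|{level}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def generate_session(
    design: StudyDesign,
    participant_id: str,
    task: str,
    level: str,
    seed: int,
    montage: Montage | None = None,
    species: tuple[str, ...] = ("HbO", "HbR", "HbT"),
    bands: tuple[BandSpec, ...] | None = None,
) -> ParticipantSession:
    """One synthetic session: three hemoglobin recordings plus scores.

    ``species``/``bands`` can be restricted to speed up analyses that only
    need part of the data; HbT always requires HbR.
    """
    if level not in FATIGUE_LEVELS:
        raise ValueError(f"unknown fatigue level {level!r}")
    design = design.resolved()
    coupling = design.coupling
    effect = design.level_effects[level]
    score_model = design.score_models[level]
    bands = bands if bands is not None else design.bands
    montage = montage or default_montage()
    rng = np.random.default_rng(seed)
    n = int(round(design.duration * design.fs))

    # summed band-limited ROI latents
    latent = np.zeros((n, montage.n_rois))
    for band in bands:
        target = apply_level_effect(coupling.targets[band.name], band.name, effect)
        latent += coupling.amplitudes[band.name] * generate_band_signals(
            target, band, n, design.fs, rng
        )

    channel_ids = montage.channel_ids
    n_ch = len(channel_ids)
    hbo_latent = np.empty((n, n_ch))
    for k, roi in enumerate(montage.roi_order):
        idx = montage.channel_indices(roi, channel_ids)
        hbo_latent[:, idx] = latent[:, [k]]

    hbo = hbo_latent + coupling.noise_sd * rng.standard_normal((n, n_ch))
    hbr = -coupling.kappa * hbo_latent + coupling.noise_sd * rng.standard_normal((n, n_ch))
    hbt = hbo + hbr

    recordings = {}
    matrices = {"HbO": hbo, "HbR": hbr, "HbT": hbt}
    for sp in species:
        recordings[sp] = ChannelRecording(
            samples=matrices[sp], fs=design.fs, species=sp, channel_ids=channel_ids
        )

    return ParticipantSession(
        participant_id=participant_id,
        task=task,
        session=_LEVEL_SESSION[level],
        recordings=recordings,
        mfi_items=draw_mfi_items(score_model, rng),
        nback=draw_nback(score_model, rng),
        fatigue_level=level,
    )


def generate_study(
    design: StudyDesign,
    out_dir: str | Path | None = None,
    montage: Montage | None = None,
    species: tuple[str, ...] = ("HbO", "HbR", "HbT"),
    bands: tuple[BandSpec, ...] | None = None,
) -> list[ParticipantSession]:
    """Full factorial study: ``n_per_cell`` sessions per (task, level) cell.

    Per-session seeds derive from (master seed, participant, task, level),
    so enlarging the study reproduces the smaller study's sessions
    verbatim. With ``out_dir`` set, recordings and score tables are also
    written in the package's CSV/JSON formats.
    """
    design = design.resolved()
    montage = montage or default_montage()
    sessions: list[ParticipantSession] = []
    for task in TASKS:
        for level in FATIGUE_LEVELS:
            for i in range(design.n_per_cell):
                pid = f"{task}-{level}-p{i + 1:02d}"
                seed = cell_seed(design.seed, pid, task, level)
                sessions.append(
                    generate_session(
                        design, pid, task, level, seed,
                        montage=montage, species=species, bands=bands,
                    )
                )
    if out_dir is not None:
        _write_study(sessions, montage, Path(out_dir))
    return sessions


def read_study(in_dir: str | Path) -> tuple[list[ParticipantSession], Montage]:
    """Read a study directory written by :func:`generate_study` back in."""
    from .data_model import read_montage, read_recording

    in_dir = Path(in_dir)
    montage = read_montage(in_dir / "montage.json")
    index = pd.read_csv(in_dir / "sessions.csv")
    mfi = pd.read_csv(in_dir / "mfi.csv").set_index("participant_id")
    nback = pd.read_csv(in_dir / "nback.csv")
    sessions = []
    for _, row in index.iterrows():
        pid = row["participant_id"]
        recordings = {}
        for sp in ("HbO", "HbR", "HbT"):
            csv = in_dir / f"{pid}_{sp}.csv"
            if csv.exists():
                recordings[sp] = read_recording(csv, in_dir / f"{pid}_{sp}.json")
        items = tuple(int(mfi.loc[pid, f"item_{i + 1:02d}"]) for i in range(20))
        trials = tuple(
            NBackTrial(float(t.reaction_time), bool(t.correct))
            for t in nback[nback["participant_id"] == pid].itertuples()
        )
        sessions.append(
            ParticipantSession(
                participant_id=pid,
                task=row["task"],
                session=row["session"],
                recordings=recordings,
                mfi_items=items,
                nback=trials,
                fatigue_level=row.get("fatigue_level"),
            )
        )
    return sessions, montage


def _write_study(
    sessions: list[ParticipantSession], montage: Montage, out_dir: Path
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_montage(montage, out_dir / "montage.json")
    mfi_rows, nback_rows, index_rows = [], [], []
    for s in sessions:
        for sp, rec in s.recordings.items():
            stem = f"{s.participant_id}_{sp}"
            write_recording(
                rec,
                out_dir / f"{stem}.csv",
                out_dir / f"{stem}.json",
                participant_id=s.participant_id,
                task=s.task,
                session=s.session,
            )
        mfi_rows.append(
            {"participant_id": s.participant_id, **{f"item_{i + 1:02d}": v for i, v in enumerate(s.mfi_items)}}
        )
        for t_i, trial in enumerate(s.nback):
            nback_rows.append(
                {
                    "participant_id": s.participant_id,
                    "trial": t_i + 1,
                    "reaction_time": trial.reaction_time,
                    "correct": int(trial.correct),
                }
            )
        index_rows.append(
            {
                "participant_id": s.participant_id,
                "task": s.task,
                "session": s.session,
                "fatigue_level": s.fatigue_level,
            }
        )
    pd.DataFrame(mfi_rows).to_csv(out_dir / "mfi.csv", index=False)
    pd.DataFrame(nback_rows).to_csv(out_dir / "nback.csv", index=False)
    pd.DataFrame(index_rows).to_csv(out_dir / "sessions.csv", index=False)
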