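"""Core domain types and plain-text I/O for multichannel hemoglobin recordings.

The pipeline operates on functional near-infrared spectroscopy (fNIRS)
recordings: time x channel matrices of oxy- (HbO), deoxy- (HbR) and total
(HbT) hemoglobin concentration change, sampled at 16 Hz by default, plus a
montage that groups the 24 measurement channels into 8 cortical regions of
interest (ROIs) spanning prefrontal cortex (PFC), frontal eye fields (FEF),
supplementary motor area (SMA) and premotor cortex (PMC).

Files are deliberately plain text: signals as CSV with a channel-id header
row, metadata and montages as JSON, so fixtures stay human-readable and
version-control friendly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SPECIES",
    "TASKS",
    "SESSIONS",
    "FATIGUE_LEVELS",
    "BandSpec",
    "DEFAULT_BANDS",
    "Montage",
    "default_montage",
    "ChannelRecording",
    "NBackTrial",
    "ParticipantSession",
    "FormatError",
    "read_recording",
    "write_recording",
    "read_montage",
    "write_montage",
]

SPECIES = ("HbO", "HbR", "HbT")
TASKS = ("PVT", "cognitive", "driving")
SESSIONS = ("morning", "afternoon", "evening")
FATIGUE_LEVELS = ("L1", "L2", "L3")


class FormatError(ValueError):
    """Raised when an input file violates the documented on-disk format."""


@dataclass(frozen=True)
class BandSpec:
    """One physiological frequency band, [low, high] in Hz.

    The five default bands follow the standard hemodynamic decomposition:
    I endogenic/metabolic, II neurogenic, III myogenic, IV respiratory,
    V cardiac activity.
    """

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got [{self.low}, {self.high}]"
            )


DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("I", 0.005, 0.021),
    BandSpec("II", 0.021, 0.052),
    BandSpec("III", 0.052, 0.145),
    BandSpec("IV", 0.145, 0.600),
    BandSpec("V", 0.6, 2.0),
)


@dataclass(frozen=True)
class Montage:
    """Channel -> ROI grouping with a fixed ROI ordering and hemisphere labels."""

    roi_channels: Mapping[str, tuple[int, ...]]
    roi_order: tuple[str, ...]
    hemisphere: Mapping[str, str]

    def __post_init__(self) -> None:
        if set(self.roi_channels) != set(self.roi_order):
            raise ValueError("roi_order and roi_channels must name the same ROIs")
        seen: set[int] = set()
        for roi, chans in self.roi_channels.items():
            overlap = seen & set(chans)
            if overlap:
                raise ValueError(f"channels {sorted(overlap)} assigned to multiple ROIs")
            seen.update(chans)
        bad_hemi = {h for h in self.hemisphere.values()} - {"left", "right", "medial"}
        if bad_hemi:
            raise ValueError(f"unknown hemisphere labels: {sorted(bad_hemi)}")

    @property
    def n_rois(self) -> int:
        return len(self.roi_order)

    @property
    def channel_ids(self) -> tuple[int, ...]:
        """All channel ids covered by the montage, ascending."""
        out: list[int] = []
        for chans in self.roi_channels.values():
            out.extend(chans)
        return tuple(sorted(out))

    def channel_indices(self, roi: str, channel_ids: Sequence[int]) -> np.ndarray:
        """0-based column indices of ``roi``'s channels within ``channel_ids``."""
        lookup = {cid: i for i, cid in enumerate(channel_ids)}
        try:
            return np.array([lookup[c] for c in self.roi_channels[roi]], dtype=int)
        except KeyError as exc:
            raise FormatError(
                f"ROI {roi!r} references channel {exc.args[0]} absent from the recording"
            ) from None

    def rois_in_hemisphere(self, side: str) -> tuple[str, ...]:
        return tuple(r for r in self.roi_order if self.hemisphere[r] == side)


#: fixed ROI ordering used for every 8-vector / 8x8 matrix in the pipeline
ROI_ORDER = ("L-PFC", "M-PFC", "R-PFC", "L-FEF", "R-FEF", "SMA", "L-PMC", "R-PMC")

_DEFAULT_ROI_CHANNELS = {
    "L-PFC": (1, 4, 8),
    "M-PFC": (2, 5, 6, 9),
    "R-PFC": (3, 7, 10),
    "L-FEF": (11, 12),
    "R-FEF": (13, 14),
    "SMA": (15, 18, 22),
    "L-PMC": (16, 19, 20, 23),
    "R-PMC": (17, 21, 24),
}

_DEFAULT_HEMISPHERE = {
    "L-PFC": "left",
    "M-PFC": "medial",
    "R-PFC": "right",
    "L-FEF": "left",
    "R-FEF": "right",
    "SMA": "medial",
    "L-PMC": "left",
    "R-PMC": "right",
}


def default_montage() -> Montage:
    """The standard 24-channel / 8-ROI frontal-motor montage.

    Prefrontal cortex is split left/medial/right; frontal eye fields and
    premotor cortex left/right; the supplementary motor area is medial.
    """
    return Montage(
        roi_channels=dict(_DEFAULT_ROI_CHANNELS),
        roi_order=ROI_ORDER,
        hemisphere=dict(_DEFAULT_HEMISPHERE),
    )


@dataclass
class ChannelRecording:
    """Raw multichannel hemoglobin time series for one session and species."""

    samples: np.ndarray  # (time, channel), float
    fs: float
    species: str
    channel_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (time x channel) array")
        if self.samples.shape[0] < 2:
            raise ValueError("recording must contain at least 2 time points")
        if self.samples.shape[1] != len(self.channel_ids):
            raise ValueError(
                f"{self.samples.shape[1]} columns but {len(self.channel_ids)} channel ids"
            )
        if not np.isfinite(self.samples).all():
            bad = np.argwhere(~np.isfinite(self.samples))[0]
            raise FormatError(
                f"non-finite value at row {bad[0] + 1}, channel {self.channel_ids[bad[1]]}"
            )
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}, got {self.species!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class NBackTrial:
    """One working-memory trial: reaction time in seconds and correctness."""

    reaction_time: float
    correct: bool

    def __post_init__(self) -> None:
        if self.reaction_time <= 0:
            raise ValueError(f"reaction time must be positive, got {self.reaction_time}")


@dataclass
class ParticipantSession:
    """All data for one participant in one session: signals, scale, behavior."""

    participant_id: str
    task: str
    session: str
    recordings: dict[str, ChannelRecording] = field(default_factory=dict)
    mfi_items: tuple[int, ...] = ()
    nback: tuple[NBackTrial, ...] = ()
    fatigue_level: str | None = None

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}, got {self.session!r}")
        if self.mfi_items:
            if len(self.mfi_items) != 20:
                raise ValueError(f"expected 20 MFI items, got {len(self.mfi_items)}")
            if any(not (1 <= v <= 5) for v in self.mfi_items):
                raise ValueError("MFI items must lie in 1..5")
        if self.fatigue_level is not None and self.fatigue_level not in FATIGUE_LEVELS:
            raise ValueError(f"fatigue level must be one of {FATIGUE_LEVELS}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_recording(signal_path: str | Path, meta_path: str | Path) -> ChannelRecording:
    """Read a CSV signal matrix plus its JSON metadata sidecar.

    The CSV carries one header row of integer channel ids; columns are
    reordered to ascending channel id on read. The sidecar supplies at
    least ``fs`` and ``species``.
    """
    signal_path, meta_path = Path(signal_path), Path(meta_path)
    with open(meta_path) as fh:
        meta = json.load(fh)
    try:
        df = pd.read_csv(signal_path)
    except ValueError as exc:
        raise FormatError(f"{signal_path}: {exc}") from exc
    try:
        channel_ids = tuple(int(c) for c in df.columns)
    except ValueError:
        raise FormatError(
            f"{signal_path}: header must contain integer channel ids, got {list(df.columns)}"
        ) from None
    for col in df.columns:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise FormatError(
                f"{signal_path}: non-numeric value at row {bad[0] + 2}, channel {col}"
            )
    order = np.argsort(channel_ids)
    samples = df.to_numpy(dtype=float)[:, order]
    fs = float(meta.get("fs", 0.0))
    if fs <= 0:
        raise FormatError(f"{meta_path}: fs must be positive, got {meta.get('fs')}")
    return ChannelRecording(
        samples=samples,
        fs=fs,
        species=str(meta.get("species", "")),
        channel_ids=tuple(channel_ids[i] for i in order),
    )


def write_recording(
    recording: ChannelRecording,
    signal_path: str | Path,
    meta_path: str | Path,
    **extra_meta,
) -> None:
    """Write a recording as CSV + JSON sidecar (12 significant digits)."""
    df = pd.DataFrame(recording.samples, columns=[str(c) for c in recording.channel_ids])
    df.to_csv(signal_path, index=False, float_format="%.12g")
    meta = {"fs": recording.fs, "species": recording.species, **extra_meta}
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")


def read_montage(path: str | Path) -> Montage:
    """Read a montage from JSON ({roi_channels, hemisphere[, roi_order]})."""
    with open(path) as fh:
        raw = json.load(fh)
    roi_channels = {r: tuple(int(c) for c in chans) for r, chans in raw["roi_channels"].items()}
    roi_order = tuple(raw.get("roi_order", list(roi_channels)))
    return Montage(
        roi_channels=roi_channels,
        roi_order=roi_order,
        hemisphere=dict(raw["hemisphere"]),
    )


def write_montage(montage: Montage, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "roi_channels": {r: list(c) for r, c in montage.roi_channels.items()},
                "roi_order": list(montage.roi_order),
                "hemisphere": dict(montage.hemisphere),
            },
            fh,
            indent=1,
        )
        fh.write("\n")
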