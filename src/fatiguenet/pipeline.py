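"""End-to-end orchestration: simulate -> preprocess -> network -> features
-> label -> stats -> classify, reproducible from one master seed.

Each enabled stage runs in order on in-memory artifacts and writes its
table(s) under the run directory; a manifest records the configuration
hash, derived stage seeds and the files each stage produced, so a rerun
with the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .data_model import DEFAULT_BANDS, Montage, SPECIES, default_montage
from .synthetic import StudyDesign, generate_study
from .preprocess import roi_aggregate
from .network import (
    DEFAULT_N_RANDOM,
    DEFAULT_SPARSITY,
    characteristic_path_length,
    clustering_coefficient,
    fc_matrix,
    small_worldness,
)
from .features import assemble_features, feature_names
from .labeling import label_study
from .group_stats import band_metric_comparison
from .classify import ClassifierConfig, crossvalidate

__all__ = ["RunConfig", "run_pipeline", "session_networks", "study_feature_table"]

logger = logging.getLogger("fatiguenet")

STAGES = ("simulate", "preprocess", "network", "features", "label", "stats", "classify")


class SimpleMetrics(NamedTuple):
    """Weighted clustering and path length of one full connectivity matrix."""

    C: float
    L: float


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    out_dir: str = "fatiguenet-run"
    seed: int = 0
    n_per_cell: int = 4
    duration: float = 1200.0
    fs: float = 16.0
    sparsity: float = DEFAULT_SPARSITY
    n_random: int = DEFAULT_N_RANDOM
    species: tuple[str, ...] = SPECIES
    n_features: int = 100
    stages: tuple[str, ...] = STAGES
    classifier: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def stage_seed(master: int, stage: str) -> int:
    """Derived per-stage seed (stable, below 2**31)."""
    digest = hashlib.sha256(f"{master}|{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def session_networks(session, montage: Montage, species=SPECIES, bands=DEFAULT_BANDS):
    """All per-(species, band) artifacts of one session.

    Returns (series, networks, metrics) dicts keyed by (species, band name);
    metrics hold full-matrix weighted C and L.
    """
    series, networks, metrics = {}, {}, {}
    for sp in species:
        for brs in roi_aggregate(session.recordings[sp], montage, bands):
            key = (sp, brs.band.name)
            series[key] = brs
            net = fc_matrix(brs)
            networks[key] = net
            C = clustering_coefficient(net.w)
            L, _ = characteristic_path_length(net.w)
            metrics[key] = SimpleMetrics(C=C, L=L)
    return series, networks, metrics


def study_feature_table(sessions, montage=None, species=SPECIES, bands=DEFAULT_BANDS):
    """Feature matrix for a list of sessions plus the artifact stores."""
    montage = montage or default_montage()
    rows, artifacts = [], []
    names = None
    for s in sessions:
        series, networks, metrics = session_networks(s, montage, species, bands)
        fv = assemble_features(
            networks, metrics, series,
            species=species, bands=tuple(b.name for b in bands),
        )
        names = fv.names
        rows.append(fv.values)
        artifacts.append((series, networks, metrics))
    table = pd.DataFrame(np.array(rows), columns=list(names))
    table.insert(0, "participant_id", [s.participant_id for s in sessions])
    table.insert(1, "task", [s.task for s in sessions])
    table.insert(2, "session", [s.session for s in sessions])
    table.insert(3, "true_level", [s.fatigue_level for s in sessions])
    return table, artifacts


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig, montage: Montage | None = None) -> dict:
    """Execute the enabled stages in order; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    montage = montage or default_montage()
    bands = DEFAULT_BANDS
    manifest: dict = {
        "config_hash": _config_hash(config),
        "master_seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "stages": {},
    }
    enabled = [s for s in STAGES if s in config.stages]

    sessions = None
    feature_table = None
    artifacts = None
    labeling = None

    for stage in enabled:
        t0 = time.perf_counter()
        outputs: list[str] = []
        logger.info("stage %s: start", stage)
        if stage == "simulate":
            design = StudyDesign(
                n_per_cell=config.n_per_cell,
                duration=config.duration,
                fs=config.fs,
                seed=stage_seed(config.seed, "simulate"),
            )
            sessions = generate_study(design, montage=montage, species=config.species)
        elif stage == "preprocess":
            _require(sessions, stage, "simulate")
            # materialised lazily with the network stage via session_networks
        elif stage == "network":
            _require(sessions, stage, "simulate")
            feature_table, artifacts = study_feature_table(
                sessions, montage, config.species, bands
            )
            sw_rows = []
            for s, (series, networks, _m) in zip(sessions, artifacts):
                for (sp, band), net in networks.items():
                    m = small_worldness(
                        net.w,
                        n_random=config.n_random,
                        seed=stage_seed(config.seed, "network"),
                        mode="weighted",
                        sparsity=config.sparsity,
                    )
                    sw_rows.append(
                        {
                            "participant_id": s.participant_id,
                            "species": sp,
                            "band": band,
                            "mode": m.mode,
                            "C": m.C,
                            "L": m.L,
                            "gamma": m.gamma,
                            "lambda": m.lam,
                            "sigma": m.sigma,
                            "seed": m.seed,
                        }
                    )
            pd.DataFrame(sw_rows).to_csv(out / "network_metrics.csv", index=False)
            outputs.append("network_metrics.csv")
        elif stage == "features":
            _require(feature_table, stage, "network")
            feature_table.to_csv(out / "features.csv", index=False, float_format="%.10g")
            outputs.append("features.csv")
        elif stage == "label":
            _require(sessions, stage, "simulate")
            labeling = label_study(sessions, seed=stage_seed(config.seed, "label"))
            labels = pd.DataFrame(
                {
                    "participant_id": [s.participant_id for s in sessions],
                    "mfi_score": labeling.mfi_scores,
                    "behavior_score": labeling.behavior_scores,
                    "level": labeling.levels,
                }
            )
            labels.to_csv(out / "labels.csv", index=False)
            trace = pd.DataFrame([asdict_step(st) for st in labeling.scan_trace])
            trace.to_csv(out / "threshold_scan.csv", index=False)
            outputs += ["labels.csv", "threshold_scan.csv"]
        elif stage == "stats":
            _require(feature_table, stage, "network")
            _require(labeling, stage, "label")
            cells = pd.crosstab(list(labeling.levels), feature_table["task"])
            if cells.shape != (3, 3) or (cells < 1).any().any():
                logger.warning(
                    "stage stats: skipped (assigned labels leave empty level x task cells)"
                )
            else:
                tidy, targets = _stats_table(feature_table, labeling, species="HbO")
                anova, posthoc = band_metric_comparison(tidy, targets)
                anova.to_csv(out / "anova.csv", index=False)
                posthoc.to_csv(out / "posthoc.csv", index=False)
                outputs += ["anova.csv", "posthoc.csv"]
        elif stage == "classify":
            _require(feature_table, stage, "network")
            _require(labeling, stage, "label")
            levels = np.array(labeling.levels)
            X = feature_table.drop(
                columns=["participant_id", "task", "session", "true_level"]
            )
            reports = {}
            tasks = {
                "nonfatigue_vs_fatigue": (
                    np.where(levels == "L1", "nonfatigue", "fatigue"), "fatigue"),
                "moderate_vs_severe": (levels, "L3"),
            }
            for name, (y, pos) in tasks.items():
                if name == "moderate_vs_severe":
                    mask = np.isin(levels, ["L2", "L3"])
                    Xt, yt = X.values[mask], y[mask]
                else:
                    Xt, yt = X.values, y
                cfg = ClassifierConfig(
                    positive_class=pos,
                    n_features=config.n_features,
                    seed=stage_seed(config.seed, "classify"),
                    **config.classifier,
                )
                counts = pd.Series(yt).value_counts()
                if counts.min() < cfg.cv_folds:
                    logger.warning("stage classify: skipping %s (class too small)", name)
                    continue
                rep = crossvalidate(Xt, yt, tuple(X.columns), cfg)
                reports[name] = rep
                with open(out / f"cv_{name}.json", "w") as fh:
                    json.dump(
                        {
                            "accuracy": rep.accuracy,
                            "recall": rep.recall,
                            "f1": rep.f1,
                            "fold_accuracies": list(rep.fold_accuracies),
                            "confusion": rep.confusion.tolist(),
                            "best_params": [
                                {k: v for k, v in p.items()} for p in rep.best_params
                            ],
                            "seed": rep.seed,
                        },
                        fh,
                        indent=1,
                        default=str,
                    )
                outputs.append(f"cv_{name}.json")
        manifest["stages"][stage] = {
            "outputs": outputs,
            "wall_time_s": round(time.perf_counter() - t0, 3),
        }
        logger.info("stage %s: done (%.1fs)", stage, manifest["stages"][stage]["wall_time_s"])

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def asdict_step(step) -> dict:
    return {
        "threshold": step.threshold,
        "statistic": step.statistic,
        "n_moderate": step.n_moderate,
        "n_severe": step.n_severe,
    }


def _require(obj, stage: str, needs: str) -> None:
    if obj is None:
        raise RuntimeError(f"stage {stage!r} requires stage {needs!r} to have run")


def _stats_table(feature_table: pd.DataFrame, labeling, species: str = "HbO"):
    """Tidy (band x session) table of HbO connectivity pairs and C/L."""
    band_names = tuple(b.name for b in DEFAULT_BANDS)
    pair_names = [
        n.split("|", 3)[3] for n in feature_names((species,), (band_names[0],))
        if "|fc|" in n
    ]
    targets = [f"fc:{p}" for p in pair_names] + ["net:C", "net:L"]
    rows = []
    levels = labeling.levels
    for i in range(len(feature_table)):
        for b in band_names:
            row = {
                "band": b,
                "level": levels[i],
                "task": feature_table.iloc[i]["task"],
            }
            for p in pair_names:
                row[f"fc:{p}"] = feature_table.iloc[i][f"{species}|{b}|fc|{p}"]
            row["net:C"] = feature_table.iloc[i][f"{species}|{b}|net|C"]
            row["net:L"] = feature_table.iloc[i][f"{species}|{b}|net|L"]
            rows.append(row)
    return pd.DataFrame(rows), targets
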