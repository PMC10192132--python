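"""End-to-end reproducible run: generate -> extract -> tune -> contrast -> classify.

One config object (loadable from YAML) drives every stage; a single global
seed is expanded deterministically into per-stage seeds so any stage can be
rerun in isolation; the run manifest records the config snapshot, the
selected k_max, per-stage wall-clock and a SHA-256 checksum of every file
emitted, so two runs with the same config are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, CohortConfig, MontageSpec, TASK, REST, generate_cohort
from .hfd import HfdParams, extract_features
from .kmax import DEFAULT_CANDIDATES, select_kmax, sweep_kmax
from .stats import channel_tests, export_topography, style_contrast, top_channels
from .classify import (
    SUBJECT_PRESENTATION,
    SUBJECT_SPECIFIC,
    assemble_samples,
    best_per_scheme,
    run_grid,
)

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]

logger = logging.getLogger("hfdeeg")


@dataclass
class StatsConfig:
    alpha: float = 0.05
    alternative: str = "less"   # one-sided, novice > expert at default group order
    top_n: int = 10


@dataclass
class ClassifyConfig:
    schemes: tuple[str, ...] = (SUBJECT_PRESENTATION, SUBJECT_SPECIFIC)
    seeds: tuple[int, ...] = (0, 1, 2)
    n_folds: int = 10
    channel_sets: tuple[str, ...] = ("full",)
    standardize: bool = True


@dataclass
class RunConfig:
    """Full pipeline configuration.

    ``k_max`` may be an integer or ``"auto"``, in which case the candidate
    sweep is run and its selection used for feature extraction.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    k_max: int | str = "auto"
    kmax_candidates: tuple[int, ...] = DEFAULT_CANDIDATES
    window_seconds: float | None = None
    stats: StatsConfig = field(default_factory=StatsConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    output_dir: str = "hfd_run"
    global_seed: int = 0
    store_recordings: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.k_max, str) and self.k_max != "auto":
            raise ValueError("k_max must be an integer or 'auto'")
        if self.k_max == "auto" and not self.kmax_candidates:
            raise ValueError("'auto' k_max requires a candidate list")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        stats = StatsConfig(**raw.pop("stats", {}))
        classify = raw.pop("classify", {})
        for key in ("schemes", "seeds", "channel_sets"):
            if key in classify:
                classify[key] = tuple(classify[key])
        return cls(cohort=cohort, stats=stats, classify=ClassifyConfig(**classify), **raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    config: dict
    version: str
    selected_k_max: int
    files: dict[str, str]            # relative path -> sha256
    stage_seconds: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, default=str))


def _stage_seed(global_seed: int, stage: int) -> int:
    ss = np.random.SeedSequence([int(global_seed) & 0x7FFFFFFF, stage])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, force: bool = False) -> RunManifest:
    """Run every stage and write outputs plus a checksummed manifest.

    Refuses to write into a directory holding a previous run manifest
    unless ``force``.  All outputs are pure functions of (config, seeds).
    """
    out = Path(config.output_dir)
    manifest_path = out / "run_manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True to redo the run")
    out.mkdir(parents=True, exist_ok=True)

    timings: dict[str, float] = {}
    files: dict[str, Path] = {}

    def _stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    # -- cohort -------------------------------------------------------------
    t0 = _stage("cohort")
    cohort_cfg = dataclasses.replace(config.cohort, seed=_stage_seed(config.global_seed, 0))
    montage = MontageSpec.default()
    cohort = generate_cohort(
        cohort_cfg, montage,
        out_dir=out / "cohort" if config.store_recordings else None,
        overwrite=force,
    )
    timings["cohort"] = time.perf_counter() - t0

    # -- k_max --------------------------------------------------------------
    t0 = _stage("kmax")
    if config.k_max == "auto":
        sweep = sweep_kmax(cohort, config.kmax_candidates)
        selected = select_kmax(sweep)
        sweep_path = out / "kmax_sweep.csv"
        sweep.to_frame().to_csv(sweep_path, index=False)
        files["kmax_sweep.csv"] = sweep_path
    else:
        selected = int(config.k_max)
    timings["kmax"] = time.perf_counter() - t0
    logger.info("k_max = %d", selected)

    # -- features -----------------------------------------------------------
    t0 = _stage("features")
    params = HfdParams(k_max=selected, window_seconds=config.window_seconds)
    features = extract_features(cohort, params, conditions=(TASK, REST))
    feat_path = out / "hfd_features.csv"
    features.to_csv(feat_path)
    files["hfd_features.csv"] = feat_path
    files["hfd_features.csv.params.json"] = feat_path.with_suffix(".csv.params.json")
    timings["features"] = time.perf_counter() - t0

    # -- contrasts ----------------------------------------------------------
    t0 = _stage("contrasts")
    sc = config.stats
    task_contrasts = channel_tests(
        features, alpha=sc.alpha, alternative=sc.alternative, condition=TASK
    )
    rest_contrasts = channel_tests(
        features, alpha=sc.alpha, alternative=sc.alternative, condition=REST
    )
    style = style_contrast(features, alpha=sc.alpha)
    topo = export_topography(task_contrasts, montage)
    for name, frame in [
        ("contrasts_task.csv", task_contrasts),
        ("contrasts_rest.csv", rest_contrasts),
        ("contrasts_style.csv", style),
        ("topography.csv", topo),
        ("top_channels.csv", top_channels(task_contrasts, sc.top_n)),
    ]:
        p = out / name
        frame.to_csv(p, index=False)
        files[name] = p
    timings["contrasts"] = time.perf_counter() - t0

    # -- classification -----------------------------------------------------
    t0 = _stage("classify")
    cc = config.classify
    best_frames = []
    for channel_set in cc.channel_sets:
        samples = assemble_samples(features, montage, channel_set=channel_set)
        report = run_grid(
            samples, schemes=cc.schemes, seeds=cc.seeds,
            n_folds=cc.n_folds, standardize=cc.standardize,
        )
        name = f"accuracy_{channel_set}.csv"
        p = out / name
        report.frame.to_csv(p, index=False)
        files[name] = p
        best = best_per_scheme(report)
        best.insert(0, "channel_set", channel_set)
        best_frames.append(best)
    best_path = out / "best_per_scheme.csv"
    pd.concat(best_frames, ignore_index=True).to_csv(best_path, index=False)
    files["best_per_scheme.csv"] = best_path
    timings["classify"] = time.perf_counter() - t0

    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        selected_k_max=selected,
        files={name: _sha256(p) for name, p in files.items()},
        stage_seconds=timings,
    )
    manifest.to_json(manifest_path)
    return manifest
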