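"""Expert/novice classification on HFD feature vectors.

Samples are subject-presentation pairs (44 subjects x 16 presentations =
704 rows at cohort defaults), each a vector of per-channel HFD values
(x windows in windowed mode).  Three train/validation split schemes probe
different questions:

- ``subject_presentation`` (case 1): rows split freely, so a subject can
  sit on both sides of a fold — measures within-cohort separability and is
  inflated by subject-identity leakage;
- ``subject_specific`` (case 2): subjects split, all of a subject's rows
  travel together — measures generalisation to unseen people;
- ``presentation_specific`` (case 3): one presentation's 44 rows, split at
  subject level — one classifier per presentation.

Classifiers and their hyperparameter grids: k-nearest-neighbours
(3/5/7/9/11 neighbours), linear SVM (C in 0.025/0.5/0.75), decision tree
(depth 3/5/7) and AdaBoost (25/50/100 estimators).  Hyperparameters are
selected by case-1 cross-validated accuracy and then frozen for the other
schemes.  Features are standardised with training-fold statistics only.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .cohort import EXPERT, NOVICE, TASK, MontageSpec
from .hfd import HFDTable

__all__ = [
    "DEFAULT_GRID",
    "SCHEMES",
    "SampleTable",
    "SplitPlan",
    "assemble_samples",
    "make_split",
    "select_hyperparameters",
    "run_grid",
    "compare_channel_sets",
    "best_per_scheme",
    "AccuracyReport",
]

SUBJECT_PRESENTATION = "subject_presentation"
SUBJECT_SPECIFIC = "subject_specific"
PRESENTATION_SPECIFIC = "presentation_specific"
SCHEMES = (SUBJECT_PRESENTATION, SUBJECT_SPECIFIC, PRESENTATION_SPECIFIC)

DEFAULT_GRID: dict[str, dict[str, list]] = {
    "nearest_neighbors": {"n_neighbors": [3, 5, 7, 9, 11]},
    "linear_svm": {"C": [0.025, 0.5, 0.75]},
    "decision_tree": {"max_depth": [3, 5, 7]},
    "adaboost": {"n_estimators": [25, 50, 100]},
}

META_COLUMNS = ("subject_id", "presentation_id", "label")


@dataclass
class SampleTable:
    """One row per subject-presentation pair: metadata plus HFD features."""

    frame: pd.DataFrame
    feature_names: tuple[str, ...]
    channel_set: str = "full"

    def __post_init__(self) -> None:
        for col in META_COLUMNS:
            if col not in self.frame.columns:
                raise ValueError(f"sample table missing column {col!r}")
        self.feature_names = tuple(self.feature_names)
        self.frame = self.frame.reset_index(drop=True)

    @property
    def X(self) -> np.ndarray:
        return self.frame.loc[:, list(self.feature_names)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def with_permuted_labels(self, seed: int) -> "SampleTable":
        """Copy with labels randomly permuted — the chance-level control."""
        rng = np.random.default_rng(seed)
        frame = self.frame.copy()
        frame["label"] = rng.permutation(frame["label"].to_numpy())
        return SampleTable(frame, self.feature_names, self.channel_set)


def assemble_samples(
    features: HFDTable,
    montage: MontageSpec,
    channel_set: str = "full",
    windowed: bool = False,
    presentation_id: str | None = None,
) -> SampleTable:
    """Pivot an HFD table into the classification sample matrix.

    ``channel_set`` is ``"full"`` (all non-auxiliary channels) or
    ``"std32"`` (the 10/20 subset).  In windowed mode the feature columns
    are channel x window; window counts must agree across rows, which holds
    within one presentation by construction (``presentation_id`` restricts
    to one).
    """
    f = features.frame
    f = f[f["condition"] == TASK]
    if presentation_id is not None:
        f = f[f["presentation_id"] == presentation_id]
        if f.empty:
            raise ValueError(f"no rows for presentation {presentation_id!r}")
    if channel_set == "std32":
        keep = set(montage.standard32_names)
    elif channel_set == "full":
        keep = set(montage.eeg_names)
    else:
        raise ValueError(f"unknown channel_set {channel_set!r}")
    f = f[f["channel"].isin(keep)]
    if f.empty:
        raise ValueError("no feature rows after channel selection")

    if not windowed:
        f = (
            f.groupby(["subject_id", "presentation_id", "group", "channel"], sort=False)
            ["hfd"].mean().reset_index().rename(columns={"group": "label"})
        )
        wide = f.pivot_table(
            index=["subject_id", "presentation_id", "label"],
            columns="channel", values="hfd", sort=False,
        )
    else:
        counts = f.groupby(["presentation_id"])["window_index"].max()
        if counts.nunique() > 1:
            raise ValueError(
                "inconsistent window counts across presentations: "
                + ", ".join(f"{p}={int(c) + 1}" for p, c in counts.items())
            )
        g = f.rename(columns={"group": "label"}).copy()
        g["feature"] = g["channel"] + "_w" + g["window_index"].astype(str)
        wide = g.pivot_table(
            index=["subject_id", "presentation_id", "label"],
            columns="feature", values="hfd", sort=False,
        )
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)][0]
        raise ValueError(f"incomplete feature vector for sample {bad}")
    feature_names = tuple(wide.columns)
    frame = wide.reset_index()
    frame.columns.name = None
    return SampleTable(frame=frame, feature_names=feature_names, channel_set=channel_set)


# ---------------------------------------------------------------------------
# Split plans
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Fold assignment of sample rows under one split scheme.

    ``folds`` holds (train, validation) integer row positions into the
    sample table the plan was built from; folds partition the in-scope
    rows, and under ``subject_specific`` no subject appears on both sides
    of any fold.
    """

    scheme: str
    folds: list[tuple[np.ndarray, np.ndarray]]
    seed: int
    presentation_id: str | None = None

    def validate(self, samples: SampleTable) -> None:
        all_val = np.concatenate([v for _, v in self.folds])
        if len(np.unique(all_val)) != len(all_val):
            raise AssertionError("validation folds overlap")
        subjects = samples.frame["subject_id"].to_numpy()
        for train, val in self.folds:
            if np.intersect1d(train, val).size:
                raise AssertionError("train/validation overlap within a fold")
            if self.scheme in (SUBJECT_SPECIFIC, PRESENTATION_SPECIFIC):
                if set(subjects[train]) & set(subjects[val]):
                    raise AssertionError("subject appears on both sides of a fold")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "scheme": self.scheme,
            "seed": self.seed,
            "presentation_id": self.presentation_id,
            "folds": [
                {"train": train.tolist(), "validation": val.tolist()}
                for train, val in self.folds
            ],
        }))


def make_split(
    samples: SampleTable,
    scheme: str,
    n_folds: int = 10,
    seed: int = 0,
    presentation_id: str | None = None,
) -> SplitPlan:
    """Build a k-fold plan under one of the three schemes (shuffled with
    ``seed``)."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if (presentation_id is not None) != (scheme == PRESENTATION_SPECIFIC):
        raise ValueError("presentation_id must be given iff scheme is presentation_specific")
    rng = np.random.default_rng(seed)
    frame = samples.frame

    if scheme == SUBJECT_PRESENTATION:
        rows = np.arange(len(frame))
        if n_folds > len(rows):
            raise ValueError(f"{n_folds} folds exceed {len(rows)} samples")
        perm = rng.permutation(rows)
        val_sets = np.array_split(perm, n_folds)
    else:
        if scheme == PRESENTATION_SPECIFIC:
            rows = np.flatnonzero((frame["presentation_id"] == presentation_id).to_numpy())
            if rows.size == 0:
                raise ValueError(f"no samples for presentation {presentation_id!r}")
        else:
            rows = np.arange(len(frame))
        subjects = frame["subject_id"].to_numpy()
        uniq = np.unique(subjects[rows])
        if n_folds > uniq.size:
            raise ValueError(f"{n_folds} folds exceed {uniq.size} subjects")
        subj_sets = np.array_split(rng.permutation(uniq), n_folds)
        val_sets = [rows[np.isin(subjects[rows], s)] for s in subj_sets]

    folds = []
    for val in val_sets:
        train = np.setdiff1d(rows, val)
        folds.append((train, np.sort(val)))
    plan = SplitPlan(scheme=scheme, folds=folds, seed=seed, presentation_id=presentation_id)
    plan.validate(samples)
    return plan


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

def _make_estimator(algorithm: str, params: Mapping, seed: int, standardize: bool):
    if algorithm == "nearest_neighbors":
        est = KNeighborsClassifier(**params)
    elif algorithm == "linear_svm":
        est = SVC(kernel="linear", random_state=seed, **params)
    elif algorithm == "decision_tree":
        est = DecisionTreeClassifier(random_state=seed, **params)
    elif algorithm == "adaboost":
        est = AdaBoostClassifier(random_state=seed, **params)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if standardize:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def _evaluate_plan(
    samples: SampleTable,
    plan: SplitPlan,
    algorithm: str,
    params: Mapping,
    seed: int,
    standardize: bool,
) -> list[float]:
    """Per-fold validation accuracies; degenerate single-class training
    folds are skipped with a warning."""
    X, y = samples.X, samples.y
    scores = []
    for train, val in plan.folds:
        if len(np.unique(y[train])) < 2:
            warnings.warn(
                f"fold with single-class training set skipped ({algorithm}, "
                f"scheme {plan.scheme})",
                stacklevel=2,
            )
            continue
        est = _make_estimator(algorithm, params, seed, standardize)
        est.fit(X[train], y[train])
        scores.append(float(np.mean(est.predict(X[val]) == y[val])))
    return scores


def _param_combos(grid: Mapping[str, list]) -> list[dict]:
    keys = list(grid)
    return [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k] for k in keys))]


def select_hyperparameters(
    samples: SampleTable,
    grid: Mapping[str, Mapping[str, list]] = DEFAULT_GRID,
    seeds: Sequence[int] = (0, 1, 2),
    n_folds: int = 10,
    standardize: bool = True,
) -> dict[str, dict]:
    """Best hyperparameters per algorithm by mean case-1 cross-validated
    accuracy over the seeds (ties resolved in grid order)."""
    best: dict[str, dict] = {}
    for algorithm, pgrid in grid.items():
        results = []
        for params in _param_combos(pgrid):
            accs = []
            for seed in seeds:
                plan = make_split(samples, SUBJECT_PRESENTATION, n_folds, seed)
                accs.extend(_evaluate_plan(samples, plan, algorithm, params, seed, standardize))
            results.append((float(np.mean(accs)), params))
        best[algorithm] = max(results, key=lambda t: t[0])[1]
    return best


@dataclass
class AccuracyReport:
    """Per (scheme, presentation, algorithm, seed) validation accuracy, with
    the hyperparameters used and the channel set the features came from."""

    frame: pd.DataFrame
    hyperparameters: dict[str, dict]
    channel_set: str = "full"

    def mean_table(self) -> pd.DataFrame:
        return (
            self.frame.groupby(["scheme", "presentation_id", "algorithm"], dropna=False)
            ["accuracy"].mean().reset_index()
        )

    def mean_accuracy(self, scheme: str, algorithm: str) -> float:
        f = self.frame
        sel = f[(f["scheme"] == scheme) & (f["algorithm"] == algorithm)]
        return float(sel["accuracy"].mean())


def run_grid(
    samples: SampleTable,
    schemes: Sequence[str] = (SUBJECT_PRESENTATION, SUBJECT_SPECIFIC),
    grid: Mapping[str, Mapping[str, list]] = DEFAULT_GRID,
    seeds: Sequence[int] = (0, 1, 2),
    n_folds: int = 10,
    presentations: Sequence[str] | None = None,
    hyperparameters: Mapping[str, Mapping] | None = None,
    standardize: bool = True,
    windowed_samples: Mapping[str, SampleTable] | None = None,
) -> AccuracyReport:
    """Cross-validated accuracy per scheme and algorithm, averaged over
    folds, reported per seed.

    Hyperparameters are tuned under the subject-presentation scheme (case 1)
    unless given, then frozen for every scheme.  For the
    presentation-specific scheme each presentation in ``presentations``
    (default: all) is run as its own task; ``windowed_samples`` may map a
    presentation id to a windowed sample table to use there instead of the
    whole-signal features.
    """
    if hyperparameters is None:
        hyperparameters = select_hyperparameters(samples, grid, seeds, n_folds, standardize)
    rows = []
    for scheme in schemes:
        if scheme == PRESENTATION_SPECIFIC:
            pids = presentations
            if pids is None:
                pids = list(pd.unique(samples.frame["presentation_id"]))
            for pid in pids:
                tbl = samples
                if windowed_samples and pid in windowed_samples:
                    tbl = windowed_samples[pid]
                for algorithm, params in hyperparameters.items():
                    for seed in seeds:
                        plan = make_split(tbl, scheme, n_folds, seed, presentation_id=pid)
                        accs = _evaluate_plan(tbl, plan, algorithm, params, seed, standardize)
                        rows.append({
                            "scheme": scheme, "presentation_id": pid,
                            "algorithm": algorithm, "seed": seed,
                            "accuracy": float(np.mean(accs)), "n_folds_used": len(accs),
                        })
        else:
            for algorithm, params in hyperparameters.items():
                for seed in seeds:
                    plan = make_split(samples, scheme, n_folds, seed)
                    accs = _evaluate_plan(samples, plan, algorithm, params, seed, standardize)
                    rows.append({
                        "scheme": scheme, "presentation_id": None,
                        "algorithm": algorithm, "seed": seed,
                        "accuracy": float(np.mean(accs)), "n_folds_used": len(accs),
                    })
    frame = pd.DataFrame(rows)
    return AccuracyReport(frame=frame, hyperparameters=dict(hyperparameters),
                          channel_set=samples.channel_set)


def compare_channel_sets(
    features: HFDTable,
    montage: MontageSpec,
    schemes: Sequence[str] = (SUBJECT_PRESENTATION,),
    grid: Mapping[str, Mapping[str, list]] = DEFAULT_GRID,
    seeds: Sequence[int] = (0, 1, 2),
    n_folds: int = 10,
    standardize: bool = True,
) -> dict[str, AccuracyReport]:
    """Identical classification pipeline on the full montage and on the
    10/20 standard-32 subset; hyperparameters tuned separately per set."""
    out: dict[str, AccuracyReport] = {}
    for channel_set in ("full", "std32"):
        samples = assemble_samples(features, montage, channel_set=channel_set)
        out[channel_set] = run_grid(
            samples, schemes=schemes, grid=grid, seeds=seeds,
            n_folds=n_folds, standardize=standardize,
        )
    return out


def best_per_scheme(report: AccuracyReport) -> pd.DataFrame:
    """Best mean accuracy per scheme (and per presentation for case 3);
    ties report every tied algorithm."""
    means = report.mean_table()
    if means.empty:
        raise ValueError("empty accuracy report")
    rows = []
    for (scheme, pid), sub in means.groupby(["scheme", "presentation_id"], dropna=False):
        top = sub["accuracy"].max()
        tied = sub[np.isclose(sub["accuracy"], top)]["algorithm"].tolist()
        rows.append({
            "scheme": scheme,
            "presentation_id": pid if pd.notna(pid) else None,
            "algorithms": sorted(tied),
            "accuracy": float(top),
        })
    return pd.DataFrame(rows)
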