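"""k_max tuning for the Higuchi estimator.

HFD has one consequential hyperparameter, the largest subsampling interval
k_max.  The tuning procedure sweeps a candidate grid, recording for each
candidate (a) the grand-mean HFD over all recordings and channels and
(b) the grand mean of the per-recording channel spread, max-channel HFD
minus min-channel HFD — the min read as the baseline complexity, the max as
the complexity of the most task-relevant channel.  The selected k_max
maximises the mean spread, preferring (within a relative tolerance) the
smallest candidate at which the mean HFD has already plateaued.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, TASK
from .hfd import HFDTable, _curve_lengths_matrix, _fit_slope

__all__ = ["DEFAULT_CANDIDATES", "KmaxSweep", "channel_spread", "sweep_kmax", "select_kmax"]

DEFAULT_CANDIDATES = (2, 5, 20, 100, 150, 200, 400)


@dataclass
class KmaxSweep:
    """Per-candidate grand means of HFD and of the channel spread."""

    candidates: tuple[int, ...]
    mean_hfd: tuple[float, ...]
    mean_spread: tuple[float, ...]
    n_recordings_used: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        order = np.argsort(self.candidates)
        self.candidates = tuple(int(self.candidates[i]) for i in order)
        self.mean_hfd = tuple(float(self.mean_hfd[i]) for i in order)
        self.mean_spread = tuple(float(self.mean_spread[i]) for i in order)
        if self.n_recordings_used:
            self.n_recordings_used = tuple(int(self.n_recordings_used[i]) for i in order)
        if len(self.candidates) != len(set(self.candidates)):
            raise ValueError("duplicate k_max candidates")
        if any(c < 2 for c in self.candidates):
            raise ValueError("k_max candidates must be >= 2")
        if len(self.mean_hfd) != len(self.candidates) or len(self.mean_spread) != len(self.candidates):
            raise ValueError("one mean per candidate required")
        if any(s < 0 for s in self.mean_spread):
            raise ValueError("channel spreads must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        data = {
            "k_max": self.candidates,
            "mean_hfd": self.mean_hfd,
            "mean_spread": self.mean_spread,
        }
        if self.n_recordings_used:
            data["n_recordings_used"] = self.n_recordings_used
        return pd.DataFrame(data)


def channel_spread(features: HFDTable) -> pd.Series:
    """Max-minus-min HFD across channels, per recording (and window).

    Indexed by (subject_id, condition, presentation_id, window_index);
    requires at least two channels per recording.
    """
    frame = features.frame.copy()
    frame["presentation_id"] = frame["presentation_id"].fillna("rest")
    grouped = frame.groupby(
        ["subject_id", "condition", "presentation_id", "window_index"], sort=True
    )["hfd"]
    counts = grouped.count()
    if (counts < 2).any():
        bad = counts[counts < 2].index[0]
        raise ValueError(f"recording {bad} has fewer than 2 channels; spread undefined")
    return grouped.max() - grouped.min()


def sweep_kmax(
    cohort: Cohort,
    candidates: Sequence[int] = DEFAULT_CANDIDATES,
    conditions: Sequence[str] = (TASK,),
) -> KmaxSweep:
    """Grand-mean HFD and channel spread per k_max candidate.

    Curve lengths are computed once per recording up to the largest
    feasible candidate and the log-log slope is refit per candidate.
    Candidates requiring more than half a recording's samples are skipped
    for that recording with a warning, and the per-candidate recording
    count is reported.
    """
    candidates = sorted(set(int(c) for c in candidates))
    if any(c < 2 for c in candidates):
        raise ValueError("k_max candidates must be >= 2")
    sums_hfd = {c: 0.0 for c in candidates}
    n_vals = {c: 0 for c in candidates}
    sums_spread = {c: 0.0 for c in candidates}
    n_recs = {c: 0 for c in candidates}

    for rec in cohort.iter_recordings(conditions=conditions):
        X = rec.eeg_signal()
        N = X.shape[1]
        feasible = [c for c in candidates if 2 * c <= N]
        skipped = [c for c in candidates if 2 * c > N]
        if skipped:
            warnings.warn(
                f"recording {rec.subject_id}/{rec.presentation_id} ({N} samples) "
                f"too short for k_max candidates {skipped}; skipped",
                stacklevel=2,
            )
        if not feasible:
            continue
        L = _curve_lengths_matrix(X, max(feasible))
        for c in feasible:
            fd = _fit_slope(L[:, :c], c)
            sums_hfd[c] += float(fd.sum())
            n_vals[c] += fd.size
            sums_spread[c] += float(fd.max() - fd.min())
            n_recs[c] += 1

    used = [c for c in candidates if n_recs[c] > 0]
    if not used:
        raise ValueError("no recording was long enough for any candidate")
    return KmaxSweep(
        candidates=tuple(used),
        mean_hfd=tuple(sums_hfd[c] / n_vals[c] for c in used),
        mean_spread=tuple(sums_spread[c] / n_recs[c] for c in used),
        n_recordings_used=tuple(n_recs[c] for c in used),
    )


def select_kmax(sweep: KmaxSweep, plateau_tol: float = 0.02) -> int:
    """Pick the k_max with the largest mean channel spread, resolved by the
    plateau of the mean HFD.

    Among candidates whose spread is within ``plateau_tol`` (relative) of
    the maximum, the smallest candidate whose mean HFD is within
    ``plateau_tol`` of the final candidate's mean HFD — i.e. where the
    mean-HFD curve has flattened — is returned; if none has plateaued, the
    smallest spread-maximising candidate is returned.
    """
    if not sweep.candidates:
        raise ValueError("empty sweep")
    cands = np.asarray(sweep.candidates)
    spread = np.asarray(sweep.mean_spread)
    hfd = np.asarray(sweep.mean_hfd)
    top = spread.max()
    near = spread >= top - plateau_tol * abs(top) if top > 0 else np.ones_like(spread, bool)
    final = hfd[-1]
    plateaued = np.abs(hfd - final) <= plateau_tol * abs(final)
    both = near & plateaued
    if both.any():
        return int(cands[both].min())
    return int(cands[near & (spread == spread[near].max())].min())
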