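"""Shared fixtures: reduced-scale montages and cohorts.

Desk-scale test cohorts use fewer subjects, channels and seconds than the
defaults and a lower sampling rate; every statistical property under test
is scale-free, so the reductions trade Monte-Carlo precision for runtime
only.
"""

from __future__ import annotations

import numpy as np
import pytest

from hfdeeg import (
    AUXILIARY_CHANNELS,
    STANDARD_32,
    CohortConfig,
    HfdParams,
    MontageSpec,
    extract_features,
    generate_cohort,
)


def small_montage(n_eeg: int = 12, n_std: int = 4) -> MontageSpec:
    """Reduced montage: n_std standard 10/20 labels, high-density fillers up
    to n_eeg EEG channels, plus the 5 auxiliary leads."""
    std = STANDARD_32[:n_std]
    fillers = tuple(f"HD{i:02d}" for i in range(1, n_eeg - n_std + 1))
    return MontageSpec(channel_names=std + fillers + AUXILIARY_CHANNELS,
                       standard32_names=std)


def make_cohort_config(**overrides) -> CohortConfig:
    """Reduced cohort defaults shared across tests; override per test."""
    base = dict(
        n_experts=6, n_novices=6, n_presentation_pairs=2,
        duration_range=(6.0, 10.0), rest_duration=8.0, sampling_rate=128.0,
        effect_channels=("HD01", "HD02"), effect_delta_fd=0.2,
        subject_sd=0.05, noise_sd=0.005, seed=11,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def montage12():
    return small_montage()


@pytest.fixture(scope="session")
def effect_cohort(montage12):
    """6+6 subjects, 2 presentation pairs, FD effect +0.2 for novices on
    HD01/HD02 during task."""
    return generate_cohort(make_cohort_config(), montage12)


@pytest.fixture(scope="session")
def effect_features(effect_cohort):
    return extract_features(effect_cohort, HfdParams(k_max=24))


def reference_curve_length(x, k: int) -> float:
    """Plain triple-loop curve length — the independent oracle for the
    vectorised implementation."""
    x = list(map(float, x))
    N = len(x)
    total = 0.0
    for m in range(1, k + 1):
        M = (N - m) // k
        s = 0.0
        for i in range(1, M + 1):
            s += abs(x[m + i * k - 1] - x[m + (i - 1) * k - 1])
        total += s * (N - 1) / (M * k) / k
    return total / k


def reference_hfd(x, k_max: int) -> float:
    """Naive HFD: triple-loop curve lengths + least-squares slope."""
    ks = np.arange(1, k_max + 1)
    L = np.array([reference_curve_length(x, int(k)) for k in ks])
    A = np.vstack([np.log(1.0 / ks), np.ones_like(ks, dtype=float)]).T
    slope, _ = np.linalg.lstsq(A, np.log(L), rcond=None)[0]
    return float(slope)
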