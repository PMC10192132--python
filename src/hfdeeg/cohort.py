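"""Synthetic EEG cohort generation.

Builds a two-group (expert / novice) cohort of multichannel EEG-like
recordings whose per-channel fractal dimension is controlled: every brain
channel carries a power-law (1/f^beta) signal at a configurable Higuchi
fractal dimension, a group effect is injected on a chosen channel subset
during the task condition only, and each subject carries a random FD offset
shared across all of that subject's channels and recordings.

Signals are produced by spectral synthesis of power-law noise: for a target
fractal dimension D in (1, 2) the amplitude spectrum is drawn proportional
to f^(-beta/2) with beta = 5 - 2*D, which is the spectral exponent of
fractional Brownian motion with Hurst exponent H = 2 - D.  Randomised
phases give an O(n log n), exactly reproducible generator.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import fft as spfft

__all__ = [
    "MontageSpec",
    "CohortConfig",
    "Recording",
    "CohortManifest",
    "Cohort",
    "synthesize_fractal_signal",
    "generate_recording",
    "generate_cohort",
    "write_recording",
    "read_recording",
    "read_cohort",
]

EXPERT = "expert"
NOVICE = "novice"
TASK = "task"
REST = "rest"

#: Non-brain auxiliary channels of the high-density cap: periocular
#: electrodes and the cardiac lead.  They never enter HFD analyses.
AUXILIARY_CHANNELS = ("VEOGL", "HEOGL", "HEOGR", "VEOGU", "HEART")

#: 32-channel subset following the international 10/20 extended layout,
#: the "standard" low-density montage the high-density cap is reduced to.
STANDARD_32 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "TP9", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
)


class ConfigurationError(ValueError):
    """Raised for invalid cohort or montage configuration."""


class ManifestExistsError(FileExistsError):
    """Raised when a cohort would overwrite an existing manifest."""


class RecordingParseError(ValueError):
    """Raised when a stored recording file is malformed or truncated."""


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MontageSpec:
    """Ordered electrode label set of a recording.

    ``channel_names`` lists every stored channel (brain + auxiliary) in
    signal-row order; ``auxiliary_names`` marks the non-brain leads and
    ``standard32_names`` the 10/20 subset used for the low-density
    comparison.
    """

    channel_names: tuple[str, ...]
    auxiliary_names: tuple[str, ...] = AUXILIARY_CHANNELS
    standard32_names: tuple[str, ...] = STANDARD_32

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        object.__setattr__(self, "auxiliary_names", tuple(self.auxiliary_names))
        object.__setattr__(self, "standard32_names", tuple(self.standard32_names))
        names = self.channel_names
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate channel labels in montage")
        missing_aux = set(self.auxiliary_names) - set(names)
        if missing_aux:
            raise ConfigurationError(f"auxiliary channels not in montage: {sorted(missing_aux)}")
        eeg = set(names) - set(self.auxiliary_names)
        bad_std = set(self.standard32_names) - eeg
        if bad_std:
            raise ConfigurationError(
                f"standard-32 channels not among EEG channels: {sorted(bad_std)}"
            )

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def eeg_names(self) -> tuple[str, ...]:
        """Brain channels, in montage order (auxiliaries removed)."""
        aux = set(self.auxiliary_names)
        return tuple(c for c in self.channel_names if c not in aux)

    def index_of(self, labels: Iterable[str]) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.channel_names)}
        try:
            return np.array([pos[lab] for lab in labels], dtype=int)
        except KeyError as exc:
            raise ConfigurationError(f"unknown channel label {exc.args[0]!r}") from exc

    @classmethod
    def default(cls) -> "MontageSpec":
        """129-channel montage: 32 standard 10/20 labels, 92 high-density
        filler sites (HD01..HD92) and the 5 auxiliary leads."""
        fillers = tuple(f"HD{i:02d}" for i in range(1, 93))
        names = STANDARD_32 + fillers + AUXILIARY_CHANNELS
        return cls(channel_names=names)


# ---------------------------------------------------------------------------
# Cohort configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    ``effect_delta_fd`` is the signed fractal-dimension offset added to
    ``effect_group``'s signals on ``effect_channels`` during the task
    condition only; it is absent at rest, which is what makes the resting
    recordings a negative control.  ``subject_sd`` is the standard
    deviation of a per-subject FD offset shared across all channels and
    recordings of that subject — the source of inter-subject variability
    that separates pooled from subject-wise cross-validation performance.
    """

    n_experts: int = 22
    n_novices: int = 22
    n_presentation_pairs: int = 8
    duration_range: tuple[float, float] = (13.0, 68.0)
    rest_duration: float = 60.0
    sampling_rate: float = 256.0
    baseline_fd: float = 1.6
    effect_channels: tuple[str, ...] = ("HD01", "HD02", "HD03", "HD04")
    effect_delta_fd: float = 0.15
    effect_group: str = NOVICE
    subject_sd: float = 0.05
    noise_sd: float = 0.005
    highcut_hz: float | None = 40.0
    amplitude_uv: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.effect_channels = tuple(self.effect_channels)
        self.duration_range = (float(self.duration_range[0]), float(self.duration_range[1]))
        if not (1.0 < self.baseline_fd < 2.0):
            raise ConfigurationError("baseline_fd must lie in (1, 2)")
        if not (1.0 < self.baseline_fd + self.effect_delta_fd < 2.0):
            raise ConfigurationError("baseline_fd + effect_delta_fd must lie in (1, 2)")
        if self.duration_range[0] <= 0 or self.duration_range[1] < self.duration_range[0]:
            raise ConfigurationError("duration_range must be positive and ordered")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.n_experts < 1 or self.n_novices < 1 or self.n_presentation_pairs < 1:
            raise ConfigurationError("cohort counts must be positive")
        if self.effect_group not in (EXPERT, NOVICE):
            raise ConfigurationError(f"effect_group must be {EXPERT!r} or {NOVICE!r}")

    def validate_against(self, montage: MontageSpec) -> None:
        eeg = set(montage.eeg_names)
        unknown = set(self.effect_channels) - eeg
        if unknown:
            raise ConfigurationError(
                f"effect_channels not EEG channels of the montage: {sorted(unknown)}"
            )


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """One subject x condition signal block (channels x samples, microvolts)."""

    subject_id: str
    group: str
    condition: str
    presentation_id: str | None
    signal: np.ndarray
    sampling_rate: float
    montage: MontageSpec

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D channels x samples array")
        if self.signal.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"signal has {self.signal.shape[0]} rows but montage lists "
                f"{self.montage.n_channels} channels"
            )
        if not np.isfinite(self.signal).all():
            raise ValueError("signal contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def eeg_signal(self) -> np.ndarray:
        """Brain channels only, montage order preserved."""
        return self.signal[self.montage.index_of(self.montage.eeg_names)]


# ---------------------------------------------------------------------------
# Fractal signal synthesis
# ---------------------------------------------------------------------------

def synthesize_fractal_signal(
    n_samples: int,
    target_fd: float,
    sampling_rate: float,
    seed,
    highcut_hz: float | None = None,
) -> np.ndarray:
    """Zero-mean, unit-variance power-law noise with Higuchi FD near ``target_fd``.

    Spectral synthesis: amplitude ~ f^(-beta/2) with beta = 5 - 2*target_fd
    (the fBm exponent for D = 2 - H), uniform random phases.  With
    ``highcut_hz`` set, spectral amplitudes above that frequency are zeroed,
    emulating low-pass-filtered EEG; the cutoff slightly depresses the
    estimated FD at fine scales, so validation signals are synthesized
    without it.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if not (1.0 < target_fd < 2.0):
        raise ValueError(f"target_fd must lie in (1, 2), got {target_fd}")
    if n_samples < 64:
        raise ValueError("n_samples must be at least 64")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beta = 5.0 - 2.0 * target_fd
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    amplitude = np.zeros_like(freqs)
    amplitude[1:] = freqs[1:] ** (-beta / 2.0)
    if highcut_hz is not None:
        amplitude[freqs > highcut_hz] = 0.0
    phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
    spectrum = amplitude * np.exp(1j * phases)
    spectrum[0] = 0.0
    x = np.fft.irfft(spectrum, n=n_samples)
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


def _subject_fd_offset(subject_id: str, config: CohortConfig) -> float:
    """Per-subject FD offset, stable across that subject's recordings.

    Derived from the cohort seed and a CRC32 of the subject id so any single
    recording can be regenerated without materialising the whole cohort.
    """
    key = zlib.crc32(subject_id.encode("utf-8"))
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, key]))
    return float(rng.normal(0.0, config.subject_sd))


def generate_recording(
    subject_id: str,
    group: str,
    condition: str,
    presentation_id: str | None,
    config: CohortConfig,
    montage: MontageSpec,
    seed,
    duration: float | None = None,
) -> Recording:
    """Generate one recording.

    Brain channels carry fractal signals at
    ``baseline_fd + subject offset (+ effect_delta_fd on effect channels,
    effect group, task condition)``; auxiliary channels carry unrelated
    white noise; white measurement noise at relative amplitude ``noise_sd``
    is mixed into every channel.
    """
    config.validate_against(montage)
    if group not in (EXPERT, NOVICE):
        raise ConfigurationError(f"unknown group {group!r}")
    if condition not in (TASK, REST):
        raise ConfigurationError(f"unknown condition {condition!r}")
    if duration is None:
        duration = config.rest_duration if condition == REST else config.duration_range[0]
    n_samples = int(round(duration * config.sampling_rate))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    subject_offset = _subject_fd_offset(subject_id, config)
    effect = set(config.effect_channels)
    aux = set(montage.auxiliary_names)
    amp = config.amplitude_uv
    C = montage.n_channels

    # per-channel target FD (NaN marks auxiliaries, which get white noise)
    fd = np.full(C, np.nan)
    for row, name in enumerate(montage.channel_names):
        if name in aux:
            continue
        f = config.baseline_fd + subject_offset
        if condition == TASK and name in effect and group == config.effect_group:
            f += config.effect_delta_fd
        fd[row] = np.clip(f, 1.01, 1.99)

    # batched spectral synthesis at an FFT-friendly length, truncated back
    nfast = int(spfft.next_fast_len(n_samples, real=True))
    freqs = np.fft.rfftfreq(nfast, d=1.0 / config.sampling_rate)
    brain = ~np.isnan(fd)
    beta = 5.0 - 2.0 * fd[brain]
    amplitude = np.zeros((brain.sum(), freqs.size))
    amplitude[:, 1:] = freqs[None, 1:] ** (-beta[:, None] / 2.0)
    if config.highcut_hz is not None:
        amplitude[:, freqs > config.highcut_hz] = 0.0
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(int(brain.sum()), freqs.size))
    spectrum = amplitude * np.exp(1j * phases)
    spectrum[:, 0] = 0.0
    x = spfft.irfft(spectrum, n=nfast, axis=1)[:, :n_samples]
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    np.divide(x, sd, out=x, where=sd > 0)

    signal = np.empty((C, n_samples))
    signal[brain] = amp * x + rng.normal(0.0, config.noise_sd * amp, size=(int(brain.sum()), n_samples))
    signal[~brain] = rng.normal(0.0, amp, size=(int((~brain).sum()), n_samples))
    return Recording(
        subject_id=subject_id,
        group=group,
        condition=condition,
        presentation_id=presentation_id,
        signal=signal,
        sampling_rate=config.sampling_rate,
        montage=montage,
    )


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortManifest:
    """Roster of subjects, presentations and recordings of one cohort."""

    subjects: list[tuple[str, str]]                      # (subject_id, group)
    presentations: list[tuple[str, str, float]]          # (presentation_id, style, duration s)
    recordings: list[dict]                               # index entries
    sampling_rate: float
    montage: MontageSpec
    config: CohortConfig

    @property
    def n_task_recordings(self) -> int:
        return sum(1 for r in self.recordings if r["condition"] == TASK)

    def presentation_duration(self, presentation_id: str) -> float:
        for pid, _style, dur in self.presentations:
            if pid == presentation_id:
                return dur
        raise KeyError(f"unknown presentation {presentation_id!r}")

    def to_dict(self) -> dict:
        cfg = dataclasses.asdict(self.config)
        return {
            "subjects": [list(s) for s in self.subjects],
            "presentations": [[p, s, d] for p, s, d in self.presentations],
            "recordings": self.recordings,
            "sampling_rate": self.sampling_rate,
            "montage": {
                "channel_names": list(self.montage.channel_names),
                "auxiliary_names": list(self.montage.auxiliary_names),
                "standard32_names": list(self.montage.standard32_names),
            },
            "config": cfg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortManifest":
        montage = MontageSpec(
            channel_names=tuple(d["montage"]["channel_names"]),
            auxiliary_names=tuple(d["montage"]["auxiliary_names"]),
            standard32_names=tuple(d["montage"]["standard32_names"]),
        )
        cfg = d["config"]
        for key in ("duration_range", "effect_channels"):
            cfg[key] = tuple(cfg[key])
        config = CohortConfig(**cfg)
        return cls(
            subjects=[tuple(s) for s in d["subjects"]],
            presentations=[(p, s, float(dur)) for p, s, dur in d["presentations"]],
            recordings=list(d["recordings"]),
            sampling_rate=float(d["sampling_rate"]),
            montage=montage,
            config=config,
        )


class Cohort:
    """A generated cohort: manifest plus access to every recording.

    Recordings are either regenerated lazily (deterministic from the cohort
    seed; the default, since a full-rate cohort is ~1 GB of samples) or read
    back from a storage directory when one was written.
    """

    def __init__(self, manifest: CohortManifest, directory: Path | None = None):
        self.manifest = manifest
        self.directory = Path(directory) if directory is not None else None

    @property
    def montage(self) -> MontageSpec:
        return self.manifest.montage

    @property
    def config(self) -> CohortConfig:
        return self.manifest.config

    def get_recording(self, entry: dict) -> Recording:
        if self.directory is not None:
            return read_recording(self.directory / entry["file"], montage=self.montage)
        return generate_recording(
            subject_id=entry["subject_id"],
            group=entry["group"],
            condition=entry["condition"],
            presentation_id=entry["presentation_id"],
            config=self.config,
            montage=self.montage,
            seed=np.random.SeedSequence(entry["seed_key"]),
            duration=entry["duration"],
        )

    def iter_recordings(self, conditions: Sequence[str] | None = None) -> Iterator[Recording]:
        for entry in self.manifest.recordings:
            if conditions is not None and entry["condition"] not in conditions:
                continue
            yield self.get_recording(entry)

    def __len__(self) -> int:
        return len(self.manifest.recordings)


def _presentation_labels(n_pairs: int) -> list[tuple[str, str]]:
    """Presentation ids (kA, kG) per pair; pair numbering skips nothing."""
    out = []
    for k in range(1, n_pairs + 1):
        out.append((f"{k}A", "A"))
        out.append((f"{k}G", "G"))
    return out


def generate_cohort(
    config: CohortConfig,
    montage: MontageSpec | None = None,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
) -> Cohort:
    """Generate the full cohort manifest (and optionally store recordings).

    Every subject receives ``2 * n_presentation_pairs`` task recordings and
    one eyes-open rest recording.  Presentation durations are drawn
    uniformly from ``duration_range``, matched within an (A, G) pair and
    identical across subjects — slide timing was fixed per presentation.
    With ``out_dir`` set, each recording is written as a columnar CSV and
    the manifest as JSON; otherwise recordings are regenerated on demand.
    """
    montage = montage or MontageSpec.default()
    config.validate_against(montage)
    root = np.random.SeedSequence(int(config.seed) & 0x7FFFFFFF)

    # presentation durations: one draw per pair, shared by the A and G form
    dur_rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 1]))
    lo, hi = config.duration_range
    pair_durations = dur_rng.uniform(lo, hi, size=config.n_presentation_pairs)
    presentations = []
    for (pid, style) in _presentation_labels(config.n_presentation_pairs):
        k = int(pid[:-1]) - 1
        presentations.append((pid, style, float(round(pair_durations[k], 1))))

    subjects = [(f"E{i+1:02d}", EXPERT) for i in range(config.n_experts)]
    subjects += [(f"N{i+1:02d}", NOVICE) for i in range(config.n_novices)]

    recordings: list[dict] = []
    base = int(config.seed) & 0x7FFFFFFF
    for si, (sid, group) in enumerate(subjects):
        for pi, (pid, style, dur) in enumerate(presentations):
            recordings.append({
                "subject_id": sid, "group": group, "condition": TASK,
                "presentation_id": pid, "style": style, "duration": dur,
                "seed_key": [base, 2, si, pi],
                "file": f"{sid}_{pid}.csv",
            })
        recordings.append({
            "subject_id": sid, "group": group, "condition": REST,
            "presentation_id": None, "style": None,
            "duration": float(config.rest_duration),
            "seed_key": [base, 3, si],
            "file": f"{sid}_rest.csv",
        })

    manifest = CohortManifest(
        subjects=subjects,
        presentations=presentations,
        recordings=recordings,
        sampling_rate=config.sampling_rate,
        montage=montage,
        config=config,
    )
    cohort = Cohort(manifest, directory=None)

    if out_dir is not None:
        out = Path(out_dir)
        manifest_path = out / "manifest.json"
        if manifest_path.exists() and not overwrite:
            raise ManifestExistsError(
                f"{manifest_path} exists; pass overwrite=True to replace it"
            )
        out.mkdir(parents=True, exist_ok=True)
        for entry in manifest.recordings:
            rec = cohort.get_recording(entry)
            write_recording(rec, out / entry["file"])
        manifest_path.write_text(json.dumps(manifest.to_dict(), indent=1))
        cohort.directory = out
    return cohort


def read_cohort(directory: str | Path) -> Cohort:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {directory}")
    manifest = CohortManifest.from_dict(json.loads(manifest_path.read_text()))
    return Cohort(manifest, directory=directory)


# ---------------------------------------------------------------------------
# Recording I/O (columnar CSV: metadata comment header, channel-label row,
# one row per sample)
# ---------------------------------------------------------------------------

def write_recording(recording: Recording, path: str | Path) -> None:
    path = Path(path)
    meta = {
        "subject_id": recording.subject_id,
        "group": recording.group,
        "condition": recording.condition,
        "presentation_id": recording.presentation_id,
        "sampling_rate": recording.sampling_rate,
        "n_samples": recording.n_samples,
    }
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        fh.write(",".join(recording.montage.channel_names) + "\n")
        np.savetxt(fh, recording.signal.T, fmt="%.8g", delimiter=",")


def read_recording(path: str | Path, montage: MontageSpec | None = None) -> Recording:
    """Read a stored recording; raises :class:`RecordingParseError` naming the
    offending field on malformed or truncated files."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" not in body:
                raise RecordingParseError(f"{path}: malformed metadata line {body!r}")
            key, _, val = body.partition("=")
            meta[key.strip()] = val.strip()
            line = fh.readline()
        header = line.strip()
        if not header:
            raise RecordingParseError(f"{path}: missing channel-label header row")
        channels = header.split(",")
        try:
            data = np.loadtxt(fh, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise RecordingParseError(f"{path}: unparseable sample data ({exc})") from exc
    for key in ("subject_id", "group", "condition", "sampling_rate", "n_samples"):
        if key not in meta:
            raise RecordingParseError(f"{path}: missing metadata field {key!r}")
    expected = int(meta["n_samples"])
    if data.shape[0] != expected:
        raise RecordingParseError(
            f"{path}: n_samples={expected} declared but {data.shape[0]} sample rows found"
        )
    if data.shape[1] != len(channels):
        raise RecordingParseError(
            f"{path}: {len(channels)} channel labels but {data.shape[1]} columns"
        )
    if montage is None:
        montage = MontageSpec(
            channel_names=tuple(channels),
            auxiliary_names=tuple(c for c in channels if c in AUXILIARY_CHANNELS),
            standard32_names=tuple(c for c in channels if c in STANDARD_32),
        )
    elif tuple(channels) != montage.channel_names:
        raise RecordingParseError(f"{path}: channel labels do not match the montage")
    pres = meta.get("presentation_id")
    return Recording(
        subject_id=meta["subject_id"],
        group=meta["group"],
        condition=meta["condition"],
        presentation_id=None if pres in (None, "None", "") else pres,
        signal=data.T,
        sampling_rate=float(meta["sampling_rate"]),
        montage=montage,
    )
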