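"""Synthetic cohort generator: determinism, structure, FD control, I/O."""

import numpy as np
import pytest

from hfdeeg import (
    CohortConfig,
    HfdParams,
    MontageSpec,
    extract_features,
    generate_cohort,
    generate_recording,
    higuchi_fd,
    higuchi_fd_channels,
    read_cohort,
    read_recording,
    synthesize_fractal_signal,
    write_recording,
)
from hfdeeg.cohort import (
    ConfigurationError,
    ManifestExistsError,
    RecordingParseError,
)

from conftest import make_cohort_config, small_montage


class TestSynthesizeFractalSignal:
    def test_deterministic_from_seed(self):
        a = synthesize_fractal_signal(512, 1.5, 256, seed=7)
        b = synthesize_fractal_signal(512, 1.5, 256, seed=7)
        assert np.array_equal(a, b)
        c = synthesize_fractal_signal(512, 1.5, 256, seed=8)
        assert not np.array_equal(a, c)

    def test_zero_mean_unit_variance(self):
        x = synthesize_fractal_signal(4096, 1.3, 256, seed=0)
        assert abs(x.mean()) < 1e-12
        assert x.std() == pytest.approx(1.0)

    @pytest.mark.parametrize("bad_fd", [0.9, 1.0, 2.0, 2.5])
    def test_target_fd_outside_open_interval_raises(self, bad_fd):
        with pytest.raises(ValueError):
            synthesize_fractal_signal(512, bad_fd, 256, seed=0)

    def test_highcut_removes_high_frequency_power(self):
        x = synthesize_fractal_signal(4096, 1.8, 256, seed=0, highcut_hz=40.0)
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(4096, 1 / 256)
        assert spec[freqs > 41].sum() / spec.sum() < 1e-20


class TestMontage:
    def test_default_montage_shape(self):
        m = MontageSpec.default()
        assert m.n_channels == 129
        assert len(m.eeg_names) == 124
        assert len(m.standard32_names) == 32
        assert set(m.auxiliary_names) == {"VEOGL", "HEOGL", "HEOGR", "VEOGU", "HEART"}

    def test_duplicate_and_unknown_labels_rejected(self):
        with pytest.raises(ConfigurationError):
            MontageSpec(channel_names=("A", "A") + tuple("VEOGL HEOGL HEOGR VEOGU HEART".split()))
        with pytest.raises(ConfigurationError):
            MontageSpec(channel_names=("Fp1",), auxiliary_names=("HEART",),
                        standard32_names=("Fp1",))


class TestCohortConfig:
    def test_invalid_fd_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            make_cohort_config(baseline_fd=2.2)
        with pytest.raises(ConfigurationError):
            make_cohort_config(baseline_fd=1.9, effect_delta_fd=0.2)

    def test_unknown_effect_channel_rejected(self):
        cfg = make_cohort_config(effect_channels=("NOPE",))
        with pytest.raises(ConfigurationError):
            generate_recording("S1", "expert", "task", "1A", cfg, small_montage(), seed=0)


class TestGenerateRecording:
    def test_task_effect_raises_novice_fd_on_effect_channels(self, montage12):
        cfg = make_cohort_config(subject_sd=0.0)
        idx = montage12.index_of(cfg.effect_channels)
        nov, exp = [], []
        for i in range(6):
            rn = generate_recording(f"N{i}", "novice", "task", "1A", cfg, montage12, seed=i)
            re_ = generate_recording(f"E{i}", "expert", "task", "1A", cfg, montage12, seed=100 + i)
            nov.append(higuchi_fd_channels(rn.signal[idx], 24).mean())
            exp.append(higuchi_fd_channels(re_.signal[idx], 24).mean())
        assert np.mean(nov) > np.mean(exp) + 0.05

    def test_rest_has_no_group_effect_by_construction(self, montage12):
        cfg = make_cohort_config(subject_sd=0.0)
        idx = montage12.index_of(cfg.effect_channels)
        nov, exp = [], []
        for i in range(6):
            rn = generate_recording(f"N{i}", "novice", "rest", None, cfg, montage12, seed=i)
            re_ = generate_recording(f"E{i}", "expert", "rest", None, cfg, montage12, seed=100 + i)
            nov.append(higuchi_fd_channels(rn.signal[idx], 24).mean())
            exp.append(higuchi_fd_channels(re_.signal[idx], 24).mean())
        assert abs(np.mean(nov) - np.mean(exp)) < 0.05

    def test_fd_calibration_slope_and_monotonicity(self, montage12):
        # estimated HFD regressed on configured target over {1.2,1.4,1.6,1.8}
        targets = [1.2, 1.4, 1.6, 1.8]
        means = []
        for t in targets:
            cfg = make_cohort_config(baseline_fd=t, effect_delta_fd=0.0,
                                     subject_sd=0.0, duration_range=(16.0, 16.0))
            vals = []
            for s in range(5):
                rec = generate_recording(f"S{s}", "expert", "task", "1A",
                                         cfg, montage12, seed=s)
                vals.append(higuchi_fd_channels(rec.eeg_signal(), 64).mean())
            means.append(np.mean(vals))
        assert all(b > a for a, b in zip(means, means[1:]))  # rank order preserved
        slope = np.polyfit(targets, means, 1)[0]
        assert 0.7 <= slope <= 1.3


class TestGenerateCohort:
    def test_default_config_yields_704_task_recordings(self):
        # manifest arithmetic only; signals stay lazy
        cohort = generate_cohort(CohortConfig(), MontageSpec.default())
        assert cohort.manifest.n_task_recordings == 704
        assert len(cohort) == 704 + 44
        assert len(cohort.manifest.subjects) == 44
        assert len(cohort.manifest.presentations) == 16

    def test_tiny_cohort_counts(self, montage12):
        # 4 subjects x (1 pair = 1A + 1G) = 8 task recordings, + 1 rest each
        cfg = make_cohort_config(n_experts=2, n_novices=2, n_presentation_pairs=1)
        cohort = generate_cohort(cfg, montage12)
        assert cohort.manifest.n_task_recordings == 8
        assert len(cohort) == 12

    def test_presentation_durations_shared_and_pair_matched(self):
        cohort = generate_cohort(CohortConfig(), MontageSpec.default())
        pres = {pid: dur for pid, _style, dur in cohort.manifest.presentations}
        for k in range(1, 9):
            assert pres[f"{k}A"] == pres[f"{k}G"]  # matched within pair
        for entry in cohort.manifest.recordings:
            if entry["condition"] == "task":
                assert entry["duration"] == pres[entry["presentation_id"]]
        lo, hi = cohort.config.duration_range
        assert all(lo <= d <= hi for d in pres.values())

    def test_cohort_is_byte_identical_across_runs(self, tmp_path, montage12):
        cfg = make_cohort_config(n_experts=1, n_novices=1, n_presentation_pairs=1,
                                 duration_range=(4.0, 5.0), rest_duration=4.0)
        generate_cohort(cfg, montage12, out_dir=tmp_path / "a")
        generate_cohort(cfg, montage12, out_dir=tmp_path / "b")
        files_a = sorted((tmp_path / "a").iterdir())
        files_b = sorted((tmp_path / "b").iterdir())
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            assert fa.read_bytes() == fb.read_bytes()

    def test_refuses_to_overwrite_manifest(self, tmp_path, montage12):
        cfg = make_cohort_config(n_experts=1, n_novices=1, n_presentation_pairs=1,
                                 duration_range=(4.0, 5.0), rest_duration=4.0)
        generate_cohort(cfg, montage12, out_dir=tmp_path)
        with pytest.raises(ManifestExistsError):
            generate_cohort(cfg, montage12, out_dir=tmp_path)
        generate_cohort(cfg, montage12, out_dir=tmp_path, overwrite=True)


class TestRecordingIO:
    def test_round_trip_preserves_signal_and_metadata(self, tmp_path, montage12):
        cfg = make_cohort_config()
        rec = generate_recording("E01", "expert", "task", "1A", cfg, montage12, seed=0,
                                 duration=4.0)
        path = tmp_path / "rec.csv"
        write_recording(rec, path)
        back = read_recording(path)
        assert back.subject_id == "E01" and back.condition == "task"
        assert back.presentation_id == "1A"
        assert back.sampling_rate == rec.sampling_rate
        assert back.montage.channel_names == montage12.channel_names
        np.testing.assert_allclose(back.signal, rec.signal, rtol=1e-7)

    def test_truncated_file_is_a_parse_error(self, tmp_path, montage12):
        cfg = make_cohort_config()
        rec = generate_recording("E01", "expert", "task", "1A", cfg, montage12, seed=0,
                                 duration=4.0)
        path = tmp_path / "rec.csv"
        write_recording(rec, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[: len(lines) // 2]) + "\n")
        with pytest.raises(RecordingParseError, match="n_samples"):
            read_recording(path)

    def test_missing_metadata_is_a_parse_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("# group=expert\nA,B\n1,2\n")
        with pytest.raises(RecordingParseError, match="subject_id"):
            read_recording(path)

    def test_stored_cohort_reads_back(self, tmp_path, montage12):
        cfg = make_cohort_config(n_experts=1, n_novices=1, n_presentation_pairs=1,
                                 duration_range=(4.0, 5.0), rest_duration=4.0)
        generate_cohort(cfg, montage12, out_dir=tmp_path)
        cohort = read_cohort(tmp_path)
        assert len(cohort) == 6  # 2 subjects x (2 task + 1 rest)
        recs = list(cohort.iter_recordings())
        assert {r.condition for r in recs} == {"task", "rest"}


def test_lazy_and_stored_recordings_agree(tmp_path, montage12):
    cfg = make_cohort_config(n_experts=1, n_novices=1, n_presentation_pairs=1,
                             duration_range=(4.0, 5.0), rest_duration=4.0)
    lazy = generate_cohort(cfg, montage12)
    stored = generate_cohort(cfg, montage12, out_dir=tmp_path)
    for a, b in zip(lazy.iter_recordings(), read_cohort(tmp_path).iter_recordings()):
        np.testing.assert_allclose(a.signal, b.signal, rtol=1e-7)
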