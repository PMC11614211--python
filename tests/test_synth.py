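"""Synthetic schedule and recording generator."""

import numpy as np
import pytest
from scipy import signal, stats

from seegdecode import (
    EffectSpec,
    MODALITIES,
    NoiseModel,
    SynthConfig,
    TaskSchedule,
    build_schedule,
    make_electrode_table,
    simulate_recording,
)
from seegdecode.synth import ConfigurationError, FIXATION_RANGE_S, ITI_RANGE_S


def _default_labels(n):
    return {f"C{i:03d}": "unknown" for i in range(n)}


class TestSchedule:
    def test_default_counts_and_jitters(self):
        sched = build_schedule(SynthConfig(n_contacts=1), seed=0)
        counts = sched.modality_counts()
        assert counts == {m: 40 for m in MODALITIES}
        n_total = len(sched.trials)
        n_catch = sum(t.is_catch for t in sched.trials)
        assert n_total == 160 + n_catch
        assert abs(n_catch - 0.10 * n_total) <= 1.0
        for t in sched.trials:
            assert FIXATION_RANGE_S[0] <= t.fixation_dur_s <= FIXATION_RANGE_S[1]
            assert ITI_RANGE_S[0] <= t.iti_dur_s <= ITI_RANGE_S[1]
            assert 1 <= t.quantity <= 9

    def test_onsets_increasing_nonoverlapping(self):
        sched = build_schedule(SynthConfig(n_contacts=1), seed=5)
        trials = sched.trials
        for prev, nxt in zip(trials, trials[1:]):
            # next fixation begins exactly at prev offset + prev ITI
            assert nxt.onset_s - nxt.fixation_dur_s == pytest.approx(
                prev.offset_s + prev.iti_dur_s
            )
            assert nxt.onset_s > prev.offset_s

    def test_seed_determinism(self):
        cfg = SynthConfig(n_contacts=1)
        assert build_schedule(cfg, seed=3) == build_schedule(cfg, seed=3)
        assert build_schedule(cfg, seed=3) != build_schedule(cfg, seed=4)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"presentations_per_modality": 0},
            {"catch_rate": 1.0},
            {"catch_rate": -0.1},
            {"n_contacts": 0},
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ConfigurationError):
            build_schedule(SynthConfig(**{"n_contacts": 1, **kwargs}), seed=0)

    def test_events_frame_round_trip(self):
        sched = build_schedule(SynthConfig(n_contacts=1, presentations_per_modality=5), seed=2)
        back = TaskSchedule.from_events_frame(sched.to_events_frame())
        assert len(back.trials) == len(sched.trials)
        for a, b in zip(sched.trials, back.trials):
            assert a.onset_s == pytest.approx(b.onset_s)
            assert a.modality == b.modality
            assert a.is_catch == b.is_catch
            assert a.iti_dur_s == pytest.approx(b.iti_dur_s)


class TestRecording:
    def test_noise_spectrum_follows_one_over_f(self):
        """Welch-spectrum oracle: noise-only PSD has log-log slope ~ -exponent."""
        cfg = SynthConfig(
            n_contacts=1,
            presentations_per_modality=4,
            noise=NoiseModel(one_over_f_exponent=1.0, amplitude_uv=20.0),
        )
        sched = build_schedule(cfg, seed=0)
        rec, _ = simulate_recording(sched, cfg, seed=0)
        f, psd = signal.welch(rec.data[0], fs=rec.sfreq, nperseg=4096)
        sel = (f >= 2) & (f <= 100)
        slope = stats.linregress(np.log10(f[sel]), np.log10(psd[sel])).slope
        assert slope == pytest.approx(-1.0, abs=0.15)

    def test_rms_amplitude_scaling(self):
        cfg = SynthConfig(
            n_contacts=1, presentations_per_modality=2,
            noise=NoiseModel(amplitude_uv=12.0),
        )
        sched = build_schedule(cfg, seed=1)
        rec, _ = simulate_recording(sched, cfg, seed=1)
        assert np.sqrt(np.mean(rec.data[0] ** 2)) == pytest.approx(12.0, rel=1e-6)

    def test_broadband_increase_detected_by_envelope_oracle(self):
        """Hilbert-envelope oracle: planted 70-150 Hz increase raises the
        post-stimulus band envelope over the pre-stimulus baseline, and the
        paired effect grows with magnitude."""
        effect_sizes = {}
        for mag in (1.5, 3.0, 6.0):
            cfg = SynthConfig(
                n_contacts=2,
                presentations_per_modality=10,
                region_labels=_default_labels(2),
                effects=(
                    EffectSpec(
                        contact="C000",
                        modalities=MODALITIES,
                        band_hz=(70.0, 150.0),
                        window_s=(0.0, 0.5),
                        magnitude=mag,
                    ),
                ),
                seed=9,
            )
            sched = build_schedule(cfg, seed=9)
            rec, manifest = simulate_recording(sched, cfg, seed=9)
            assert len(manifest["effects"]) == 1
            sos = signal.butter(4, (70, 150), btype="bandpass", fs=rec.sfreq, output="sos")
            env = np.abs(signal.hilbert(signal.sosfiltfilt(sos, rec.data[0])))
            diffs = []
            for t in sched.trials:
                if t.is_catch:
                    continue
                i = int(round(t.onset_s * rec.sfreq))
                pre = env[i - 600 : i - 100].mean()
                post = env[i + 50 : i + 450].mean()
                diffs.append(post - pre)
            diffs = np.asarray(diffs)
            assert diffs.mean() > 0
            effect_sizes[mag] = diffs.mean() / diffs.std(ddof=1)
        assert effect_sizes[1.5] < effect_sizes[3.0] < effect_sizes[6.0]

    def test_zero_noise_erp_is_deterministic(self):
        """With zero-amplitude noise, a single ERP effect reproduces the
        fixed template at each target trial onset, exactly."""
        from seegdecode.synth import _erp_template

        cfg = SynthConfig(
            n_contacts=2,
            presentations_per_modality=3,
            catch_rate=0.0,
            region_labels=_default_labels(2),
            noise=NoiseModel(amplitude_uv=0.0),
            effects=(
                EffectSpec(
                    contact="C001",
                    modalities=("arabic",),
                    band_hz=(8.0, 12.0),
                    window_s=(0.0, 0.5),
                    magnitude=1.0,
                    erp_amplitude=50.0,
                ),
            ),
            seed=4,
        )
        sched = build_schedule(cfg, seed=4)
        rec, _ = simulate_recording(sched, cfg, seed=4)
        assert np.all(rec.data[0] == 0.0)
        template = _erp_template(rec.sfreq, 50.0)
        expected = np.zeros(rec.n_samples)
        for t in sched.trials:
            if t.modality == "arabic" and not t.is_catch:
                i = int(round(t.onset_s * rec.sfreq))
                expected[i : i + len(template)] += template
        np.testing.assert_allclose(rec.data[1], expected, atol=1e-12)

    def test_effect_band_above_nyquist_rejected(self):
        cfg = SynthConfig(
            n_contacts=1,
            region_labels=_default_labels(1),
            effects=(
                EffectSpec(
                    contact="C000", modalities=("dots",),
                    band_hz=(400.0, 600.0), window_s=(0.0, 0.5), magnitude=2.0,
                ),
            ),
        )
        with pytest.raises(ConfigurationError, match="Nyquist"):
            cfg.validate()

    def test_recording_determinism(self):
        cfg = SynthConfig(n_contacts=2, presentations_per_modality=2,
                          region_labels=_default_labels(2))
        sched = build_schedule(cfg, seed=6)
        rec1, m1 = simulate_recording(sched, cfg, seed=6)
        rec2, m2 = simulate_recording(sched, cfg, seed=6)
        np.testing.assert_array_equal(rec1.data, rec2.data)
        assert m1 == m2


class TestElectrodeTable:
    def test_identity_mapping(self):
        cfg = SynthConfig(
            n_contacts=3,
            region_labels={"A": "superiortemporal", "B": "putamen", "C": "superiorparietal"},
        )
        table = make_electrode_table(cfg)
        assert list(table["name"]) == ["A", "B", "C"]
        assert list(table["region"]) == ["superiortemporal", "putamen", "superiorparietal"]

    def test_missing_labels_error(self):
        with pytest.raises(ConfigurationError):
            make_electrode_table(SynthConfig(n_contacts=2, region_labels=None))
        with pytest.raises(ConfigurationError):
            make_electrode_table(SynthConfig(n_contacts=2, region_labels={"A": "x"}))

    def test_duplicate_contact_names_error(self):
        class Dupes(dict):
            def __iter__(self):
                return iter(["A", "A"])

        cfg = SynthConfig(n_contacts=2, region_labels=Dupes({"A": "x"}))
        with pytest.raises(ConfigurationError, match="duplicate"):
            make_electrode_table(cfg)
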