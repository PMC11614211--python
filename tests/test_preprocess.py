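"""Re-referencing, epoching and rejection-threshold estimation."""

import numpy as np
import pytest

from seegdecode import (
    Recording,
    SynthConfig,
    average_reference,
    build_schedule,
    drop_bad_epochs,
    estimate_rejection_threshold,
    extract_epochs,
)
from seegdecode.preprocess import EpochSet, ITI, STIMULUS
from seegdecode.synth import STIMULUS_DUR_S, TaskSchedule, Trial


def _schedule(onsets, itis, fix=1.0, modality="arabic"):
    return TaskSchedule(
        trials=tuple(
            Trial(onset_s=o, modality=modality, quantity=5, is_catch=False,
                  fixation_dur_s=fix, iti_dur_s=iti)
            for o, iti in zip(onsets, itis)
        )
    )


def _gauss_epochs(rng, n_epochs=20, n_ch=3, n_samp=200, scale=1.0):
    data = rng.normal(0, scale, size=(n_epochs, n_ch, n_samp))
    half = n_epochs // 2
    cond = np.array([STIMULUS] * half + [ITI] * (n_epochs - half), dtype=object)
    return EpochSet(
        data=data, window=(-0.1, 0.1), condition=cond,
        modality=np.array([""] * n_epochs, dtype=object),
        sfreq=1000.0, ch_names=[f"c{i}" for i in range(n_ch)],
    )


class TestAverageReference:
    def test_zero_mean_and_idempotence(self, rng):
        rec = Recording(rng.normal(size=(5, 1000)), 100.0, list("abcde"))
        out = average_reference(rec)
        assert np.max(np.abs(out.data.mean(axis=0))) < 1e-10
        np.testing.assert_allclose(average_reference(out).data, out.data, atol=1e-12)

    def test_identical_channels_become_zero(self):
        x = np.sin(np.linspace(0, 10, 500))
        rec = Recording(np.stack([x, x, x]), 100.0, ["a", "b", "c"])
        assert np.max(np.abs(average_reference(rec).data)) < 1e-12

    def test_antisymmetric_pair_unchanged(self):
        x = np.sin(np.linspace(0, 10, 500))
        rec = Recording(np.stack([x, -x]), 100.0, ["a", "b"])
        np.testing.assert_allclose(average_reference(rec).data, rec.data, atol=1e-12)

    def test_single_channel_error(self):
        with pytest.raises(ValueError):
            average_reference(Recording(np.zeros((1, 10)), 10.0, ["a"]))


class TestExtractEpochs:
    def test_stimulus_epoch_covers_minus1_plus1(self, rng):
        sfreq = 500.0
        rec = Recording(rng.normal(size=(2, int(20 * sfreq))), sfreq, ["a", "b"])
        sched = _schedule([10.0], [3.5])
        ep = extract_epochs(rec, sched, balance=False)
        stim = ep.select(np.flatnonzero(ep.condition == STIMULUS))
        assert stim.n_epochs == 1
        i0 = int(round((10.0 - 1.0) * sfreq))
        np.testing.assert_array_equal(stim.data[0], rec.data[:, i0 : i0 + int(2 * sfreq)])

    def test_long_itis_yield_matched_baselines(self, rng):
        sfreq = 200.0
        onsets = 5.0 + np.arange(8) * 5.5  # fix 1 + stim 1 + iti 3.5
        rec = Recording(rng.normal(size=(2, int(60 * sfreq))), sfreq, ["a", "b"])
        ep = extract_epochs(rec, _schedule(onsets, [3.5] * 8), balance=False)
        counts = ep.class_counts()
        assert counts[STIMULUS] == counts[ITI] == 8

    def test_baseline_respects_guard_and_next_fixation(self, rng):
        sfreq = 200.0
        onsets = [5.0, 10.5]
        rec = Recording(rng.normal(size=(2, int(20 * sfreq))), sfreq, ["a", "b"])
        ep = extract_epochs(rec, _schedule(onsets, [3.5, 3.5]), balance=False)
        for c, center in zip(ep.condition, ep.centers_s):
            if c == ITI:
                prev = [o for o in onsets if o + 1.0 <= center]
                offset = max(prev) + STIMULUS_DUR_S
                assert center >= offset + 1.99 - 1e-9
                assert center + 1.0 <= offset + 3.5 + 1e-9  # ends before next fixation

    def test_short_itis_error(self, rng):
        sfreq = 200.0
        onsets = 5.0 + np.arange(4) * 3.5
        rec = Recording(rng.normal(size=(2, int(30 * sfreq))), sfreq, ["a", "b"])
        with pytest.raises(ValueError, match="baseline"):
            extract_epochs(rec, _schedule(onsets, [1.5] * 4), balance=False)

    def test_balancing_equalizes_counts(self, rng):
        sfreq = 200.0
        onsets = 5.0 + np.cumsum([0] + [5.5] * 7)
        itis = [3.5, 3.5, 3.5, 3.5, 2.0, 2.0, 2.0, 2.0]  # only 4 host baselines
        rec = Recording(rng.normal(size=(2, int(60 * sfreq))), sfreq, ["a", "b"])
        ep = extract_epochs(rec, _schedule(list(onsets), itis), balance=True, seed=1)
        counts = ep.class_counts()
        assert counts[STIMULUS] == counts[ITI] == 4


class TestRejectionThreshold:
    def test_outlier_lies_above_selected_threshold(self, rng):
        ep = _gauss_epochs(rng, n_epochs=30)
        ep.data[7] *= 20.0
        thr = estimate_rejection_threshold(ep, seed=0)
        assert thr < np.ptp(ep.data[7], axis=-1).max()

    def test_matches_direct_cv_objective(self, rng):
        """Independent re-evaluation of the grid + CV-RMSE objective."""
        from sklearn.model_selection import KFold

        ep = _gauss_epochs(rng, n_epochs=24)
        ep.data[3] *= 15.0
        ep.data[11] *= 8.0
        n_candidates, folds, seed = 30, 5, 7
        thr = estimate_rejection_threshold(ep, n_candidates=n_candidates, folds=folds, seed=seed)

        ptps = np.ptp(ep.data, axis=2).max(axis=1)
        grid = np.linspace(ptps.min(), ptps.max(), n_candidates)
        scores = np.zeros(n_candidates)
        for tr, va in KFold(folds, shuffle=True, random_state=seed).split(np.arange(ep.n_epochs)):
            med = np.median(ep.data[va], axis=0)
            for i, cand in enumerate(grid):
                keep = tr[ptps[tr] <= cand]
                scores[i] += (
                    np.inf if len(keep) == 0
                    else np.sqrt(np.mean((ep.data[keep].mean(axis=0) - med) ** 2))
                )
        assert thr == pytest.approx(grid[np.argmin(scores)])

    def test_scale_equivariance(self, rng):
        ep = _gauss_epochs(rng, n_epochs=20)
        ep.data[5] *= 12.0
        thr1 = estimate_rejection_threshold(ep, seed=3)
        scaled = _gauss_epochs(rng, n_epochs=1)  # fresh container
        scaled = EpochSet(
            data=ep.data * 4.0, window=ep.window, condition=ep.condition,
            modality=ep.modality, sfreq=ep.sfreq, ch_names=ep.ch_names,
        )
        thr2 = estimate_rejection_threshold(scaled, seed=3)
        assert thr2 == pytest.approx(4.0 * thr1, rel=1e-9)

    def test_identical_epochs_keep_everything(self, rng):
        base = rng.normal(size=(1, 2, 100))
        ep = EpochSet(
            data=np.repeat(base, 12, axis=0), window=(-0.05, 0.05),
            condition=np.array([STIMULUS] * 6 + [ITI] * 6, dtype=object),
            modality=np.array([""] * 12, dtype=object),
            sfreq=1000.0, ch_names=["a", "b"],
        )
        common_ptp = np.ptp(base[0], axis=-1).max()
        thr = estimate_rejection_threshold(ep, seed=0)
        assert thr >= common_ptp - 1e-12

    def test_too_few_epochs_error(self, rng):
        with pytest.raises(ValueError):
            estimate_rejection_threshold(_gauss_epochs(rng, n_epochs=8))


class TestDropBadEpochs:
    def test_infinite_threshold_keeps_all(self, rng):
        ep = _gauss_epochs(rng)
        out = drop_bad_epochs(ep, np.inf, rebalance=False)
        assert out.kept_mask.all()

    def test_spike_epoch_dropped_exactly(self, rng):
        ep = _gauss_epochs(rng, n_epochs=10, scale=1.0)
        thr = 50.0
        ep.data[4, 1, 10] = 2 * thr  # one-channel spike
        out = drop_bad_epochs(ep, thr, rebalance=False)
        assert not out.kept_mask[4]
        assert out.kept_mask.sum() == 9
        assert out.rejected[4] and out.rejected.sum() == 1

    def test_rebalancing_restores_equal_counts(self, rng):
        ep = _gauss_epochs(rng, n_epochs=80)  # 40 stimulus / 40 iti
        thr = 100.0
        for i in (0, 1, 2):  # three stimulus epochs spike
            ep.data[i, 0, 0] = 3 * thr
        out = drop_bad_epochs(ep, thr, seed=0, rebalance=True)
        counts = out.class_counts()
        assert counts[STIMULUS] == counts[ITI] == 37

    def test_all_rejected_error(self, rng):
        ep = _gauss_epochs(rng)
        with pytest.raises(ValueError):
            drop_bad_epochs(ep, 1e-12)


def test_epoching_preserves_samples_end_to_end(small_cohort):
    """Epoch data equals the corresponding recording slices (no filtering)."""
    _, schedule, rec, _ = small_cohort
    ref = average_reference(rec)
    ep = extract_epochs(ref, schedule, balance=False)
    for k in range(0, ep.n_epochs, 7):
        i0 = int(round((ep.centers_s[k] - 1.0) * ref.sfreq))
        np.testing.assert_array_equal(ep.data[k], ref.data[:, i0 : i0 + ep.n_samples])
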