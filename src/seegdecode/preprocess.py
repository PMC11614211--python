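"""Re-referencing, epoching and amplitude-based trial rejection.

The preprocessing chain mirrors common intracranial-EEG practice: the
multichannel recording is common-average re-referenced (which sharpens
high-frequency broadband activity), cut into 2-s epochs around stimulus
onsets and around baseline points placed inside sufficiently long
inter-trial intervals, and trials whose peak-to-peak amplitude at any
contact exceeds a cross-validated global threshold are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np
from sklearn.model_selection import KFold

if TYPE_CHECKING:  # pragma: no cover
    from .synth import TaskSchedule

logger = logging.getLogger(__name__)

#: Default guard between a stimulus offset and the baseline alignment point,
#: chosen so brain activity has returned to baseline before the epoch's
#: alignment point (1990 ms).
DEFAULT_ITI_GUARD_S = 1.99

STIMULUS = "stimulus"
ITI = "iti"


@dataclass
class Recording:
    """Continuous multichannel voltage recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltages in microvolts.
    sfreq : float
        Sampling frequency in Hz.
    ch_names : list of str
        Unique channel (contact) names.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("ch_names length does not match data")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq


@dataclass
class EpochSet:
    """Set of fixed-length epochs cut from one recording.

    ``condition`` holds ``"stimulus"`` or ``"iti"`` per epoch; ``modality``
    holds the stimulus modality (empty string for baseline epochs).
    ``kept_mask`` tracks which epochs survive artifact rejection and class
    re-balancing; the data array itself is never mutated.
    """

    data: np.ndarray  # (n_epochs, n_channels, n_samples)
    window: tuple[float, float]
    condition: np.ndarray  # (n_epochs,) of str
    modality: np.ndarray  # (n_epochs,) of str
    sfreq: float
    ch_names: list[str]
    centers_s: np.ndarray = field(default=None)  # alignment times in the recording
    kept_mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.condition = np.asarray(self.condition, dtype=object)
        self.modality = np.asarray(self.modality, dtype=object)
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.n_epochs, dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if self.centers_s is None:
            self.centers_s = np.full(self.n_epochs, np.nan)
        self.centers_s = np.asarray(self.centers_s, dtype=float)
        for arr, name in [
            (self.condition, "condition"),
            (self.modality, "modality"),
            (self.kept_mask, "kept_mask"),
            (self.centers_s, "centers_s"),
        ]:
            if len(arr) != self.n_epochs:
                raise ValueError(f"{name} length does not match epoch count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.n_samples) / self.sfreq

    def class_counts(self, mask: np.ndarray | None = None) -> dict[str, int]:
        mask = self.kept_mask if mask is None else mask
        return {
            STIMULUS: int(np.sum((self.condition == STIMULUS) & mask)),
            ITI: int(np.sum((self.condition == ITI) & mask)),
        }

    def select(self, idx: np.ndarray) -> "EpochSet":
        """Return a new EpochSet restricted to the given epoch indices."""
        idx = np.asarray(idx)
        return EpochSet(
            data=self.data[idx],
            window=self.window,
            condition=self.condition[idx],
            modality=self.modality[idx],
            sfreq=self.sfreq,
            ch_names=list(self.ch_names),
            centers_s=self.centers_s[idx],
            kept_mask=self.kept_mask[idx],
        )

    def kept(self) -> "EpochSet":
        """Return only the epochs whose ``kept_mask`` is True."""
        return self.select(np.flatnonzero(self.kept_mask))

    def max_peak_to_peak(self) -> np.ndarray:
        """Per-epoch maximum over channels of the peak-to-peak amplitude."""
        return np.ptp(self.data, axis=2).max(axis=1)


def average_reference(rec: Recording) -> Recording:
    """Common-average re-reference: subtract the instantaneous channel mean.

    After referencing the mean across channels is zero at every sample.
    The operation is idempotent.
    """
    if rec.n_channels < 2:
        raise ValueError("average reference is undefined for a single channel")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return Recording(data=data, sfreq=rec.sfreq, ch_names=list(rec.ch_names))


def _balance_classes(
    condition: np.ndarray, mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Equalize stimulus/ITI counts within ``mask`` by subsampling the larger
    class uniformly at random.  Returns the updated boolean mask."""
    mask = mask.copy()
    stim_idx = np.flatnonzero((condition == STIMULUS) & mask)
    iti_idx = np.flatnonzero((condition == ITI) & mask)
    n = min(len(stim_idx), len(iti_idx))
    for idx in (stim_idx, iti_idx):
        if len(idx) > n:
            drop = rng.choice(idx, size=len(idx) - n, replace=False)
            mask[drop] = False
    return mask


def extract_epochs(
    rec: Recording,
    schedule: "TaskSchedule",
    iti_guard_s: float = DEFAULT_ITI_GUARD_S,
    window: tuple[float, float] = (-1.0, 1.0),
    balance: bool = True,
    seed: int = 0,
) -> EpochSet:
    """Cut stimulus and inter-trial (baseline) epochs from a recording.

    One stimulus epoch is taken per non-catch trial, aligned to stimulus
    onset with a (-1, +1) s window.  One baseline epoch is attempted per
    trial, aligned to a point at least ``iti_guard_s`` after the stimulus
    offset and chosen so the epoch ends before the next fixation onset
    (midpoint of the eligible interval); inter-trial intervals shorter than
    ``iti_guard_s`` + 1 s yield no baseline epoch.

    With ``balance=True`` the larger class is subsampled (seeded) so
    stimulus and baseline counts are equal.
    """
    rng = np.random.default_rng(seed)
    n_samp = int(round((window[1] - window[0]) * rec.sfreq))

    chunks, conditions, modalities, centers = [], [], [], []

    def _try_add(center: float, cond: str, modality: str) -> bool:
        start = int(round((center + window[0]) * rec.sfreq))
        if start < 0 or start + n_samp > rec.n_samples:
            logger.warning(
                "skipping %s epoch at %.3f s: window outside recording", cond, center
            )
            return False
        chunks.append(rec.data[:, start : start + n_samp])
        conditions.append(cond)
        modalities.append(modality)
        centers.append(center)
        return True

    for trial in schedule.trials:
        if not trial.is_catch:
            _try_add(trial.onset_s, STIMULUS, trial.modality)
        # baseline epoch inside the inter-trial interval following this trial
        offset = trial.offset_s
        next_fix = offset + trial.iti_dur_s
        lo, hi = offset + iti_guard_s, next_fix - window[1]
        if hi >= lo:
            _try_add((lo + hi) / 2.0, ITI, "")

    conditions = np.asarray(conditions, dtype=object)
    if int(np.sum(conditions == ITI)) == 0:
        raise ValueError(
            "no inter-trial interval can host a baseline epoch "
            f"(guard {iti_guard_s:.3f} s requires ITIs >= {iti_guard_s + window[1]:.3f} s)"
        )

    epochs = EpochSet(
        data=np.stack(chunks),
        window=window,
        condition=conditions,
        modality=np.asarray(modalities, dtype=object),
        sfreq=rec.sfreq,
        ch_names=list(rec.ch_names),
        centers_s=np.asarray(centers),
    )
    if balance:
        epochs.kept_mask = _balance_classes(epochs.condition, epochs.kept_mask, rng)
        epochs = epochs.kept()
    return epochs


def estimate_rejection_threshold(
    epochs: EpochSet,
    n_candidates: int = 30,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Cross-validated global peak-to-peak rejection threshold.

    Candidate thresholds span the observed range of per-epoch maximum
    peak-to-peak amplitudes.  For each candidate, epochs are split into
    ``folds`` folds; the RMSE between the mean of threshold-surviving
    training epochs and the median of the validation epochs is accumulated,
    and the candidate minimizing the summed objective is returned.  This is
    the cross-validated global-threshold criterion used for trial rejection,
    without any channel-level repair.
    """
    if epochs.n_epochs < 10:
        raise ValueError("need at least 10 epochs to estimate a threshold")
    ptps = epochs.max_peak_to_peak()
    grid = np.linspace(ptps.min(), ptps.max(), n_candidates)
    scores = np.zeros(n_candidates)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, val_idx in kf.split(np.arange(epochs.n_epochs)):
        med_val = np.median(epochs.data[val_idx], axis=0)
        for i, thr in enumerate(grid):
            keep = train_idx[ptps[train_idx] <= thr]
            if len(keep) == 0:
                scores[i] = np.inf
                continue
            mean_train = epochs.data[keep].mean(axis=0)
            scores[i] += float(np.sqrt(np.mean((mean_train - med_val) ** 2)))
    return float(grid[int(np.argmin(scores))])


def drop_bad_epochs(
    epochs: EpochSet,
    threshold: float,
    seed: int = 0,
    rebalance: bool = True,
) -> EpochSet:
    """Reject epochs whose max-over-channels peak-to-peak exceeds ``threshold``.

    Returns a new EpochSet whose ``kept_mask`` is False for rejected epochs
    (and, when ``rebalance`` is set, for the seeded subsample of the larger
    class dropped to restore stimulus/baseline balance).  The rejection mask
    alone is available as the ``rejected`` attribute on the result.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    rejected = epochs.max_peak_to_peak() > threshold
    mask = epochs.kept_mask & ~rejected
    if not mask.any():
        raise ValueError("all epochs rejected by the threshold")
    if rebalance:
        rng = np.random.default_rng(seed)
        mask = _balance_classes(epochs.condition, mask, rng)
        if not mask.any():
            raise ValueError("rejection left one class empty")
    out = replace(epochs, kept_mask=mask)
    out.rejected = rejected
    return out
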