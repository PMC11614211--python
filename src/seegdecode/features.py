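"""Per-epoch classifier features: Morlet time-frequency power with the
low-frequency voltage trace appended.

Each epoch of one contact is decomposed with Morlet wavelets into a
(frequency x time) power grid; the 0.1-40 Hz band-passed voltage trace,
resampled to the same time grid, is appended as one extra row so
event-related potentials can contribute to classification alongside
spectral power.  Time points within half the longest wavelet's support of
an epoch edge are cropped to keep wavelet edge artifacts out of the
features.  The flattened grid is the classifier's feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .preprocess import EpochSet

_LOG_FLOOR = 1e-30


def default_freqs(n: int = 50, fmin: float = 3.0, fmax: float = 250.0) -> np.ndarray:
    """Log-spaced analysis frequencies.

    The lower bound defaults to 3 Hz so that the longest wavelet (3 cycles)
    fits a 2-s epoch with usable time points left after edge cropping;
    longer epochs admit lower frequencies.
    """
    return np.geomspace(fmin, fmax, n)


def default_n_cycles(freqs: np.ndarray) -> np.ndarray:
    """Half-frequency cycle counts with a floor of 3 cycles."""
    return np.maximum(np.asarray(freqs) / 2.0, 3.0)


@dataclass
class TFRConfig:
    freqs_hz: np.ndarray = field(default_factory=default_freqs)
    n_cycles: np.ndarray | None = None
    decim: int = 10
    bandpass_hz: tuple[float, float] = (0.1, 40.0)
    log_power: bool = True

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        if self.n_cycles is None:
            self.n_cycles = default_n_cycles(self.freqs_hz)
        self.n_cycles = np.broadcast_to(
            np.asarray(self.n_cycles, dtype=float), self.freqs_hz.shape
        ).copy()
        if not np.all(np.diff(self.freqs_hz) > 0):
            raise ValueError("freqs_hz must be strictly increasing")
        if self.freqs_hz[0] < 0.5 or self.freqs_hz[-1] > 500:
            raise ValueError("freqs_hz outside a plausible LFP range")
        if np.any(self.n_cycles <= 0):
            raise ValueError("n_cycles must be positive")
        if self.decim < 1:
            raise ValueError("decim must be >= 1")
        lo, hi = self.bandpass_hz
        if not (0 < lo < hi):
            raise ValueError("invalid bandpass band")

    @property
    def n_freqs(self) -> int:
        return len(self.freqs_hz)

    def crop_s(self) -> float:
        """Half the longest wavelet support (seconds) cropped at each edge."""
        return float((self.n_cycles / self.freqs_hz).max() / 2.0)

    def validate_for(self, sfreq: float, n_samples: int) -> None:
        if self.freqs_hz[-1] > sfreq / 2:
            raise ValueError(
                f"max frequency {self.freqs_hz[-1]} Hz exceeds Nyquist ({sfreq / 2})"
            )
        longest = (self.n_cycles / self.freqs_hz).max() * sfreq
        if longest > n_samples:
            raise ValueError(
                "epoch shorter than the longest wavelet support; "
                "raise the minimum frequency or shorten the wavelets"
            )
        if sfreq / self.decim < 2 * self.bandpass_hz[1]:
            raise ValueError(
                "decimated rate must stay above twice the voltage band edge"
            )


def _grid_selection(
    cfg: TFRConfig, window: tuple[float, float], sfreq: float, n_samples: int
) -> tuple[np.ndarray, np.ndarray]:
    """Decimated time stamps and the boolean crop mask applied to them."""
    times = window[0] + np.arange(n_samples)[:: cfg.decim] / sfreq
    crop = cfg.crop_s()
    eps = 1e-9
    keep = (times >= window[0] + crop - eps) & (times <= window[1] - crop + eps)
    return times, keep


def morlet_power(
    epochs: EpochSet, cfg: TFRConfig, channel: str
) -> tuple[np.ndarray, np.ndarray]:
    """Morlet wavelet power for one contact.

    Returns ``(power, times)`` with ``power`` of shape
    (n_epochs, n_freqs, n_times): non-negative power at the decimated,
    edge-cropped time grid.
    """
    from mne.time_frequency import tfr_array_morlet

    cfg.validate_for(epochs.sfreq, epochs.n_samples)
    ci = epochs.ch_names.index(channel)
    power = tfr_array_morlet(
        epochs.data[:, ci : ci + 1, :],
        sfreq=epochs.sfreq,
        freqs=cfg.freqs_hz,
        n_cycles=cfg.n_cycles,
        output="power",
        decim=cfg.decim,
        zero_mean=True,
        verbose="error",
    )[:, 0]  # (n_epochs, n_freqs, n_times_decim)
    times, keep = _grid_selection(cfg, epochs.window, epochs.sfreq, epochs.n_samples)
    return power[:, :, keep], times[keep]


def bandpass_voltage(
    epochs: EpochSet,
    channel: str,
    band: tuple[float, float] | None = None,
    cfg: TFRConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-phase band-passed voltage trace on the power time grid.

    The low-pass edge (default 40 Hz) is a 4th-order Butterworth applied
    forward-backward per epoch.  A high-pass edge below the epoch's
    spectral resolution (shorter than one cycle per epoch, as 0.1 Hz is for
    2-s epochs) reduces to mean removal and is implemented as such; a
    resolvable high-pass edge gets a 2nd-order zero-phase Butterworth.
    The result is decimated and cropped exactly like the power grid.
    """
    cfg = cfg if cfg is not None else TFRConfig()
    band = band if band is not None else cfg.bandpass_hz
    lo, hi = band
    if not (0 < lo < hi < epochs.sfreq / 2):
        raise ValueError(f"invalid band {band} for sfreq {epochs.sfreq}")
    ci = epochs.ch_names.index(channel)
    x = epochs.data[:, ci, :]
    x = x - x.mean(axis=-1, keepdims=True)
    epoch_len_s = epochs.n_samples / epochs.sfreq
    if lo > 1.0 / epoch_len_s:
        sos_hp = signal.butter(2, lo, btype="highpass", fs=epochs.sfreq, output="sos")
        x = signal.sosfiltfilt(sos_hp, x, axis=-1)
    sos = signal.butter(4, hi, btype="lowpass", fs=epochs.sfreq, output="sos")
    traces = signal.sosfiltfilt(sos, x, axis=-1)
    times, keep = _grid_selection(cfg, epochs.window, epochs.sfreq, epochs.n_samples)
    return traces[:, :: cfg.decim][:, keep], times[keep]


@dataclass
class EpochFeatureSet:
    """Flattened (n_freqs + 1) x n_times feature grids for a set of epochs.

    Rows 0..n_freqs-1 are (optionally log10) Morlet power; the final row is
    the band-passed voltage trace.  ``vectors`` has one flattened grid per
    epoch; ``unflatten`` is the exact inverse of the flattening.
    """

    vectors: np.ndarray  # (n_epochs, n_rows * n_times)
    freqs_hz: np.ndarray
    times: np.ndarray
    log_power: bool = True

    @property
    def n_epochs(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_rows(self) -> int:
        return len(self.freqs_hz) + 1

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_times)

    def unflatten(self, vector: np.ndarray) -> np.ndarray:
        return np.asarray(vector).reshape(self.grid_shape)

    def flatten(self, grid: np.ndarray) -> np.ndarray:
        grid = np.asarray(grid)
        if grid.shape != self.grid_shape:
            raise ValueError(f"grid shape {grid.shape} != {self.grid_shape}")
        return grid.reshape(-1)

    def grid(self, epoch: int) -> np.ndarray:
        return self.unflatten(self.vectors[epoch])

    def select(self, idx: np.ndarray) -> "EpochFeatureSet":
        return EpochFeatureSet(
            vectors=self.vectors[np.asarray(idx)],
            freqs_hz=self.freqs_hz,
            times=self.times,
            log_power=self.log_power,
        )


def build_feature_matrix(
    power: np.ndarray,
    voltage: np.ndarray,
    cfg: TFRConfig,
    freqs_hz: np.ndarray | None = None,
    times: np.ndarray | None = None,
) -> EpochFeatureSet:
    """Assemble per-epoch feature vectors from power grids and voltage traces.

    Power is log10-transformed when ``cfg.log_power`` is set; the voltage
    trace is appended as the final grid row; grids are flattened row-major.
    """
    power = np.asarray(power, dtype=float)
    voltage = np.asarray(voltage, dtype=float)
    if power.ndim != 3 or voltage.ndim != 2:
        raise ValueError("power must be (epochs, freqs, times); voltage (epochs, times)")
    if power.shape[0] != voltage.shape[0] or power.shape[2] != voltage.shape[1]:
        raise ValueError("power and voltage have mismatched epoch/time axes")
    freqs_hz = cfg.freqs_hz if freqs_hz is None else np.asarray(freqs_hz)
    if power.shape[1] != len(freqs_hz):
        raise ValueError("power frequency axis does not match configuration")
    if cfg.log_power:
        power = np.log10(np.maximum(power, _LOG_FLOOR))
    grids = np.concatenate([power, voltage[:, None, :]], axis=1)
    n_ep = grids.shape[0]
    if times is None:
        times = np.arange(power.shape[2], dtype=float)
    return EpochFeatureSet(
        vectors=grids.reshape(n_ep, -1),
        freqs_hz=np.asarray(freqs_hz, dtype=float),
        times=np.asarray(times, dtype=float),
        log_power=cfg.log_power,
    )


def standardize(
    vectors: np.ndarray, train_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score every feature using mean/SD of the training epochs only.

    Zero-variance features are left unscaled (SD treated as 1).  Returns
    ``(z, mean, sd)`` where ``z`` covers all epochs.
    """
    train = vectors[np.asarray(train_idx)]
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (vectors - mean) / sd, mean, sd
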