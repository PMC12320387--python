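"""Signal conditioning and differential-entropy (DE) feature extraction.

EEG windows a few seconds long are well approximated as Gaussian, and the
differential entropy of a Gaussian has the closed form

    DE = 1/2 * log(2 * pi * e * sigma^2)   [nats]

so per-band DE reduces to a log-variance feature. The pipeline is: optional
anti-aliased resampling, zero-phase Butterworth band decomposition, then DE
on non-overlapping tapered windows, yielding a windows x channels x bands
tensor whose per-window flattened dimension is C*B (e.g. 62*5 = 310 for a
62-channel cap with five bands).

Two DE estimators are provided. ``"variance"`` (default) computes the
closed form from the tapered window's time-domain variance, with a taper
power normalization so stationary noise is estimated without bias.
``"psd"`` integrates the periodogram over the band and applies the same
closed form to the recovered band power; the two agree for band-limited
Gaussian signals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .montage import DEFeatureTensor, EEGRecording

__all__ = [
    "BandSpec",
    "WindowSpec",
    "BAND_PRESETS",
    "band_preset",
    "resample",
    "bandpass",
    "band_decompose",
    "differential_entropy",
    "extract_de_features",
]

logger = logging.getLogger(__name__)

#: Variance floor for degenerate (constant) windows, in signal units^2.
VARIANCE_FLOOR = 1e-12

_LOG_2PIE = math.log(2 * math.pi * math.e)


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band, e.g. ``BandSpec("alpha", 8, 14)``."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"band '{self.name}': need 0 < low < high Hz")


@dataclass(frozen=True)
class WindowSpec:
    """Analysis window: length and overlap in seconds, plus taper."""

    length_s: float = 4.0
    overlap_s: float = 0.0
    taper: str = "hanning"

    def __post_init__(self) -> None:
        if self.length_s <= 0:
            raise ValueError("window length must be positive")
        if not (0 <= self.overlap_s < self.length_s):
            raise ValueError("overlap must satisfy 0 <= overlap < length")
        if self.taper not in ("hanning", "rect"):
            raise ValueError("taper must be 'hanning' or 'rect'")


# Five-band split used with 62-channel caps (after a 1-70 Hz bandpass) and
# the four-band split used with 32-channel caps (after 4-45 Hz).
BAND_PRESETS: dict[str, tuple[BandSpec, ...]] = {
    "seed5": (
        BandSpec("delta", 1, 4),
        BandSpec("theta", 4, 8),
        BandSpec("alpha", 8, 14),
        BandSpec("beta", 14, 31),
        BandSpec("gamma", 31, 50),
    ),
    "deap4": (
        BandSpec("theta", 4, 8),
        BandSpec("alpha", 8, 13),
        BandSpec("beta", 13, 30),
        BandSpec("gamma", 30, 45),
    ),
}


def band_preset(name: str) -> list[BandSpec]:
    try:
        return list(BAND_PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown band preset '{name}' (have {sorted(BAND_PRESETS)})"
        ) from None


def resample(rec: EEGRecording, fs_out: float) -> EEGRecording:
    """Anti-aliased polyphase downsampling; trial bounds are rescaled.

    Upsampling is not supported (``fs_out`` must not exceed ``rec.fs``).
    Trial boundaries are mapped by ``floor(bound * fs_out / fs)``.
    """
    if fs_out > rec.fs:
        raise ValueError(
            f"upsampling not supported (fs={rec.fs} Hz -> {fs_out} Hz requested)"
        )
    if fs_out == rec.fs:
        return EEGRecording(
            rec.signal.copy(), rec.fs, rec.montage, list(rec.trials), rec.subject_id
        )
    frac = Fraction(fs_out / rec.fs).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    out = sps.resample_poly(rec.signal, up, down, axis=1)
    scale = fs_out / rec.fs
    trials = [
        (int(math.floor(s * scale)), int(math.floor(e * scale)), lab)
        for s, e, lab in rec.trials
    ]
    return EEGRecording(out, fs_out, rec.montage, trials, rec.subject_id)


def _band_sos(low: float, high: float, fs: float, order: int = 4):
    nyq = fs / 2
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz invalid for fs={fs} Hz (Nyquist {nyq} Hz)"
        )
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(rec: EEGRecording, low: float, high: float, order: int = 4) -> EEGRecording:
    """Zero-phase (forward-backward) Butterworth bandpass, same shape."""
    sos = _band_sos(low, high, rec.fs, order)
    out = sps.sosfiltfilt(sos, rec.signal, axis=1)
    return EEGRecording(out, rec.fs, rec.montage, list(rec.trials), rec.subject_id)


def band_decompose(rec: EEGRecording, bands: list[BandSpec]) -> list[EEGRecording]:
    """One zero-phase band-filtered copy of the recording per band, in order."""
    return [bandpass(rec, b.low, b.high) for b in bands]


def differential_entropy(window_samples: np.ndarray, floor: float = VARIANCE_FLOOR) -> float:
    """Closed-form Gaussian differential entropy of one window, in nats.

    ``1/2 log(2 pi e sigma^2)`` with ``sigma^2`` the maximum-likelihood
    (ddof=0) variance of the samples. A constant window is floored at
    ``1/2 log(2 pi e floor)`` so downstream training stays finite.
    """
    x = np.asarray(window_samples, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D window with at least 2 samples")
    var = float(np.var(x))
    if var < floor:
        logger.warning("zero-variance window; flooring variance at %g", floor)
        var = floor
    return 0.5 * (_LOG_2PIE + math.log(var))


def _window_starts(n_trial: int, win_len: int, step: int) -> list[int]:
    # non-overlapping tiling by default; trailing partial window dropped
    return list(range(0, n_trial - win_len + 1, step))


def _taper(win: WindowSpec, n: int) -> tuple[np.ndarray, float]:
    if win.taper == "hanning":
        w = np.hanning(n)
        return w, float(np.mean(w**2))  # power normalization factor
    return np.ones(n), 1.0


def extract_de_features(
    rec: EEGRecording,
    bands: list[BandSpec],
    win: WindowSpec = WindowSpec(),
    method: str = "variance",
    floor: float = VARIANCE_FLOOR,
) -> DEFeatureTensor:
    """DE features per window, channel, and band for every trial.

    Windows tile each trial from its start with step ``length - overlap``;
    a trial shorter than one window contributes nothing (logged). Each
    window inherits its trial's label.

    ``method="variance"``: band-filter the full recording once per band,
    then take the tapered-window variance (divided by the taper's mean
    square, removing the taper's power bias for stationary signals).
    ``method="psd"``: per window, integrate the Hann periodogram over the
    band and use the closed form on that band power.
    """
    if method not in ("variance", "psd"):
        raise ValueError("method must be 'variance' or 'psd'")
    win_len = int(round(win.length_s * rec.fs))
    step = win_len - int(round(win.overlap_s * rec.fs))
    if win_len < 2:
        raise ValueError("window shorter than 2 samples at this sampling rate")

    banded = band_decompose(rec, bands) if method == "variance" else None
    taper, power_norm = _taper(win, win_len)

    values: list[np.ndarray] = []
    labels: list[int] = []
    trial_idx: list[int] = []
    for t, (s, e, lab) in enumerate(rec.trials):
        starts = _window_starts(e - s, win_len, step)
        if not starts:
            logger.warning(
                "trial %d of %s (%d samples) shorter than window (%d); skipped",
                t, rec.subject_id, e - s, win_len,
            )
            continue
        for w0 in starts:
            sl = slice(s + w0, s + w0 + win_len)
            if method == "variance":
                per_band = []
                for br in banded:
                    seg = br.signal[:, sl] * taper  # (C, win_len)
                    var = seg.var(axis=1) / power_norm
                    per_band.append(np.maximum(var, floor))
                var_cb = np.column_stack(per_band)  # (C, B)
            else:
                seg = rec.signal[:, sl]
                freqs, psd = sps.periodogram(seg, fs=rec.fs, window=taper, axis=1)
                per_band = []
                for b in bands:
                    m = (freqs >= b.low) & (freqs <= b.high)
                    bp = np.trapezoid(psd[:, m], freqs[m], axis=1)
                    per_band.append(np.maximum(bp, floor))
                var_cb = np.column_stack(per_band)
            values.append(0.5 * (_LOG_2PIE + np.log(var_cb)))
            labels.append(int(lab))
            trial_idx.append(t)

    arr = (
        np.stack(values)
        if values
        else np.zeros((0, rec.montage.n_channels, len(bands)))
    )
    return DEFeatureTensor(
        values=arr,
        band_edges=np.array([[b.low, b.high] for b in bands], dtype=float).reshape(-1, 2),
        window_s=win.length_s,
        montage=rec.montage,
        labels=np.array(labels, dtype=int),
        subject_id=rec.subject_id,
        trial_index=np.array(trial_idx, dtype=int),
    )
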