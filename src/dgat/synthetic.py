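"""Synthetic multichannel EEG-like recordings with planted structure.

The generator emulates the statistical skeleton of multi-subject emotion
datasets: several subjects, several trials per emotion class, band-limited
multichannel signals in which the class is encoded two ways —

* **connectivity**: per class, latent band-limited noise sources are mixed
  through a class-specific coupling matrix whose off-diagonal blocks join
  designated channel groups (a "frontal" group and friends), planting
  inter-channel correlation;
* **band power**: per class, one designated (band, channel-group) pair
  gets an amplitude gain, planting a differential-entropy contrast.

Connectivity lives in the mixing matrix and band power in the gains, so
connectivity-recovery tests probe a different signal than band-power
tests. Per-subject amplitude jitter and white sensor noise are added on
top. Signals are filtered white noise, hence near-Gaussian in every band,
matching the Gaussianity assumption behind the closed-form differential
entropy. No attempt is made at physiological realism (1/f background,
artifacts); the generator targets exactly the structure the classifier
exploits.

One global seed fans out to per-subject, per-trial substreams, so
generation is reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .features import BandSpec, band_preset
from .montage import EEGRecording, Montage, load_montage

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "planted_coupling",
    "generate_dataset",
    "de_features_for_dataset",
    "channel_groups",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-shape and effect-size knobs for the generator.

    Defaults emulate a 15-subject, 3-class, 5-trials-per-class design.
    ``coupling_strength`` scales the planted off-diagonal mixing blocks;
    ``band_effect`` is the amplitude gain (power gain ``(1+g)^2``) applied
    to each class's designated band within its designated channel group;
    ``subject_variability`` is the log-sd of per-subject per-channel
    amplitude jitter; ``noise_sd`` is the white sensor-noise amplitude
    relative to unit-variance band sources.
    """

    n_subjects: int = 15
    n_trials_per_class: int = 5
    n_classes: int = 3
    montage: str = "synth16"
    fs: float = 128.0
    trial_s: float = 8.0
    bands: tuple[BandSpec, ...] = tuple(band_preset("deap4"))
    n_groups: int = 4
    coupling_strength: float = 0.6
    band_effect: float = 0.5
    subject_variability: float = 0.1
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_trials_per_class, self.n_classes) < 1:
            raise ValueError("all counts must be >= 1")
        top = max(b.high for b in self.bands)
        if self.fs <= 2 * top:
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest band edge ({top} Hz)"
            )
        if self.coupling_strength < 0:
            raise ValueError("coupling_strength must be nonnegative")


def channel_groups(n_channels: int, n_groups: int) -> list[np.ndarray]:
    """Contiguous near-equal channel-index groups (group 0 = "frontal")."""
    return [np.asarray(g) for g in np.array_split(np.arange(n_channels), n_groups)]


def planted_coupling(config: SyntheticConfig, class_label: int) -> np.ndarray:
    """Ground-truth N x N coupling (mixing) matrix for one class.

    Identity plus ``coupling_strength`` on the symmetric off-diagonal block
    joining channel groups ``class mod G`` and ``(class + 1) mod G``, so
    distinct classes plant distinct blocks. With zero coupling strength the
    matrix is the identity for every class.
    """
    if not (0 <= class_label < config.n_classes):
        raise ValueError(f"class {class_label} out of range")
    montage = load_montage(config.montage)
    n = montage.n_channels
    groups = channel_groups(n, config.n_groups)
    g1 = groups[class_label % config.n_groups]
    g2 = groups[(class_label + 1) % config.n_groups]
    m = np.eye(n)
    if config.coupling_strength > 0:
        m[np.ix_(g1, g2)] += config.coupling_strength
        m[np.ix_(g2, g1)] += config.coupling_strength
    return m


def _band_gains(config: SyntheticConfig, class_label: int, n: int) -> np.ndarray:
    """(n_bands, N) amplitude gains: class's designated band x group boosted."""
    gains = np.ones((len(config.bands), n))
    groups = channel_groups(n, config.n_groups)
    b = class_label % len(config.bands)
    g = groups[class_label % config.n_groups]
    gains[b, g] += config.band_effect
    return gains


def _band_noise(
    rng: np.random.Generator, band: BandSpec, n_ch: int, n_samp: int, fs: float
) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise, channels x samples."""
    sos = sps.butter(4, [band.low, band.high], btype="bandpass", fs=fs, output="sos")
    pad = int(2 * fs)  # filter warm-up, discarded
    x = sps.sosfilt(sos, rng.standard_normal((n_ch, n_samp + pad)), axis=1)
    x = x[:, pad:]
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


@dataclass
class SyntheticDataset:
    """Recordings plus the ground truth that generated them."""

    recordings: list[EEGRecording]
    couplings: dict[int, np.ndarray]
    config: SyntheticConfig
    montage: Montage = field(init=False)

    def __post_init__(self) -> None:
        self.montage = self.recordings[0].montage


def generate_dataset(config: SyntheticConfig = SyntheticConfig()) -> SyntheticDataset:
    """One labeled multi-trial recording per subject, plus ground truth.

    Per trial of class ``c``: each band's latent channel noise is scaled by
    the class band gains, mixed through the class coupling matrix, summed
    over bands, multiplied by the subject's per-channel gain, and corrupted
    with white noise. Trials are concatenated (class-blocked, trial order
    ``class 0 x n_trials, class 1 x n_trials, ...``) into one continuous
    signal per subject with half-open trial annotations.
    """
    montage = load_montage(config.montage)
    n = montage.n_channels
    n_samp = int(round(config.trial_s * config.fs))
    couplings = {c: planted_coupling(config, c) for c in range(config.n_classes)}
    gains = {c: _band_gains(config, c, n) for c in range(config.n_classes)}

    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects)
    recordings: list[EEGRecording] = []
    for s, sseq in enumerate(subject_seeds):
        trial_seqs = sseq.spawn(config.n_classes * config.n_trials_per_class + 1)
        subj_rng = np.random.default_rng(trial_seqs[-1])
        subj_gain = np.exp(
            config.subject_variability * subj_rng.standard_normal((n, 1))
        )
        chunks: list[np.ndarray] = []
        trials: list[tuple[int, int, int]] = []
        cursor = 0
        k = 0
        for c in range(config.n_classes):
            for _ in range(config.n_trials_per_class):
                rng = np.random.default_rng(trial_seqs[k])
                k += 1
                x = np.zeros((n, n_samp))
                for b, band in enumerate(config.bands):
                    u = _band_noise(rng, band, n, n_samp, config.fs)
                    x += couplings[c] @ (gains[c][b][:, None] * u)
                x = subj_gain * x
                x += config.noise_sd * rng.standard_normal((n, n_samp))
                chunks.append(x)
                trials.append((cursor, cursor + n_samp, c))
                cursor += n_samp
        recordings.append(
            EEGRecording(
                np.concatenate(chunks, axis=1),
                config.fs,
                montage,
                trials,
                subject_id=f"s{s:02d}",
            )
        )
    return SyntheticDataset(recordings, couplings, config)


def de_features_for_dataset(dataset: SyntheticDataset, window_s: float = 4.0):
    """Differential-entropy tensors for every subject of a generated set."""
    from .features import WindowSpec, extract_de_features

    win = WindowSpec(length_s=window_s)
    bands = list(dataset.config.bands)
    return [extract_de_features(rec, bands, win) for rec in dataset.recordings]
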