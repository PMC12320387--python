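"""Electrode montages, recording/feature containers, and on-disk formats.

A :class:`Montage` is a named, ordered set of electrodes with unit-sphere
3-D coordinates. Coordinates for the packaged 62-channel and 32-channel
layouts are derived at load time from the standard 10-20/10-10 template
shipped with :mod:`mne`, centered and projected onto the unit sphere.
Custom layouts are read from plain ``label,x,y,z`` CSV tables, and
``synth<N>`` names generate an N-electrode Fibonacci-sphere layout for
simulation work.

Recordings travel either as EDF files or as HDF5 containers; extracted
differential-entropy feature tensors use the same HDF5 container format
(one group per array, montage stored inline so files are self-contained).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "Montage",
    "EEGRecording",
    "DEFeatureTensor",
    "MontageNotFoundError",
    "ChannelMismatchError",
    "load_montage",
    "electrode_distances",
    "read_recording",
    "write_recording",
    "read_features",
    "write_features",
    "write_edf",
]


class MontageNotFoundError(KeyError):
    """Raised when a montage name is not packaged and not a readable file."""


class ChannelMismatchError(ValueError):
    """Raised when a file's channels do not cover the requested montage."""


# Channel name lists for the two packaged layouts. The 62-channel list is
# the extended 10-10 set used by 62-electrode ESI caps (CB1/CB2 sit below
# O1/O2; the template lacks them, so they take the I1/I2 positions, the
# nearest standard inferior-occipital sites). The 32-channel list is the
# Biosemi arrangement used by 32-electrode affective-computing caps.
_SEED62_LABELS = (
    "FP1 FPZ FP2 AF3 AF4 F7 F5 F3 F1 FZ F2 F4 F6 F8 "
    "FT7 FC5 FC3 FC1 FCZ FC2 FC4 FC6 FT8 T7 C5 C3 C1 CZ C2 C4 C6 T8 "
    "TP7 CP5 CP3 CP1 CPZ CP2 CP4 CP6 TP8 P7 P5 P3 P1 PZ P2 P4 P6 P8 "
    "PO7 PO5 PO3 POZ PO4 PO6 PO8 CB1 O1 OZ O2 CB2"
).split()
_DEAP32_LABELS = (
    "FP1 AF3 F3 F7 FC5 FC1 C3 T7 CP5 CP1 P3 P7 PO3 O1 OZ PZ "
    "FP2 AF4 FZ F4 F8 FC6 FC2 CZ C4 T8 CP6 CP2 P4 P8 PO4 O2"
).split()
_TEMPLATE_ALIASES = {"CB1": "I1", "CB2": "I2"}


@dataclass(frozen=True)
class Montage:
    """Named electrode layout: ordered labels + unit-sphere coordinates."""

    name: str
    channel_labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), each row unit norm

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (n_channels, 3) array")
        if pos.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{len(self.channel_labels)} labels but {pos.shape[0]} positions"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("electrode positions must lie on the unit sphere")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)


@dataclass
class EEGRecording:
    """Continuous multichannel recording with trial annotations.

    ``signal`` is channels x samples in microvolts; ``trials`` is a list of
    ``(start_sample, end_sample, label)`` with 0-based half-open intervals.
    """

    signal: np.ndarray
    fs: float
    montage: Montage
    trials: list[tuple[int, int, int]] = field(default_factory=list)
    subject_id: str = "s00"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if self.signal.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"signal has {self.signal.shape[0]} rows but montage "
                f"'{self.montage.name}' has {self.montage.n_channels} channels"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        n = self.signal.shape[1]
        spans = sorted((int(s), int(e)) for s, e, _ in self.trials)
        for (s, e), (s2, _) in zip(spans, spans[1:] + [(n, n)]):
            if not (0 <= s < e <= n):
                raise ValueError(f"trial [{s}, {e}) outside signal bounds [0, {n})")
            if e > s2:
                raise ValueError("trials must not overlap")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def trial_signal(self, index: int) -> np.ndarray:
        s, e, _ = self.trials[index]
        return self.signal[:, s:e]


@dataclass
class DEFeatureTensor:
    """Windowed differential-entropy features, windows x channels x bands."""

    values: np.ndarray  # (T, C, B) in nats
    band_edges: np.ndarray  # (B, 2) Hz
    window_s: float
    montage: Montage
    labels: np.ndarray  # (T,) int
    subject_id: str = "s00"
    trial_index: np.ndarray | None = None  # (T,) int, which trial each window is from

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.band_edges = np.asarray(self.band_edges, dtype=float).reshape(-1, 2)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.trial_index is None:
            self.trial_index = np.zeros(len(self.labels), dtype=int)
        self.trial_index = np.asarray(self.trial_index, dtype=int)
        t, c, b = self.values.shape if self.values.ndim == 3 else (0, 0, 0)
        if self.values.ndim != 3:
            raise ValueError("values must be a (T, C, B) array")
        if c != self.montage.n_channels:
            raise ValueError("channel axis does not match montage")
        if b != len(self.band_edges):
            raise ValueError("band axis does not match band_edges")
        if len(self.labels) != t or len(self.trial_index) != t:
            raise ValueError("labels/trial_index must have length T")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def flat(self) -> np.ndarray:
        """Samples x (C*B) view used for export and classical baselines."""
        return self.values.reshape(self.n_windows, self.n_channels * self.n_bands)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """N approximately equispaced points on the unit sphere (deterministic)."""
    i = np.arange(n, dtype=float)
    golden = (1 + 5**0.5) / 2
    z = 1 - (2 * i + 1) / n
    r = np.sqrt(np.maximum(0.0, 1 - z**2))
    phi = 2 * np.pi * i / golden
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _template_positions(labels: list[str]) -> np.ndarray:
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # template rename deprecation
        tmpl = mne.channels.make_standard_montage("standard_1005")
    pos = tmpl.get_positions()["ch_pos"]
    by_lower = {k.lower(): v for k, v in pos.items()}
    out = []
    for lab in labels:
        key = _TEMPLATE_ALIASES.get(lab, lab).lower()
        if key not in by_lower:
            raise MontageNotFoundError(f"no template position for channel '{lab}'")
        out.append(by_lower[key])
    arr = np.array(out, dtype=float)
    arr -= arr.mean(axis=0)
    arr /= np.linalg.norm(arr, axis=1, keepdims=True)
    return arr


def load_montage(name: str | Path) -> Montage:
    """Load a packaged montage by name, a synthetic layout, or a CSV table.

    Parameters
    ----------
    name
        ``"seed62"`` (62-channel 10-10 cap), ``"deap32"`` (32-channel cap),
        ``"synth<N>"`` for an N-electrode simulated layout, or a path to a
        ``label,x,y,z`` CSV file. Custom coordinates are projected onto the
        unit sphere.
    """
    key = str(name)
    if key == "seed62":
        return Montage("seed62", tuple(_SEED62_LABELS), _template_positions(_SEED62_LABELS))
    if key == "deap32":
        return Montage("deap32", tuple(_DEAP32_LABELS), _template_positions(_DEAP32_LABELS))
    if key.startswith("synth") and key[5:].isdigit():
        n = int(key[5:])
        if n < 1:
            raise MontageNotFoundError(f"synthetic montage needs >= 1 channel: '{key}'")
        labels = tuple(f"CH{i + 1:02d}" for i in range(n))
        return Montage(key, labels, _fibonacci_sphere(n))
    path = Path(key)
    if path.is_file():
        return _read_montage_csv(path)
    raise MontageNotFoundError(
        f"unknown montage '{key}' (expected 'seed62', 'deap32', 'synth<N>', or a CSV path)"
    )


def _read_montage_csv(path: Path) -> Montage:
    labels: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(",")]
        if parts[0].lower() == "label":  # optional header
            continue
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 'label,x,y,z', got {line!r}")
        try:
            xyz = [float(v) for v in parts[1:]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric coordinate in {line!r}") from exc
        labels.append(parts[0])
        rows.append(xyz)
    if not labels:
        raise ValueError(f"{path}: no electrode rows found")
    arr = np.asarray(rows, dtype=float)
    norms = np.linalg.norm(arr, axis=1)
    if np.any(norms == 0):
        bad = labels[int(np.argmax(norms == 0))]
        raise ValueError(f"{path}: zero-length position for channel '{bad}'")
    arr /= norms[:, None]
    return Montage(path.stem, tuple(labels), arr)


def electrode_distances(montage: Montage) -> np.ndarray:
    """Pairwise 3-D Euclidean (chord) distances between electrodes.

    Chord distance on the unit sphere is monotone in geodesic distance, so
    any distance-threshold graph built from it matches the geodesic one.
    """
    diff = montage.positions[:, None, :] - montage.positions[None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(d, 0.0)
    return d


def write_montage_csv(montage: Montage, path: str | Path) -> None:
    lines = ["label,x,y,z"]
    for lab, (x, y, z) in zip(montage.channel_labels, montage.positions):
        lines.append(f"{lab},{x:.10f},{y:.10f},{z:.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Recording I/O


def read_recording(
    path: str | Path,
    montage: Montage | str,
    format: str = "container",
) -> EEGRecording:
    """Read a recording from EDF or from the HDF5 container format.

    Channels are reordered to match the montage by label (case-insensitive);
    missing channels raise :class:`ChannelMismatchError` naming them. EDF
    carries no trial annotations, so ``trials`` is empty for EDF input.
    """
    if isinstance(montage, str):
        montage = load_montage(montage)
    if format == "edf":
        return _read_edf(Path(path), montage)
    if format == "container":
        return _read_container(Path(path), montage)
    raise ValueError(f"unknown recording format '{format}'")


def _read_edf(path: Path, montage: Montage) -> EEGRecording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises a zoo of parse errors
        raise ValueError(f"could not parse EDF file {path}: {exc}") from exc
    have = {n.lower(): i for i, n in enumerate(raw.ch_names)}
    order = []
    missing = []
    for lab in montage.channel_labels:
        idx = have.get(lab.lower())
        (order.append(idx) if idx is not None else missing.append(lab))
    if missing:
        raise ChannelMismatchError(
            f"{path} is missing channels required by montage "
            f"'{montage.name}': {', '.join(missing)}"
        )
    data = raw.get_data()[order] * 1e6  # mne returns volts; we store microvolts
    return EEGRecording(data, float(raw.info["sfreq"]), montage, [], path.stem)


def write_recording(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording (with trials) to the HDF5 container format."""
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "eeg_recording"
        f.attrs["fs"] = rec.fs
        f.attrs["subject_id"] = rec.subject_id
        f.create_dataset("signal", data=rec.signal)
        trials = np.array([[s, e, l] for s, e, l in rec.trials], dtype=np.int64)
        f.create_dataset("trials", data=trials.reshape(-1, 3))
        _write_montage_group(f, rec.montage)


def _read_container(path: Path, montage: Montage | None) -> EEGRecording:
    try:
        with h5py.File(path, "r") as f:
            stored = _read_montage_group(f)
            signal = np.asarray(f["signal"])
            trials = [tuple(int(v) for v in row) for row in np.asarray(f["trials"])]
            fs = float(f.attrs["fs"])
            subject = str(f.attrs["subject_id"])
    except OSError as exc:
        raise ValueError(f"could not parse container file {path}: {exc}") from exc
    if montage is not None:
        have = {n.lower(): i for i, n in enumerate(stored.channel_labels)}
        missing = [l for l in montage.channel_labels if l.lower() not in have]
        if missing:
            raise ChannelMismatchError(
                f"{path} is missing channels required by montage "
                f"'{montage.name}': {', '.join(missing)}"
            )
        order = [have[l.lower()] for l in montage.channel_labels]
        signal = signal[order]
    else:
        montage = stored
    return EEGRecording(signal, fs, montage, trials, subject)


def _write_montage_group(f: h5py.File, montage: Montage) -> None:
    g = f.create_group("montage")
    g.attrs["name"] = montage.name
    g.create_dataset(
        "channel_labels",
        data=np.array([l.encode() for l in montage.channel_labels]),
    )
    g.create_dataset("positions", data=montage.positions)


def _read_montage_group(f: h5py.File) -> Montage:
    g = f["montage"]
    labels = tuple(l.decode() for l in np.asarray(g["channel_labels"]))
    return Montage(str(g.attrs["name"]), labels, np.asarray(g["positions"]))


# ---------------------------------------------------------------------------
# Feature tensor I/O


def write_features(tensor: DEFeatureTensor, path: str | Path) -> None:
    """Write a feature tensor to a self-contained HDF5 file (lossless)."""
    try:
        with h5py.File(path, "w") as f:
            f.attrs["kind"] = "de_features"
            f.attrs["window_s"] = tensor.window_s
            f.attrs["subject_id"] = tensor.subject_id
            f.create_dataset("values", data=tensor.values)
            f.create_dataset("band_edges", data=tensor.band_edges)
            f.create_dataset("labels", data=tensor.labels)
            f.create_dataset("trial_index", data=tensor.trial_index)
            _write_montage_group(f, tensor.montage)
    except OSError as exc:
        raise OSError(f"could not write features to {path}: {exc}") from exc


def read_features(path: str | Path) -> DEFeatureTensor:
    """Read a feature tensor written by :func:`write_features`."""
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("kind") != "de_features":
                raise ValueError(f"{path} is not a DE feature container")
            montage = _read_montage_group(f)
            values = np.asarray(f["values"])
            if values.ndim != 3:  # T=0 round-trips as an empty 3-D array
                values = values.reshape(0, montage.n_channels, -1)
            return DEFeatureTensor(
                values=values,
                band_edges=np.asarray(f["band_edges"]),
                window_s=float(f.attrs["window_s"]),
                montage=montage,
                labels=np.asarray(f["labels"], dtype=int),
                subject_id=str(f.attrs["subject_id"]),
                trial_index=np.asarray(f["trial_index"], dtype=int),
            )
    except OSError as exc:
        raise ValueError(f"could not parse feature file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Minimal EDF writer (16-bit, one data record per second). Enough to export
# simulated recordings for tools that speak EDF, and to test the reader.


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    fs = rec.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_ch, n_samp = rec.signal.shape
    n_rec = n_samp // spr
    phys_min, phys_max = -32768.0, 32767.0  # 1 uV per digital unit
    buf = io.BytesIO()

    def field(vals, width):
        for v in vals:
            buf.write(str(v).encode("ascii")[:width].ljust(width))

    field(["0"], 8)
    field([f"X X X {rec.subject_id}"], 80)
    field(["Startdate 01-JAN-2020 X X X"], 80)
    field(["01.01.20", "00.00.00"], 8)
    field([256 * (1 + n_ch)], 8)
    field([""], 44)
    field([n_rec], 8)
    field([1], 8)
    field([n_ch], 4)
    field(rec.montage.channel_labels, 16)
    field([""] * n_ch, 80)
    field(["uV"] * n_ch, 8)
    field([phys_min] * n_ch, 8)
    field([phys_max] * n_ch, 8)
    field([-32768] * n_ch, 8)
    field([32767] * n_ch, 8)
    field([""] * n_ch, 80)
    field([spr] * n_ch, 8)
    field([""] * n_ch, 32)
    for r in range(n_rec):
        chunk = np.clip(rec.signal[:, r * spr : (r + 1) * spr], phys_min, phys_max)
        buf.write(np.round(chunk).astype("<i2").tobytes())
    Path(path).write_bytes(buf.getvalue())
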