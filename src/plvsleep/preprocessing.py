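"""Reading, curating and segmenting polysomnography EEG.

This module takes a multichannel EEG recording plus its 30 s sleep-stage
hypnogram and produces stage-labeled, band-filtered 30 s epochs:

1. hypnogram curation — three deletion rules that drop epochs whose stage
   label is unreliable (too-short stage runs, brief wake intrusions and
   their flanks, the first/last epoch of every run);
2. common average reference (CAR);
3. zero-phase broadband filtering (default 0.5–40 Hz) and a six-band
   filter bank (delta … gamma);
4. non-overlapping 30 s segmentation aligned to the hypnogram.

Only REM, N2 and N3 epochs survive curation; wake and N1 are discarded.
EDF recordings are read through :mod:`mne`; stage annotations come from a
plain-text file (see :func:`read_hypnogram` for the two dialects).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .bands import BandDefinition, CANONICAL_BANDS

EPOCH_SECONDS = 30.0

#: default curation thresholds: a stage run shorter than 6 epochs (3 min)
#: is dropped, and a wake run of at most 2 epochs inside a sleep block is
#: treated as an intrusion.
DEFAULT_MIN_RUN_EPOCHS = 6
DEFAULT_INTRUSION_MAX_EPOCHS = 2

#: stages retained for analysis
ANALYSIS_STAGES = frozenset({"REM", "N2", "N3"})

#: common R&K / AASM annotation spellings → canonical labels
STAGE_ALIASES: Mapping[str, str] = {
    "W": "W", "WAKE": "W", "SLEEP STAGE W": "W", "0": "W",
    "REM": "REM", "R": "REM", "SLEEP STAGE R": "REM", "5": "REM",
    "N1": "N1", "S1": "N1", "1": "N1", "SLEEP STAGE 1": "N1", "SLEEP STAGE N1": "N1",
    "N2": "N2", "S2": "N2", "2": "N2", "SLEEP STAGE 2": "N2", "SLEEP STAGE N2": "N2",
    # R&K S3 and S4 both map to N3
    "N3": "N3", "S3": "N3", "3": "N3", "SLEEP STAGE 3": "N3", "SLEEP STAGE N3": "N3",
    "S4": "N3", "4": "N3", "SLEEP STAGE 4": "N3",
}


def normalize_stage(label: str) -> str:
    key = label.strip().upper()
    if key not in STAGE_ALIASES:
        raise ValueError(f"unrecognized sleep-stage label {label!r}")
    return STAGE_ALIASES[key]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RawRecording:
    """Continuous multichannel EEG: ``signal`` is channels × samples in µV."""

    signal: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a channels × samples matrix")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channel_labels:
            self.channel_labels = tuple(f"ch{i}" for i in range(self.signal.shape[0]))
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError("channel_labels must match the number of channels")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass(frozen=True)
class HypnogramAnnotation:
    """One sleep-stage label per 30 s epoch, aligned to the recording start."""

    stages: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("hypnogram must contain at least one epoch")
        object.__setattr__(self, "stages", tuple(normalize_stage(s) for s in self.stages))

    def __len__(self) -> int:
        return len(self.stages)

    def runs(self) -> list[tuple[str, int, int]]:
        """Run-length encoding: (stage, start_epoch, length) triples."""
        out: list[tuple[str, int, int]] = []
        start = 0
        for i in range(1, len(self.stages) + 1):
            if i == len(self.stages) or self.stages[i] != self.stages[start]:
                out.append((self.stages[start], start, i - start))
                start = i
        return out


@dataclass
class EpochSet:
    """Stage-labeled tensor of 30 s epochs: ``data`` is epochs × channels × samples."""

    data: np.ndarray
    labels: np.ndarray
    sampling_rate: float
    band: str | None = None
    channel_labels: tuple[str, ...] = ()
    epoch_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs × channels × samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per epoch required")
        if self.epoch_indices.size == 0:
            self.epoch_indices = np.arange(self.data.shape[0])
        if not self.channel_labels:
            self.channel_labels = tuple(f"ch{i}" for i in range(self.data.shape[1]))

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


# ---------------------------------------------------------------------------
# referencing and filtering
# ---------------------------------------------------------------------------

def apply_car(raw: RawRecording) -> RawRecording:
    """Common average reference: subtract the instantaneous cross-channel mean.

    Requires at least two channels; after CAR the per-sample channel mean
    is zero, which removes noise common to all derivations.
    """
    if raw.n_channels < 2:
        raise ValueError("CAR is undefined for a single channel")
    referenced = raw.signal - raw.signal.mean(axis=0, keepdims=True)
    return replace(raw, signal=referenced)


def _bandpass_sos(low_hz: float, high_hz: float, sampling_rate: float, order: int = 4):
    nyq = sampling_rate / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"band edges ({low_hz}, {high_hz}) Hz must satisfy "
            f"0 < low < high < Nyquist ({nyq} Hz)"
        )
    return butter(order, [low_hz, high_hz], btype="bandpass", fs=sampling_rate, output="sos")


def bandpass(raw: RawRecording, low_hz: float, high_hz: float, order: int = 4) -> RawRecording:
    """Zero-phase Butterworth band-pass (forward–backward, order per pass).

    Zero-phase filtering is essential here: a causal filter would add a
    frequency-dependent phase shift and bias every downstream phase-locking
    estimate.
    """
    sos = _bandpass_sos(low_hz, high_hz, raw.sampling_rate, order=order)
    return replace(raw, signal=sosfiltfilt(sos, raw.signal, axis=1))


def bandpass_array(x: np.ndarray, low_hz: float, high_hz: float,
                   sampling_rate: float, order: int = 4, axis: int = -1) -> np.ndarray:
    """Zero-phase band-pass on a bare array (same filter as :func:`bandpass`)."""
    sos = _bandpass_sos(low_hz, high_hz, sampling_rate, order=order)
    return sosfiltfilt(sos, np.asarray(x, dtype=float), axis=axis)


# ---------------------------------------------------------------------------
# hypnogram curation
# ---------------------------------------------------------------------------

def curate_hypnogram(
    hyp: HypnogramAnnotation,
    min_run_epochs: int = DEFAULT_MIN_RUN_EPOCHS,
    intrusion_max_epochs: int = DEFAULT_INTRUSION_MAX_EPOCHS,
) -> list[int]:
    """Apply the three epoch-deletion rules; return kept epoch indices.

    Rule 1 drops every stage run shorter than ``min_run_epochs`` (default
    6 epochs = 3 min).  Rule 2 drops wake runs of at most
    ``intrusion_max_epochs`` epochs occurring between two non-wake runs,
    together with one flanking epoch on each side.  Both rules are
    evaluated on the original run structure and their deletions combined;
    fragments created by intrusion removal are re-checked against the
    run-length minimum.  Rule 3 then trims the first and last epoch of
    every surviving contiguous same-stage segment.  Finally only REM, N2
    and N3 epochs are kept.
    """
    n = len(hyp)
    keep = np.ones(n, dtype=bool)
    runs = hyp.runs()

    # rule 1: whole runs shorter than the minimum
    for stage, start, length in runs:
        if length < min_run_epochs:
            keep[start:start + length] = False

    # rule 2: brief wake intrusions inside a sleep block, plus flanks
    for idx, (stage, start, length) in enumerate(runs):
        if stage != "W" or length > intrusion_max_epochs:
            continue
        if idx == 0 or idx == len(runs) - 1:
            continue  # wake at the recording edge is not an intrusion
        if runs[idx - 1][0] == "W" or runs[idx + 1][0] == "W":
            continue
        lo = max(start - 1, 0)
        hi = min(start + length + 1, n)
        keep[lo:hi] = False

    # re-check fragments against the run-length minimum, then trim run edges
    for stage, start, length in _kept_segments(hyp.stages, keep):
        if length < min_run_epochs:
            keep[start:start + length] = False

    for stage, start, length in _kept_segments(hyp.stages, keep):
        keep[start] = False
        keep[start + length - 1] = False

    return [i for i in range(n) if keep[i] and hyp.stages[i] in ANALYSIS_STAGES]


def _kept_segments(stages: Sequence[str], keep: np.ndarray) -> list[tuple[str, int, int]]:
    """Contiguous same-stage segments restricted to currently kept epochs."""
    segs: list[tuple[str, int, int]] = []
    start = None
    for i in range(len(stages) + 1):
        boundary = (
            i == len(stages)
            or not keep[i]
            or (start is not None and stages[i] != stages[start])
        )
        if start is not None and boundary:
            segs.append((stages[start], start, i - start))
            start = None
        if i < len(stages) and keep[i] and start is None:
            start = i
    return segs


# ---------------------------------------------------------------------------
# segmentation and filter bank
# ---------------------------------------------------------------------------

def segment_epochs(
    raw: RawRecording,
    hyp: HypnogramAnnotation,
    kept: Iterable[int],
) -> EpochSet:
    """Cut the recording into the kept non-overlapping 30 s epochs.

    Epoch ``i`` covers samples ``[i*30*fs, (i+1)*30*fs)`` (0-based,
    half-open); its label is copied from the hypnogram.
    """
    kept = sorted(set(int(i) for i in kept))
    samples_per_epoch = int(round(EPOCH_SECONDS * raw.sampling_rate))
    if kept:
        if kept[0] < 0:
            raise IndexError("negative epoch index")
        if (kept[-1] + 1) * samples_per_epoch > raw.n_samples:
            raise IndexError(
                f"epoch {kept[-1]} extends beyond the recording "
                f"({raw.n_samples} samples at {raw.sampling_rate} Hz)"
            )
        if kept[-1] >= len(hyp):
            raise IndexError(f"epoch {kept[-1]} beyond hypnogram length {len(hyp)}")
    data = np.stack(
        [raw.signal[:, i * samples_per_epoch:(i + 1) * samples_per_epoch] for i in kept]
    ) if kept else np.empty((0, raw.n_channels, samples_per_epoch))
    labels = np.array([hyp.stages[i] for i in kept], dtype=object)
    return EpochSet(
        data=data,
        labels=labels,
        sampling_rate=raw.sampling_rate,
        channel_labels=raw.channel_labels,
        epoch_indices=np.array(kept, dtype=int),
    )


def filter_bank(
    epochs: EpochSet,
    bands: Sequence[BandDefinition] = CANONICAL_BANDS,
) -> dict[str, EpochSet]:
    """Decompose every epoch into the requested narrow bands.

    Each band output keeps the labels, ordering and epoch indices of the
    input; filtering is per epoch (no cross-epoch smearing).
    """
    out: dict[str, EpochSet] = {}
    for band in bands:
        if epochs.n_epochs:
            filtered = bandpass_array(
                epochs.data, band.low_hz, band.high_hz, epochs.sampling_rate, axis=2
            )
        else:
            filtered = epochs.data.copy()
        out[band.name] = EpochSet(
            data=filtered,
            labels=epochs.labels.copy(),
            sampling_rate=epochs.sampling_rate,
            band=band.name,
            channel_labels=epochs.channel_labels,
            epoch_indices=epochs.epoch_indices.copy(),
        )
    return out


def reject_high_amplitude(epochs: EpochSet, threshold_uv: float) -> EpochSet:
    """Optional artifact hook: drop epochs whose peak |amplitude| exceeds a threshold."""
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be positive")
    peak = np.abs(epochs.data).max(axis=(1, 2))
    keep = peak <= threshold_uv
    return EpochSet(
        data=epochs.data[keep],
        labels=epochs.labels[keep],
        sampling_rate=epochs.sampling_rate,
        band=epochs.band,
        channel_labels=epochs.channel_labels,
        epoch_indices=epochs.epoch_indices[keep],
    )


# ---------------------------------------------------------------------------
# EDF and annotation I/O
# ---------------------------------------------------------------------------

def read_edf(path: str | Path, channels: Sequence[str] | None = None) -> RawRecording:
    """Read an EDF recording into a :class:`RawRecording` (µV)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channels is not None:
        raw.pick(list(channels))
    data = raw.get_data() * 1e6  # mne returns volts
    return RawRecording(
        signal=data,
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
    )


def read_hypnogram(path: str | Path) -> HypnogramAnnotation:
    """Read stage annotations from a plain-text file.

    Two dialects are supported:

    * one stage label per line (each line = one 30 s epoch);
    * two whitespace-separated columns ``onset_seconds  stage``, where each
      row labels the 30 s epochs from its onset up to the next row's onset
      (the final row labels a single epoch).  Onsets must be multiples
      of 30 s and strictly increasing.

    Lines starting with ``#`` and blank lines are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    rows = [
        line.split() for line in path.read_text().splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not rows:
        raise ValueError(f"annotation file {path} contains no stage labels")
    n_cols = {len(r) for r in rows}
    if n_cols == {1}:
        return HypnogramAnnotation(tuple(r[0] for r in rows))
    if n_cols == {2}:
        onsets = [float(r[0]) for r in rows]
        stages = [r[1] for r in rows]
        if any(o % EPOCH_SECONDS for o in onsets):
            raise ValueError("onsets must be multiples of 30 s")
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("onsets must be strictly increasing")
        expanded: list[str] = []
        for i, (onset, stage) in enumerate(zip(onsets, stages)):
            end = onsets[i + 1] if i + 1 < len(onsets) else onset + EPOCH_SECONDS
            expanded.extend([stage] * int((end - onset) / EPOCH_SECONDS))
        return HypnogramAnnotation(tuple(expanded))
    raise ValueError("annotation file mixes one-column and two-column rows")


def write_hypnogram(hyp: HypnogramAnnotation, path: str | Path) -> None:
    Path(path).write_text("\n".join(hyp.stages) + "\n")


def write_edf(raw: RawRecording, path: str | Path) -> None:
    """Write a RawRecording as a minimal EDF file (16-bit, 1 s data records).

    Implements the plain EDF container (fixed 256-byte headers plus
    little-endian int16 data records) so synthetic recordings can be
    round-tripped through the EDF reader. Signals are scaled per channel
    to the full digital range; the recording is truncated to a whole
    number of seconds.
    """
    path = Path(path)
    fs = raw.sampling_rate
    spr = int(round(fs))  # samples per 1 s record
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_records = raw.n_samples // spr
    if n_records == 0:
        raise ValueError("recording shorter than one 1 s data record")
    nchan = raw.n_channels
    sig = raw.signal[:, : n_records * spr]

    phys_min = np.floor(sig.min(axis=1))
    phys_max = np.ceil(sig.max(axis=1))
    flat = phys_max <= phys_min
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0
    dig_min, dig_max = -32768, 32767

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF header field too long: {text!r}")
        return b.ljust(width)

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X X X X", 80),
        pad(now.strftime("%d.%m.%y"), 8), pad(now.strftime("%H.%M.%S"), 8),
        pad(str(256 * (nchan + 1)), 8), pad("", 44),
        pad(str(n_records), 8), pad("1", 8), pad(str(nchan), 4),
    ])
    labels = [lab[:16] for lab in raw.channel_labels]
    header += b"".join(pad(lab, 16) for lab in labels)
    header += b"".join(pad("", 80) for _ in range(nchan))          # transducer
    header += b"".join(pad("uV", 8) for _ in range(nchan))         # physical dim
    header += b"".join(pad(f"{v:g}"[:8], 8) for v in phys_min)
    header += b"".join(pad(f"{v:g}"[:8], 8) for v in phys_max)
    header += b"".join(pad(str(dig_min), 8) for _ in range(nchan))
    header += b"".join(pad(str(dig_max), 8) for _ in range(nchan))
    header += b"".join(pad("", 80) for _ in range(nchan))          # prefiltering
    header += b"".join(pad(str(spr), 8) for _ in range(nchan))
    header += b"".join(pad("", 32) for _ in range(nchan))          # reserved

    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((sig - phys_min[:, None]) * gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            fh.write(digital[:, rec * spr:(rec + 1) * spr].tobytes())
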