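"""Synthetic multichannel EEG with planted, calibrated phase coupling.

Generates stage-labeled 30 s epochs whose band-specific phase-locking
values (PLV) are analytically known, so the whole connectivity →
band-evaluation → classification pipeline can be exercised and checked
without real polysomnography.

Coupling model
--------------
Per frequency band, one shared narrowband carrier (band-pass filtered
Gaussian noise, via its analytic signal) is distributed to all channels.
Each channel applies its own slowly varying Gaussian phase jitter with
per-sample wrapped-normal marginal of standard deviation σ_ch.  The PLV
between a jittered channel and the carrier tends to ``exp(−σ_ch²/2)``
(the modulus of the wrapped-normal characteristic function); between two
channels the phase-difference variance adds, so the pairwise PLV target
is ``exp(−(σ_i² + σ_j²)/2)``.  A channel with σ = ∞ receives an
independent carrier (no coupling).

The jitter is temporally smooth (low-pass filtered noise rescaled to the
requested marginal σ) so the jittered signal stays narrowband and the
Hilbert-transform phase used downstream reads the planted jitter
faithfully; per-sample independent jitter would whiten the spectrum and
bias the measured PLV away from the closed-form target.

Stage contrasts
---------------
The default coupling table plants the qualitative ordering observed in
NREM sleep connectivity: PLV rises from N2 to N3 in the delta and alpha
bands, falls in beta2 and gamma, and decreases overall from low to high
frequency bands (with alpha above theta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import nnls
from scipy.signal import butter, hilbert, sosfiltfilt

from .bands import BandDefinition, CANONICAL_BANDS, STAGE_ORDER
from .preprocessing import EpochSet, HypnogramAnnotation, RawRecording, write_edf


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def plv_target_from_sigma(sigma: float) -> float:
    """Expected PLV for a wrapped-normal phase error of standard deviation σ.

    ``exp(−σ²/2)`` is the modulus of the characteristic function of a
    wrapped-normal distribution at frequency 1, i.e. the mean resultant
    length of ``exp(iθ)`` with θ ~ N(0, σ²).  σ here is the standard
    deviation of the *phase difference* whose PLV is sought: for two
    channels jittered independently against a shared carrier with σ_i and
    σ_j, pass ``sqrt(σ_i² + σ_j²)``.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return math.exp(-sigma**2 / 2.0)


def sigma_from_plv_target(plv: float) -> float:
    """Inverse of :func:`plv_target_from_sigma` (pairwise σ for a target PLV)."""
    if not 0 < plv <= 1:
        raise ValueError("target PLV must be in (0, 1]")
    return math.sqrt(-2.0 * math.log(plv))


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CouplingSpec:
    """Planted coupling for one (stage, band) cell.

    ``pair_sigma`` is either a scalar (the same pairwise jitter σ for every
    channel pair) or a full symmetric C×C matrix of pairwise σ values in
    radians; ``np.inf`` means "uncoupled".  Channel-level jitter standard
    deviations are derived so that σ_i² + σ_j² reproduces the requested
    pairwise values (exactly for a uniform matrix, least-squares
    otherwise).
    """

    stage: str
    band: str
    pair_sigma: float | np.ndarray
    band_amplitude: float = 1.0
    noise_amplitude: float = 0.0

    def __post_init__(self) -> None:
        ps = self.pair_sigma
        if np.isscalar(ps):
            if ps < 0:
                raise ValueError("pair_sigma must be non-negative")
        else:
            ps = np.asarray(ps, dtype=float)
            if ps.ndim != 2 or ps.shape[0] != ps.shape[1]:
                raise ValueError("pair_sigma matrix must be square")
            finite = np.isfinite(ps)
            if not np.array_equal(ps[finite], ps.T[finite.T]):
                raise ValueError("pair_sigma matrix must be symmetric")
            if (ps[finite] < 0).any():
                raise ValueError("pair_sigma entries must be non-negative")
            object.__setattr__(self, "pair_sigma", ps)
        if self.band_amplitude < 0 or self.noise_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")

    def channel_sigmas(self, n_channels: int) -> np.ndarray:
        """Per-channel jitter σ_ch realizing the pairwise targets."""
        ps = self.pair_sigma
        if np.isscalar(ps):
            if np.isinf(ps):
                return np.full(n_channels, np.inf)
            return np.full(n_channels, float(ps) / math.sqrt(2.0))
        if ps.shape[0] != n_channels:
            raise ValueError("pair_sigma matrix does not match n_channels")
        iu, ju = np.triu_indices(n_channels, k=1)
        finite = np.isfinite(ps[iu, ju])
        uncoupled = np.ones(n_channels, dtype=bool)
        uncoupled[iu[finite]] = False
        uncoupled[ju[finite]] = False
        coupled = np.flatnonzero(~uncoupled)
        sig = np.full(n_channels, np.inf)
        if coupled.size:
            pos = {c: k for k, c in enumerate(coupled)}
            rows, rhs = [], []
            for i, j, ok in zip(iu, ju, finite):
                if not ok:
                    continue
                row = np.zeros(coupled.size)
                row[pos[i]] = 1.0
                row[pos[j]] = 1.0
                rows.append(row)
                rhs.append(ps[i, j] ** 2)
            var, _ = nnls(np.array(rows), np.array(rhs))
            sig[coupled] = np.sqrt(var)
        return sig


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to synthesize one stage-labeled dataset."""

    epochs_per_stage: int = 100
    n_channels: int = 12
    sampling_rate: float = 512.0
    epoch_seconds: float = 30.0
    seed: int = 0
    stages: tuple[str, ...] = STAGE_ORDER
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS
    coupling: Mapping[tuple[str, str], CouplingSpec] = field(default_factory=dict)
    #: bandwidth of the smooth phase jitter (Hz); small vs. band bandwidth
    jitter_cutoff_hz: float = 1.0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least two channels")
        if self.epochs_per_stage < 1:
            raise ValueError("epochs_per_stage must be >= 1")
        if self.sampling_rate <= 0 or self.epoch_seconds <= 0:
            raise ValueError("sampling_rate and epoch_seconds must be positive")
        nyq = self.sampling_rate / 2.0
        for b in self.bands:
            if b.high_hz >= nyq:
                raise ValueError(f"band {b.name} exceeds Nyquist ({nyq} Hz)")
        if not self.coupling:
            object.__setattr__(self, "coupling", default_coupling())
        missing = [
            (s, b.name) for s in self.stages for b in self.bands
            if (s, b.name) not in self.coupling
        ]
        if missing:
            raise ValueError(f"missing CouplingSpec for {missing}")

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.epoch_seconds * self.sampling_rate))


#: default pairwise PLV targets per (stage, band), chosen to plant the
#: qualitative NREM ordering: N3 > N2 in delta/alpha, N2 > N3 in
#: beta2/gamma, overall decay with frequency, alpha above theta.
DEFAULT_TARGET_PLV: Mapping[tuple[str, str], float] = {
    ("REM", "delta"): 0.45, ("N2", "delta"): 0.50, ("N3", "delta"): 0.65,
    ("REM", "theta"): 0.35, ("N2", "theta"): 0.38, ("N3", "theta"): 0.40,
    ("REM", "alpha"): 0.42, ("N2", "alpha"): 0.45, ("N3", "alpha"): 0.60,
    ("REM", "beta1"): 0.30, ("N2", "beta1"): 0.32, ("N3", "beta1"): 0.32,
    ("REM", "beta2"): 0.25, ("N2", "beta2"): 0.30, ("N3", "beta2"): 0.22,
    ("REM", "gamma"): 0.18, ("N2", "gamma"): 0.25, ("N3", "gamma"): 0.15,
}


def default_coupling(noise_amplitude: float = 0.1) -> dict[tuple[str, str], CouplingSpec]:
    """The default stage-by-band coupling table (see :data:`DEFAULT_TARGET_PLV`)."""
    return {
        (stage, band): CouplingSpec(
            stage=stage,
            band=band,
            pair_sigma=sigma_from_plv_target(plv),
            noise_amplitude=noise_amplitude,
        )
        for (stage, band), plv in DEFAULT_TARGET_PLV.items()
    }


def uniform_coupling(
    pair_sigma_by_band: Mapping[str, float],
    stages: Sequence[str] = STAGE_ORDER,
    noise_amplitude: float = 0.0,
) -> dict[tuple[str, str], CouplingSpec]:
    """Same coupling in every stage: a zero-contrast (chance-level) design."""
    return {
        (stage, band): CouplingSpec(stage, band, sigma, noise_amplitude=noise_amplitude)
        for stage in stages
        for band, sigma in pair_sigma_by_band.items()
    }


def complementary_coupling(
    noise_amplitude: float = 0.0,
) -> dict[tuple[str, str], CouplingSpec]:
    """Each band separates a different class pair; no band separates all three.

    delta singles out REM, alpha singles out N2, beta1 singles out N3;
    theta/beta2/gamma carry no contrast.  Feature-level fusion across
    bands can then outperform any single band.
    """
    base = {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta1": 1.0,
            "beta2": 1.2, "gamma": 1.4}
    coupling = uniform_coupling(base, noise_amplitude=noise_amplitude)
    strong = 0.35
    coupling[("REM", "delta")] = CouplingSpec("REM", "delta", strong,
                                              noise_amplitude=noise_amplitude)
    coupling[("N2", "alpha")] = CouplingSpec("N2", "alpha", strong,
                                             noise_amplitude=noise_amplitude)
    coupling[("N3", "beta1")] = CouplingSpec("N3", "beta1", strong,
                                             noise_amplitude=noise_amplitude)
    return coupling


def single_band_contrast_coupling(
    band: str = "alpha",
    sigmas: Mapping[str, float] = None,
    baseline_sigma: float = 1.0,
    noise_amplitude: float = 0.0,
) -> dict[tuple[str, str], CouplingSpec]:
    """Class contrast planted in one band only; all other bands identical across stages."""
    if sigmas is None:
        sigmas = {"REM": 1.4, "N2": 0.9, "N3": 0.4}
    coupling = uniform_coupling(
        {b.name: baseline_sigma for b in CANONICAL_BANDS},
        noise_amplitude=noise_amplitude,
    )
    for stage, sigma in sigmas.items():
        coupling[(stage, band)] = CouplingSpec(stage, band, sigma,
                                               noise_amplitude=noise_amplitude)
    return coupling


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

#: carriers occupy the interior of their band (edges inset by this fraction
#: of the bandwidth) so their power does not sit on the analysis filter's
#: half-power edge, where adjacent bands would otherwise cross-talk and
#: bias the measured PLV below the closed-form target
CARRIER_EDGE_INSET = 0.1


def _narrowband_carriers(rng: np.random.Generator, k: int, n: int,
                         band: BandDefinition, fs: float) -> np.ndarray:
    """k unit-RMS analytic narrowband carriers (band-passed Gaussian noise)."""
    pad = int(2 * fs)
    bw = band.high_hz - band.low_hz
    lo = band.low_hz + CARRIER_EDGE_INSET * bw
    hi = band.high_hz - CARRIER_EDGE_INSET * bw
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal((k, n + 2 * pad)), axis=1)[:, pad:pad + n]
    z = hilbert(x, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return z / rms


def _smooth_jitter_block(rng: np.random.Generator, k: int, n: int, fs: float,
                         cutoff_hz: float) -> np.ndarray:
    """k rows of slowly varying Gaussian jitter, each with unit per-sample std."""
    pad = int(2 * fs)
    sos = butter(4, min(cutoff_hz, fs / 4), btype="lowpass", fs=fs, output="sos")
    theta = sosfiltfilt(sos, rng.standard_normal((k, n + 2 * pad)), axis=1)[:, pad:pad + n]
    sd = theta.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return theta / sd


def synth_epoch(stage: str, config: GeneratorConfig, epoch_seed: int) -> np.ndarray:
    """One channels × samples epoch for ``stage``; deterministic given ``epoch_seed``."""
    if stage not in config.stages:
        raise ValueError(f"unknown stage {stage!r}; config covers {config.stages}")
    n = config.samples_per_epoch
    fs = config.sampling_rate
    C = config.n_channels
    # independent child streams per band plus one for broadband noise
    streams = np.random.SeedSequence(epoch_seed).spawn(len(config.bands) + 1)
    out = np.zeros((C, n))
    for band, ss in zip(config.bands, streams[:-1]):
        spec = config.coupling[(stage, band.name)]
        rng = np.random.default_rng(ss)
        carrier = _narrowband_carriers(rng, 1, n, band, fs)[0]
        sigmas = spec.channel_sigmas(C)
        theta = _smooth_jitter_block(rng, C, n, fs, config.jitter_cutoff_hz)
        coupled = np.isfinite(sigmas)
        z = np.empty((C, n), dtype=complex)
        z[coupled] = carrier * np.exp(1j * theta[coupled] * sigmas[coupled, None])
        if (~coupled).any():
            z[~coupled] = _narrowband_carriers(rng, int((~coupled).sum()), n, band, fs)
        out += spec.band_amplitude * z.real
    # one broadband noise term per epoch; amplitude averaged over the
    # per-band specs (they normally agree)
    noise_amp = float(np.mean(
        [config.coupling[(stage, b.name)].noise_amplitude for b in config.bands]
    ))
    if noise_amp > 0:
        out += noise_amp * np.random.default_rng(streams[-1]).standard_normal((C, n))
    return out


def synth_dataset(config: GeneratorConfig) -> EpochSet:
    """Full labeled dataset: ``epochs_per_stage`` per stage, seeded shuffle."""
    master = np.random.SeedSequence(config.seed)
    n_total = config.epochs_per_stage * len(config.stages)
    children = master.spawn(n_total + 1)
    data = np.empty((n_total, config.n_channels, config.samples_per_epoch))
    labels = np.empty(n_total, dtype=object)
    k = 0
    for stage in config.stages:
        for _ in range(config.epochs_per_stage):
            epoch_seed = int(children[k].generate_state(1)[0] % (2**31))
            data[k] = synth_epoch(stage, config, epoch_seed)
            labels[k] = stage
            k += 1
    perm = np.random.default_rng(children[-1]).permutation(n_total)
    return EpochSet(
        data=data[perm],
        labels=labels[perm],
        sampling_rate=config.sampling_rate,
    )


def synth_hypnogram(run_lengths: Sequence[tuple[str, int]]) -> HypnogramAnnotation:
    """Build a hypnogram from (stage, epoch-count) runs, e.g. for curation tests."""
    if not run_lengths:
        raise ValueError("run_lengths must be non-empty")
    stages: list[str] = []
    for stage, count in run_lengths:
        if count < 1:
            raise ValueError("run counts must be >= 1")
        stages.extend([stage] * count)
    return HypnogramAnnotation(tuple(stages))


# ---------------------------------------------------------------------------
# on-disk bundle and EDF export
# ---------------------------------------------------------------------------

def save_dataset(epochs: EpochSet, directory: str | Path) -> None:
    """Write a dataset bundle: one .npy array + a plain-text label table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "epochs.npy", epochs.data)
    with open(directory / "labels.tsv", "w") as fh:
        fh.write("epoch\tstage\n")
        for i, (idx, stage) in enumerate(zip(epochs.epoch_indices, epochs.labels)):
            fh.write(f"{idx}\t{stage}\n")
    (directory / "meta.tsv").write_text(
        f"sampling_rate\t{epochs.sampling_rate}\nband\t{epochs.band or ''}\n"
    )


def load_dataset(directory: str | Path) -> EpochSet:
    directory = Path(directory)
    data = np.load(directory / "epochs.npy")
    rows = (directory / "labels.tsv").read_text().splitlines()[1:]
    idx, labels = zip(*(r.split("\t") for r in rows))
    meta = dict(r.split("\t") for r in (directory / "meta.tsv").read_text().splitlines())
    return EpochSet(
        data=data,
        labels=np.array(labels, dtype=object),
        sampling_rate=float(meta["sampling_rate"]),
        band=meta.get("band") or None,
        epoch_indices=np.array([int(i) for i in idx]),
    )


def export_edf(epochs: EpochSet, edf_path: str | Path,
               hypnogram_path: str | Path | None = None) -> None:
    """Concatenate epochs into a continuous EDF recording (+ stage file).

    The epochs are laid out back-to-back in order, so epoch ``i`` of the
    written hypnogram labels samples ``[i·30·fs, (i+1)·30·fs)`` — a full
    round trip through :func:`plvsleep.preprocessing.read_edf` and
    :func:`plvsleep.preprocessing.segment_epochs`.
    """
    if epochs.n_epochs == 0:
        raise ValueError("cannot export an empty EpochSet")
    signal = np.concatenate(list(epochs.data), axis=1)
    raw = RawRecording(
        signal=signal,
        sampling_rate=epochs.sampling_rate,
        channel_labels=epochs.channel_labels,
    )
    write_edf(raw, edf_path)
    if hypnogram_path is not None:
        Path(hypnogram_path).write_text("\n".join(epochs.labels) + "\n")
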