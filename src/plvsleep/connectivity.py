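"""Phase-locking-value connectivity, stage-average networks and ANOVA.

The phase-locking value (PLV) between two channels is the modulus of the
time-averaged unit phasor of their instantaneous phase difference within
one 30 s epoch:

    PLV = | (1/T) Σ_t exp(i(ϕ_a(t) − ϕ_b(t))) |   ∈ [0, 1]

Instantaneous phase is the angle of the analytic (Hilbert) signal of a
narrowband epoch.  For C channels this yields a symmetric C×C matrix per
epoch per band (C = 12 → 66 distinct channel pairs); stage-average
matrices are thresholded into binary brain networks at the largest
threshold that leaves no node isolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import hilbert
from scipy.stats import f_oneway

from .preprocessing import EpochSet

#: seconds discarded at each epoch edge before averaging, to suppress
#: Hilbert-transform edge artifacts
DEFAULT_EDGE_TRIM_SECONDS = 0.5


# ---------------------------------------------------------------------------
# phase extraction and PLV
# ---------------------------------------------------------------------------

def instantaneous_phase(epoch: np.ndarray) -> np.ndarray:
    """Per-channel instantaneous phase (radians in (−π, π]) of a narrowband epoch.

    Amplitude-invariant: scaling any channel by a positive constant leaves
    its phase unchanged. An all-zero channel has no defined phase and is
    rejected.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if not np.all(np.any(epoch != 0, axis=1)):
        raise ValueError("phase undefined for an all-zero channel")
    return np.angle(hilbert(epoch, axis=1))


def plv_pair(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """PLV of two phase series: resultant length of exp(i(ϕ_a − ϕ_b)) over time."""
    phase_a = np.asarray(phase_a, dtype=float)
    phase_b = np.asarray(phase_b, dtype=float)
    if phase_a.shape != phase_b.shape:
        raise ValueError("phase series must have equal length")
    if phase_a.size == 0:
        raise ValueError("phase series must be non-empty")
    return float(np.abs(np.mean(np.exp(1j * (phase_a - phase_b)))))


def plv_matrix(phase_epoch: np.ndarray) -> np.ndarray:
    """All-pairs PLV of a channels × samples phase array; symmetric, unit diagonal."""
    phase_epoch = np.asarray(phase_epoch, dtype=float)
    if phase_epoch.ndim != 2 or phase_epoch.shape[0] < 2:
        raise ValueError("need a channels × samples array with >= 2 channels")
    z = np.exp(1j * phase_epoch)
    m = np.abs(z @ z.conj().T) / phase_epoch.shape[1]
    m = np.clip(m, 0.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return m


def epoch_plv(epoch: np.ndarray, sampling_rate: float,
              edge_trim_seconds: float = DEFAULT_EDGE_TRIM_SECONDS) -> np.ndarray:
    """PLV matrix of one narrowband signal epoch (phase extraction + edge trim)."""
    phase = instantaneous_phase(epoch)
    trim = int(round(edge_trim_seconds * sampling_rate))
    if 2 * trim >= phase.shape[1]:
        raise ValueError("edge trim leaves no samples")
    if trim:
        phase = phase[:, trim:phase.shape[1] - trim]
    return plv_matrix(phase)


# ---------------------------------------------------------------------------
# upper-triangle feature vectorization
# ---------------------------------------------------------------------------

def upper_triangle_pairs(n_channels: int) -> list[tuple[int, int]]:
    """Row-major (i, j) channel pairs above the diagonal; index map for features."""
    return [(i, j) for i in range(n_channels) for j in range(i + 1, n_channels)]


def vectorize_upper(matrix: np.ndarray) -> np.ndarray:
    """C×C symmetric matrix → C(C−1)/2 feature vector (row-major upper triangle)."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    iu, ju = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu, ju].copy()

def matrix_from_vector(vector: np.ndarray, n_channels: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`: symmetric matrix with unit diagonal."""
    vector = np.asarray(vector, dtype=float)
    if vector.size != n_channels * (n_channels - 1) // 2:
        raise ValueError("vector length does not match n_channels")
    m = np.eye(n_channels)
    iu, ju = np.triu_indices(n_channels, k=1)
    m[iu, ju] = vector
    m[ju, iu] = vector
    return m


# ---------------------------------------------------------------------------
# per-dataset feature tables
# ---------------------------------------------------------------------------

def epochset_plv_matrices(epochs: EpochSet,
                          edge_trim_seconds: float = DEFAULT_EDGE_TRIM_SECONDS
                          ) -> np.ndarray:
    """Stack of per-epoch PLV matrices (epochs × C × C) for one band."""
    return np.stack([
        epoch_plv(epochs.data[k], epochs.sampling_rate, edge_trim_seconds)
        for k in range(epochs.n_epochs)
    ]) if epochs.n_epochs else np.empty((0, epochs.n_channels, epochs.n_channels))


def plv_feature_table(band_epochs: Mapping[str, EpochSet],
                      edge_trim_seconds: float = DEFAULT_EDGE_TRIM_SECONDS
                      ) -> pd.DataFrame:
    """Long-format feature table over all bands.

    One row per (band, epoch): columns are the 66 pair features named
    ``"i-j"`` after their channel indices, plus ``band``, ``stage`` and
    ``epoch`` bookkeeping columns.
    """
    frames = []
    for band, epochs in band_epochs.items():
        mats = epochset_plv_matrices(epochs, edge_trim_seconds)
        pairs = upper_triangle_pairs(epochs.n_channels)
        cols = [f"{i}-{j}" for i, j in pairs]
        feats = np.stack([vectorize_upper(m) for m in mats]) if len(mats) else \
            np.empty((0, len(pairs)))
        df = pd.DataFrame(feats, columns=cols)
        df.insert(0, "epoch", epochs.epoch_indices)
        df.insert(1, "stage", epochs.labels)
        df.insert(2, "band", band)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The channel-pair feature columns of a :func:`plv_feature_table` frame."""
    return [c for c in table.columns if c not in ("epoch", "stage", "band")]


# ---------------------------------------------------------------------------
# stage-average networks
# ---------------------------------------------------------------------------

def stage_mean_plv(matrices: Sequence[np.ndarray] | np.ndarray,
                   labels: Sequence[str], stage: str) -> np.ndarray:
    """Entrywise mean PLV matrix over all epochs of one sleep stage."""
    matrices = np.asarray(matrices, dtype=float)
    labels = np.asarray(labels)
    mask = labels == stage
    if not mask.any():
        raise ValueError(f"no epochs labeled {stage!r}")
    return matrices[mask].mean(axis=0)


@dataclass(frozen=True)
class BinaryNetwork:
    """Thresholded brain network: 0/1 adjacency and the threshold that built it."""

    adjacency: np.ndarray
    threshold: float

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def to_networkx(self):
        import networkx as nx
        return nx.from_numpy_array(self.adjacency)


def no_isolate_threshold(matrix: np.ndarray) -> tuple[float, BinaryNetwork]:
    """Largest threshold that leaves no isolated node in the binary network.

    Keeping edges with weight ≥ τ, node i stays connected iff
    τ ≤ max_{j≠i} w_ij, so the no-isolate threshold is the minimum over
    nodes of their largest incident weight.  Any strictly larger
    edge-weight threshold isolates at least one node.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1] or matrix.shape[0] < 2:
        raise ValueError("need a square matrix with >= 2 nodes")
    off = matrix.copy()
    np.fill_diagonal(off, -np.inf)
    tau = float(off.max(axis=1).min())
    adjacency = (off >= tau).astype(int)
    return tau, BinaryNetwork(adjacency=adjacency, threshold=tau)


def network_difference(mat_a: np.ndarray, mat_b: np.ndarray) -> np.ndarray:
    """Signed stage-difference matrix: positive entries = increase in ``mat_a``."""
    mat_a = np.asarray(mat_a, dtype=float)
    mat_b = np.asarray(mat_b, dtype=float)
    if mat_a.shape != mat_b.shape:
        raise ValueError("matrices must share a shape")
    return mat_a - mat_b


# ---------------------------------------------------------------------------
# stage / band comparisons
# ---------------------------------------------------------------------------

def epoch_mean_plv(matrices: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Per-epoch mean over the off-diagonal pairs (the ANOVA operand)."""
    matrices = np.asarray(matrices, dtype=float)
    return np.array([vectorize_upper(m).mean() for m in matrices])


def stage_band_anova(groups: Iterable[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA across groups of per-epoch mean PLV; returns (F, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least two values")
    pooled = np.concatenate(groups)
    if np.allclose(pooled, pooled[0]):
        return 0.0, 1.0
    res = f_oneway(*groups)
    f = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(f):  # identical group means with zero within-variance
        return 0.0, 1.0
    return f, p
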