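"""Ordinal-pattern connectivity between biosignal channels.

Edges of the channel graph are weighted by standardized permutation mutual
information (SPMI): each signal is symbolized into ordinal patterns
(Bandt-Pompe), permutation entropies of the marginal and joint pattern
distributions are estimated, and

    SPMI(X, Y) = (PE_X + PE_Y - PE_XY) / PE_XY

which lies in [0, 1] for any non-degenerate pair (0 = independent patterns,
1 = one symbol stream determines the other).  SPMI is symmetric and
invariant to the logarithm base; natural logs are used internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OrdinalConfig",
    "ConnectivityMatrix",
    "DegenerateSignalError",
    "ordinal_patterns",
    "permutation_entropy",
    "joint_permutation_entropy",
    "spmi",
    "spmi_matrix",
    "threshold_edges",
    "matrix_to_tsv",
    "edges_to_tsv",
]


class DegenerateSignalError(ValueError):
    """Raised when a pattern distribution carries no entropy (e.g. both
    series strictly monotone), making the SPMI ratio 0/0."""


@dataclass(frozen=True)
class OrdinalConfig:
    """Embedding parameters for ordinal-pattern symbolization.

    ``n`` is the embedding dimension (patterns live in S_n, so there are n!
    of them), ``tau`` the time lag between embedded samples.  A series of
    length N yields N - (n-1)*tau patterns.  ``degenerate_as_zero`` maps the
    0/0 SPMI of fully ordered pairs to 0 instead of raising; useful when
    sweeping all channel pairs of real recordings.
    """

    n: int = 5
    tau: int = 1
    degenerate_as_zero: bool = False

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"embedding dimension must be >= 2, got {self.n}")
        if self.tau < 1:
            raise ValueError(f"time lag must be >= 1, got {self.tau}")

    @property
    def n_patterns(self) -> int:
        return math.factorial(self.n)

    def n_vectors(self, series_length: int) -> int:
        return series_length - (self.n - 1) * self.tau


@dataclass
class ConnectivityMatrix:
    """Symmetric channel-by-channel SPMI matrix with unit diagonal."""

    values: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.values.shape[0])]
        if len(self.channel_names) != self.values.shape[0]:
            raise ValueError("channel_names length mismatch")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def _factorials(n: int) -> np.ndarray:
    out = np.ones(n, dtype=np.int64)
    for i in range(1, n):
        out[i] = out[i - 1] * i
    return out


def ordinal_patterns(series: np.ndarray, cfg: OrdinalConfig) -> np.ndarray:
    """Symbolize ``series`` into lexicographic ordinal-pattern indices.

    Each embedded vector x_i = [x(i), x(i+tau), ..., x(i+(n-1)tau)] is ranked
    by value; ties are broken by order of occurrence (the earlier sample
    ranks lower), the standard stable convention.  The resulting permutation
    is encoded as its lexicographic rank in 0..n!-1 via the Lehmer code.

    Returns an int array of length N - (n-1)*tau.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    n, tau = cfg.n, cfg.tau
    m = cfg.n_vectors(x.size)
    if m < 1:
        raise ValueError(
            f"series of length {x.size} too short for n={n}, tau={tau}"
        )
    idx = np.arange(m)[:, None] + tau * np.arange(n)[None, :]
    emb = x[idx]                                   # (m, n)
    order = np.argsort(emb, axis=1, kind="stable")  # positions by ascending value
    # Lehmer code of the permutation `order`: digit j counts later entries
    # smaller than order[:, j]; lexicographic rank = sum digit_j * (n-1-j)!
    smaller_later = (order[:, :, None] > order[:, None, :]) & (
        np.arange(n)[None, None, :] > np.arange(n)[None, :, None]
    )
    digits = smaller_later.sum(axis=2)             # (m, n)
    weights = _factorials(n)[::-1]                 # (n-1)!, ..., 1!, 0!
    return (digits * weights[None, :]).sum(axis=1).astype(np.int64)


def _entropy_from_counts(counts: np.ndarray) -> float:
    """Shannon entropy (nats) of an empirical count vector.

    Counts are sorted before summation so that the floating-point result
    depends only on the multiset of counts; this makes SPMI symmetry and
    SPMI(X, X) = 1 exact rather than within rounding.
    """
    c = np.sort(counts[counts > 0]).astype(float)
    total = c.sum()
    if total == 0:
        raise ValueError("empty pattern distribution")
    p = c / total
    return float(-(p * np.log(p)).sum())


def permutation_entropy(series: np.ndarray, cfg: OrdinalConfig) -> float:
    """Permutation entropy in nats: Shannon entropy of the empirical
    ordinal-pattern distribution.  Bounded by ln(n!)."""
    patterns = ordinal_patterns(series, cfg)
    counts = np.bincount(patterns, minlength=cfg.n_patterns)
    return _entropy_from_counts(counts)


def _joint_counts(px: np.ndarray, py: np.ndarray, n_patterns: int) -> np.ndarray:
    return np.bincount(px * n_patterns + py, minlength=n_patterns * n_patterns)


def joint_permutation_entropy(
    x: np.ndarray, y: np.ndarray, cfg: OrdinalConfig
) -> float:
    """Joint permutation entropy: entropy of the paired pattern stream
    (pattern of x at i, pattern of y at i).  Satisfies
    max(PE_x, PE_y) <= PE_xy <= PE_x + PE_y."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    px = ordinal_patterns(x, cfg)
    py = ordinal_patterns(y, cfg)
    return _entropy_from_counts(_joint_counts(px, py, cfg.n_patterns))


def _spmi_from_entropies(pe_x: float, pe_y: float, pe_xy: float,
                         cfg: OrdinalConfig) -> float:
    if pe_xy == 0.0:
        if cfg.degenerate_as_zero:
            return 0.0
        raise DegenerateSignalError(
            "joint permutation entropy is zero (both series fully ordered); "
            "set degenerate_as_zero=True to map this to SPMI 0"
        )
    return (pe_x + pe_y - pe_xy) / pe_xy


def spmi(x: np.ndarray, y: np.ndarray, cfg: OrdinalConfig) -> float:
    """Standardized permutation mutual information of two equal-length series."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    px = ordinal_patterns(x, cfg)
    py = ordinal_patterns(y, cfg)
    k = cfg.n_patterns
    pe_x = _entropy_from_counts(np.bincount(px, minlength=k))
    pe_y = _entropy_from_counts(np.bincount(py, minlength=k))
    pe_xy = _entropy_from_counts(_joint_counts(px, py, k))
    return _spmi_from_entropies(pe_x, pe_y, pe_xy, cfg)


def spmi_matrix(
    segment: np.ndarray,
    cfg: OrdinalConfig,
    channel_names: list[str] | None = None,
) -> ConnectivityMatrix:
    """All-pairs SPMI over the rows (channels) of ``segment``.

    Every unordered pair is computed once and mirrored; the diagonal is 1 by
    definition.  EEG-EEG, EEG-EMG and EMG-EMG pairs are treated identically.
    """
    data = np.asarray(segment, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("segment must be a (channels >= 2) x samples matrix")
    n_ch = data.shape[0]
    k = cfg.n_patterns
    patterns = np.stack([ordinal_patterns(data[c], cfg) for c in range(n_ch)])
    marginals = [
        _entropy_from_counts(np.bincount(patterns[c], minlength=k))
        for c in range(n_ch)
    ]
    values = np.eye(n_ch)
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            pe_xy = _entropy_from_counts(
                _joint_counts(patterns[i], patterns[j], k)
            )
            values[i, j] = values[j, i] = _spmi_from_entropies(
                marginals[i], marginals[j], pe_xy, cfg
            )
    return ConnectivityMatrix(values, list(channel_names or []))


def threshold_edges(matrix: ConnectivityMatrix, q: float) -> np.ndarray:
    """Retain the strongest fraction ``q`` of channel pairs as graph edges.

    Keeps the k = floor(q * P) pairs with the largest SPMI, P = N(N-1)/2.
    With N = 40 channels and q = 0.25 this yields 195 edges.  Ties are broken
    lexicographically on (channel i, channel j); no self-loops.  Returns a
    (k, 2) int array of undirected edges with i < j.
    """
    if not (0.0 < q <= 1.0):
        raise ValueError(f"edge retention fraction must be in (0, 1], got {q}")
    n = matrix.n_channels
    iu, ju = np.triu_indices(n, k=1)
    vals = matrix.values[iu, ju]
    k = int(np.floor(q * vals.size))
    # sort by descending SPMI, then ascending (i, j) for deterministic ties
    order = np.lexsort((ju, iu, -vals))[:k]
    edges = np.stack([iu[order], ju[order]], axis=1)
    return edges[np.lexsort((edges[:, 1], edges[:, 0]))]


def matrix_to_tsv(matrix: ConnectivityMatrix, path) -> None:
    df = pd.DataFrame(
        matrix.values, index=matrix.channel_names, columns=matrix.channel_names
    )
    df.to_csv(path, sep="\t")


def edges_to_tsv(matrix: ConnectivityMatrix, edges: np.ndarray, path) -> None:
    names = matrix.channel_names
    rows = [
        {"src": names[i], "dst": names[j], "spmi": matrix.values[i, j]}
        for i, j in edges
    ]
    pd.DataFrame(rows, columns=["src", "dst", "spmi"]).to_csv(
        path, sep="\t", index=False
    )
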