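"""Synthetic token sequences and projection weights.

All inputs to the attention block are generated here with controlled
statistics: a token-embedding matrix ``X`` (d rows, one column per token)
and the key/query/value projections ``W_K``, ``W_Q`` (D x d) and ``W_V``
(d x d).  In *tied* mode the key and query projections share a single
matrix W and the value projection is the identity, the weight-sharing
simplification commonly used to analyze a single attention block.

Every generator is a pure function of its arguments, including the seed;
there is no hidden global random state.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TokenSequence",
    "ProjectionWeights",
    "make_tokens",
    "make_weights",
    "save_matrix",
    "load_matrix",
]


@dataclass(frozen=True)
class TokenSequence:
    """Embedded tokens X in R^{d x N}; column t is the t-th token x_t."""

    X: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
            raise ValueError(f"token matrix must be 2-D with positive shape, got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("token matrix contains non-finite entries")
        object.__setattr__(self, "X", X)

    @property
    def d(self) -> int:
        return self.X.shape[0]

    @property
    def N(self) -> int:
        return self.X.shape[1]

    def column(self, t: int) -> np.ndarray:
        return self.X[:, t]


@dataclass(frozen=True)
class ProjectionWeights:
    """Key/query/value projections; ``tied`` means W_K == W_Q and W_V == I."""

    W_K: np.ndarray
    W_Q: np.ndarray
    W_V: np.ndarray
    tied: bool = False

    def __post_init__(self) -> None:
        W_K = np.asarray(self.W_K, dtype=np.float64)
        W_Q = np.asarray(self.W_Q, dtype=np.float64)
        W_V = np.asarray(self.W_V, dtype=np.float64)
        for name, M in (("W_K", W_K), ("W_Q", W_Q), ("W_V", W_V)):
            if M.ndim != 2:
                raise ValueError(f"{name} must be a matrix, got ndim={M.ndim}")
            if not np.all(np.isfinite(M)):
                raise ValueError(f"{name} contains non-finite entries")
        if W_K.shape != W_Q.shape:
            raise ValueError(f"W_K and W_Q shapes differ: {W_K.shape} vs {W_Q.shape}")
        d = W_K.shape[1]
        if W_V.shape != (d, d):
            raise ValueError(f"W_V must be {d}x{d}, got {W_V.shape}")
        if self.tied:
            if not np.array_equal(W_K, W_Q):
                raise ValueError("tied weights require W_K == W_Q elementwise")
            if not np.array_equal(W_V, np.eye(d)):
                raise ValueError("tied weights require W_V to be the identity")
        object.__setattr__(self, "W_K", W_K)
        object.__setattr__(self, "W_Q", W_Q)
        object.__setattr__(self, "W_V", W_V)

    @property
    def d(self) -> int:
        return self.W_K.shape[1]

    @property
    def D(self) -> int:
        return self.W_K.shape[0]


def make_tokens(
    d: int,
    N: int,
    scale: float = 1.0,
    normalize: bool = True,
    seed: int = 0,
) -> TokenSequence:
    """Draw a d x N token matrix with i.i.d. Gaussian entries of std ``scale``.

    With ``normalize`` each column is rescaled to Euclidean norm ``scale``
    (the spherical-normalization convention that keeps the exponential
    kernel well conditioned).  Deterministic in ``seed``.
    """
    if not (isinstance(d, (int, np.integer)) and d >= 1):
        raise ValueError(f"d must be a positive integer, got {d!r}")
    if not (isinstance(N, (int, np.integer)) and N >= 1):
        raise ValueError(f"N must be a positive integer, got {N!r}")
    if not (np.isfinite(scale) and scale > 0):
        raise ValueError(f"scale must be positive, got {scale!r}")
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, scale, size=(d, N))
    if normalize:
        norms = np.linalg.norm(X, axis=0)
        X = X * (scale / norms)
    return TokenSequence(X)


def make_weights(
    d: int,
    D: int,
    tied: bool = False,
    scale: float = 1.0,
    seed: int = 0,
) -> ProjectionWeights:
    """Draw projection weights with Gaussian entries of std ``scale/sqrt(d)``.

    The 1/sqrt(d) factor keeps key/query norms roughly independent of the
    embedding dimension.  In tied mode a single W (D x d) is sampled for
    both W_K and W_Q, and W_V is the d x d identity; any D is allowed.
    """
    if not (isinstance(d, (int, np.integer)) and d >= 1):
        raise ValueError(f"d must be a positive integer, got {d!r}")
    if not (isinstance(D, (int, np.integer)) and D >= 1):
        raise ValueError(f"D must be a positive integer, got {D!r}")
    if not (np.isfinite(scale) and scale > 0):
        raise ValueError(f"scale must be positive, got {scale!r}")
    rng = np.random.default_rng(seed)
    std = scale / np.sqrt(d)
    if tied:
        W = rng.normal(0.0, std, size=(D, d))
        return ProjectionWeights(W_K=W, W_Q=W, W_V=np.eye(d), tied=True)
    W_K = rng.normal(0.0, std, size=(D, d))
    W_Q = rng.normal(0.0, std, size=(D, d))
    W_V = rng.normal(0.0, std, size=(d, d))
    return ProjectionWeights(W_K=W_K, W_Q=W_Q, W_V=W_V, tied=False)


def save_matrix(path: str | Path, M: np.ndarray) -> None:
    """Write a matrix as CSV with a header comment naming its dimensions."""
    M = np.atleast_2d(np.asarray(M, dtype=np.float64))
    np.savetxt(
        path,
        M,
        delimiter=",",
        header=f"rows={M.shape[0]} cols={M.shape[1]}",
        fmt="%.17g",
    )


def load_matrix(path: str | Path) -> np.ndarray:
    """Read a matrix written by :func:`save_matrix`; exact round trip."""
    path = Path(path)
    M = np.loadtxt(path, delimiter=",", ndmin=2)
    header = path.read_text().splitlines()[0]
    match = re.match(r"#\s*rows=(\d+)\s+cols=(\d+)", header)
    if match:
        expected = (int(match.group(1)), int(match.group(2)))
        if M.shape != expected:
            raise ValueError(f"header says {expected} but data has shape {M.shape}")
    return M
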