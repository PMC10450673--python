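"""Exact softmax self-attention and its kernelized (linear-attention) form.

This is the ground truth the neuron-astrocyte circuit approximates.  Given
tokens X and projections, keys/queries/values are K = W_K X, Q = W_Q X,
V = W_V X, and the attention output with residual is

    L = V softmax(K^T Q) + X,

with the softmax normalized along columns, so column t of L - X is a
convex combination of value vectors with weights
alpha_i(t) = e^{k_i^T q_t} / sum_j e^{k_j^T q_t}.

``linear_attention`` replaces each exponential by the feature-map inner
product phi(k_i)^T phi(q_t).  It is the closed form of the circuit's
reading phase and serves as the brute-force oracle the streaming circuit
must match to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DegenerateNormalizationError, NumericRangeError
from .feature_maps import FeatureMap, gram
from .fixtures import ProjectionWeights, TokenSequence

__all__ = [
    "KQVProjection",
    "AttentionOutput",
    "project",
    "column_softmax",
    "softmax_self_attention",
    "exact_normalizers",
    "linear_attention",
    "default_epsilon",
]


@dataclass(frozen=True)
class KQVProjection:
    """Keys, queries, values (columnwise) plus the tokens they came from."""

    K: np.ndarray
    Q: np.ndarray
    V: np.ndarray
    X: np.ndarray

    @property
    def N(self) -> int:
        return self.X.shape[1]

    @property
    def d(self) -> int:
        return self.X.shape[0]

    @property
    def D(self) -> int:
        return self.K.shape[0]


@dataclass(frozen=True)
class AttentionOutput:
    """Stacked per-token outputs L (d x N); A is the N x N attention matrix.

    ``trace`` carries the per-token normalizer recorded by the circuit
    (astrocyte p_t, or the inhibitory activity R_t for the shunting
    control); it is None for the closed-form reference computations.
    """

    L: np.ndarray
    A: Optional[np.ndarray] = None
    trace: Optional[np.ndarray] = None


def project(tokens: TokenSequence, weights: ProjectionWeights) -> KQVProjection:
    """K = W_K X, Q = W_Q X, V = W_V X (exact matrix products)."""
    if weights.d != tokens.d:
        raise ValueError(
            f"weights expect embedding dimension {weights.d}, tokens have {tokens.d}"
        )
    X = tokens.X
    return KQVProjection(K=weights.W_K @ X, Q=weights.W_Q @ X, V=weights.W_V @ X, X=X)


def column_softmax(logits: np.ndarray) -> np.ndarray:
    """Columnwise softmax with per-column max subtraction.

    Subtracting the column max leaves the result exactly invariant (it
    cancels in numerator and denominator) while preventing overflow.
    """
    logits = np.asarray(logits, dtype=np.float64)
    shifted = logits - logits.max(axis=0, keepdims=True)
    E = np.exp(shifted)
    A = E / E.sum(axis=0, keepdims=True)
    if not np.all(np.isfinite(A)):
        raise NumericRangeError("softmax produced non-finite attention weights")
    return A


def softmax_self_attention(P: KQVProjection, temperature: float = 1.0) -> AttentionOutput:
    """Exact attention with residual: L = V softmax(K^T Q / temperature) + X."""
    if not (np.isfinite(temperature) and temperature > 0):
        raise ValueError(f"temperature must be positive, got {temperature!r}")
    logits = P.K.T @ P.Q
    if temperature != 1.0:
        logits = logits / temperature
    A = column_softmax(logits)
    L = P.V @ A + P.X
    return AttentionOutput(L=L, A=A)


def exact_normalizers(P: KQVProjection) -> np.ndarray:
    """The softmax denominators Z_t = sum_j e^{k_j^T q_t}, one per token."""
    with np.errstate(over="ignore"):
        Z = np.exp(P.K.T @ P.Q).sum(axis=0)
    if not np.all(np.isfinite(Z)):
        raise NumericRangeError("softmax normalizer overflow; reduce the token/weight scale")
    return Z


def default_epsilon(fm: FeatureMap) -> float:
    """Degenerate-normalization guard: positive-feature denominators can be
    legitimately tiny, oscillatory (cosine) ones cannot."""
    return 1e-300 if fm.kind in ("positive_exp", "exact_kernel_oracle") else 1e-12


def linear_attention(
    P: KQVProjection,
    fm: FeatureMap,
    epsilon: Optional[float] = None,
) -> AttentionOutput:
    """Kernelized attention: column t is V phi(K)^T phi(q_t) / (phi(q_t)^T sum_j phi(k_j)) + x_t.

    With the exact-kernel oracle this reproduces softmax attention to
    machine precision; with random features it is the finite-m estimate.
    """
    if epsilon is None:
        epsilon = default_epsilon(fm)
    G = gram(fm, P.K, P.Q)
    denom = G.sum(axis=0)
    if np.any(np.abs(denom) < epsilon):
        t = int(np.argmin(np.abs(denom)))
        raise DegenerateNormalizationError(
            f"attention denominator {denom[t]:.4g} for token {t} is below epsilon={epsilon:.4g}"
        )
    A = G / denom
    L = P.V @ A + P.X
    return AttentionOutput(L=L, A=A)
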