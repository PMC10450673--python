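"""Random feature maps for the exponential dot-product kernel.

The hidden-layer nonlinearity phi must satisfy phi(x)^T phi(y) ~= e^{x^T y}
for the circuit's divisive normalization to reproduce softmax attention.
Two randomized constructions achieve this in expectation:

* ``cosine_rbf``   phi(x) = sqrt(2/m) * e^{|x|^2/2} * cos(Pi x + b),
  with Pi ~ N(0,1)^{m x D} and phases b ~ U[0, 2*pi) — the classical
  random-Fourier-feature map for the RBF kernel, re-weighted so the
  Gaussian-kernel estimate becomes an exponential-kernel estimate.
* ``positive_exp`` phi(x) = (1/sqrt(m)) * e^{-|x|^2/2} * e^{Pi x},
  the strictly positive exponential features used by linear-attention
  architectures; positivity guarantees valid (non-negative) attention
  weights at any finite m.

A third kind, ``exact_kernel_oracle``, evaluates e^{x^T y} in closed form.
It is the infinite-width limit used as a test oracle; it has no finite
feature vector, so :func:`apply` rejects it while :func:`kernel_estimate`
and the Gram-matrix helper support it exactly.

With ``prenormalize`` arguments are first projected to the unit sphere and
the norm-dependent prefactors are dropped (they are then constants that
cancel in the attention numerator/denominator), giving the plain forms
cos(Pi x + b) and exp(Pi x).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import NumericRangeError

__all__ = [
    "FeatureMap",
    "KINDS",
    "sample_feature_map",
    "apply",
    "feature_matrix",
    "kernel_estimate",
    "gram",
]

KINDS = ("cosine_rbf", "positive_exp", "exact_kernel_oracle")


@dataclass(frozen=True)
class FeatureMap:
    """A sampled feature map: projection Pi (m x D), phases b, and kind.

    ``scale`` is an optional positive prefactor multiplying phi; the
    attention ratio is invariant to it, which the tests exploit.
    """

    kind: str
    m: int
    D: int
    Pi: Optional[np.ndarray] = None
    b: Optional[np.ndarray] = None
    prenormalize: bool = False
    seed: Optional[int] = None
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature map kind {self.kind!r}; expected one of {KINDS}")
        if self.m < 1 or self.D < 1:
            raise ValueError(f"m and D must be >= 1, got m={self.m}, D={self.D}")
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError(f"scale must be positive, got {self.scale!r}")
        if self.kind != "exact_kernel_oracle":
            if self.Pi is None or self.Pi.shape != (self.m, self.D):
                shape = None if self.Pi is None else self.Pi.shape
                raise ValueError(f"Pi must have shape ({self.m}, {self.D}), got {shape}")
        if self.kind == "cosine_rbf":
            if self.b is None or self.b.shape != (self.m,):
                raise ValueError(f"cosine_rbf requires phases b of length {self.m}")

    def scaled(self, c: float) -> "FeatureMap":
        """Return a copy with phi multiplied by the positive constant c."""
        if not (np.isfinite(c) and c > 0):
            raise ValueError(f"prefactor must be positive, got {c!r}")
        return replace(self, scale=self.scale * c)

    def to_descriptor(self) -> dict:
        """JSON-serializable descriptor; Pi and b regenerate from the seed."""
        if self.seed is None:
            raise ValueError("feature map was built without a seed; cannot serialize")
        return {
            "kind": self.kind,
            "m": self.m,
            "D": self.D,
            "seed": int(self.seed),
            "prenormalize": bool(self.prenormalize),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_descriptor())

    @staticmethod
    def from_descriptor(desc: dict) -> "FeatureMap":
        return sample_feature_map(
            desc["kind"],
            m=desc["m"],
            D=desc["D"],
            prenormalize=desc.get("prenormalize", False),
            seed=desc["seed"],
        )

    @staticmethod
    def from_json(s: str) -> "FeatureMap":
        return FeatureMap.from_descriptor(json.loads(s))


def sample_feature_map(
    kind: str,
    m: int,
    D: int,
    prenormalize: bool = False,
    seed: int = 0,
) -> FeatureMap:
    """Sample Pi (standard normal) and, for cosine maps, phases b ~ U[0,2pi)."""
    if kind not in KINDS:
        raise ValueError(f"unknown feature map kind {kind!r}; expected one of {KINDS}")
    if not (isinstance(m, (int, np.integer)) and m >= 1):
        raise ValueError(f"m must be a positive integer, got {m!r}")
    if not (isinstance(D, (int, np.integer)) and D >= 1):
        raise ValueError(f"D must be a positive integer, got {D!r}")
    if kind == "exact_kernel_oracle":
        return FeatureMap(kind=kind, m=int(m), D=int(D), prenormalize=prenormalize, seed=int(seed))
    rng = np.random.default_rng(seed)
    Pi = rng.standard_normal((int(m), int(D)))
    b = rng.uniform(0.0, 2.0 * np.pi, size=int(m)) if kind == "cosine_rbf" else None
    return FeatureMap(
        kind=kind, m=int(m), D=int(D), Pi=Pi, b=b, prenormalize=prenormalize, seed=int(seed)
    )


def feature_matrix(fm: FeatureMap, M: np.ndarray) -> np.ndarray:
    """Apply phi columnwise: M is D x n, the result is m x n."""
    if fm.kind == "exact_kernel_oracle":
        raise ValueError(
            "exact_kernel_oracle has no finite feature representation; "
            "use kernel_estimate or gram instead"
        )
    M = np.atleast_2d(np.asarray(M, dtype=np.float64))
    if M.shape[0] != fm.D:
        raise ValueError(f"arguments have dimension {M.shape[0]}, feature map expects {fm.D}")
    if not np.all(np.isfinite(M)):
        raise ValueError("feature map arguments contain non-finite entries")
    norms = np.linalg.norm(M, axis=0)
    if fm.prenormalize:
        if np.any(norms == 0.0):
            raise ValueError("cannot spherically normalize a zero vector")
        Z = fm.Pi @ (M / norms)
        if fm.kind == "cosine_rbf":
            out = np.cos(Z + fm.b[:, None])
        else:
            with np.errstate(over="ignore"):
                out = np.exp(Z)
    else:
        with np.errstate(over="ignore", under="ignore"):
            if fm.kind == "cosine_rbf":
                pref = np.sqrt(2.0 / fm.m) * np.exp(norms**2 / 2.0)
                out = pref * np.cos(fm.Pi @ M + fm.b[:, None])
            else:
                # exponent-space form of (1/sqrt(m)) e^{-|x|^2/2} e^{Pi x}:
                # avoids spurious inf*0 when the two factors are extreme
                out = np.exp(fm.Pi @ M - norms**2 / 2.0) / np.sqrt(fm.m)
    if not np.all(np.isfinite(out)):
        worst = float(norms.max())
        raise NumericRangeError(
            f"feature map overflow for argument with norm {worst:.4g}; "
            "enable prenormalize or reduce the token/weight scale"
        )
    if fm.scale != 1.0:
        out = fm.scale * out
    return out


def apply(fm: FeatureMap, x: np.ndarray) -> np.ndarray:
    """phi(x) for a single D-vector; strictly positive for positive_exp."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError(f"expected a vector, got ndim={x.ndim}")
    if x.shape[0] != fm.D:
        raise ValueError(f"argument has length {x.shape[0]}, feature map expects {fm.D}")
    return feature_matrix(fm, x[:, None])[:, 0]


def gram(fm: FeatureMap, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """phi(A)^T phi(B) for column matrices A (D x nA) and B (D x nB).

    For the exact oracle this is exp(A^T B), the kernel itself.
    """
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    if fm.kind == "exact_kernel_oracle":
        if A.shape[0] != B.shape[0]:
            raise ValueError(f"dimension mismatch: {A.shape[0]} vs {B.shape[0]}")
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
            raise ValueError("kernel arguments contain non-finite entries")
        with np.errstate(over="ignore"):
            G = np.exp(A.T @ B)
        if not np.all(np.isfinite(G)):
            raise NumericRangeError("exact kernel overflow; reduce the token/weight scale")
        return G
    return feature_matrix(fm, A).T @ feature_matrix(fm, B)


def kernel_estimate(fm: FeatureMap, x: np.ndarray, y: np.ndarray) -> float:
    """phi(x)^T phi(y): a randomized estimate of e^{x^T y} (exact for the oracle)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be vectors of equal length, got {x.shape} and {y.shape}")
    return float(gram(fm, x[:, None], y[:, None])[0, 0])
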