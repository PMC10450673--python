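"""The neuron-astrocyte circuit: writing-phase plasticity and gated reading.

The network is a three-layer perceptron (first layer f, hidden layer h,
last layer l) whose hidden-to-last synapses H are tripartite: each of the
d*m synapses is ensheathed by an astrocyte process.  A binary read gate r
switches between two phases:

Writing phase (r = 0).  Tokens stream in one at a time; the forward pass
is f_t = x_t, h_t = phi(W_K f_t), l_t = W_V f_t (with tied weights,
l_t = f_t).  Two plasticity rules accrue state:

* Hebbian:      H <- H + eta_H * l_t h_t^T,   so H = eta_H * V phi(K)^T
* presynaptic:  g <- g + h_t,                 so g = sum_j phi(k_j)

The neuron-to-astrocyte weight g is the same for every postsynaptic
neuron, which is what lets the astrocyte act as a single shared scalar.

Reading phase (r = 1).  For a query token x, h = phi(W_Q x); every
astrocyte process responds with g_a h_a, and spatial averaging of the
Ca2+ levels across processes leaves the single scalar p = (1/m) g^T h.
Gliotransmitter release divides the synaptic drive by p:

    l = (1/p) H h + x,

which, with eta_H = 1/m, equals column t of the kernelized attention
V phi(K)^T phi(q_t) / (phi(q_t)^T sum_j phi(k_j)) + x_t exactly — the
softmax approximation enters only through phi.

Astrocyte relaxation is treated as instantaneous: p is recomputed per
read token and no Ca2+ ODE is simulated.  The modulation matrix (every
entry 1/p) is kept as the scalar 1/p, never materialized.

For the exact-kernel oracle map (infinite-width limit) the plastic state
cannot be held as finite arrays; the written keys and values are stored
and the reading phase evaluates e^{k_j^T q} in closed form, reproducing
the same algebra.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np

from .attention import AttentionOutput, default_epsilon
from .errors import DegenerateNormalizationError, NotWrittenError
from .feature_maps import FeatureMap, apply as fm_apply
from .fixtures import ProjectionWeights, TokenSequence, load_matrix, save_matrix

__all__ = [
    "CircuitState",
    "ForwardTrace",
    "write_sequence",
    "read_token",
    "run_block",
]


def _neumaier_add(total: np.ndarray, comp: np.ndarray, term: np.ndarray):
    """One compensated-summation step (Kahan-Babuska-Neumaier).

    Keeping a running compensation makes the finalized sum equal to the
    correctly rounded exact sum for all practical inputs, so the plastic
    state is bit-for-bit invariant under token presentation order — the
    commutativity the associative-memory math promises.
    """
    new = total + term
    big = np.abs(total) >= np.abs(term)
    comp = comp + np.where(big, (total - new) + term, (term - new) + total)
    return new, comp


@dataclass
class CircuitState:
    """Plastic state: Hebbian weights H (d x m), presynaptic weights g (m),
    the astrocyte scalar p from the last read, and the read gate r."""

    H: np.ndarray
    g: np.ndarray
    eta_H: float
    m: int
    r: int = 0
    p: Optional[float] = None
    n_written: int = 0
    # compensation accumulators for order-independent summation
    _H_comp: np.ndarray = None
    _g_comp: np.ndarray = None
    # lazy storage for the exact-kernel oracle (no finite feature vector)
    _keys: List[np.ndarray] = field(default_factory=list)
    _values: List[np.ndarray] = field(default_factory=list)

    @classmethod
    def zeros(cls, d: int, m: int, eta_H: Optional[float] = None) -> "CircuitState":
        """Fresh pre-writing state: H = 0, g = 0; eta_H defaults to 1/m."""
        if d < 1 or m < 1:
            raise ValueError(f"d and m must be >= 1, got d={d}, m={m}")
        if eta_H is None:
            eta_H = 1.0 / m
        if not (np.isfinite(eta_H) and eta_H > 0):
            raise ValueError(f"eta_H must be positive, got {eta_H!r}")
        return cls(
            H=np.zeros((d, m)),
            g=np.zeros(m),
            eta_H=float(eta_H),
            m=int(m),
            _H_comp=np.zeros((d, m)),
            _g_comp=np.zeros(m),
        )

    @property
    def H_total(self) -> np.ndarray:
        """Finalized Hebbian weights (accumulator plus compensation)."""
        return self.H + self._H_comp

    @property
    def g_total(self) -> np.ndarray:
        return self.g + self._g_comp

    def save(self, directory: str | Path) -> None:
        """Serialize to a JSON + CSV bundle (compensation is finalized)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "eta_H": self.eta_H,
            "m": self.m,
            "r": self.r,
            "p": self.p,
            "n_written": self.n_written,
            "oracle": bool(self._keys),
        }
        (directory / "state.json").write_text(json.dumps(meta, indent=2))
        save_matrix(directory / "H.csv", self.H_total)
        save_matrix(directory / "g.csv", self.g_total[None, :])
        if self._keys:
            save_matrix(directory / "keys.csv", np.column_stack(self._keys))
            save_matrix(directory / "values.csv", np.column_stack(self._values))

    @classmethod
    def load(cls, directory: str | Path) -> "CircuitState":
        directory = Path(directory)
        meta = json.loads((directory / "state.json").read_text())
        H = load_matrix(directory / "H.csv")
        g = load_matrix(directory / "g.csv")[0]
        state = cls(
            H=H,
            g=g,
            eta_H=meta["eta_H"],
            m=meta["m"],
            r=meta["r"],
            p=meta["p"],
            n_written=meta["n_written"],
            _H_comp=np.zeros_like(H),
            _g_comp=np.zeros_like(g),
        )
        if meta.get("oracle"):
            keys = load_matrix(directory / "keys.csv")
            values = load_matrix(directory / "values.csv")
            state._keys = [keys[:, j] for j in range(keys.shape[1])]
            state._values = [values[:, j] for j in range(values.shape[1])]
        return state


@dataclass(frozen=True)
class ForwardTrace:
    """One forward pass: layer activities f, h, l and the normalizer value.

    ``p`` is the astrocyte scalar (or the inhibitory activity R for the
    shunting control).  ``h`` is None for the exact-kernel oracle, whose
    hidden layer is not finite-dimensional.
    """

    f: np.ndarray
    h: Optional[np.ndarray]
    ell: np.ndarray
    p: float


def _resolve_mode(weights: ProjectionWeights, mode: str) -> str:
    if mode == "auto":
        return "tied" if weights.tied else "general"
    if mode not in ("tied", "general"):
        raise ValueError(f"mode must be 'auto', 'tied' or 'general', got {mode!r}")
    if mode == "tied" and not weights.tied:
        raise ValueError("tied mode requires tied weights (W_K == W_Q, W_V == I)")
    return mode


def write_sequence(
    tokens: TokenSequence,
    weights: ProjectionWeights,
    fm: FeatureMap,
    state: Optional[CircuitState] = None,
    mode: str = "auto",
) -> CircuitState:
    """Stream tokens through the writing phase (read gate r = 0).

    Per token: h_t = phi(W_K x_t) and l_t = W_V x_t (tied mode: l_t = x_t,
    the same value with one matrix product fewer); H accrues
    eta_H * l_t h_t^T and g accrues h_t.  After the pass,
    H == eta_H * V phi(K)^T and g == sum_j phi(k_j).
    """
    mode = _resolve_mode(weights, mode)
    if weights.d != tokens.d:
        raise ValueError(f"weights expect dimension {weights.d}, tokens have {tokens.d}")
    if fm.kind != "exact_kernel_oracle" and fm.D != weights.D:
        raise ValueError(f"feature map expects dimension {fm.D}, keys have {weights.D}")
    if state is None:
        state = CircuitState.zeros(tokens.d, fm.m)
    state.r = 0
    for t in range(tokens.N):
        f = tokens.column(t)
        k = weights.W_K @ f
        ell = f if mode == "tied" else weights.W_V @ f
        if fm.kind == "exact_kernel_oracle":
            state._keys.append(k)
            state._values.append(ell)
        else:
            h = fm_apply(fm, k)
            state.H, state._H_comp = _neumaier_add(
                state.H, state._H_comp, state.eta_H * np.outer(ell, h)
            )
            state.g, state._g_comp = _neumaier_add(state.g, state._g_comp, h)
        state.n_written += 1
    return state


def read_token(
    x: np.ndarray,
    weights: ProjectionWeights,
    fm: FeatureMap,
    state: CircuitState,
    epsilon: Optional[float] = None,
    normalizer: str = "astro",
    mode: str = "auto",
) -> ForwardTrace:
    """Forward a query token with the read gate open (r = 1).

    h = phi(W_Q x); the astrocyte scalar p = (1/m) g^T h divisively
    normalizes the synaptic drive: l = (1/p) H h + x.  With
    normalizer="shunting" the inhibitory neuron R = g^T h takes the
    astrocyte's place: l = (1/R) H h + x.
    """
    mode = _resolve_mode(weights, mode)
    if state.n_written == 0:
        raise NotWrittenError("reading before any token was written; run write_sequence first")
    if normalizer not in ("astro", "shunting"):
        raise ValueError(f"normalizer must be 'astro' or 'shunting', got {normalizer!r}")
    if epsilon is None:
        epsilon = default_epsilon(fm)
    state.r = 1
    f = np.asarray(x, dtype=np.float64)
    q = weights.W_Q @ f
    if fm.kind == "exact_kernel_oracle":
        K_w = np.column_stack(state._keys)
        V_w = np.column_stack(state._values)
        s = np.exp(K_w.T @ q)
        h = None
        gh = float(s.sum())
        Hh = state.eta_H * (V_w @ s)
    else:
        h = fm_apply(fm, q)
        gh = float(state.g_total @ h)
        Hh = state.H_total @ h
    denom = gh / state.m if normalizer == "astro" else gh
    if abs(denom) < epsilon:
        raise DegenerateNormalizationError(
            f"normalizer {denom:.4g} is below epsilon={epsilon:.4g}; "
            "the attention denominator is degenerate"
        )
    ell = Hh / denom + f
    state.p = denom
    return ForwardTrace(f=f, h=h, ell=ell, p=denom)


def run_block(
    tokens: TokenSequence,
    weights: ProjectionWeights,
    fm: FeatureMap,
    eta_H: Optional[float] = None,
    epsilon: Optional[float] = None,
    normalizer: str = "astro",
    mode: str = "auto",
) -> AttentionOutput:
    """One full block: write all N tokens, then read all N tokens.

    Returns the stacked outputs L (approximately softmax attention plus
    the residual) and the recorded normalizer trace (p_1..p_N, or
    R_1..R_N for the shunting control).  eta_H defaults to 1/m for the
    astrocyte circuit and to 1 for the shunting circuit, the unique pair
    under which the two forward passes coincide exactly.
    """
    if eta_H is None:
        eta_H = 1.0 / fm.m if normalizer == "astro" else 1.0
    state = CircuitState.zeros(tokens.d, fm.m, eta_H=eta_H)
    state = write_sequence(tokens, weights, fm, state=state, mode=mode)
    columns = []
    trace = np.empty(tokens.N)
    for t in range(tokens.N):
        out = read_token(
            tokens.column(t), weights, fm, state,
            epsilon=epsilon, normalizer=normalizer, mode=mode,
        )
        columns.append(out.ell)
        trace[t] = out.p
    return AttentionOutput(L=np.column_stack(columns), A=None, trace=trace)
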