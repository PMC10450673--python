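"""Non-astrocytic control circuit: divisive normalization by shunting inhibition.

Identical three-layer network and writing phase, but the astrocyte is
replaced by a single inhibitory neuron whose activity R = g^T h divisively
normalizes the feed-forward drive from the hidden layer only:

    f = x,  h = phi(W f),  R = g^T h,  l = (r/R) H h + f.

The residual input from f bypasses the shunting, which biophysically
corresponds to the two input pathways synapsing at different distances
from the inhibitory shunt on the dendritic tree.

Scale convention: the astrocyte circuit uses the Hebbian rate eta_H = 1/m
and the spatially averaged p = (1/m) g^T h, so the 1/m factors cancel in
the ratio.  Here R = g^T h carries no 1/m, so the Hebbian rate defaults
to eta_H = 1; this is the unique choice under which the two circuits
implement the same forward pass exactly, and both then equal the
kernelized attention closed form.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .attention import AttentionOutput
from .circuit import CircuitState, ForwardTrace, read_token, run_block, write_sequence
from .feature_maps import FeatureMap
from .fixtures import ProjectionWeights, TokenSequence

__all__ = ["ShuntingState", "shunting_write_sequence", "shunting_read_token", "shunting_run_block"]

#: The shunting circuit shares the astrocyte circuit's plastic state
#: (H, g); only the normalizer differs, so the state type is reused.
#: The inhibitory activity R is recomputed each forward pass and recorded
#: in the trace, never stored as a weight.
ShuntingState = CircuitState


def shunting_write_sequence(
    tokens: TokenSequence,
    weights: ProjectionWeights,
    fm: FeatureMap,
    state: Optional[ShuntingState] = None,
    mode: str = "auto",
) -> ShuntingState:
    """Writing phase with the shunting convention eta_H = 1."""
    if state is None:
        state = ShuntingState.zeros(tokens.d, fm.m, eta_H=1.0)
    return write_sequence(tokens, weights, fm, state=state, mode=mode)


def shunting_read_token(
    x: np.ndarray,
    weights: ProjectionWeights,
    fm: FeatureMap,
    state: ShuntingState,
    epsilon: Optional[float] = None,
    mode: str = "auto",
) -> ForwardTrace:
    """Reading phase: l = (1/R) H h + x with R = g^T h (trace field p holds R)."""
    return read_token(
        x, weights, fm, state, epsilon=epsilon, normalizer="shunting", mode=mode
    )


def shunting_run_block(
    tokens: TokenSequence,
    weights: ProjectionWeights,
    fm: FeatureMap,
    epsilon: Optional[float] = None,
    mode: str = "auto",
) -> AttentionOutput:
    """Full write-then-read block; the trace records R_t per read token."""
    return run_block(
        tokens, weights, fm, eta_H=1.0, epsilon=epsilon, normalizer="shunting", mode=mode
    )
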