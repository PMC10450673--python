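"""The inhibitory-neuron control circuit matches the astrocyte circuit.

Divisive normalization does not require an astrocyte: an inhibitory
neuron with activity R = g^T h shunting the hidden-layer drive implements
the same forward pass, provided the Hebbian rate is 1 instead of 1/m
(the 1/m bookkeeping moves from the weights into the astrocyte's spatial
average).  The two circuits agree to machine precision.
"""

import numpy as np

from astroformer import (
    make_tokens,
    make_weights,
    run_block,
    sample_feature_map,
    shunting_run_block,
)

tokens = make_tokens(8, 12, seed=0)
weights = make_weights(8, 8, seed=1)
fm = sample_feature_map("positive_exp", m=256, D=8, seed=2)

astro = run_block(tokens, weights, fm)
shunt = shunting_run_block(tokens, weights, fm)

diff = np.linalg.norm(shunt.L - astro.L) / np.linalg.norm(astro.L)
print(f"relative difference between circuits: {diff:.3e}  (machine precision)")
print(f"inhibitory activity R_t = m * astrocyte p_t: "
      f"max rel dev = {np.abs(shunt.trace / (fm.m * astro.trace) - 1).max():.3e}")
print("same forward pass, two biological mechanisms for the softmax denominator")
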