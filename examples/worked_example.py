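"""Two-token worked example: the circuit recovers softmax attention.

Tokens are the unit basis vectors of R^2 and the tied projection is the
identity, so keys = queries = values = tokens and the attention weights
have the closed form [e/(1+e), 1/(1+e)] for each token on itself vs the
other.  The neuron-astrocyte circuit with the exact-kernel hidden layer
reproduces this exactly; with positive random features it converges as
the hidden layer widens.
"""

import math

import numpy as np

from astroformer import (
    ProjectionWeights,
    TokenSequence,
    project,
    run_block,
    sample_feature_map,
    softmax_self_attention,
)

tokens = TokenSequence(np.array([[1.0, 0.0], [0.0, 1.0]]))
weights = ProjectionWeights(np.eye(2), np.eye(2), np.eye(2), tied=True)

ref = softmax_self_attention(project(tokens, weights))
e = math.e
print(f"closed form weights:     [{e/(1+e):.6f}, {1/(1+e):.6f}]  (e/(1+e), 1/(1+e))")
print(f"softmax reference A[:,0]: [{ref.A[0,0]:.6f}, {ref.A[1,0]:.6f}]")
print(f"reference output L[:,0]:  [{ref.L[0,0]:.6f}, {ref.L[1,0]:.6f}]  (attention + residual)")

fm_exact = sample_feature_map("exact_kernel_oracle", m=1, D=2, seed=0)
exact = run_block(tokens, weights, fm_exact)
print(f"circuit, exact kernel:    [{exact.L[0,0]:.6f}, {exact.L[1,0]:.6f}]  (machine-precision match)")

for m in (16, 256, 4096):
    cols = np.array([
        run_block(tokens, weights,
                  sample_feature_map("positive_exp", m=m, D=2, seed=s)).L[:, 0]
        for s in range(15)
    ])
    med = np.median(cols, axis=0)
    print(f"circuit, positive_exp m={m:>5d}: median L[:,0] = [{med[0]:.4f}, {med[1]:.4f}]")
print("the median circuit output approaches the reference as the hidden layer widens")
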