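# Methods

## Model

The package implements a three-layer neuron–astrocyte network whose
forward pass, in its general (untied-weights) form, is

```
f = x ∈ R^d
h = φ[(1−r) W_K f + r W_Q f] ∈ R^m
ℓ = r (H ⊙ P̃) h + (1−r) W_V f + r f ∈ R^d
```

where `r ∈ {0,1}` is a global read gate, `H` are the hidden-to-output
synapses (each one tripartite, i.e. ensheathed by an astrocyte process),
and `P̃` is the astrocyte modulation with every entry equal to `1/p`.
With tied weights (`W_K = W_Q = W`, `W_V = I`) this reduces to
`h = φ(Wf)`, `ℓ = r (H ⊙ P̃) h + f`: during writing `ℓ = f` is the whole
output, so the unconditional residual of the tied form and the gated
residual of the general form agree in both phases. The implementation
follows the general gated form; `mode="tied"` is the specialization that
skips the identity `W_V` product and is bit-identical to the general path.

**Phase protocol.** One full writing pass over all N tokens, then one
full reading pass. This is the schedule under which the plastic state
contains all tokens when reading begins — the condition for the reading
phase to equal full (non-causal) attention. Interleaved per-token
reading/writing (online attention over a growing prefix) is not modeled.

**Plasticity.** Writing streams tokens one at a time:
`H ← H + η_H ℓ_t h_tᵀ` (Hebbian, default `η_H = 1/m`) and `g ← g + h_t`
(presynaptic). Both are sums of per-token terms, so the final state is
independent of presentation order. Because the neuron-to-astrocyte
increment depends only on presynaptic activity, `g` is shared across
postsynaptic neurons — this is what lets spatial averaging collapse all
astrocyte processes to one scalar.

**Astrocyte dynamics.** Relaxation is treated as instantaneous: no Ca²⁺
ODE is integrated. The scalar `p = (1/m) gᵀh` is recomputed per read
token, and the modulation matrix (all entries `1/p`) is stored as the
scalar, never materialized as a d×m matrix.

**Shunting control circuit.** Replacing the astrocyte by an inhibitory
neuron `R = gᵀh` that divisively normalizes only the hidden-layer drive
gives `ℓ = (r/R) H h + f`. With the astro convention (`η_H = 1/m`,
`p = gᵀh/m`) the factors of m cancel in the ratio; with `R = gᵀh`
carrying no 1/m, the forward passes coincide exactly iff the shunting
circuit uses `η_H = 1` (equivalently, folds 1/m into R). The package
adopts `η_H = 1`; the alternative `R ← gᵀh/m` with `η_H = 1/m` would give
identical outputs.

## Feature maps

Both random maps are unbiased estimators of the exponential kernel:
`E[φ(x)ᵀφ(y)] = e^{xᵀy}` exactly, for the cosine map via the
random-Fourier-feature identity for the Gaussian kernel multiplied by
`e^{(‖x‖²+‖y‖²)/2}`, and for the positive-exponential map via the
Gaussian moment-generating function. The positive map is strictly
positive elementwise, so its attention weights are valid (non-negative)
at any finite m; the cosine map can produce negative kernel estimates,
and hence degenerate attention denominators, at small m.

`prenormalize` projects arguments to the unit sphere and drops the
norm-dependent prefactors (then constants that cancel in the attention
ratio), giving the plain forms `cos(Πx+b)` and `exp(Πx)`. Default off,
matching the prefactored definitions literally. The
`exact_kernel_oracle` kind evaluates `e^{xᵀy}` in closed form; it is the
infinite-width limit used as a test oracle, has no finite feature vector
(`apply` rejects it), and is represented in the circuit by storing the
written keys and values and evaluating the kernel at read time.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `d`, `D` | 16 (experiments) | embedding / key-query dimension |
| `N` | 32 (sweeps), 50 (traces) | tokens per sequence |
| `m` | swept `d…50d`; 10⁴–10⁵ for traces | hidden width (number of tripartite synapse columns) |
| token `scale` | 1.0, spherically normalized | column norm of X |
| weight `scale` | 1.0 | weight std is `scale/√d` (variance-preserving) |
| `eta_H` | `1/m` astro, `1` shunting | Hebbian learning rate |
| softmax temperature | 1 | no `1/√D` factor inside the softmax, matching the model's attention definition |

Fixture defaults were chosen once so that typical logits satisfy
`|kᵀq| ≲ 1` (max ≈ 4 only at weight scale 2), keeping `e^{kᵀq}` well
conditioned and the positive-feature estimator variance (which grows like
`e^{‖k‖²+‖q‖²}`) moderate.

## What the synthetic generator does and does not emulate

Tokens are i.i.d. Gaussian columns normalized to unit norm; weights are
i.i.d. Gaussian. This matches common attention initialization and gives
fully controlled, download-free instances for every test. It does **not**
emulate trained Transformers: real embeddings and projections are highly
anisotropic, their logits span a much wider range, and their softmax
normalizers vary over orders of magnitude across tokens, whereas the
synthetic normalizers `Z_t` vary by only ~5% around `N`. Consequences:
passing tests demonstrate the algebraic identities and the Monte-Carlo
convergence rates, but absolute error levels and trace correlations on
trained-weight instances can differ. In particular, with near-flat
normalizers the astrocyte–normalizer Pearson correlation is noise-limited:
at m = 10⁴ it is ≈ 0.85–0.96 across seeds, and exceeds 0.99 only around
m = 10⁵ (where the estimator noise drops below the normalizer spread).
Pushing fixture scales up does not help — the positive-feature estimator
variance grows faster than the normalizer spread.

## Numerical choices

* **Order-independent plasticity.** Plain floating-point accumulation is
  commutative but not associative, so streaming sums would depend
  slightly on token order. The accumulators use Neumaier-compensated
  summation; the finalized sums equal the correctly rounded exact sums
  for all practical inputs, making the written state bit-for-bit
  invariant under permutation of token presentation — the commutativity
  the associative-memory algebra promises.
* **Softmax stabilization.** Per-column max subtraction, which leaves
  the softmax exactly invariant.
* **Overflow policy.** A non-finite feature or kernel value raises a
  `NumericRangeError` naming the offending norm rather than clamping;
  clamping would silently corrupt the kernel. The positive-exponential
  map is evaluated in exponent space (`exp(Πx − ‖x‖²/2)`) to avoid
  spurious `0·∞` when the prefactor underflows.
* **Degenerate normalizers.** Denominators below an epsilon raise a
  `DegenerateNormalizationError`. The guard defaults to 1e-300 for
  positive features and the exact kernel (whose denominators are
  positive and can only degenerate by underflow) and 1e-12 for cosine
  features (whose denominators can genuinely cancel).
* **Reading before writing** raises a state error rather than dividing
  by the zero `g`.

## Problem sizes

The test suite and the acceptance script use desk-scale instances chosen
as the smallest sizes at which every property is sharply resolved:
algebraic identities on ~100 random instances with d, D ≤ 16, N ≤ 32,
m ≤ 256; convergence sweeps at d = D = 16, N = 32, m = 16…800 with 10
feature-map seeds; unbiasedness at m = 10³ over 200 seeds; traces at
d = D = 16, N = 50, m = 10⁴–10⁵. The full suite runs in well under a
minute.

## Limitations

* Single-head, non-causal attention without positional encodings; the
  feed-forward network and layer-normalization steps of a full
  Transformer block are outside the modeled surface, which is
  `SelfAttn(X) + X`.
* No biophysical calcium or gliotransmitter kinetics; the read gate r is
  imposed, not derived from a neuromodulatory mechanism.
* Only the two printed random feature constructions (plus the exact
  oracle) are provided; variance-reduced variants (e.g. orthogonal
  random features) are out of scope.
* Loading pretrained Transformer weights is out of scope; all instances
  are synthetic.
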