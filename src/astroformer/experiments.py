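"""Desk-scale numerical validations of the circuit-Transformer equivalence.

Two experiments mirror the standard checks for random-feature attention:

* ``error_sweep`` — with tokens and weights held fixed, measure the
  relative Frobenius error between the circuit's output and exact
  softmax attention (both with residual) as the hidden width m grows.
  The error is scale-free: ||L_circuit - L_softmax||_F / ||L_softmax||_F.
* ``trace_experiment`` — during the reading phase, compare the recorded
  astrocyte responses, rescaled as m * p_t, with the exact softmax
  normalizers Z_t = sum_j e^{k_j^T q_t}.  The factor m is the unique
  scaling that makes the astrocyte scalar an unbiased estimator of Z_t.

Both use synthetic tokens and weights with matched shapes in place of
pretrained-Transformer weight transfer, which is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .attention import exact_normalizers, project, softmax_self_attention
from .circuit import run_block
from .errors import AstroformerError
from .feature_maps import sample_feature_map
from .fixtures import make_tokens, make_weights

__all__ = [
    "SweepResult",
    "TraceResult",
    "derive_seed",
    "error_sweep",
    "trace_experiment",
    "sweep_to_csv",
    "trace_to_csv",
]


def derive_seed(*keys: int) -> int:
    """Deterministically derive an independent 31-bit seed from integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class SweepResult:
    """Rows of (m, seed, rel_error); failed rows carry NaN and a message."""

    table: pd.DataFrame
    meta: dict

    def median_by_m(self) -> pd.Series:
        ok = self.table.dropna(subset=["rel_error"])
        return ok.groupby("m")["rel_error"].median()


@dataclass(frozen=True)
class TraceResult:
    """Paired series (m * p_t, Z_t) per token and their Pearson correlation.

    ``correlation_defined`` is False for N == 1, where the statistic does
    not exist; ``pearson_r`` is then NaN.
    """

    table: pd.DataFrame
    pearson_r: float
    correlation_defined: bool
    meta: dict


def error_sweep(
    d: int,
    D: int,
    N: int,
    m_values: Sequence[int],
    n_seeds: int,
    map_kind: str = "positive_exp",
    base_seed: int = 0,
    tied: bool = False,
    token_scale: float = 1.0,
    normalize: bool = True,
    weight_scale: float = 1.0,
) -> SweepResult:
    """Relative-error-vs-m sweep on one fixed instance of tokens and weights.

    For each (m, seed) the feature map is resampled and the circuit run;
    numeric failures (degenerate normalizers, overflow) are recorded
    per-row as NaN with a message rather than aborting the sweep.
    """
    m_values = list(m_values)
    if not m_values:
        raise ValueError("m_values must be non-empty")
    if any(b <= a for a, b in zip(m_values, m_values[1:])):
        raise ValueError(f"m_values must be strictly ascending, got {m_values}")
    if n_seeds < 1:
        raise ValueError(f"n_seeds must be >= 1, got {n_seeds}")
    tokens = make_tokens(d, N, scale=token_scale, normalize=normalize,
                         seed=derive_seed(base_seed, 0))
    weights = make_weights(d, D, tied=tied, scale=weight_scale,
                           seed=derive_seed(base_seed, 1))
    P = project(tokens, weights)
    L_ref = softmax_self_attention(P).L
    ref_norm = np.linalg.norm(L_ref)
    rows = []
    for m in m_values:
        for i in range(n_seeds):
            fm_seed = derive_seed(base_seed, 2, m, i)
            fm = sample_feature_map(map_kind, m=m, D=D, seed=fm_seed)
            try:
                L = run_block(tokens, weights, fm).L
                rel = float(np.linalg.norm(L - L_ref) / ref_norm)
                rows.append({"m": m, "seed": fm_seed, "rel_error": rel, "message": ""})
            except AstroformerError as exc:
                rows.append({"m": m, "seed": fm_seed, "rel_error": np.nan,
                             "message": str(exc)})
    table = pd.DataFrame(rows)
    meta = {
        "d": d, "D": D, "N": N, "map_kind": map_kind, "n_seeds": n_seeds,
        "base_seed": base_seed, "tied": tied, "token_scale": token_scale,
        "normalize": normalize, "weight_scale": weight_scale,
    }
    return SweepResult(table=table, meta=meta)


def trace_experiment(
    d: int,
    D: int,
    N: int,
    m: int,
    map_kind: str = "positive_exp",
    seed: int = 0,
    tied: bool = False,
    token_scale: float = 1.0,
    normalize: bool = True,
    weight_scale: float = 1.0,
) -> TraceResult:
    """Astrocyte responses vs exact softmax normalizers on one instance."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    tokens = make_tokens(d, N, scale=token_scale, normalize=normalize,
                         seed=derive_seed(seed, 0))
    weights = make_weights(d, D, tied=tied, scale=weight_scale,
                           seed=derive_seed(seed, 1))
    fm = sample_feature_map(map_kind, m=m, D=D, seed=derive_seed(seed, 2))
    out = run_block(tokens, weights, fm)
    astro = m * out.trace
    Z = exact_normalizers(project(tokens, weights))
    table = pd.DataFrame({
        "token_index": np.arange(N),
        "astro_value": astro,
        "exact_normalizer": Z,
    })
    if N >= 2:
        pearson_r = float(stats.pearsonr(astro, Z).statistic)
        defined = True
    else:
        pearson_r = float("nan")
        defined = False
    meta = {
        "d": d, "D": D, "N": N, "m": m, "map_kind": map_kind, "seed": seed,
        "tied": tied, "token_scale": token_scale, "normalize": normalize,
        "weight_scale": weight_scale, "pearson_r": pearson_r,
        "correlation_defined": defined,
    }
    return TraceResult(table=table, pearson_r=pearson_r,
                       correlation_defined=defined, meta=meta)


def _write_with_header(df: pd.DataFrame, meta: dict, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)


def sweep_to_csv(result: SweepResult, path: str | Path) -> None:
    """CSV export with full parameters and seeds in header comments."""
    _write_with_header(result.table, result.meta, path)


def trace_to_csv(result: TraceResult, path: str | Path) -> None:
    """CSV export of the paired (m*p_t, Z_t) series with parameter header."""
    _write_with_header(result.table, result.meta, path)
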