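import numpy as np
import pytest

from astroformer import make_tokens, make_weights, sample_feature_map
from astroformer.experiments import derive_seed


def draw_instances(n_base: int, base_seed: int = 20230814):
    """Random small attention instances spanning dimensions, widths, both
    feature-map kinds and both weight-tying modes.

    Returns a list of dicts with tokens, weights, feature map and labels;
    deterministic in base_seed.  n_base base draws expand to 4*n_base
    instances (2 kinds x 2 tying modes).
    """
    rng = np.random.default_rng(base_seed)
    instances = []
    for idx in range(n_base):
        d = int(rng.integers(2, 17))
        D = int(rng.integers(2, 17))
        N = int(rng.integers(1, 33))
        m = int(rng.integers(4, 257))
        for kind in ("cosine_rbf", "positive_exp"):
            for tied in (True, False):
                seed = derive_seed(base_seed, idx, tied)
                tokens = make_tokens(d, N, scale=1.0, normalize=True,
                                     seed=derive_seed(seed, 0))
                weights = make_weights(d, D, tied=tied, scale=1.0,
                                       seed=derive_seed(seed, 1))
                fm = sample_feature_map(kind, m=m, D=D, seed=derive_seed(seed, 2))
                instances.append({
                    "tokens": tokens, "weights": weights, "fm": fm,
                    "kind": kind, "tied": tied, "d": d, "D": D, "N": N, "m": m,
                })
    return instances


@pytest.fixture(scope="session")
def instance_grid():
    """>=100 random instances for the oracle-identity and equivalence checks."""
    return draw_instances(26)


@pytest.fixture(scope="session")
def small_instances():
    """A lighter grid for per-module unit tests."""
    return draw_instances(6, base_seed=7)
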