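"""Independent oracles shared by the test suite.

These deliberately avoid the library's own solvers: the GEM oracle is an
exhaustive grid search over the probability simplex.
"""

import numpy as np

from yieldens import OOBMatrix
from yieldens.ensembles import gem_objective


def grid_search_simplex(P, y, step=0.01):
    """Exhaustive simplex grid minimizer of the GEM objective for k <= 3."""
    k = P.shape[1]
    ticks = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    if k == 1:
        return np.ones(1), gem_objective(np.ones(1), P, y)
    best_w, best_obj = None, np.inf
    if k == 2:
        for a in ticks:
            w = np.array([a, 1.0 - a])
            obj = gem_objective(w, P, y)
            if obj < best_obj:
                best_w, best_obj = w, obj
        return best_w, best_obj
    for a in ticks:
        for b in ticks[ticks <= 1.0 - a + 1e-12]:
            w = np.array([a, b, 1.0 - a - b])
            obj = gem_objective(w, P, y)
            if obj < best_obj:
                best_w, best_obj = w, obj
    return best_w, best_obj


def random_oob(seed, n=200, k=3):
    """A seeded random holdout-prediction instance around plausible yields."""
    rng = np.random.default_rng(seed)
    y = rng.normal(150.0, 20.0, size=n)
    P = y[:, None] + rng.normal(0.0, rng.uniform(2.0, 15.0, size=k), size=(n, k))
    return OOBMatrix(P, y, [f"m{j}" for j in range(k)])
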