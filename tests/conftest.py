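import numpy as np
import pytest

from holomri.phantom import PhantomConfig, make_brain_slice, to_mr_series
from holomri.segmentation import segment_brain_and_tumor


def upwind_value_iteration(weights: np.ndarray, seeds, tol: float = 1e-12) -> np.ndarray:
    """Independent Eikonal oracle: Bellman-style fixed-point sweeping.

    Applies the same first-order upwind update as the fast-marching solver,
    but as a plain value iteration over the whole grid until convergence —
    no heap, no acceptance order.  Slow but unarguable.
    """
    weights = np.asarray(weights, dtype=float)
    h = 1.0 / weights
    T = np.full(weights.shape, np.inf)
    for r, c in seeds:
        T[int(r), int(c)] = 0.0
    seed_mask = np.isfinite(T)
    pad = np.pad
    while True:
        P = pad(T, 1, constant_values=np.inf)
        with np.errstate(invalid="ignore"):
            a = np.minimum(P[:-2, 1:-1], P[2:, 1:-1])
            b = np.minimum(P[1:-1, :-2], P[1:-1, 2:])
            lo = np.minimum(a, b)
            hi = np.maximum(a, b)
            one_sided = lo + h
            disc = 2.0 * h * h - (a - b) ** 2
            two_sided = 0.5 * (a + b + np.sqrt(np.maximum(disc, 0.0)))
            cand = np.where((hi - lo) >= h, one_sided, two_sided)
        cand = np.where(np.isfinite(lo), cand, np.inf)
        new = np.where(seed_mask, 0.0, np.minimum(T, cand))
        change = np.nanmax(np.where(np.isfinite(T) | np.isfinite(new), np.abs(np.where(np.isfinite(T), T, 0) - np.where(np.isfinite(new), new, 0)), 0))
        done = np.array_equal(np.isfinite(T), np.isfinite(new)) and change < tol
        T = new
        if done:
            return T


@pytest.fixture(scope="session")
def default_truth():
    """The default phantom slice (paper-like geometry, noise sigma 0.01, seed 0)."""
    return make_brain_slice(PhantomConfig())


@pytest.fixture(scope="session")
def default_segmentation(default_truth):
    """Brain + tumor segmentation of the default phantom at default config."""
    series = to_mr_series([default_truth])
    return segment_brain_and_tumor(series)[0]
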