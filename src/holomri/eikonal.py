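"""First-order fast marching solver for the Eikonal equation |grad T| = 1/F.

A front started at one or more seed points propagates over the pixel grid
with local speed F(x, y) > 0; T(x, y) is its first-arrival time.  The solver
is the classic single-pass fast marching method: a min-heap of trial points,
a first-order upwind discretisation on the 4-neighbour stencil, and each
point accepted exactly once in nondecreasing time order.  Ties are broken
deterministically by (time, row, col).

Pixels outside an optional support mask are never visited; their arrival
time is infinite (and maps to 1 after normalisation), which is how the
tumor stage restricts propagation to the skull-stripped brain.
"""

from __future__ import annotations

import heapq

import numpy as np

_FAR, _TRIAL, _ACCEPTED = 0, 1, 2


def fmm_arrival_times(
    weights: np.ndarray,
    seeds,
    support: np.ndarray | None = None,
) -> np.ndarray:
    """Raw first-arrival times from ``seeds`` under speed field ``weights``.

    Parameters
    ----------
    weights
        2-D strictly positive speed map F (the pixel weight matrix).
    seeds
        Iterable of (row, col) seed coordinates; T = 0 there.
    support
        Optional boolean mask; propagation is confined to True pixels.
        Unreached pixels get ``np.inf``.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2:
        raise ValueError("weights must be 2-D")
    rows, cols = weights.shape
    if support is None:
        allowed = np.ones((rows, cols), dtype=bool)
    else:
        allowed = np.asarray(support, dtype=bool)
        if allowed.shape != weights.shape:
            raise ValueError("support mask shape must match weights")
    if np.any(weights[allowed] <= 0):
        raise ValueError("speed weights must be strictly positive on the propagation domain")

    seeds = [(int(r), int(c)) for r, c in seeds]
    if not seeds:
        raise ValueError("at least one seed point is required")
    for r, c in seeds:
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"seed {(r, c)} outside image bounds {(rows, cols)}")
        if not allowed[r, c]:
            raise ValueError(f"seed {(r, c)} lies outside the propagation support")

    T = np.full((rows, cols), np.inf)
    state = np.full((rows, cols), _FAR, dtype=np.uint8)
    inv_w = 1.0 / np.where(weights > 0, weights, 1.0)

    heap: list[tuple[float, int, int]] = []
    for r, c in seeds:
        T[r, c] = 0.0
        state[r, c] = _TRIAL
        heapq.heappush(heap, (0.0, r, c))

    push = heapq.heappush
    pop = heapq.heappop
    inf = np.inf

    while heap:
        t, r, c = pop(heap)
        if state[r, c] == _ACCEPTED or t > T[r, c]:
            continue  # stale heap entry
        state[r, c] = _ACCEPTED
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nr, nc = r + dr, c + dc
            if not (0 <= nr < rows and 0 <= nc < cols):
                continue
            if state[nr, nc] == _ACCEPTED or not allowed[nr, nc]:
                continue
            # smallest accepted neighbour per axis (upwind values)
            a = inf
            if nr > 0 and state[nr - 1, nc] == _ACCEPTED:
                a = T[nr - 1, nc]
            if nr < rows - 1 and state[nr + 1, nc] == _ACCEPTED and T[nr + 1, nc] < a:
                a = T[nr + 1, nc]
            b = inf
            if nc > 0 and state[nr, nc - 1] == _ACCEPTED:
                b = T[nr, nc - 1]
            if nc < cols - 1 and state[nr, nc + 1] == _ACCEPTED and T[nr, nc + 1] < b:
                b = T[nr, nc + 1]
            h = inv_w[nr, nc]
            t_new = _solve_upwind(a, b, h)
            if t_new < T[nr, nc]:
                T[nr, nc] = t_new
                state[nr, nc] = _TRIAL
                push(heap, (t_new, nr, nc))
    return T


def _solve_upwind(a: float, b: float, h: float) -> float:
    """Solve the quadratic upwind discretisation of |grad T| = h on unit spacing.

    ``a`` and ``b`` are the smaller accepted neighbour times along each axis
    (inf if that axis has none); ``h`` = 1/F at the updated pixel.
    """
    if a > b:
        a, b = b, a
    if b - a >= h:  # one-sided update: the slower axis cannot contribute
        return a + h
    s = a + b
    disc = 2.0 * h * h - (a - b) ** 2
    return 0.5 * (s + np.sqrt(disc))


def normalize_arrival_times(times: np.ndarray) -> np.ndarray:
    """Min-max normalise arrival times to [0, 1] over reached pixels.

    Seeds stay at 0; unreached pixels (infinite raw time) are set to 1.
    A degenerate map (all seeds) normalises to zeros on the reached set.
    """
    times = np.asarray(times, dtype=float)
    out = np.ones_like(times)
    reached = np.isfinite(times)
    if not np.any(reached):
        return out
    tmax = times[reached].max()
    out[reached] = times[reached] / tmax if tmax > 0 else 0.0
    return out
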