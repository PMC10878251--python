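"""Numba kernels for the two sequential phases of the yearly schedule.

Foraging and care allocation cannot be expressed as independent per-agent
array operations: each forager removes resources that later foragers in the
same step can no longer take, and each care event consumes both the carer's
single care slot and the recipient's single cared-for slot.  Both phases
therefore iterate over agents in a randomized order.  The kernels receive
all randomness (a permutation plus one uniform deviate per slot) from the
caller's numpy Generator, so trajectories are reproducible independent of
numba internals.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forage_kernel", "care_kernel", "radius_offsets"]


def radius_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Integer (dx, dy) offsets with Euclidean length <= radius, incl. (0, 0)."""
    r = int(np.floor(radius))
    dx, dy = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    keep = dx * dx + dy * dy <= radius * radius
    return dx[keep].astype(np.int64), dy[keep].astype(np.int64)


@njit(cache=True)
def forage_kernel(
    order,          # int64[cap] permutation of slots
    u,              # float64[cap] one uniform per slot (patch choice)
    alive,          # bool[cap]
    age,            # int64[cap]
    x, y,           # int64[cap] positions (mutated)
    score,          # int64[cap] resource scores (mutated)
    forage_failed,  # bool[cap] (mutated; True iff attempt found no patch)
    resources,      # int64[W, H] patch resources (mutated)
    foraged,        # bool[W, H] per-step exhaustion flags (mutated)
    offs_dx, offs_dy,  # int64[n_off] movement-radius offsets
    adult_age, adult_yield, child_yield, width, height,
):
    """One foraging pass over all living agents in ``order``.

    An adult needs an unforaged in-radius patch holding >= adult_yield and
    strips it to zero; a child needs >= child_yield, takes child_yield, and
    the patch is closed for the step only once it drops below child_yield.
    Returns total resource income collected this step.
    """
    total = 0
    n_off = offs_dx.shape[0]
    for k in range(order.shape[0]):
        i = order[k]
        if not alive[i]:
            continue
        adult = age[i] >= adult_age
        need = adult_yield if adult else child_yield
        cx = x[i]
        cy = y[i]
        count = 0
        for j in range(n_off):
            px = cx + offs_dx[j]
            py = cy + offs_dy[j]
            if px < 0 or px >= width or py < 0 or py >= height:
                continue
            if foraged[px, py] or resources[px, py] < need:
                continue
            count += 1
        if count == 0:
            forage_failed[i] = True
            continue
        target = int(u[i] * count)
        if target >= count:
            target = count - 1
        seen = 0
        for j in range(n_off):
            px = cx + offs_dx[j]
            py = cy + offs_dy[j]
            if px < 0 or px >= width or py < 0 or py >= height:
                continue
            if foraged[px, py] or resources[px, py] < need:
                continue
            if seen == target:
                x[i] = px
                y[i] = py
                if adult:
                    score[i] += adult_yield
                    resources[px, py] = 0
                    foraged[px, py] = True
                    total += adult_yield
                else:
                    score[i] += child_yield
                    resources[px, py] -= child_yield
                    if resources[px, py] < child_yield:
                        foraged[px, py] = True
                    total += child_yield
                break
            seen += 1
    return total


@njit(cache=True)
def care_kernel(
    order,        # int64[cap] permutation of slots (carer processing order)
    u,            # float64[cap] one uniform per slot (recipient choice)
    alive,        # bool[cap]
    infected,     # bool[cap]
    cared_for,    # bool[cap] (mutated)
    score,        # int64[cap] (mutated when intensity > 0)
    agent_id,     # int64[cap] unique ids
    parent_id,    # int64[cap] id of parent, -1 if none
    intensity,    # resource points transferred per care event
):
    """Kin-directed care: each agent may nurse one infected parent/offspring.

    Carers are processed in ``order``; a carer with enough resources (when
    intensity > 0) picks uniformly at random one infected relative not yet
    cared for this step, transfers ``intensity`` points, and marks the
    recipient cared-for (which also shields them from extrinsic mortality
    for the rest of the step).  Returns (care events, points transferred).
    """
    events = 0
    transferred = 0
    cap = order.shape[0]
    for k in range(cap):
        i = order[k]
        if not alive[i]:
            continue
        if intensity > 0 and score[i] < intensity:
            continue
        pid = parent_id[i]
        aid = agent_id[i]
        count = 0
        for j in range(cap):
            if not alive[j] or not infected[j] or cared_for[j] or j == i:
                continue
            if (pid >= 0 and agent_id[j] == pid) or parent_id[j] == aid:
                count += 1
        if count == 0:
            continue
        target = int(u[i] * count)
        if target >= count:
            target = count - 1
        seen = 0
        for j in range(cap):
            if not alive[j] or not infected[j] or cared_for[j] or j == i:
                continue
            if (pid >= 0 and agent_id[j] == pid) or parent_id[j] == aid:
                if seen == target:
                    if intensity > 0:
                        score[i] -= intensity
                        score[j] += intensity
                        transferred += intensity
                    cared_for[j] = True
                    events += 1
                    break
                seen += 1
    return events, transferred
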