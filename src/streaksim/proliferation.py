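"""Stochastic cell growth and division.

With growth on, every cell's target volume starts uniform on [30, 70]
voxels and increases by one voxel every 20 MCS; when a cell's actual volume
reaches 100 voxels it divides along a randomly oriented line through its
center of mass, both daughters getting fresh ids and target volume 50.
Division is deliberately unoriented and spatially uniform.
"""

from __future__ import annotations

import numpy as np

from .core import TissueState

GROWTH_PERIOD = 20
DIVISION_VOLUME = 100
DAUGHTER_TARGET = 50


def init_growth(state: TissueState, rng=None,
                low: int = 30, high: int = 70) -> None:
    """Assign initial target volumes uniformly on [low, high] (inclusive)."""
    rng = rng if rng is not None else state.rng
    live = state.live_cells()
    state.tvol[live] = rng.integers(low, high + 1, size=live.size)


def grow_cells(state: TissueState, every: int = GROWTH_PERIOD) -> bool:
    """Increment every live cell's target volume by one voxel each ``every``
    MCS (keyed off ``state.step``).  Returns True when growth fired."""
    if state.step == 0 or state.step % every != 0:
        return False
    live = state.live_cells()
    state.tvol[live] += 1
    return True


def divide_cell(state: TissueState, cid: int, rng=None,
                max_tries: int = 10):
    """Split one cell along a random line through its centroid.

    Voxels are partitioned by the sign of their projection on the line's
    normal; both daughters keep the parent's type and polarization, get
    fresh ids and target volume 50, and the lineage event is logged as
    (step, parent, d1, d2).  A degenerate orientation (one empty side) is
    resampled up to ``max_tries`` times, after which the division is
    skipped.  Returns (d1, d2, angle) or None if skipped.
    """
    rng = rng if rng is not None else state.rng
    coords = np.argwhere(state.owner == cid)
    if coords.shape[0] < 2:
        return None
    centroid = np.array([state.sumx[cid], state.sumy[cid]]) / state.vol[cid]
    for _ in range(max_tries):
        angle = float(rng.uniform(0.0, np.pi))
        normal = np.array([np.cos(angle), np.sin(angle)])
        side = (coords - centroid) @ normal > 0.0
        if side.any() and not side.all():
            break
    else:
        return None
    d1 = state.new_cell_id(int(state.ctype[cid]), DAUGHTER_TARGET, parent=cid)
    d2 = state.new_cell_id(int(state.ctype[cid]), DAUGHTER_TARGET, parent=cid)
    for did, mask in ((d1, ~side), (d2, side)):
        vx = coords[mask]
        state.owner[vx[:, 0], vx[:, 1]] = did
        state.vol[did] = vx.shape[0]
        state.sumx[did] = vx[:, 0].sum()
        state.sumy[did] = vx[:, 1].sum()
        state.pol[did] = state.pol[cid]
    state.vol[cid] = 0
    state.sumx[cid] = 0.0
    state.sumy[cid] = 0.0
    state.lineage.append((state.step, int(cid), int(d1), int(d2)))
    return d1, d2, angle


def divide_ready_cells(state: TissueState, rng=None,
                       volume_threshold: int = DIVISION_VOLUME) -> list:
    """Divide every cell whose volume has reached the threshold (checked
    once per MCS, after the flips).  Returns the lineage events fired."""
    rng = rng if rng is not None else state.rng
    events = []
    ready = [int(c) for c in state.live_cells()
             if state.vol[c] >= volume_threshold]
    for cid in ready:
        out = divide_cell(state, cid, rng=rng)
        if out is not None:
            events.append((state.step, cid, out[0], out[1]))
    return events
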