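"""Quantitative readouts: tracks, velocity fields, vorticity, streak shape.

The substrate of all flow metrics is the track table, one row per live cell
per sampling step with its centroid (in the embryo frame) and polarization.
Velocities are centroid shifts over a time window; the gridded velocity
field bin-averages them, and the vorticity w = dv_y/dx - dv_x/dy (negative
clockwise, positive counter-clockwise) is measured by central differences
on the binned field.  Streak geometry, the vortex-area classifier and the
two-streak interaction classifier condense runs into the qualitative
outcome categories used to discriminate mechanisms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import S, ST, TissueState

TRACK_COLUMNS = ("step", "id", "type", "x", "y", "Px", "Py")

#: physical calibration: one voxel is ~10 um, one MCS ~3 s
VOXEL_UM = 10.0
STEP_S = 3.0


def track_rows(state: TissueState) -> list[tuple]:
    """One (step, id, type, x, y, Px, Py) row per live cell; x is the
    column coordinate, y the row (increasing anteriorly)."""
    cent = state.centroids()
    rows = []
    for cid in state.live_cells():
        rows.append((state.step, int(cid), int(state.ctype[cid]),
                     float(cent[cid, 1]), float(cent[cid, 0]),
                     float(state.pol[cid, 1]), float(state.pol[cid, 0])))
    return rows


def make_track_table(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    return df.astype({"step": int, "id": int, "type": int})


@dataclass
class VelocityField:
    """Bin-averaged cell velocities; empty bins are NaN, not zero.

    ``mx``/``my`` hold the mean position of the cells contributing to each
    bin (NaN when empty), which is the point the bin velocity is really
    attached to."""

    vx: np.ndarray
    vy: np.ndarray
    counts: np.ndarray
    bin_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    mx: np.ndarray | None = None
    my: np.ndarray | None = None

    def bin_centers(self):
        ny, nx = self.vx.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.bin_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.bin_size
        return xs, ys


def _nearest_step(tracks: pd.DataFrame, t: float) -> int:
    steps = tracks["step"].unique()
    return int(steps[np.argmin(np.abs(steps - t))])


def velocity_field(tracks: pd.DataFrame, t0: float, t1: float,
                   bin_size: float = 10.0,
                   extent: tuple | None = None) -> VelocityField:
    """Bin-averaged velocity field over the window [t0, t1].

    Per-cell velocity is (centroid(t1) - centroid(t0)) / (t1 - t0) using the
    nearest sampled steps; cells are binned by their mean position.  Raises
    on an empty window.
    """
    if not t1 > t0:
        raise ValueError("need t1 > t0")
    s0, s1 = _nearest_step(tracks, t0), _nearest_step(tracks, t1)
    if s0 == s1:
        raise ValueError("window contains no displacement interval")
    a = tracks[tracks.step == s0].set_index("id")
    b = tracks[tracks.step == s1].set_index("id")
    common = a.index.intersection(b.index)
    if common.empty:
        raise ValueError("no cells present at both window ends")
    dt = float(s1 - s0)
    vx = (b.loc[common, "x"] - a.loc[common, "x"]).to_numpy() / dt
    vy = (b.loc[common, "y"] - a.loc[common, "y"]).to_numpy() / dt
    mx = 0.5 * (a.loc[common, "x"] + b.loc[common, "x"]).to_numpy()
    my = 0.5 * (a.loc[common, "y"] + b.loc[common, "y"]).to_numpy()
    if extent is None:
        x0, y0 = 0.0, 0.0
        x1 = mx.max() + bin_size
        y1 = my.max() + bin_size
    else:
        (x0, x1), (y0, y1) = extent
    nx = max(1, int(np.ceil((x1 - x0) / bin_size)))
    ny = max(1, int(np.ceil((y1 - y0) / bin_size)))
    ix = np.clip(((mx - x0) / bin_size).astype(int), 0, nx - 1)
    iy = np.clip(((my - y0) / bin_size).astype(int), 0, ny - 1)
    flat = iy * nx + ix
    counts = np.bincount(flat, minlength=ny * nx).reshape(ny, nx)
    sx = np.bincount(flat, weights=vx, minlength=ny * nx).reshape(ny, nx)
    sy = np.bincount(flat, weights=vy, minlength=ny * nx).reshape(ny, nx)
    smx = np.bincount(flat, weights=mx, minlength=ny * nx).reshape(ny, nx)
    smy = np.bincount(flat, weights=my, minlength=ny * nx).reshape(ny, nx)
    with np.errstate(invalid="ignore"):
        gx = np.where(counts > 0, sx / np.maximum(counts, 1), np.nan)
        gy = np.where(counts > 0, sy / np.maximum(counts, 1), np.nan)
        gmx = np.where(counts > 0, smx / np.maximum(counts, 1), np.nan)
        gmy = np.where(counts > 0, smy / np.maximum(counts, 1), np.nan)
    return VelocityField(vx=gx, vy=gy, counts=counts, bin_size=bin_size,
                         origin=(x0, y0), mx=gmx, my=gmy)


def vorticity_grid(vfield: VelocityField) -> np.ndarray:
    """w = dv_y/dx - dv_x/dy by central differences on the binned field.

    Bins lacking a populated neighbor pair in either direction come out NaN.
    """
    h = vfield.bin_size
    vy, vx = vfield.vy, vfield.vx
    dvy_dx = np.full_like(vy, np.nan)
    dvx_dy = np.full_like(vx, np.nan)
    dvy_dx[:, 1:-1] = (vy[:, 2:] - vy[:, :-2]) / (2 * h)
    dvx_dy[1:-1, :] = (vx[2:, :] - vx[:-2, :]) / (2 * h)
    return dvy_dx - dvx_dy


def vorticity_profile(vfield: VelocityField, y: float) -> np.ndarray:
    """Vorticity along the horizontal transect nearest ``y`` (lattice units).

    Returns an (n, 2) array of (x position, w); NaN where the field is not
    populated.  Raises if the transect misses the populated field entirely.
    """
    omega = vorticity_grid(vfield)
    xs, ys = vfield.bin_centers()
    row = int(np.argmin(np.abs(ys - y)))
    if np.all(np.isnan(omega[row])):
        raise ValueError("transect crosses no populated velocity bins")
    return np.column_stack([xs, omega[row]])


def streak_geometry(state: TissueState) -> dict:
    """Principal-axis aspect ratio and tip topology of the S+ST region.

    aspect_ratio: ratio of the principal-axis lengths of the voxel set,
    from the second moments of the region (the regionprops major/minor-axis
    convention, 4 sigma along each principal axis; exactly long/short side
    for a solid rectangle).  aspect_ratio_extent: the same ratio from the
    full projected extents (max - min + 1), more sensitive to outlying
    voxels.  tip_attached: some ST voxel touches an S voxel (Moore
    adjacency).  tip_split: the ST voxel set has more than one connected
    component.
    """
    meso = state.type_mask("S", "ST")
    if not meso.any():
        raise ValueError("no mesoderm (S or ST) cells")
    coords = np.argwhere(meso).astype(float)
    centered = coords - coords.mean(axis=0)
    cov = np.cov(centered.T, bias=True) + np.eye(2) / 12.0  # voxel's own extent
    evals, vecs = np.linalg.eigh(cov)
    aspect = float(np.sqrt(evals.max() / evals.min()))
    proj = centered @ vecs
    extents = proj.max(axis=0) - proj.min(axis=0) + 1.0
    aspect_extent = float(extents.max() / extents.min())

    st_mask = state.type_mask("ST")
    s_mask = state.type_mask("S")
    eight = np.ones((3, 3), dtype=bool)
    if st_mask.any():
        grown = ndimage.binary_dilation(st_mask, structure=eight)
        tip_attached = bool((grown & s_mask).any())
        _, n_comp = ndimage.label(st_mask, structure=eight)
        tip_split = bool(n_comp > 1)
    else:
        tip_attached = False
        tip_split = False
    return {"aspect_ratio": aspect, "aspect_ratio_extent": aspect_extent,
            "tip_attached": tip_attached, "tip_split": tip_split}


def vortex_strength(vfield: VelocityField, ap_mask: np.ndarray,
                    threshold_frac: float = 0.2,
                    min_peak: float = 0.0) -> dict:
    """Fraction of AP-area bins with |w| above a fraction of the maximum.

    The classifier maps the fraction onto the vortex grades: below 0.10
    "None", 0.10-0.25 "Weak", above 0.25 "Strong".  Because the 20%-of-max
    rule is scale-free, a field dominated by fluctuation noise can still
    grade high; ``min_peak`` (units 1/step) sets an absolute vorticity
    floor below which the field counts as vortex-free.  The mean |w| over
    the AP is reported alongside for magnitude comparisons.
    """
    omega = vorticity_grid(vfield)
    xs, ys = vfield.bin_centers()
    H, W = ap_mask.shape
    jj = np.clip(np.round(xs).astype(int), 0, W - 1)
    ii = np.clip(np.round(ys).astype(int), 0, H - 1)
    in_ap = ap_mask[np.ix_(ii, jj)]
    vals = omega[in_ap]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0 or not np.isfinite(omega).any():
        return {"fraction": 0.0, "grade": "None", "mean_abs": 0.0}
    peak = np.nanmax(np.abs(omega))
    mean_abs = float(np.abs(vals).mean())
    if peak == 0 or peak < min_peak:
        return {"fraction": 0.0, "grade": "None", "mean_abs": mean_abs}
    frac = float((np.abs(vals) > threshold_frac * peak).mean())
    grade = "None" if frac < 0.10 else ("Weak" if frac <= 0.25 else "Strong")
    return {"fraction": frac, "grade": grade, "mean_abs": mean_abs}


def classify_two_streak_interaction(tips_a: np.ndarray, tips_b: np.ndarray,
                                    center, merged: bool | None = None,
                                    merge_distance: float = 10.0,
                                    tolerance: float = 0.10) -> str:
    """Classify a double-streak run as repel, attract/fuse or
    none-until-contact.

    ``tips_a``/``tips_b`` are (T, 2) arrays of the two ST-group centroids
    over time (x, y); ``center`` is the embryo center.  The straight-
    extension null advances each tip from its initial position toward the
    center at its observed mean path speed; the observed tip-tip distance
    trajectory is compared with the null's.  Sustained excess separation
    means repulsion; closing faster than the null plus merging means
    attraction; merging while tracking the null means the streaks only
    interact on contact.  A dissolved tip (NaN positions) is unclassifiable.
    """
    a = np.asarray(tips_a, dtype=float)
    b = np.asarray(tips_b, dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("a streak tip dissolved; interaction unclassifiable")
    if len(a) < 3 or len(a) != len(b):
        raise ValueError("need equal-length tip tracks with >= 3 samples")
    center = np.asarray(center, dtype=float)
    T = len(a)
    d_obs = np.linalg.norm(a - b, axis=1)
    if merged is None:
        merged = bool(d_obs[-1] < merge_distance)
    # truncate at merge to keep the comparison pre-contact
    end = int(np.argmax(d_obs < merge_distance)) or T - 1
    if not (d_obs < merge_distance).any():
        end = T - 1
    # null speed: center-ward component of the net displacement -- the
    # straight-extension rate along the radial streak axis.  (Path length
    # overestimates it through diffusive wiggle; the full net speed
    # overestimates it when the tips deflect sideways.)
    speeds = []
    for p in (a, b):
        u = center - p[0]
        n = np.linalg.norm(u)
        u = u / n if n > 0 else u
        speeds.append(max(0.0, float((p[-1] - p[0]) @ u)) / (T - 1))
    d_null = np.empty(T)
    for t in range(T):
        pts = []
        for p, v in zip((a, b), speeds):
            u = center - p[0]
            dist = np.linalg.norm(u)
            u = u / dist if dist > 0 else u
            pts.append(p[0] + u * min(v * t, dist))
        d_null[t] = np.linalg.norm(pts[0] - pts[1])
    d0 = max(d_obs[0], 1e-9)
    excess = np.mean(d_obs[1:end + 1] - d_null[1:end + 1]) / d0
    if not merged and (excess > tolerance
                       or d_obs[-1] > (1 + 1.5 * tolerance) * d0):
        return "repel"
    if merged and excess < -tolerance:
        return "attract/fuse"
    if merged:
        return "none-until-contact"
    return "repel" if excess > tolerance else "none-until-contact"


def classify_table_row(initial_extent_x: float, final_extent_x: float,
                       geometry: dict, vortex: dict) -> dict:
    """Condense one run into the qualitative outcome categories.

    accretes: the mesoderm's lateral extent shrank to under 60% of the
    initial sickle's (the wings pulled in to the midline).  streak_quality:
    "Good" for an attached, unsplit streak with aspect ratio in the 5-12
    band; "Poor" for a connected but short/broad/split streak (aspect >= 2);
    "None" otherwise.  vortices: the vortex-strength grade.
    """
    accretes = final_extent_x < 0.6 * initial_extent_x
    ar = geometry["aspect_ratio"]
    if (geometry["tip_attached"] and not geometry["tip_split"]
            and 5.0 <= ar <= 12.0):
        quality = "Good"
    elif ar >= 2.0:
        quality = "Poor"
    else:
        quality = "None"
    return {"accretes": bool(accretes), "streak_quality": quality,
            "vortices": vortex.get("grade", "None"),
            "aspect_ratio": ar}


def mesoderm_extent_x(state: TissueState) -> float:
    cols = np.where(state.type_mask("S", "ST").any(axis=0))[0]
    return float(cols.max() - cols.min() + 1) if cols.size else 0.0


_UNIT_FACTORS = {
    "length": lambda vox, sec: vox,                      # voxel -> um
    "time": lambda vox, sec: sec,                        # step -> s
    "velocity": lambda vox, sec: vox / sec * 60.0,       # voxel/step -> um/min
    "vorticity": lambda vox, sec: 60.0 / sec,            # 1/step -> 1/min
    "diffusivity": lambda vox, sec: (vox * 1e-4) ** 2 / sec,  # -> cm^2/s
}


def convert_units(quantity: float, kind: str, inverse: bool = False,
                  voxel_um: float = VOXEL_UM, step_s: float = STEP_S) -> float:
    """Convert between simulation units (voxel, step) and physical units.

    Kinds: length (voxel -> um), time (step -> s), velocity (voxel/step ->
    um/min), vorticity (1/step -> 1/min), diffusivity (voxel^2/step ->
    cm^2/s).  ``inverse=True`` converts back; the round trip is exact.
    """
    if kind not in _UNIT_FACTORS:
        raise ValueError(f"unknown unit kind {kind!r}")
    f = _UNIT_FACTORS[kind](voxel_um, step_s)
    return float(quantity / f) if inverse else float(quantity * f)
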