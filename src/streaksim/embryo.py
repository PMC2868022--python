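"""Initial conditions and differentiation events.

Builds the disk embryo (AP interior, AO ring), induces the sickle-shaped
mesendoderm at the posterior AO/AP border, selects the streak-tip (ST)
subgroup, constructs the two-streak configuration, and provides the
mechanism presets M1-M4/M2b that assign which type secretes the chemotactic
agent, which responds and with what coefficient, and the adhesion-table
overrides of the streak hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.spatial import cKDTree

from .core import (AO, AP, S, ST, AdhesionTable, EnergyModel, SimParams,
                   SizingError, TissueState, run_mcs)
from .fields import ScalarField
from .guidance import ChemoResponse

# Streak adhesion hierarchy: mesoderm coheres strongly (J(S,S)=J(ST,ST)=2),
# tip binds streak at intermediate strength (J(S,ST)=4); the repulsion /
# S-attraction mechanisms additionally weaken tip-AO contact (J(ST,AO)=9)
# so the tip detaches from the ring and moves anteriorly.
_STREAK_OVERRIDES = {("S", "S"): 2.0, ("ST", "ST"): 2.0, ("S", "ST"): 4.0}
_TIP_AO_OVERRIDE = {("ST", "AO"): 9.0}


@dataclass
class MechanismConfig:
    """One streak-extension hypothesis: who secretes, who responds, how."""

    name: str
    secreting_type: str
    responses: list[ChemoResponse]
    adhesion_overrides: dict = dc_field(default_factory=dict)
    polarization_on: bool = True
    growth_on: bool = False
    field_params: dict = dc_field(default_factory=dict)
    # "calibrated": scale the source so the equilibrated field reaches the
    # scenario's peak target -- needed when a small mesoderm group must
    # read a gradient sourced by another small group (M3, M4).  "printed":
    # keep the nominal production rate -- M2/M2b drive most of the
    # epiblast, which integrates plenty of drive (a calibrated amplitude
    # tears the tissue), and M1's AP-wide source saturates on its own.
    amplitude_mode: str = "printed"
    # multiplier on the scenario's calibrated peak target; M4's chasing S
    # crowd needs a gentler field than M3's fleeing tip
    amplitude_factor: float = 1.0

    def make_field(self, shape) -> ScalarField:
        kw = dict(D=1.0, k1=1.5e-3, k2=1.0e-3)
        kw.update(self.field_params)
        return ScalarField.zeros(shape, producer_type=self.secreting_type,
                                 name=f"agent_{self.name}", **kw)

    def adhesion_table(self, base: AdhesionTable | None = None) -> AdhesionTable:
        base = base if base is not None else AdhesionTable.default()
        return base.with_overrides(self.adhesion_overrides)


_PRESETS = {
    "M1": ("AP", [("ST", 80.0)], dict(_STREAK_OVERRIDES)),
    "M2": ("ST", [("AP", -60.0)], dict(_STREAK_OVERRIDES)),
    "M2b": ("ST", [("AP", -60.0), ("AO", -15.0)], dict(_STREAK_OVERRIDES)),
    "M3": ("S", [("ST", -40.0)], {**_STREAK_OVERRIDES, **_TIP_AO_OVERRIDE}),
    "M4": ("ST", [("S", 40.0)], {**_STREAK_OVERRIDES, **_TIP_AO_OVERRIDE}),
}


def configure_mechanism(name: str, polarization_on: bool = True,
                        growth_on: bool = False) -> MechanismConfig:
    """Preset for mechanism M1, M2, M2b, M3 or M4.

    M1: AP secretes an attractant for ST (beta=+80).  M2: ST secretes a
    repellent for AP (beta=-60); M2b additionally repels AO (beta=-15).
    M3: S secretes a repellent for ST (beta=-40).  M4: ST secretes an
    attractant for S (beta=+40).
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown mechanism {name!r}; choose from {sorted(_PRESETS)}")
    secreting, resp, overrides = _PRESETS[name]
    field_name = f"agent_{name}"
    responses = [ChemoResponse(t, field_name, b) for t, b in resp]
    return MechanismConfig(name=name, secreting_type=secreting,
                           responses=responses,
                           adhesion_overrides=dict(overrides),
                           polarization_on=polarization_on,
                           growth_on=growth_on,
                           amplitude_mode="calibrated" if name in ("M3", "M4")
                           else "printed",
                           amplitude_factor=0.5 if name == "M4" else 1.0)


def mechanism_names() -> tuple[str, ...]:
    return tuple(_PRESETS)


# -- embryo construction ----------------------------------------------------


def build_disk_embryo(n_cells: int = 625, ap_radius: float = 77.0,
                      target_volume: int = 50,
                      lattice_shape: tuple[int, int] | None = None,
                      margin: int = 25, relax_mcs: int = 100,
                      params: SimParams | None = None,
                      rng=None) -> TissueState:
    """Disk embryo of ~``n_cells`` cells with an AO ring around an AP core.

    Voronoi-like seeding (two Lloyd iterations of nearest-seed assignment)
    tiles a disk of area n_cells * target_volume with roughly equal cells;
    a short Metropolis relaxation under adhesion + volume constraint rounds
    them.  Cells whose centroid lies within ``ap_radius`` of the center are
    then typed AP, the remainder AO (a ring about three cells wide at the
    defaults).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    params = params if params is not None else SimParams()
    R = float(np.sqrt(n_cells * target_volume / np.pi))
    if ap_radius >= R:
        raise SizingError("ap_radius must be smaller than the disk radius")
    if lattice_shape is None:
        side = int(np.ceil(2 * (R + margin)))
        lattice_shape = (side, side)
    H, W = lattice_shape
    if min(H, W) < 2 * R + 4:
        raise SizingError(f"lattice {lattice_shape} too small for disk radius {R:.1f}")
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0

    yy, xx = np.indices((H, W))
    rr = np.hypot(yy - cy, xx - cx)
    disk = rr <= R
    voxels = np.column_stack(np.nonzero(disk)).astype(float)

    # rejection-sample seeds in the disk, then Lloyd steps for even volumes
    seeds = []
    while len(seeds) < n_cells:
        pts = rng.uniform(-R, R, size=(2 * n_cells, 2))
        pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= R - 1.0]
        seeds.extend(pts.tolist())
    seeds = np.array(seeds[:n_cells]) + (cy, cx)
    for _ in range(2):
        _, assign = cKDTree(seeds).query(voxels)
        for k in range(n_cells):
            m = assign == k
            if m.any():
                seeds[k] = voxels[m].mean(axis=0)
    _, assign = cKDTree(seeds).query(voxels)

    owner = np.zeros((H, W), dtype=np.int32)
    owner[disk] = assign + 1
    ctype = np.concatenate([[0], np.full(n_cells, AP)])
    tvol = np.concatenate([[0], np.full(n_cells, target_volume)])
    state = TissueState(owner, ctype, tvol=tvol, params=params, rng=rng)

    energy = EnergyModel(adhesion=AdhesionTable.default(), alpha=params.alpha)
    for _ in range(relax_mcs):
        run_mcs(state, energy)
    state.step = 0
    state.recompute_geometry()

    cent = state.centroids()
    radii = np.hypot(cent[:, 0] - cy, cent[:, 1] - cx)
    for cid in state.live_cells():
        state.ctype[cid] = AP if radii[cid] <= ap_radius else AO
    return state


def differentiate_mesoderm(state: TissueState, induction: ScalarField,
                           threshold: float = 0.7) -> int:
    """Retype AP cells as mesoderm (S) where the induction morphogen at the
    cell centroid exceeds the threshold.  Returns the number converted."""
    cent = state.centroids()
    n = 0
    H, W = state.shape
    for cid in state.live_cells():
        if state.ctype[cid] != AP:
            continue
        i = min(max(int(round(cent[cid, 0])), 0), H - 1)
        j = min(max(int(round(cent[cid, 1])), 0), W - 1)
        if induction.values[i, j] > threshold:
            state.ctype[cid] = S
            n += 1
    return n


def _posterior_angles(state: TissueState, ids) -> np.ndarray:
    """Signed angle of each cell about the embryo center, measured from the
    posterior axis (decreasing row)."""
    com = state.center_of_mass()
    cent = state.centroids()[ids]
    return np.arctan2(cent[:, 1] - com[1], -(cent[:, 0] - com[0]))


def select_tip_cells(state: TissueState, fraction: float = 0.25,
                     inner_edge: bool = True) -> int:
    """Retype the central angular window of the sickle as streak-tip (ST).

    ``fraction`` is the retained share of the sickle's angular extent,
    centered on its angular median.  With ``inner_edge`` (default) only the
    anterior (inner-radius) half of that window is retyped, placing the tip
    group on the sickle's inner edge with S behind and beside it; the
    defaults keep the tip group at roughly 10-15% of the sickle cells.
    Returns the number of ST cells.
    """
    ids = state.live_cells()
    s_ids = ids[state.ctype[ids] == S]
    if s_ids.size == 0:
        raise ValueError("no S cells to select a tip from")
    if fraction <= 0:
        return 0
    phi = _posterior_angles(state, s_ids)
    center = 0.5 * (phi.max() + phi.min())
    half = 0.5 * fraction * (phi.max() - phi.min())
    chosen = s_ids[np.abs(phi - center) <= half]
    if inner_edge and chosen.size > 1:
        com = state.center_of_mass()
        cent = state.centroids()[chosen]
        radii = np.hypot(cent[:, 0] - com[0], cent[:, 1] - com[1])
        chosen = chosen[radii <= np.median(radii)]
    state.ctype[chosen] = ST
    return int(chosen.size)


def _mark_sickle(state: TissueState, phi0: float, half_width: float,
                 depth: float, ap_radius: float, tip_fraction: float) -> tuple:
    """Type one synthetic sickle fragment (S with a central ST group)."""
    com = state.center_of_mass()
    cent = state.centroids()
    ids = state.live_cells()
    radii = np.hypot(cent[ids, 0] - com[0], cent[ids, 1] - com[1])
    phi = _posterior_angles(state, ids)
    dphi = np.angle(np.exp(1j * (phi - phi0)))
    band = ((state.ctype[ids] == AP) & (radii > ap_radius - depth)
            & (radii <= ap_radius) & (np.abs(dphi) <= half_width))
    s_ids = ids[band]
    state.ctype[s_ids] = S
    tip = s_ids[np.abs(dphi[band]) <= tip_fraction * half_width]
    state.ctype[tip] = ST
    return s_ids, tip


def build_double_streak(state: TissueState, ap_radius: float = 77.0,
                        separation_deg: float = 90.0,
                        half_width_deg: float = 40.0,
                        depth: float | None = None,
                        tip_fraction: float = 0.2) -> dict:
    """Two sickle fragments (posterior and lateral), each with its own
    central ST group, ~``separation_deg`` apart on the AP border.

    Returns a dict with the per-group S and ST ids and the initial tip-tip
    centroid distance.
    """
    if depth is None:
        depth = 0.29 * ap_radius       # ~3 cell diameters at full scale
    hw = np.deg2rad(half_width_deg)
    sep = np.deg2rad(separation_deg)
    s1, tip1 = _mark_sickle(state, 0.0, hw, depth, ap_radius, tip_fraction)
    s2, tip2 = _mark_sickle(state, sep, hw, depth, ap_radius, tip_fraction)
    cent = state.centroids()
    d = float(np.linalg.norm(cent[tip1].mean(axis=0) - cent[tip2].mean(axis=0)))
    return {"s_groups": (s1, s2), "tip_groups": (tip1, tip2),
            "tip_distance": d}
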