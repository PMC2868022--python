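"""Lattice state and Metropolis dynamics of the multicell Potts (GGH) model.

A tissue is a 2D integer lattice in which each voxel stores the id of the
cell occupying it (0 = medium/substrate); a cell is the contiguous patch of
voxels sharing one id.  Cells carry a type (AP, AO, S or ST), a volume and a
target volume, a centroid and a polarization vector.  The tissue evolves by
voxel-copy attempts: a random source voxel tries to copy its owner onto a
random lattice neighbor, and the proposal is accepted with the Boltzmann
criterion

    P(accept) = 1                 if dE <= 0
    P(accept) = exp(-dE / T)      if dE > 0

where ``dE`` sums the active effective-energy terms (adhesion, volume
constraint, and the directed-motility terms from :mod:`streaksim.guidance`)
and the temperature ``T`` models intrinsic cytoskeletal motility.  One Monte
Carlo step (MCS) performs as many attempts as there are lattice sites.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._kernels import DX4, DX8, DY4, DY8

CELL_TYPE_NAMES = ("medium", "AP", "AO", "S", "ST")
MEDIUM, AP, AO, S, ST = range(5)
TYPE_CODES = {name: code for code, name in enumerate(CELL_TYPE_NAMES)}
N_TYPES = len(CELL_TYPE_NAMES)


class SizingError(ValueError):
    """Lattice too small for the requested operation."""


class OutOfBoundsError(IndexError):
    """Voxel coordinate outside the lattice."""


def _type_code(t) -> int:
    if isinstance(t, str):
        return TYPE_CODES[t]
    code = int(t)
    if not 0 <= code < N_TYPES:
        raise ValueError(f"unknown cell type {t!r}")
    return code


class AdhesionTable:
    """Symmetric contact-energy table J(type_a, type_b), addressed by name.

    Lower J means stronger adhesion.  The default hierarchy is the one used
    throughout the simulations: J = 3 between cells of the same type, 7
    between cells of different types, 9 against the medium/substrate, so that
    cells cohere into a tissue (J(cell, medium) > 2 J(cell, cell) keeps the
    aggregate compact) and like types stay sorted.
    """

    def __init__(self, matrix: np.ndarray | None = None):
        if matrix is None:
            matrix = np.zeros((N_TYPES, N_TYPES))
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (N_TYPES, N_TYPES):
            raise ValueError("adhesion matrix must be 5x5")
        if not np.allclose(matrix, matrix.T):
            raise ValueError("adhesion matrix must be symmetric")
        if not np.all(np.isfinite(matrix)):
            raise ValueError("adhesion energies must be finite")
        self._J = matrix

    @classmethod
    def default(cls, same: float = 3.0, different: float = 7.0,
                medium: float = 9.0) -> "AdhesionTable":
        J = np.full((N_TYPES, N_TYPES), different)
        np.fill_diagonal(J, same)
        J[0, :] = medium
        J[:, 0] = medium
        J[0, 0] = 0.0
        return cls(J)

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self._J[_type_code(a), _type_code(b)])

    def set(self, a, b, value: float) -> None:
        if not np.isfinite(value):
            raise ValueError("adhesion energy must be finite")
        ia, ib = _type_code(a), _type_code(b)
        self._J[ia, ib] = value
        self._J[ib, ia] = value

    def with_overrides(self, overrides: dict) -> "AdhesionTable":
        """Copy with entries replaced; keys are (name, name) pairs."""
        out = AdhesionTable(self._J.copy())
        for (a, b), v in overrides.items():
            out.set(a, b, v)
        return out

    @property
    def matrix(self) -> np.ndarray:
        return self._J.copy()

    def copy(self) -> "AdhesionTable":
        return AdhesionTable(self._J.copy())


@dataclass
class SimParams:
    """Global Metropolis parameters.

    temperature
        Intrinsic motility T of the Boltzmann criterion (energy units).
    alpha
        Cell compressibility: weight of the quadratic volume constraint
        (energy / voxel^2).
    contact_neighborhood
        Neighborhood used for adhesion contacts; the 8-connected Moore
        neighborhood reduces lattice anisotropy.
    proposal_neighborhood
        Neighborhood from which copy targets are drawn.
    flips_per_mcs
        Copy attempts per MCS; ``None`` means one per lattice site.
    recenter_every
        Period (in MCS) of the rigid recentering that pins the embryo's
        center of mass to the lattice center.
    """

    temperature: float = 6.0
    alpha: float = 0.6
    contact_neighborhood: str = "moore"
    proposal_neighborhood: str = "von_neumann"
    flips_per_mcs: int | None = None
    recenter_every: int = 50

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.contact_neighborhood not in ("moore", "von_neumann"):
            raise ValueError("contact_neighborhood must be 'moore' or 'von_neumann'")
        if self.proposal_neighborhood not in ("moore", "von_neumann"):
            raise ValueError("proposal_neighborhood must be 'moore' or 'von_neumann'")

    def contact_offsets(self):
        if self.contact_neighborhood == "moore":
            return DX8, DY8
        return DX4, DY4

    @property
    def n_proposal_dirs(self) -> int:
        return 8 if self.proposal_neighborhood == "moore" else 4


@dataclass
class EnergyModel:
    """The effective-energy terms active during a run.

    ``chemo`` is a list of ``(concentration_grid, beta_by_type)`` pairs where
    ``beta_by_type`` is a length-5 array of chemotactic coefficients
    (positive = attraction); haptotaxis enters as one more entry on the ECM
    field.  ``lambda_p`` switches on the polarization alignment term.
    """

    adhesion: AdhesionTable = field(default_factory=AdhesionTable.default)
    alpha: float = 0.6
    chemo: list = field(default_factory=list)
    lambda_p: float = 0.0

    def pack(self, shape):
        J = np.ascontiguousarray(self.adhesion.matrix)
        if self.chemo:
            fields = np.stack([np.asarray(u, dtype=float) for u, _ in self.chemo])
            beta = np.stack([np.asarray(b, dtype=float) for _, b in self.chemo])
        else:
            fields = np.zeros((0,) + tuple(shape))
            beta = np.zeros((0, N_TYPES))
        return J, fields, beta


class TissueState:
    """Owner lattice plus per-cell bookkeeping arrays.

    Cell attributes are stored id-indexed in flat arrays (index 0 is the
    medium pseudo-cell): ``ctype``, ``vol``, ``tvol``, centroid coordinate
    sums ``sumx``/``sumy`` (row/col), polarization ``pol`` and ``parent``.
    Volumes and centroid sums are maintained incrementally by the sweep and
    recomputed exactly at every recentering to bound drift.
    """

    def __init__(self, owner: np.ndarray, ctype: np.ndarray,
                 tvol: np.ndarray | None = None,
                 params: SimParams | None = None,
                 rng: np.random.Generator | int | None = None):
        owner = np.ascontiguousarray(owner, dtype=np.int32)
        if owner.ndim != 2:
            raise ValueError("owner grid must be 2D")
        self.owner = owner
        n_ids = max(int(owner.max()) + 1, len(ctype))
        cap = max(n_ids, 8)
        self.ctype = np.zeros(cap, dtype=np.int64)
        self.ctype[: len(ctype)] = [_type_code(t) for t in ctype]
        self.vol = np.zeros(cap, dtype=np.int64)
        self.tvol = np.zeros(cap, dtype=np.int64)
        if tvol is not None:
            self.tvol[: len(tvol)] = tvol
        self.sumx = np.zeros(cap, dtype=np.float64)
        self.sumy = np.zeros(cap, dtype=np.float64)
        self.pol = np.zeros((cap, 2), dtype=np.float64)
        self.parent = np.full(cap, -1, dtype=np.int64)
        self.n_ids = n_ids
        self.step = 0
        self.cum_shift = np.zeros(2, dtype=np.int64)
        self.lineage: list[tuple[int, int, int, int]] = []
        self.params = params if params is not None else SimParams()
        if isinstance(rng, np.random.Generator):
            self.rng = rng
        else:
            self.rng = np.random.default_rng(rng)
        self.recompute_geometry()

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self):
        return self.owner.shape

    def recompute_geometry(self) -> None:
        """Exact volumes and centroid sums from the owner grid."""
        n = self.n_ids
        flat = self.owner.ravel()
        self.vol[:n] = np.bincount(flat, minlength=n)[:n]
        rows, cols = np.indices(self.owner.shape)
        self.sumx[:n] = np.bincount(flat, weights=rows.ravel(), minlength=n)[:n]
        self.sumy[:n] = np.bincount(flat, weights=cols.ravel(), minlength=n)[:n]
        self.vol[0] = 0
        self.sumx[0] = 0.0
        self.sumy[0] = 0.0

    def centroids(self) -> np.ndarray:
        """(n_ids, 2) array of (row, col) centroids; NaN for empty ids."""
        n = self.n_ids
        out = np.full((n, 2), np.nan)
        live = self.vol[:n] > 0
        out[live, 0] = self.sumx[:n][live] / self.vol[:n][live]
        out[live, 1] = self.sumy[:n][live] / self.vol[:n][live]
        return out

    def live_cells(self) -> np.ndarray:
        n = self.n_ids
        ids = np.arange(n)
        return ids[(self.vol[:n] > 0) & (self.ctype[:n] > 0)]

    def center_of_mass(self) -> np.ndarray:
        total = self.vol[: self.n_ids].sum()
        if total == 0:
            raise ValueError("no cells on the lattice")
        return np.array([self.sumx[: self.n_ids].sum() / total,
                         self.sumy[: self.n_ids].sum() / total])

    def type_mask(self, *types) -> np.ndarray:
        codes = [_type_code(t) for t in types]
        return np.isin(self.ctype[self.owner], codes)

    # -- bookkeeping --------------------------------------------------------

    def _ensure_capacity(self, n: int) -> None:
        cap = len(self.ctype)
        if n <= cap:
            return
        new = max(n, 2 * cap)
        for name in ("ctype", "vol", "tvol", "parent"):
            arr = getattr(self, name)
            grown = np.zeros(new, dtype=arr.dtype)
            if name == "parent":
                grown[:] = -1
            grown[:cap] = arr
            setattr(self, name, grown)
        for name in ("sumx", "sumy"):
            arr = getattr(self, name)
            grown = np.zeros(new, dtype=arr.dtype)
            grown[:cap] = arr
            setattr(self, name, grown)
        pol = np.zeros((new, 2))
        pol[:cap] = self.pol
        self.pol = pol

    def new_cell_id(self, cell_type, target_volume: int = 50,
                    parent: int = -1) -> int:
        cid = self.n_ids
        self._ensure_capacity(cid + 1)
        self.n_ids = cid + 1
        self.ctype[cid] = _type_code(cell_type)
        self.tvol[cid] = target_volume
        self.parent[cid] = parent
        return cid

    def check(self) -> None:
        """Verify the grid/bookkeeping invariants; raise AssertionError."""
        n = self.n_ids
        tally = np.bincount(self.owner.ravel(), minlength=n)[:n]
        tally[0] = 0
        if not np.array_equal(tally, self.vol[:n]):
            raise AssertionError("volume bookkeeping out of sync with grid")
        if self.vol[:n].sum() + (self.owner == 0).sum() != self.owner.size:
            raise AssertionError("cell + medium voxels != lattice size")
        on_grid = np.unique(self.owner)
        if (self.ctype[on_grid[on_grid > 0]] == 0).any():
            raise AssertionError("grid id without a typed cell record")


# -- energy terms -----------------------------------------------------------


def delta_adhesion(state: TissueState, source, target,
                   table: AdhesionTable | None = None) -> float:
    """Adhesion energy change for copying owner(source) onto target.

    Both voxels must be lattice-adjacent; contacts between voxels of the same
    cell contribute zero, so a same-owner proposal returns 0.
    """
    H, W = state.shape
    xs, ys = source
    xt, yt = target
    for (x, y) in ((xs, ys), (xt, yt)):
        if not (0 <= x < H and 0 <= y < W):
            raise OutOfBoundsError(f"voxel {(x, y)} outside {H}x{W} lattice")
    if max(abs(xs - xt), abs(ys - yt)) != 1:
        raise ValueError("source and target must be lattice-adjacent")
    if state.owner[xs, ys] == state.owner[xt, yt]:
        return 0.0
    J = (table or AdhesionTable.default()).matrix
    dxc, dyc = state.params.contact_offsets()
    return float(_kernels.delta_adhesion(
        state.owner, state.ctype, xs, ys, xt, yt, J, dxc, dyc))


def delta_volume(gainer, loser, alpha: float = 0.6) -> float:
    """Volume-constraint energy change; gainer/loser are (V, T) or None.

    The medium carries no volume term, so at most one side may be None.
    """
    if gainer is None and loser is None:
        raise ValueError("at most one of gainer/loser may be None")
    dE = 0.0
    if gainer is not None:
        V, T = gainer
        dE += alpha * ((V + 1 - T) ** 2 - (V - T) ** 2)
    if loser is not None:
        V, T = loser
        dE += alpha * ((V - 1 - T) ** 2 - (V - T) ** 2)
    return float(dE)


def attempt_flip(state: TissueState, source, target, delta_e: float,
                 rng: np.random.Generator | None = None) -> bool:
    """Metropolis acceptance of one proposal with precomputed total dE.

    Accepts unconditionally when dE <= 0, else with probability
    exp(-dE / T); on acceptance updates the owner grid, volumes and centroid
    sums incrementally.
    """
    rng = rng if rng is not None else state.rng
    T = state.params.temperature
    if delta_e > 0.0:
        if delta_e == np.inf or rng.random() >= np.exp(-delta_e / T):
            return False
    xs, ys = source
    xt, yt = target
    s_id = int(state.owner[xs, ys])
    t_id = int(state.owner[xt, yt])
    if s_id == t_id:
        return True
    _kernels.apply_flip(state.owner, state.vol, state.sumx, state.sumy,
                        xt, yt, s_id, t_id)
    return True


def run_mcs(state: TissueState, energy: EnergyModel | None = None,
            n_attempts: int | None = None) -> TissueState:
    """Advance the tissue one Monte Carlo step (in place).

    Performs ``flips_per_mcs`` voxel-copy attempts (default: one per lattice
    site) with the given energy model and increments the step counter.
    """
    if energy is None:
        energy = EnergyModel(alpha=state.params.alpha)
    J, fields, beta = energy.pack(state.shape)
    if n_attempts is None:
        n_attempts = state.params.flips_per_mcs or state.owner.size
    dxc, dyc = state.params.contact_offsets()
    seed = int(state.rng.integers(0, 2**31 - 1))
    _kernels.sweep(state.owner, state.ctype, state.vol, state.tvol,
                   state.sumx, state.sumy,
                   J, energy.alpha, state.params.temperature,
                   n_attempts, state.params.n_proposal_dirs,
                   fields, beta, state.pol, energy.lambda_p,
                   dxc, dyc, seed)
    state.step += 1
    return state


def recenter(state: TissueState, fields=()) -> np.ndarray:
    """Rigidly translate tissue and fields so the embryo CoM sits at center.

    Returns the integer (row, col) shift applied.  All recorded positions
    after a recenter are therefore in the embryo frame.  Raises SizingError
    if the shift would push cells off the lattice.
    """
    H, W = state.shape
    com = state.center_of_mass()
    center = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
    shift = np.rint(center - com).astype(np.int64)
    if shift[0] == 0 and shift[1] == 0:
        state.recompute_geometry()
        return shift
    rows = np.where((state.owner > 0).any(axis=1))[0]
    cols = np.where((state.owner > 0).any(axis=0))[0]
    if (rows.min() + shift[0] < 0 or rows.max() + shift[0] >= H
            or cols.min() + shift[1] < 0 or cols.max() + shift[1] >= W):
        raise SizingError("recentering would push cells off the lattice")
    state.owner = np.ascontiguousarray(
        np.roll(state.owner, tuple(shift), axis=(0, 1)))
    for f in fields:
        values = f.values if hasattr(f, "values") else f
        values[:, :] = np.roll(values, tuple(shift), axis=(0, 1))
    state.cum_shift += shift
    state.recompute_geometry()
    return shift


def fragmentation_report(state: TissueState) -> dict[int, int]:
    """Connected-component count per cell (4-connectivity), for auditing.

    Cell connectivity is not enforced by the dynamics; a count above 1 flags
    a fragmented cell.
    """
    from scipy import ndimage

    report = {}
    slices = ndimage.find_objects(state.owner)
    for cid in state.live_cells():
        sl = slices[cid - 1]
        if sl is None:
            continue
        mask = state.owner[sl] == cid
        _, n = ndimage.label(mask)
        report[int(cid)] = int(n)
    return report
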