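"""Scalar reaction-diffusion fields on lattices parallel to the tissue.

Three kinds of field drive the model:

* the anterior-posterior *induction morphogen*, produced by the AO ring with
  a posterior-weighted rate and solved quasi-statically (a Poisson problem
  with an absorbing far boundary);
* the *chemotactic agents*, produced by one cell type and co-evolved with
  the tissue through an explicit diffusion/production/decay scheme
  (du/dt = D lap u + k1 [producer] - k2 u);
* the slow *ECM anchor*, a barely-diffusing field deposited by AO cells that
  serves as a haptotaxis target pinning the embryo boundary.

Concentrations are in arbitrary units; time in Monte Carlo steps; space in
voxels.  With production on, the saturation level of a broad producing
region is k1 / k2 = 1.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _kernels
from .core import AO, TissueState, _type_code


class FieldStabilityError(ValueError):
    """Requested explicit time step violates the diffusion stability bound."""


@dataclass
class ScalarField:
    """A concentration grid with its kinetic parameters.

    D is the diffusion constant (voxel^2/step), k1 the production rate on
    producer voxels, k2 the first-order decay rate (1/step).  ``anisotropy``
    selects the posterior-weighted production factor (1 - j/j0)^2 used by the
    induction morphogen, where j is the anterior distance from the
    posterior-most epiblast row and j0 the anterior-most.
    """

    values: np.ndarray
    D: float = 1.0
    k1: float = 1.5e-3
    k2: float = 1.0e-3
    producer_type: str | None = None
    anisotropy: str = "none"
    boundary: str = "no_flux"
    name: str = ""
    _buf: np.ndarray | None = dc_field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("field grid must be 2D")
        for p, label in ((self.D, "D"), (self.k1, "k1"), (self.k2, "k2")):
            if p < 0:
                raise ValueError(f"{label} must be non-negative")
        if self.anisotropy not in ("none", "posterior_weighted"):
            raise ValueError("anisotropy must be 'none' or 'posterior_weighted'")
        if self.boundary not in ("no_flux", "absorbing"):
            raise ValueError("boundary must be 'no_flux' or 'absorbing'")

    @classmethod
    def zeros(cls, shape, **kw) -> "ScalarField":
        return cls(np.zeros(shape), **kw)

    def stability_limit(self) -> float:
        """Largest stable explicit step: dt <= 1 / (4 D + k2)."""
        denom = 4.0 * self.D + self.k2
        return np.inf if denom == 0 else 1.0 / denom


def production_weight(field: ScalarField, state: TissueState) -> np.ndarray:
    """k1-weighted source grid: producer occupancy times the posterior factor."""
    if field.producer_type is None:
        return np.zeros(state.shape)
    code = _type_code(field.producer_type)
    mask = (state.ctype[state.owner] == code).astype(np.float64)
    if field.anisotropy == "posterior_weighted":
        mask *= posterior_weight(state)
    return field.k1 * mask


def posterior_weight(state: TissueState) -> np.ndarray:
    """(1 - j/j0)^2 over the lattice, j measured anteriorly from the
    posterior-most epiblast row; zero anterior of the epiblast."""
    occupied = np.where((state.owner > 0).any(axis=1))[0]
    if occupied.size == 0:
        return np.zeros(state.shape)
    j_post, j_ant = occupied.min(), occupied.max()
    j0 = max(j_ant - j_post, 1)
    rows = np.arange(state.shape[0])
    w = 1.0 - (rows - j_post) / j0
    w = np.clip(w, 0.0, 1.0) ** 2
    return np.repeat(w[:, None], state.shape[1], axis=1)


def step_field(field: ScalarField, state: TissueState, dt: float = 1.0,
               substep: float | None = None) -> ScalarField:
    """Advance a chemotactic-agent field by ``dt`` time units (in place).

    Internally substeps the explicit scheme at half the stability bound
    (dt_sub = 0.125 for D = 1), so field time keeps pace with MCS time while
    remaining unconditionally stable and non-negative.  An explicitly
    requested ``substep`` above the bound raises :class:`FieldStabilityError`.
    """
    limit = field.stability_limit()
    if substep is not None:
        if substep > limit:
            raise FieldStabilityError(
                f"substep {substep} exceeds stability bound {limit:.4g}")
        dt_sub = min(substep, dt)
    else:
        dt_sub = min(0.5 * limit, dt)
    nsub = max(1, int(np.ceil(dt / dt_sub - 1e-12)))
    dt_sub = dt / nsub
    production = production_weight(field, state)
    if field._buf is None or field._buf.shape != field.values.shape:
        field._buf = np.empty_like(field.values)
    _kernels.diffuse_react(field.values, production, field.k2, field.D,
                           dt_sub, nsub, field.boundary == "absorbing",
                           field._buf)
    return field


def _steady_solve(production: np.ndarray, D: float, k2: float,
                  absorbing: bool) -> np.ndarray:
    """Sparse direct solve of D lap u - k2 u + production = 0."""
    H, W = production.shape
    N = H * W
    yy, xx = np.mgrid[0:H, 0:W]
    idx = np.arange(N).reshape(H, W)
    main = np.full(N, -k2)
    rows_l, cols_l, vals_l = [], [], []
    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        main -= D
        ny, nx = yy + dy, xx + dx
        inb = (ny >= 0) & (ny < H) & (nx >= 0) & (nx < W)
        if absorbing:
            m = inb.ravel()
            rows_l.append(idx.ravel()[m])
            cols_l.append(idx[np.clip(ny, 0, H - 1), np.clip(nx, 0, W - 1)].ravel()[m])
            vals_l.append(np.full(m.sum(), D))
        else:
            nb = np.where(inb, idx[np.clip(ny, 0, H - 1), np.clip(nx, 0, W - 1)], idx)
            rows_l.append(idx.ravel())
            cols_l.append(nb.ravel())
            vals_l.append(np.full(N, D))
    A = sp.coo_matrix(
        (np.concatenate(vals_l), (np.concatenate(rows_l), np.concatenate(cols_l))),
        shape=(N, N)).tocsc() + sp.diags(main).tocsc()
    u = spla.spsolve(A, -production.ravel())
    return u.reshape(H, W)


def solve_induction_field(state: TissueState, k1: float = 1.5e-3,
                          k2: float = 1.0e-3, D: float = 1.0,
                          normalize: bool = True,
                          peak: float | None = None) -> ScalarField:
    """Quasi-static induction morphogen: production on AO voxels with the
    posterior weight (1 - j/j0)^2, relaxed to steady state (sparse direct
    solve; residual at machine precision).

    The converged maximum sits on the posterior midline.  With
    ``normalize=True`` (default) the field is rescaled so its maximum equals
    ``peak`` (default: the saturation level k1/k2 = 1.5): on this geometry
    the AO ring is narrower than the diffusion length sqrt(D/k2), so the raw
    steady state cannot reach saturation, and the differentiation threshold
    is defined on the saturation-referenced display scale (0 -> 1.5).  The
    spatial shape of the field, hence of the induced sickle, is set entirely
    by the solved system.  Returns a zero field (with a warning) when no AO
    cells exist.
    """
    field = ScalarField.zeros(state.shape, D=D, k1=k1, k2=k2,
                              producer_type="AO",
                              anisotropy="posterior_weighted",
                              boundary="no_flux",
                              name="induction")
    if not (state.ctype[: state.n_ids][state.live_cells()] == AO).any():
        warnings.warn("no AO cells: induction field is identically zero")
        return field
    production = production_weight(field, state)
    field.values = _steady_solve(production, D, k2, absorbing=False)
    top = field.values.max()
    if normalize and top > 0 and k2 > 0:
        field.values *= (peak if peak is not None else k1 / k2) / top
    return field


def equilibrate_field(field: ScalarField, state: TissueState) -> ScalarField:
    """Replace the field values with the steady state for the current tissue.

    Used to initialize a chemotactic agent quasi-statically before the
    co-evolved run; requires a positive decay rate.
    """
    if field.k2 <= 0:
        raise ValueError("equilibration requires a positive decay rate")
    production = production_weight(field, state)
    field.values = _steady_solve(production, field.D, field.k2,
                                 absorbing=field.boundary == "absorbing")
    return field


def build_ecm_anchor(state: TissueState, D_ecm: float = 0.01,
                     k2_ecm: float = 1.0e-4, k1: float = 1.5e-3,
                     equilibrate: bool = True) -> ScalarField:
    """Slow ECM field deposited by AO cells, used as a haptotaxis anchor.

    The small diffusivity and decay give a sharp ring-shaped profile whose
    gradient length outside the ring is sqrt(D_ecm / k2_ecm) (10 voxels at
    the defaults); AO cells hill-climb it, pinning the embryo boundary
    without explicit recentering.
    """
    field = ScalarField.zeros(state.shape, D=D_ecm, k1=k1, k2=k2_ecm,
                              producer_type="AO", name="ecm")
    if equilibrate and k2_ecm > 0:
        equilibrate_field(field, state)
    return field
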