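"""Directed-motility energy terms: chemotaxis, polarization, haptotaxis.

Chemotaxis biases the Metropolis dynamics by adding, for a voxel copy of the
responding cell from ``source`` to ``target``,

    dE_chem = -beta * (u(target) - u(source)),

so a positive coefficient makes uphill moves energetically favorable
(attraction) and a negative one repulsion.  The same term can be rewritten
through a per-cell *polarization vector* P:

    dE_pol = -lambda_P * (P . x),

with x the unit displacement of the proposed boundary shift.  With P slaved
to the local gradient the two formulations generate the same motion; the
polarization form additionally supports *induced polarization*, a
flock-model co-alignment in which each cell's P relaxes toward the mean
polarization of its contact neighbors plus its own chemotactic drive:

    P <- (1 - rho) P + gamma <P>_neighbors + chi * sum_f beta_f grad(u_f).

All cells are updated synchronously once per MCS from previous-step values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .core import N_TYPES, TissueState, _type_code


@dataclass(frozen=True)
class ChemoResponse:
    """One (responder type, field, beta) chemotactic coupling.

    ``field`` is the name of the chemotactic agent; beta is signed, positive
    for attraction under the convention adopted throughout (the mechanism
    presets use +80/+40 for attraction and -60/-40/-15 for repulsion).
    """

    responder_type: str
    field: str
    beta: float

    def __post_init__(self):
        _type_code(self.responder_type)
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")


def beta_by_type(responses, field_name: str) -> np.ndarray:
    """Length-5 coefficient vector for one field from a response list."""
    beta = np.zeros(N_TYPES)
    for r in responses:
        if r.field == field_name:
            beta[_type_code(r.responder_type)] = r.beta
    return beta


@dataclass
class PolarizationParams:
    """Coefficients of the induced-polarization update.

    memory (rho)
        Fraction of P forgotten per step; rho = 1 erases P each step.
    neighbor_coupling (gamma)
        Gain on the contact-weighted mean polarization of touching cells.
        A uniform polarization field is stationary iff gamma = rho.
    chemo_gain (chi)
        Coupling of the cell's own chemotactic drive beta*grad(u) into P.
        The defaults keep the stationary single-cell drive chi*beta/rho at
        the plain-chemotaxis scale while letting co-alignment spread through
        the tissue.
    strength (lambda_P)
        Weight of the alignment energy -lambda_P (P . x).
    max_magnitude
        Saturation bound on |P| (cell motility cannot grow without limit);
        vectors above the bound are rescaled onto it.
    zero_net
        Project out the tissue-mean polarization after each update.  The
        co-alignment forces are internal, so they cannot impart net momentum
        to an anchored embryo; without the projection the mean polarization
        integrates the chemotactic input (the uniform mode is undamped when
        gamma approaches rho) and the whole tissue drifts without bound.
        The vortical flows of interest carry no net momentum and are
        unaffected.
    """

    memory: float = 0.1
    neighbor_coupling: float = 0.095
    chemo_gain: float = 0.1
    strength: float = 1.0
    zero_net: bool = True
    max_magnitude: float = np.inf

    def __post_init__(self):
        if not 0.0 <= self.memory <= 1.0:
            raise ValueError("memory (rho) must be in [0, 1]")
        for v, label in ((self.neighbor_coupling, "neighbor_coupling"),
                         (self.chemo_gain, "chemo_gain"),
                         (self.strength, "strength")):
            if v < 0:
                raise ValueError(f"{label} must be non-negative")


def delta_chemotaxis(beta: float, u: np.ndarray, source, target) -> float:
    """-beta * (u(target) - u(source)) for one proposed voxel copy."""
    xs, ys = source
    xt, yt = target
    return float(-beta * (u[xt, yt] - u[xs, ys]))


def delta_haptotaxis(beta_ecm: float, ecm: np.ndarray, source, target) -> float:
    """Haptotaxis on the ECM field; identical contract to chemotaxis."""
    return delta_chemotaxis(beta_ecm, ecm, source, target)


def delta_polarization(P, displacement, lambda_p: float = 1.0) -> float:
    """-lambda_P * (P . x) for a unit boundary-shift vector x."""
    P = np.asarray(P, dtype=float)
    x = np.asarray(displacement, dtype=float)
    return float(-lambda_p * (P @ x))


def update_polarization(P, neighbor_Ps, grad_u, params: PolarizationParams):
    """Single-cell induced-polarization update (returns the new P).

    ``neighbor_Ps`` is an iterable of neighbor polarization vectors (empty
    -> zero neighbor term); ``grad_u`` is the cell's already beta-weighted
    chemotactic drive sum_f beta_f grad(u_f) at its centroid.
    """
    P = np.asarray(P, dtype=float)
    neighbor_Ps = np.asarray(list(neighbor_Ps), dtype=float)
    if neighbor_Ps.size:
        mean_nb = neighbor_Ps.mean(axis=0)
    else:
        mean_nb = np.zeros(2)
    grad_u = np.asarray(grad_u, dtype=float)
    return ((1.0 - params.memory) * P
            + params.neighbor_coupling * mean_nb
            + params.chemo_gain * grad_u)


def gradient_at(u: np.ndarray, point) -> np.ndarray:
    """Central-difference gradient (d/drow, d/dcol) at a (row, col) point."""
    H, W = u.shape
    i = int(round(point[0]))
    j = int(round(point[1]))
    i = min(max(i, 1), H - 2)
    j = min(max(j, 1), W - 2)
    gx = 0.5 * (u[i + 1, j] - u[i - 1, j])
    gy = 0.5 * (u[i, j + 1] - u[i, j - 1])
    return np.array([gx, gy])


def chemo_drive(state: TissueState, chemo, ids=None) -> np.ndarray:
    """Per-cell beta-weighted gradient drive sum_f beta_f grad(u_f).

    ``chemo`` is the EnergyModel-style list of (grid, beta_by_type) pairs;
    gradients are evaluated at cell centroids by central differences.
    """
    if ids is None:
        ids = state.live_cells()
    drive = np.zeros((state.n_ids, 2))
    if not chemo:
        return drive
    cent = state.centroids()
    for u, beta in chemo:
        beta = np.asarray(beta)
        for cid in ids:
            b = beta[state.ctype[cid]]
            if b != 0.0:
                drive[cid] += b * gradient_at(u, cent[cid])
    return drive


def update_all_polarizations(state: TissueState, chemo,
                             params: PolarizationParams) -> None:
    """Synchronous per-MCS polarization update for every live cell.

    The neighbor average is the contact-length-weighted mean over Moore
    boundary bonds, computed in one lattice pass from previous-step values.
    """
    n = state.n_ids
    sums = np.zeros((n, 2))
    counts = np.zeros(n, dtype=np.int64)
    _kernels.contact_pol_sums(state.owner, state.pol, sums, counts)
    mean_nb = np.zeros((n, 2))
    has = counts > 0
    mean_nb[has] = sums[has] / counts[has, None]
    drive = chemo_drive(state, chemo)
    live = state.live_cells()
    state.pol[live] = ((1.0 - params.memory) * state.pol[live]
                       + params.neighbor_coupling * mean_nb[live]
                       + params.chemo_gain * drive[live])
    if np.isfinite(params.max_magnitude):
        norms = np.linalg.norm(state.pol[live], axis=1)
        over = norms > params.max_magnitude
        if over.any():
            idx = live[over]
            state.pol[idx] *= (params.max_magnitude / norms[over])[:, None]
    if params.zero_net and live.size:
        state.pol[live] -= state.pol[live].mean(axis=0)
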