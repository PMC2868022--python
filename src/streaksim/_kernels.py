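"""Jit-compiled inner loops: Metropolis sweep, field stepping, contact sums.

Everything here takes bare numpy arrays so the kernels compile once and are
reused across simulations; the public wrappers live in :mod:`streaksim.core`,
:mod:`streaksim.fields` and :mod:`streaksim.guidance`.

Conventions shared with the rest of the package:

* ``owner`` is an ``(H, W)`` integer grid of cell ids, 0 = medium/substrate.
* ``ctype[id]`` maps a cell id to its type code (0 medium, 1 AP, 2 AO,
  3 S, 4 ST).
* ``J`` is the 5x5 symmetric contact-energy matrix indexed by type code.
* ``fields`` is an ``(nf, H, W)`` stack of chemotactic agent concentrations
  and ``beta[f, t]`` the chemotactic coefficient of type ``t`` for field
  ``f`` (positive = attraction).
* Voxel coordinates are ``(row, col)``; rows increase anteriorly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Proposal / contact neighborhoods.  The first four entries of the 8-offset
# table are the von Neumann directions, so a prefix of length 4 or 8 selects
# the proposal neighborhood.
DX8 = np.array([1, -1, 0, 0, 1, 1, -1, -1], dtype=np.int64)
DY8 = np.array([0, 0, 1, -1, 1, -1, 1, -1], dtype=np.int64)
DX4 = DX8[:4].copy()
DY4 = DY8[:4].copy()


@njit(cache=True)
def delta_adhesion(owner, ctype, xs, ys, xt, yt, J, dxc, dyc):
    """Adhesion energy change for copying owner(source) onto the target voxel.

    Sums the J-changes over the contact neighborhood (dxc, dyc) of the target;
    bonds between voxels of the same cell contribute nothing.  Out-of-lattice
    neighbors count as medium.
    """
    H, W = owner.shape
    s_id = owner[xs, ys]
    t_id = owner[xt, yt]
    new_t = ctype[s_id]
    old_t = ctype[t_id]
    dE = 0.0
    for k in range(dxc.shape[0]):
        xn = xt + dxc[k]
        yn = yt + dyc[k]
        if 0 <= xn < H and 0 <= yn < W:
            n_id = owner[xn, yn]
            n_t = ctype[n_id]
        else:
            n_id = 0
            n_t = 0
        if n_id != s_id:
            dE += J[new_t, n_t]
        if n_id != t_id:
            dE -= J[old_t, n_t]
    return dE


@njit(cache=True)
def flip_delta(owner, ctype, vol, tvol, J, alpha,
               fields, beta, pol, lambda_p,
               xs, ys, xt, yt, dxc, dyc):
    """Total effective-energy change for one voxel-copy proposal.

    Terms: adhesion + volume constraint + chemotaxis (per field, coefficient
    of the *source* cell's type) + polarization alignment of the source cell.
    Returns 0.0 for a same-cell proposal (identity move).
    """
    s_id = owner[xs, ys]
    t_id = owner[xt, yt]
    if s_id == t_id:
        return 0.0
    dE = delta_adhesion(owner, ctype, xs, ys, xt, yt, J, dxc, dyc)
    if s_id != 0:
        dE += alpha * (2.0 * (vol[s_id] - tvol[s_id]) + 1.0)
    if t_id != 0:
        dE += alpha * (-2.0 * (vol[t_id] - tvol[t_id]) + 1.0)
    if s_id != 0:
        st = ctype[s_id]
        for f in range(fields.shape[0]):
            b = beta[f, st]
            if b != 0.0:
                dE -= b * (fields[f, xt, yt] - fields[f, xs, ys])
        if lambda_p > 0.0:
            dx = float(xt - xs)
            dy = float(yt - ys)
            inv = 1.0 / np.sqrt(dx * dx + dy * dy)
            dE -= lambda_p * (pol[s_id, 0] * dx + pol[s_id, 1] * dy) * inv
    return dE


@njit(cache=True)
def apply_flip(owner, vol, sumx, sumy, xt, yt, s_id, t_id):
    owner[xt, yt] = s_id
    if s_id != 0:
        vol[s_id] += 1
        sumx[s_id] += xt
        sumy[s_id] += yt
    if t_id != 0:
        vol[t_id] -= 1
        sumx[t_id] -= xt
        sumy[t_id] -= yt


@njit(cache=True)
def sweep(owner, ctype, vol, tvol, sumx, sumy,
          J, alpha, temperature,
          n_attempts, n_prop_dirs,
          fields, beta, pol, lambda_p,
          dxc, dyc, seed):
    """One Monte Carlo step: ``n_attempts`` random voxel-copy proposals.

    Downhill and zero-energy proposals are always accepted; uphill proposals
    with probability exp(-dE/T).  Volumes and centroid sums are updated
    incrementally.  Returns the number of accepted copies.
    """
    np.random.seed(seed)
    H, W = owner.shape
    accepted = 0
    for _ in range(n_attempts):
        xs = np.random.randint(0, H)
        ys = np.random.randint(0, W)
        d = np.random.randint(0, n_prop_dirs)
        xt = xs + DX8[d]
        yt = ys + DY8[d]
        if xt < 0 or xt >= H or yt < 0 or yt >= W:
            continue
        s_id = owner[xs, ys]
        t_id = owner[xt, yt]
        if s_id == t_id:
            continue
        dE = flip_delta(owner, ctype, vol, tvol, J, alpha,
                        fields, beta, pol, lambda_p,
                        xs, ys, xt, yt, dxc, dyc)
        if dE <= 0.0 or np.random.random() < np.exp(-dE / temperature):
            apply_flip(owner, vol, sumx, sumy, xt, yt, s_id, t_id)
            accepted += 1
    return accepted


@njit(cache=True)
def diffuse_react(u, production, k2, D, dt, nsub, absorbing, buf):
    """Explicit Euler substeps of du/dt = D*lap(u) + production - k2*u.

    ``production`` is the already-weighted source grid (k1 times producer
    occupancy).  Boundary: no-flux (reflect) or absorbing (zero outside).
    """
    H, W = u.shape
    for _ in range(nsub):
        for i in range(H):
            for j in range(W):
                c = u[i, j]
                if absorbing:
                    up = u[i - 1, j] if i > 0 else 0.0
                    dn = u[i + 1, j] if i < H - 1 else 0.0
                    lf = u[i, j - 1] if j > 0 else 0.0
                    rt = u[i, j + 1] if j < W - 1 else 0.0
                else:
                    up = u[i - 1, j] if i > 0 else c
                    dn = u[i + 1, j] if i < H - 1 else c
                    lf = u[i, j - 1] if j > 0 else c
                    rt = u[i, j + 1] if j < W - 1 else c
                lap = up + dn + lf + rt - 4.0 * c
                buf[i, j] = c + dt * (D * lap + production[i, j] - k2 * c)
        u[:, :] = buf


@njit(cache=True)
def contact_pol_sums(owner, pol, sums, counts):
    """Accumulate neighbor polarizations over Moore boundary bonds.

    For every pair of adjacent voxels owned by two different cells, each cell
    receives the other's polarization once, i.e. the neighbor average is
    weighted by shared contact length.
    """
    H, W = owner.shape
    for i in range(H):
        for j in range(W):
            a = owner[i, j]
            # forward bonds only: E, S, SE, SW
            for k in range(4):
                if k == 0:
                    ni, nj = i, j + 1
                elif k == 1:
                    ni, nj = i + 1, j
                elif k == 2:
                    ni, nj = i + 1, j + 1
                else:
                    ni, nj = i + 1, j - 1
                if ni >= H or nj < 0 or nj >= W:
                    continue
                b = owner[ni, nj]
                if a != b and a > 0 and b > 0:
                    sums[a, 0] += pol[b, 0]
                    sums[a, 1] += pol[b, 1]
                    counts[a] += 1
                    sums[b, 0] += pol[a, 0]
                    sums[b, 1] += pol[a, 1]
                    counts[b] += 1


@njit(cache=True)
def boundary_length(owner, type_a, type_b, ctype):
    """Total Moore-bond contact length between voxels of two given types."""
    H, W = owner.shape
    n = 0
    for i in range(H):
        for j in range(W):
            ta = ctype[owner[i, j]]
            for k in range(4):
                if k == 0:
                    ni, nj = i, j + 1
                elif k == 1:
                    ni, nj = i + 1, j
                elif k == 2:
                    ni, nj = i + 1, j + 1
                else:
                    ni, nj = i + 1, j - 1
                if ni >= H or nj < 0 or nj >= W:
                    continue
                tb = ctype[owner[ni, nj]]
                if (ta == type_a and tb == type_b) or (ta == type_b and tb == type_a):
                    n += 1
    return n
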