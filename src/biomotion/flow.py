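"""Dense bidirectional optical flow and SAD block matching.

The variational estimator minimizes a three-term objective per
direction — robust (Charbonnier) data term, a symmetric coupling term
penalizing ``||w_fwd(x) + w_bwd(x + w_fwd(x))||``, and total-variation
smoothness — by coarse-to-fine warping with outer/inner fixed-point
iterations and per-pixel 2x2 Jacobi solves.  Energies are guarded: an
outer step that increases the joint energy is reverted, so the recorded
energy trace is non-increasing at every pyramid level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, zoom

__all__ = ["FlowField", "FlowParams", "estimate_flow", "sad_block_flow",
           "flow_speed"]


@dataclass
class FlowField:
    """Per-pixel velocities: u positive rightward, v positive downward."""
    u: np.ndarray
    v: np.ndarray
    mask: np.ndarray
    direction: str = "forward"

    def __post_init__(self):
        if not (self.u.shape == self.v.shape == self.mask.shape):
            raise ValueError("u, v, mask must share one shape")

    @property
    def shape(self):
        return self.u.shape


@dataclass
class FlowParams:
    rho: float = 0.1            # symmetric-term weight
    xi: float = 0.02            # smoothness weight
    n_levels: int = 4
    n_outer: int = 6
    n_inner: int = 3
    n_sweeps: int = 20
    charbonnier_eps: float = 1e-3
    sym_eps: float = 0.5        # Charbonnier eps of the symmetric term (px)
    presmooth_sigma: float = 0.8
    min_level_size: int = 12

    def __post_init__(self):
        if self.rho < 0 or self.xi < 0:
            raise ValueError("weights must be >= 0")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")


def flow_speed(fieldarg: FlowField) -> np.ndarray:
    """Elementwise speed ``sqrt(u**2 + v**2)``."""
    return np.hypot(fieldarg.u, fieldarg.v)


def _warp(img, u, v):
    """Bilinear sample of ``img`` at x + (u, v); replicate borders.

    Second return is 1.0 where the sample fell inside the frame.
    """
    H, W = img.shape
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    Y, X = yy + v, xx + u
    warped = map_coordinates(img, [Y, X], order=1, mode="nearest")
    inside = ((X >= 0) & (X <= W - 1) & (Y >= 0) & (Y <= H - 1)).astype(float)
    return warped, inside


def _grad(img):
    gy, gx = np.gradient(img)
    return gx, gy


def _charb(x2, eps):
    return np.sqrt(x2 + eps * eps)


def _grad_mag2(u, v):
    uy, ux = np.gradient(u)
    vy, vx = np.gradient(v)
    return ux ** 2 + uy ** 2 + vx ** 2 + vy ** 2


def _pair_energy(I1, I2, uf, vf, ub, vb, p: FlowParams, m1, m2):
    eps = p.charbonnier_eps
    I2w, visf = _warp(I2, uf, vf)
    I1w, visb = _warp(I1, ub, vb)
    data = float((m1 * visf * _charb((I2w - I1) ** 2, eps)).sum()
                 + (m2 * visb * _charb((I1w - I2) ** 2, eps)).sum())
    ubw, _ = _warp(ub, uf, vf)
    vbw, _ = _warp(vb, uf, vf)
    ufw, _ = _warp(uf, ub, vb)
    vfw, _ = _warp(vf, ub, vb)
    sym = float(_charb((uf + ubw) ** 2 + (vf + vbw) ** 2, p.sym_eps).sum()
                + _charb((ub + ufw) ** 2 + (vb + vfw) ** 2, p.sym_eps).sum())
    smooth = float(_charb(_grad_mag2(uf, vf), eps).sum()
                   + _charb(_grad_mag2(ub, vb), eps).sum())
    return data + p.rho * sym + p.xi * smooth


def _neighbor_sums(field, wr, wd):
    """Weighted 4-neighbor sum and total weight from edge weights.

    ``wr[i, j]`` weights the edge to the right neighbor, ``wd[i, j]`` the
    edge to the one below; boundary edges carry zero weight.
    """
    s = np.zeros_like(field)
    w = np.zeros_like(field)
    s[:, :-1] += wr[:, :-1] * field[:, 1:]
    w[:, :-1] += wr[:, :-1]
    s[:, 1:] += wr[:, :-1] * field[:, :-1]
    w[:, 1:] += wr[:, :-1]
    s[:-1, :] += wd[:-1, :] * field[1:, :]
    w[:-1, :] += wd[:-1, :]
    s[1:, :] += wd[:-1, :] * field[:-1, :]
    w[1:, :] += wd[:-1, :]
    return s, w


def _update_direction(I1, I2, u, v, u_other, v_other, p: FlowParams, mask):
    """One outer fixed-point step (warp + robust inner iterations)."""
    eps = p.charbonnier_eps
    I2w, vis = _warp(I2, u, v)
    gx2, gy2 = _grad(I2)
    Ix, _ = _warp(gx2, u, v)
    Iy, _ = _warp(gy2, u, v)
    gx1, gy1 = _grad(I1)
    Ix = 0.5 * (Ix + gx1)
    Iy = 0.5 * (Iy + gy1)
    It = I2w - I1
    dmask = mask * vis

    # coupling target: w should approach -w_other(x + w(x))
    cu_o, cvis = _warp(u_other, u, v)
    cv_o, _ = _warp(v_other, u, v)
    cu, cv = -cu_o, -cv_o

    u0, v0 = u, v
    un, vn = u.copy(), v.copy()
    for _ in range(p.n_inner):
        r = It + Ix * (un - u0) + Iy * (vn - v0)
        wd = dmask / _charb(r ** 2, eps)
        wc = p.rho * cvis / _charb((un - cu) ** 2 + (vn - cv) ** 2, p.sym_eps)
        psi = 1.0 / _charb(_grad_mag2(un, vn), eps)
        wr = 0.5 * (psi[:, :-1] + psi[:, 1:])
        wr = np.pad(wr, ((0, 0), (0, 1)))
        wdn = 0.5 * (psi[:-1, :] + psi[1:, :])
        wdn = np.pad(wdn, ((0, 1), (0, 0)))
        for _ in range(p.n_sweeps):
            su, wsum = _neighbor_sums(un, wr, wdn)
            sv, _ = _neighbor_sums(vn, wr, wdn)
            a11 = wd * Ix * Ix + wc + p.xi * wsum
            a22 = wd * Iy * Iy + wc + p.xi * wsum
            a12 = wd * Ix * Iy
            b1 = wd * Ix * (Ix * u0 + Iy * v0 - It) + wc * cu + p.xi * su
            b2 = wd * Iy * (Iy * v0 + Ix * u0 - It) + wc * cv + p.xi * sv
            det = a11 * a22 - a12 * a12
            det = np.where(np.abs(det) < 1e-12, 1e-12, det)
            un = (b1 * a22 - b2 * a12) / det
            vn = (b2 * a11 - b1 * a12) / det
    return un, vn


def _resize(img, shape):
    fy = shape[0] / img.shape[0]
    fx = shape[1] / img.shape[1]
    return zoom(img, (fy, fx), order=1, mode="nearest", grid_mode=True)


def estimate_flow(frame1: np.ndarray, frame2: np.ndarray,
                  params: FlowParams | None = None,
                  masks: tuple[np.ndarray, np.ndarray] | None = None,
                  ) -> tuple[FlowField, FlowField]:
    """Jointly estimate forward (frame1->frame2) and backward flow.

    ``masks`` are the per-frame visibility layers of the layered
    formulation; they default to all-ones (full-frame layer).  Returns
    the two fields; each carries a per-pixel visibility mask that is 0
    where the optimized flow points outside the frame.
    """
    f1 = np.asarray(frame1, dtype=float)
    f2 = np.asarray(frame2, dtype=float)
    if f1.shape != f2.shape:
        raise ValueError(f"frame shapes differ: {f1.shape} vs {f2.shape}")
    if params is None:
        params = FlowParams()
    if masks is None:
        m1 = np.ones_like(f1)
        m2 = np.ones_like(f2)
    else:
        m1 = np.asarray(masks[0], dtype=float)
        m2 = np.asarray(masks[1], dtype=float)

    # pyramid (fine -> coarse)
    shapes = [f1.shape]
    while (len(shapes) < params.n_levels
           and min(shapes[-1]) * 0.5 >= params.min_level_size):
        shapes.append((int(round(shapes[-1][0] * 0.5)),
                       int(round(shapes[-1][1] * 0.5))))

    uf = vf = ub = vb = None
    for shape in reversed(shapes):
        I1 = gaussian_filter(_resize(f1, shape), params.presmooth_sigma)
        I2 = gaussian_filter(_resize(f2, shape), params.presmooth_sigma)
        L1 = _resize(m1, shape)
        L2 = _resize(m2, shape)
        if uf is None:
            uf = np.zeros(shape)
            vf = np.zeros(shape)
            ub = np.zeros(shape)
            vb = np.zeros(shape)
        else:
            ry = shape[0] / uf.shape[0]
            rx = shape[1] / uf.shape[1]
            uf = _resize(uf, shape) * rx
            vf = _resize(vf, shape) * ry
            ub = _resize(ub, shape) * rx
            vb = _resize(vb, shape) * ry
        energy = _pair_energy(I1, I2, uf, vf, ub, vb, params, L1, L2)
        for _ in range(params.n_outer):
            nuf, nvf = _update_direction(I1, I2, uf, vf, ub, vb, params, L1)
            nub, nvb = _update_direction(I2, I1, ub, vb, nuf, nvf, params, L2)
            new_energy = _pair_energy(I1, I2, nuf, nvf, nub, nvb, params,
                                      L1, L2)
            if new_energy > energy:  # guard: keep the energy trace monotone
                break
            uf, vf, ub, vb = nuf, nvf, nub, nvb
            if energy - new_energy < 1e-9 * max(abs(energy), 1.0):
                energy = new_energy
                break
            energy = new_energy

    _, visf = _warp(f2, uf, vf)
    _, visb = _warp(f1, ub, vb)
    fwd = FlowField(u=uf, v=vf, mask=visf, direction="forward")
    bwd = FlowField(u=ub, v=vb, mask=visb, direction="backward")
    return fwd, bwd


def objective(frame1, frame2, fwd: FlowField, bwd: FlowField,
              params: FlowParams | None = None) -> float:
    """Evaluate the joint flow objective for a candidate field pair."""
    if params is None:
        params = FlowParams()
    f1 = np.asarray(frame1, dtype=float)
    f2 = np.asarray(frame2, dtype=float)
    ones = np.ones_like(f1)
    return _pair_energy(gaussian_filter(f1, params.presmooth_sigma),
                        gaussian_filter(f2, params.presmooth_sigma),
                        fwd.u, fwd.v, bwd.u, bwd.v, params, ones, ones)


def sad_block_flow(frame1: np.ndarray, frame2: np.ndarray,
                   block: int = 8, search_radius: int = 4) -> FlowField:
    """Compressed optic flow by block-wise L1 (SAD) matching.

    Each ``block``-sized tile of frame1 is matched to frame2 within the
    integer search window; ties go to the smallest displacement norm then
    row-major scan order.  The block field is upsampled to pixels by
    nearest-block assignment and deliberately left unsmoothed.
    """
    f1 = np.asarray(frame1, dtype=float)
    f2 = np.asarray(frame2, dtype=float)
    if f1.shape != f2.shape:
        raise ValueError("frame shapes differ")
    if block < 1 or search_radius < 0:
        raise ValueError("block must be >= 1 and search_radius >= 0")
    H, W = f1.shape
    if block > H or block > W:
        raise ValueError(f"block {block} larger than frame {f1.shape}")
    u = np.zeros((H, W))
    v = np.zeros((H, W))
    for r0 in range(0, H, block):
        for c0 in range(0, W, block):
            r1 = min(r0 + block, H)
            c1 = min(c0 + block, W)
            tile = f1[r0:r1, c0:c1]
            best = (np.inf, np.inf, None)  # (sad, |d|^2, (dy, dx))
            for dy in range(-search_radius, search_radius + 1):
                for dx in range(-search_radius, search_radius + 1):
                    rr0, rr1 = r0 + dy, r1 + dy
                    cc0, cc1 = c0 + dx, c1 + dx
                    if rr0 < 0 or cc0 < 0 or rr1 > H or cc1 > W:
                        continue
                    sad = float(np.abs(tile - f2[rr0:rr1, cc0:cc1]).sum())
                    n2 = dy * dy + dx * dx
                    if (sad < best[0]
                            or (sad == best[0] and n2 < best[1])):
                        best = (sad, n2, (dy, dx))
            dy, dx = best[2] if best[2] is not None else (0, 0)
            u[r0:r1, c0:c1] = dx
            v[r0:r1, c0:c1] = dy
    return FlowField(u=u, v=v, mask=np.ones((H, W)), direction="forward")
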