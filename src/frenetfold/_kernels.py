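"""Numba kernels for the single-site Glauber sweep.

A move at angle index j (chain site j+1) re-orients transfer j+1; the
downstream tail r_{j+2} … r_{N-1} is rigidly rotated about the pivot
r_{j+1} by B = G_j^T R_old^T R_new G_j, so the energy difference is local
in (θ, φ) and the excluded-volume check only needs the upstream×downstream
pairs.  Frames are row-stacked [n; b; t]; positions advance along frame
row 2.  All randomness is drawn outside the kernel (per-sweep arrays from
a numpy Generator) so trajectories are bit-reproducible.
"""

import numpy as np
from numba import njit

__all__ = ["propagate", "sweep"]

_TWO_PI = 2.0 * np.pi


@njit(cache=True)
def _wrap(x):
    y = (x + np.pi) % _TWO_PI
    if y <= 0.0:
        y += _TWO_PI
    return y - np.pi


@njit(cache=True)
def _rot(theta, phi, out):
    ct = np.cos(theta)
    st = np.sin(theta)
    cp = np.cos(phi)
    sp = -np.sin(phi)  # right-handed helix carries φ = +0.9
    out[0, 0] = ct * cp
    out[0, 1] = -ct * sp
    out[0, 2] = st
    out[1, 0] = sp
    out[1, 1] = cp
    out[1, 2] = 0.0
    out[2, 0] = -st * cp
    out[2, 1] = st * sp
    out[2, 2] = ct


@njit(cache=True)
def propagate(theta, phi, L, pos, frames):
    """Fill pos (M+2,3) and frames (M+1,3,3) from the angle arrays."""
    M = theta.shape[0]
    for r in range(3):
        for c in range(3):
            frames[0, r, c] = 1.0 if r == c else 0.0
    pos[0, 0] = 0.0
    pos[0, 1] = 0.0
    pos[0, 2] = 0.0
    for c in range(3):
        pos[1, c] = pos[0, c] + L * frames[0, 2, c]
    R = np.empty((3, 3))
    for k in range(1, M + 1):
        _rot(theta[k - 1], phi[k - 1], R)
        for r in range(3):
            for c in range(3):
                s = 0.0
                for q in range(3):
                    s += R[r, q] * frames[k - 1, q, c]
                frames[k, r, c] = s
        for c in range(3):
            pos[k + 1, c] = pos[k, c] + L * frames[k, 2, c]


@njit(cache=True)
def _local_energy(j, th, ph, theta, lam, m, a, b, c, d, his, mu):
    """Energy terms containing (θ_j, φ_j), with candidate values th/ph."""
    M = theta.shape[0]
    e = lam[j] * (th * th - m[j] * m[j]) ** 2
    if j > 0:
        e += -2.0 * th * theta[j - 1]
    if j < M - 1:  # kinetic pair belongs to sites with a right neighbour
        e += -2.0 * theta[j + 1] * th + 2.0 * th * th
    if j >= 1:  # torsion sector (gauge slot j=0 excluded)
        t2 = th * th
        e += 0.5 * d[j] * t2 * ph * ph - b[j] * t2 * ph - a[j] * ph + 0.5 * c[j] * ph * ph
    if his[j]:
        e += -mu * th * th
    return e


@njit(cache=True)
def sweep(
    theta,
    phi,
    pos,
    frames,
    lam,
    m,
    a,
    b,
    c,
    d,
    his,
    mu,
    beta,
    L,
    rmin,
    sig_t,
    sig_p,
    order,
    normals,
    uniforms,
    moved,
):
    """One pass of single-site Glauber updates in the given site order.

    Mutates theta/phi/pos/frames in place.  Returns (accepted moves,
    ΔF, Δ(μN)-relevant Δ(Σ_his θ²)) accumulated over the sweep.
    """
    M = theta.shape[0]
    N = M + 2
    rmin2 = rmin * rmin
    R_old = np.empty((3, 3))
    R_new = np.empty((3, 3))
    B = np.empty((3, 3))
    tmp = np.empty((3, 3))
    n_accept = 0
    dF = 0.0
    dN = 0.0
    for idx in range(M):
        j = order[idx]
        th_old = theta[j]
        ph_old = phi[j]
        th_new = _wrap(th_old + sig_t * normals[idx, 0])
        ph_new = ph_old if j == 0 else _wrap(ph_old + sig_p * normals[idx, 1])

        e_old = _local_energy(j, th_old, ph_old, theta, lam, m, a, b, c, d, his, mu)
        e_new = _local_energy(j, th_new, ph_new, theta, lam, m, a, b, c, d, his, mu)
        delta = e_new - e_old

        # Glauber acceptance on the finite part first (cheap reject)
        if beta * delta > 700.0:
            continue
        p = 1.0 / (1.0 + np.exp(beta * delta))
        if uniforms[idx] >= p:
            continue

        # tail rotation B = G_j^T R_old^T R_new G_j  (row-frame convention)
        k = j + 1  # transfer index; pivot is pos[k]
        _rot(th_old, ph_old, R_old)
        _rot(th_new, ph_new, R_new)
        for r in range(3):
            for cc in range(3):
                s = 0.0
                for q in range(3):
                    s += R_old[q, r] * R_new[q, cc]  # R_old^T R_new
                tmp[r, cc] = s
        for r in range(3):
            for cc in range(3):
                s = 0.0
                for q in range(3):
                    for w in range(3):
                        s += frames[j, q, r] * tmp[q, w] * frames[j, w, cc]
                B[r, cc] = s
        # Gram-Schmidt the rows of B: without this, the orthogonality error
        # of the frames feeds back through B and compounds exponentially
        s = np.sqrt(B[0, 0] ** 2 + B[0, 1] ** 2 + B[0, 2] ** 2)
        for cc in range(3):
            B[0, cc] /= s
        s = B[1, 0] * B[0, 0] + B[1, 1] * B[0, 1] + B[1, 2] * B[0, 2]
        for cc in range(3):
            B[1, cc] -= s * B[0, cc]
        s = np.sqrt(B[1, 0] ** 2 + B[1, 1] ** 2 + B[1, 2] ** 2)
        for cc in range(3):
            B[1, cc] /= s
        B[2, 0] = B[0, 1] * B[1, 2] - B[0, 2] * B[1, 1]
        B[2, 1] = B[0, 2] * B[1, 0] - B[0, 0] * B[1, 2]
        B[2, 2] = B[0, 0] * B[1, 1] - B[0, 1] * B[1, 0]

        # moved tail positions and hard-core check against the fixed head
        px = pos[k, 0]
        py = pos[k, 1]
        pz = pos[k, 2]
        ok = True
        for v in range(k + 1, N):
            vx = pos[v, 0] - px
            vy = pos[v, 1] - py
            vz = pos[v, 2] - pz
            moved[v, 0] = px + vx * B[0, 0] + vy * B[1, 0] + vz * B[2, 0]
            moved[v, 1] = py + vx * B[0, 1] + vy * B[1, 1] + vz * B[2, 1]
            moved[v, 2] = pz + vx * B[0, 2] + vy * B[1, 2] + vz * B[2, 2]
        for u in range(0, k + 1):
            v0 = k + 1 if k + 1 >= u + 2 else u + 2
            for v in range(v0, N):
                dx = moved[v, 0] - pos[u, 0]
                dy = moved[v, 1] - pos[u, 1]
                dz = moved[v, 2] - pos[u, 2]
                if dx * dx + dy * dy + dz * dz < rmin2:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue

        # accept
        theta[j] = th_new
        phi[j] = ph_new
        for v in range(k + 1, N):
            pos[v, 0] = moved[v, 0]
            pos[v, 1] = moved[v, 1]
            pos[v, 2] = moved[v, 2]
        for t in range(k, M + 1):
            for r in range(3):
                for cc in range(3):
                    tmp[r, cc] = frames[t, r, cc]
            for r in range(3):
                for cc in range(3):
                    s = 0.0
                    for q in range(3):
                        s += tmp[r, q] * B[q, cc]
                    frames[t, r, cc] = s
        n_accept += 1
        if his[j]:
            dn = th_new * th_new - th_old * th_old
            dN += dn
            dF += delta + mu * dn  # delta included -μΔN; recover pure ΔF
        else:
            dF += delta
    return n_accept, dF, dN
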