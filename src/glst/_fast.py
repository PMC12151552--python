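"""Optional numba-accelerated inner loops.

The far-field passes and the kernel calibration are dominated by sin/cos of
atom-node phases.  These kernels fuse the phase computation, a
double-precision polynomial sincos (octant range reduction; pointwise error
~1e-14, far below every supported threshold) and the accumulations, avoiding
both libm overhead and large numpy temporaries.  Everything here has a pure
numpy equivalent in :mod:`glst.core` / :mod:`glst.cubature`; a test asserts
the two paths agree to 1e-12.  If numba is unavailable the package falls
back to the numpy path transparently.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    import numba

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False


if HAVE_NUMBA:
    _TWO_OVER_PI = 0.6366197723675814
    _PI_OVER_2_HI = 1.5707963267948966
    # residual of pi/2 beyond double precision, for large-phase reduction
    _PI_OVER_2_LO = 6.123233995736766e-17

    @numba.njit(inline="always", fastmath=True)
    def _sincos(x):
        q = np.rint(x * _TWO_OVER_PI)
        r = (x - q * _PI_OVER_2_HI) - q * _PI_OVER_2_LO
        r2 = r * r
        sr = r * (
            1.0
            + r2
            * (
                -0.16666666666666666
                + r2
                * (
                    8.333333333333333e-3
                    + r2
                    * (
                        -1.984126984126984e-4
                        + r2
                        * (
                            2.7557319223985893e-6
                            + r2
                            * (-2.505210838544172e-8 + r2 * 1.605904383682161e-10)
                        )
                    )
                )
            )
        )
        cr = (
            1.0
            + r2
            * (
                -0.5
                + r2
                * (
                    4.166666666666666e-2
                    + r2
                    * (
                        -1.3888888888888887e-3
                        + r2
                        * (
                            2.48015873015873e-5
                            + r2
                            * (-2.7557319223985888e-7 + r2 * 2.08767569878681e-9)
                        )
                    )
                )
            )
        )
        k = int(q) & 3
        if k == 0:
            return sr, cr
        elif k == 1:
            return cr, -sr
        elif k == 2:
            return -sr, -cr
        return -cr, sr

    @numba.njit(fastmath=True)
    def basis_block(pos, q, K):
        """Ca, Sa = q * (cos, sin)(pos . k) for a node block; (N, J)."""
        n = pos.shape[0]
        J = K.shape[0]
        Ca = np.empty((n, J))
        Sa = np.empty((n, J))
        for i in range(n):
            x, y, z = pos[i, 0], pos[i, 1], pos[i, 2]
            qi = q[i]
            for j in range(J):
                ph = x * K[j, 0] + y * K[j, 1] + z * K[j, 2]
                s, c = _sincos(ph)
                Ca[i, j] = qi * c
                Sa[i, j] = qi * s
        return Ca, Sa

    @numba.njit(fastmath=True)
    def energy_force_accum(Ca, Sa, Rc, Rs, cell_of_atom, W, K,
                           energies, forces):
        """energies += (Ca*R_cell_c + Sa*R_cell_s) @ W;
        forces += (Sa*R_cell_c - Ca*R_cell_s) @ (W*K), fused and in place.

        ``Rc``/``Rs`` are per-cell remote sums (n_cells, J); each atom reads
        its own cell's row, so no per-atom copy is materialized."""
        n, J = Ca.shape
        for i in range(n):
            c = cell_of_atom[i]
            e = 0.0
            fx = 0.0
            fy = 0.0
            fz = 0.0
            for j in range(J):
                rc = Rc[c, j]
                rs = Rs[c, j]
                ee = Ca[i, j] * rc + Sa[i, j] * rs
                tt = Sa[i, j] * rc - Ca[i, j] * rs
                w = W[j]
                e += w * ee
                wt = w * tt
                fx += wt * K[j, 0]
                fy += wt * K[j, 1]
                fz += wt * K[j, 2]
            energies[i] += e
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz

    @numba.njit(fastmath=True)
    def weighted_cos_grid(A, w_pts, scales, w_rad, radii):
        """out[r, d] = sum_n w_rad[n] sum_m w_pts[m] cos(scales[n]*radii[r]*A[m, d]).

        The shared evaluation core of the cubature probe grids and the
        product-rule screens (A holds direction cosines point x direction).
        """
        M, D = A.shape
        R = radii.size
        N = scales.size
        out = np.zeros((R, D))
        for n in range(N):
            wn = w_rad[n]
            for r in range(R):
                cs = scales[n] * radii[r]
                for m in range(M):
                    wm = wn * w_pts[m]
                    for d in range(D):
                        s, c = _sincos(cs * A[m, d])
                        out[r, d] += wm * c
        return out

else:  # pragma: no cover

    def basis_block(pos, q, K):
        phase = pos @ K.T
        return np.cos(phase) * q[:, None], np.sin(phase) * q[:, None]

    def energy_force_accum(Ca, Sa, Rc, Rs, cell_of_atom, W, K,
                           energies, forces):
        Rca = Rc[cell_of_atom]
        Rsa = Rs[cell_of_atom]
        energies += (Ca * Rca + Sa * Rsa) @ W
        forces += (Sa * Rca - Ca * Rsa) @ (W[:, None] * K)

    def weighted_cos_grid(A, w_pts, scales, w_rad, radii):
        out = np.zeros((radii.size, A.shape[1]))
        for n in range(scales.size):
            ph = scales[n] * radii[:, None, None] * A[None, :, :]
            out += w_rad[n] * np.einsum("m,rmd->rd", w_pts, np.cos(ph))
        return out
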