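"""Numba-compiled inner loops for the energy function.

The energy terms operate on very small arrays (3 beads x <= 60 residues),
where numpy's per-call overhead dominates; these kernels evaluate the
same expressions in compiled scalar loops.  Falls back to None when numba
is unavailable so the callers can keep a pure-numpy path.
"""
from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency normally
    njit = None


if njit is not None:

    @njit(cache=True, fastmath=False)
    def bonded_kernel(P, C, N,
                      eq_pc, k_pc, eq_cp, k_cp, eq_cn, k_cn,
                      eq_pcp, k_pcp, eq_cpc, k_cpc, eq_pcn, k_pcn,
                      eq_ncp, k_ncp,
                      eq_pcpc, k_pcpc, eq_ncpc, k_ncpc, eq_cpcp, k_cpcp):
        n = P.shape[0]
        U_b = 0.0
        U_a = 0.0
        U_d = 0.0
        for i in range(n):
            # bonds P-C and C-N
            dpc0 = C[i, 0] - P[i, 0]
            dpc1 = C[i, 1] - P[i, 1]
            dpc2 = C[i, 2] - P[i, 2]
            r_pc = np.sqrt(dpc0 * dpc0 + dpc1 * dpc1 + dpc2 * dpc2)
            U_b += k_pc[i] * (r_pc - eq_pc[i]) ** 2
            dcn0 = N[i, 0] - C[i, 0]
            dcn1 = N[i, 1] - C[i, 1]
            dcn2 = N[i, 2] - C[i, 2]
            r_cn = np.sqrt(dcn0 * dcn0 + dcn1 * dcn1 + dcn2 * dcn2)
            U_b += k_cn[i] * (r_cn - eq_cn[i]) ** 2
            # angle P-C-N (center C_i)
            cosv = -(dpc0 * dcn0 + dpc1 * dcn1 + dpc2 * dcn2) / (r_pc * r_cn)
            if cosv > 1.0:
                cosv = 1.0
            elif cosv < -1.0:
                cosv = -1.0
            U_a += k_pcn[i] * (np.arccos(cosv) - eq_pcn[i]) ** 2
            if i + 1 >= n:
                continue
            # bond C_i - P_{i+1}
            dcp0 = P[i + 1, 0] - C[i, 0]
            dcp1 = P[i + 1, 1] - C[i, 1]
            dcp2 = P[i + 1, 2] - C[i, 2]
            r_cp = np.sqrt(dcp0 * dcp0 + dcp1 * dcp1 + dcp2 * dcp2)
            U_b += k_cp[i] * (r_cp - eq_cp[i]) ** 2
            # angle P_i-C_i-P_{i+1}
            cosv = -(dpc0 * dcp0 + dpc1 * dcp1 + dpc2 * dcp2) / (r_pc * r_cp)
            if cosv > 1.0:
                cosv = 1.0
            elif cosv < -1.0:
                cosv = -1.0
            U_a += k_pcp[i] * (np.arccos(cosv) - eq_pcp[i]) ** 2
            # angle N_i-C_i-P_{i+1}
            cosv = (dcn0 * dcp0 + dcn1 * dcp1 + dcn2 * dcp2) / (r_cn * r_cp)
            if cosv > 1.0:
                cosv = 1.0
            elif cosv < -1.0:
                cosv = -1.0
            U_a += k_ncp[i] * (np.arccos(cosv) - eq_ncp[i]) ** 2
            # angle C_i-P_{i+1}-C_{i+1}
            dpc0n = C[i + 1, 0] - P[i + 1, 0]
            dpc1n = C[i + 1, 1] - P[i + 1, 1]
            dpc2n = C[i + 1, 2] - P[i + 1, 2]
            r_pcn = np.sqrt(dpc0n * dpc0n + dpc1n * dpc1n + dpc2n * dpc2n)
            cosv = -(dcp0 * dpc0n + dcp1 * dpc1n + dcp2 * dpc2n) / (r_cp * r_pcn)
            if cosv > 1.0:
                cosv = 1.0
            elif cosv < -1.0:
                cosv = -1.0
            U_a += k_cpc[i + 1] * (np.arccos(cosv) - eq_cpc[i + 1]) ** 2
            # dihedrals about b2 = C_i -> P_{i+1}
            # n2 = b2 x b3, b3 = P_{i+1} -> C_{i+1}
            n2x = dcp1 * dpc2n - dcp2 * dpc1n
            n2y = dcp2 * dpc0n - dcp0 * dpc2n
            n2z = dcp0 * dpc1n - dcp1 * dpc0n
            # PCPC: b1 = P_i -> C_i
            U_d += k_pcpc[i] * (1.0 - np.cos(
                _dihed(dpc0, dpc1, dpc2, dcp0, dcp1, dcp2, r_cp,
                       n2x, n2y, n2z) - eq_pcpc[i]))
            # NCPC: b1 = N_i -> C_i = -dcn
            U_d += k_ncpc[i] * (1.0 - np.cos(
                _dihed(-dcn0, -dcn1, -dcn2, dcp0, dcp1, dcp2, r_cp,
                       n2x, n2y, n2z) - eq_ncpc[i]))
            if i + 2 < n:
                # CPCP: b1 = C_i->P_{i+1} (dcp), b2 = P_{i+1}->C_{i+1}
                # (dpc next), b3 = C_{i+1}->P_{i+2}
                dcp0n = P[i + 2, 0] - C[i + 1, 0]
                dcp1n = P[i + 2, 1] - C[i + 1, 1]
                dcp2n = P[i + 2, 2] - C[i + 1, 2]
                m2x = dpc1n * dcp2n - dpc2n * dcp1n
                m2y = dpc2n * dcp0n - dpc0n * dcp2n
                m2z = dpc0n * dcp1n - dpc1n * dcp0n
                U_d += k_cpcp[i + 1] * (1.0 - np.cos(
                    _dihed(dcp0, dcp1, dcp2, dpc0n, dpc1n, dpc2n, r_pcn,
                           m2x, m2y, m2z) - eq_cpcp[i + 1]))
        return U_b, U_a, U_d

    @njit(cache=True, inline="always")
    def _dihed(b1x, b1y, b1z, b2x, b2y, b2z, r2, n2x, n2y, n2z):
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        mx = (n1y * b2z - n1z * b2y) / r2
        my = (n1z * b2x - n1x * b2z) / r2
        mz = (n1x * b2y - n1y * b2x) / r2
        x = n1x * n2x + n1y * n2y + n1z * n2z
        y = mx * n2x + my * n2y + mz * n2z
        return np.arctan2(y, x)

    @njit(cache=True)
    def excluded_kernel(pos, idx_i, idx_j, sigma, eps):
        U = 0.0
        for k in range(idx_i.shape[0]):
            a = idx_i[k]
            b = idx_j[k]
            dx = pos[a, 0] - pos[b, 0]
            dy = pos[a, 1] - pos[b, 1]
            dz = pos[a, 2] - pos[b, 2]
            d2 = dx * dx + dy * dy + dz * dz
            s2 = sigma[k] * sigma[k]
            if d2 < s2:
                x = (s2 / d2) ** 3
                U += eps * (x * x - 2.0 * x + 1.0)
        return U

    @njit(cache=True)
    def screened_coulomb_kernel(P, min_sep, prefactor, lam):
        n = P.shape[0]
        U = 0.0
        for i in range(n):
            for j in range(i + min_sep, n):
                dx = P[i, 0] - P[j, 0]
                dy = P[i, 1] - P[j, 1]
                dz = P[i, 2] - P[j, 2]
                d = np.sqrt(dx * dx + dy * dy + dz * dz)
                U += np.exp(-d / lam) / d
        return prefactor * U

else:  # pragma: no cover
    bonded_kernel = None
    excluded_kernel = None
    screened_coulomb_kernel = None
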