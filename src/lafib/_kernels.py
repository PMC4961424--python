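"""Vectorized tissue integration kernel.

The monodomain step couples the surface Laplacian (CSR matrix, units 1/mm^2)
to the ionic model.  To keep multi-second runs tractable on one CPU, all
voltage-dependent gate steady states, Rush-Larsen factors and current factors
are tabulated on a 0.05-mV grid and linearly interpolated; reversal
potentials and the Na-pump saturation term are refreshed on a coarser
schedule (default every 0.5 ms) since the concentrations they depend on move
on a timescale of seconds.  Accuracy against the exact-formula integrator is
covered by tests.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ._crn import (
    gate_inf_tau, v_factors, N_VGATE, VGATE_STATE_IDX,
    RTF, CM, FARADAY, V_I, V_UP, V_REL,
    G_NA, G_KR, G_KS, G_B_NA, G_B_CA,
    I_NAK_MAX, KM_NAI, KM_KO, KO, NAO, CAO,
    I_NACA_MAX, KM_NA, KM_CA, K_SAT, I_PCA_MAX,
    K_REL, I_UP_MAX, K_UP, CA_UP_MAX,
    CMDN_MAX, TRPN_MAX, CSQN_MAX, KM_CMDN, KM_TRPN, KM_CSQN,
    TAU_TR, TAU_F_CA, TAU_U,
    IV, IM, IH, IJ, IOA, IOI, IUA, IUI, IXR, IXS,
    ID, IF, IFCA, IU, IVG, IW, INAI, IKI, ICAI, ICAUP, ICAREL,
)

V_MIN = -120.0
V_MAX = 80.0
DV_TAB = 0.1
N_TAB = int(round((V_MAX - V_MIN) / DV_TAB)) + 1

X_MIN = -60.0
X_MAX = 60.0
DX_SIG = 0.02
N_SIG = int(round((X_MAX - X_MIN) / DX_SIG)) + 1

_KO_FRAC = KO / (KO + KM_KO)
_NACA_DEN = (KM_NA ** 3 + NAO ** 3) * (KM_CA + CAO)


@njit(cache=True)
def _fill_tables(vgrid, dt, tab):
    g = np.empty((N_VGATE, 2))
    vf = np.empty(6)
    for r in range(vgrid.shape[0]):
        gate_inf_tau(vgrid[r], g)
        for k in range(N_VGATE):
            tab[r, 2 * k] = g[k, 0]
            tab[r, 2 * k + 1] = math.exp(-dt / g[k, 1])
        v_factors(vgrid[r], vf)
        for k in range(6):
            tab[r, 24 + k] = vf[k]
        # precomputed Na/Ca exchanger denominator reciprocal
        tab[r, 30] = 1.0 / (_NACA_DEN * (1.0 + K_SAT * vf[5]))


_table_cache: dict[float, np.ndarray] = {}
_sig_cache: list[np.ndarray] = []


def voltage_tables(dt: float) -> np.ndarray:
    """(N_TAB, 30) lookup table for step size ``dt`` (cached)."""
    key = round(float(dt), 9)
    if key not in _table_cache:
        vgrid = V_MIN + DV_TAB * np.arange(N_TAB)
        tab = np.empty((N_TAB, 31))
        _fill_tables(vgrid, key, tab)
        # float32 keeps the whole table L2-resident (the lookup rows are
        # effectively random during fibrillation)
        _table_cache[key] = tab.astype(np.float32)
    return _table_cache[key]


def sigmoid_table() -> np.ndarray:
    """(N_SIG, 2): logistic sigmoid and 1/tau_v of the SR release gate."""
    if not _sig_cache:
        x = X_MIN + DX_SIG * np.arange(N_SIG)
        sig = 1.0 / (1.0 + np.exp(-x))
        _sig_cache.append(np.column_stack(
            [sig, 1.0 / (1.91 + 2.09 * sig)]).astype(np.float32))
    return _sig_cache[0]


@njit(cache=True)
def _refresh_slow(S, conducting, e_na, e_k, e_ca, fnak_nai):
    for i in range(S.shape[0]):
        if conducting[i]:
            e_na[i] = RTF * math.log(NAO / S[i, INAI])
            e_k[i] = RTF * math.log(KO / S[i, IKI])
            e_ca[i] = 0.5 * RTF * math.log(CAO / S[i, ICAI])
            fnak_nai[i] = 1.0 / (1.0 + (KM_NAI / S[i, INAI]) ** 1.5)


@njit(cache=True, fastmath=True)
def run_chunk(S, Vbuf, conducting,
              indptr, indices, wdata, diff_d,
              tab, sig_tab,
              s_to, s_kur, s_cal, s_k1, s_kr, s_ks,
              dt, t0,
              stim_nodes, stim_ptr, stim_on, stim_off, stim_amp,
              sample_every, v_samples,
              lap, istim, e_na, e_k, e_ca, fnak_nai,
              refresh_every):
    """Advance the tissue by ``v_samples.shape[0] * sample_every`` steps.

    ``S`` is the (n, 21) state array; ``Vbuf`` a contiguous copy of S[:, 0]
    kept in sync.  ``v_samples`` (n_samples, n, float32) receives V after
    every ``sample_every`` steps.  Returns the 1-based step index at which
    |V| exceeded 300 mV, or 0 on success.
    """
    n = S.shape[0]
    n_steps = v_samples.shape[0] * sample_every
    n_ev = stim_on.shape[0]
    fca_rl = math.exp(-dt / TAU_F_CA)
    u_rl = math.exp(-dt / TAU_U)
    conv = CM / (FARADAY * V_I)
    conv_ca = CM / (2.0 * FARADAY * V_I)
    had_stim = True  # force istim build on first step
    for step in range(n_steps):
        t = t0 + step * dt
        if step % refresh_every == 0:
            _refresh_slow(S, conducting, e_na, e_k, e_ca, fnak_nai)
        # stimulus currents
        any_stim = False
        for e in range(n_ev):
            if stim_on[e] - 1e-9 <= t < stim_off[e] - 1e-9:
                any_stim = True
                break
        if any_stim or had_stim:
            for i in range(n):
                istim[i] = 0.0
            for e in range(n_ev):
                if stim_on[e] - 1e-9 <= t < stim_off[e] - 1e-9:
                    for q in range(stim_ptr[e], stim_ptr[e + 1]):
                        istim[stim_nodes[q]] = stim_amp[e]
        had_stim = any_stim
        # diffusion term from the pre-step voltage field
        for i in range(n):
            acc = 0.0
            for q in range(indptr[i], indptr[i + 1]):
                acc += wdata[q] * Vbuf[indices[q]]
            lap[i] = acc
        # reaction update per conducting node
        for i in range(n):
            if not conducting[i]:
                continue
            v = Vbuf[i]
            pos = (v - V_MIN) * (1.0 / DV_TAB)
            if pos < 0.0:
                pos = 0.0
            elif pos > N_TAB - 2:
                pos = float(N_TAB - 2)
            k0 = int(pos)
            fr = pos - k0
            m = S[i, IM]; hh = S[i, IH]; jj = S[i, IJ]
            oa = S[i, IOA]; oi = S[i, IOI]; ua = S[i, IUA]; ui = S[i, IUI]
            xr = S[i, IXR]; xs = S[i, IXS]
            dd = S[i, ID]; ff = S[i, IF]; fca = S[i, IFCA]
            uu = S[i, IU]; vv = S[i, IVG]; ww = S[i, IW]
            nai = S[i, INAI]; cai = S[i, ICAI]
            fk1 = tab[k0, 24] + (tab[k0 + 1, 24] - tab[k0, 24]) * fr
            fkr = tab[k0, 25] + (tab[k0 + 1, 25] - tab[k0, 25]) * fr
            gkur = tab[k0, 26] + (tab[k0 + 1, 26] - tab[k0, 26]) * fr
            fnak = tab[k0, 27] + (tab[k0 + 1, 27] - tab[k0, 27]) * fr
            e1 = tab[k0, 28] + (tab[k0 + 1, 28] - tab[k0, 28]) * fr
            e2 = tab[k0, 29] + (tab[k0 + 1, 29] - tab[k0, 29]) * fr

            i_na = G_NA * m * m * m * hh * jj * (v - e_na[i])
            i_k1 = s_k1 * 0.09 * (v - e_k[i]) * fk1
            i_to = s_to * 0.1652 * oa * oa * oa * oi * (v - e_k[i])
            i_kur = s_kur * gkur * ua * ua * ua * ui * (v - e_k[i])
            i_kr = s_kr * G_KR * xr * (v - e_k[i]) * fkr
            i_ks = s_ks * G_KS * xs * xs * (v - e_k[i])
            i_cal = s_cal * 0.12375 * dd * ff * fca * (v - 65.0)
            i_nak = I_NAK_MAX * fnak * _KO_FRAC * fnak_nai[i]
            inv_den = tab[k0, 30] + (tab[k0 + 1, 30] - tab[k0, 30]) * fr
            i_naca = (I_NACA_MAX * (e1 * nai * nai * nai * CAO
                                    - e2 * NAO * NAO * NAO * cai) * inv_den)
            i_bna = G_B_NA * (v - e_na[i])
            i_bca = G_B_CA * (v - e_ca[i])
            # Cai-dependent fractions via one combined reciprocal
            ca_p = cai + 0.0005          # IpCa Km
            ca_u = cai + K_UP
            ca_f = cai + 0.00035         # f_Ca Km
            rcp = 1.0 / (ca_p * ca_u * ca_f)
            i_pca = I_PCA_MAX * cai * ca_u * ca_f * rcp
            i_ion = (i_na + i_k1 + i_to + i_kur + i_kr + i_ks + i_cal
                     + i_nak + i_naca + i_bna + i_bca + i_pca)

            i_rel = K_REL * uu * uu * vv * ww * (S[i, ICAREL] - cai)
            i_tr = (S[i, ICAUP] - S[i, ICAREL]) * (1.0 / TAU_TR)
            i_up = I_UP_MAX * cai * ca_p * ca_f * rcp
            i_up_leak = I_UP_MAX * S[i, ICAUP] * (1.0 / CA_UP_MAX)
            fn = (1e-12 * V_REL * i_rel
                  - (5e-13 / FARADAY) * (0.5 * i_cal * CM - 0.2 * i_naca * CM))

            # gate updates (Rush-Larsen via tables, unrolled)
            inf = tab[k0, 0] + (tab[k0 + 1, 0] - tab[k0, 0]) * fr
            rl = tab[k0, 1] + (tab[k0 + 1, 1] - tab[k0, 1]) * fr
            S[i, IM] = inf + (m - inf) * rl
            inf = tab[k0, 2] + (tab[k0 + 1, 2] - tab[k0, 2]) * fr
            rl = tab[k0, 3] + (tab[k0 + 1, 3] - tab[k0, 3]) * fr
            S[i, IH] = inf + (hh - inf) * rl
            inf = tab[k0, 4] + (tab[k0 + 1, 4] - tab[k0, 4]) * fr
            rl = tab[k0, 5] + (tab[k0 + 1, 5] - tab[k0, 5]) * fr
            S[i, IJ] = inf + (jj - inf) * rl
            inf = tab[k0, 6] + (tab[k0 + 1, 6] - tab[k0, 6]) * fr
            rl = tab[k0, 7] + (tab[k0 + 1, 7] - tab[k0, 7]) * fr
            S[i, IOA] = inf + (oa - inf) * rl
            inf = tab[k0, 8] + (tab[k0 + 1, 8] - tab[k0, 8]) * fr
            rl = tab[k0, 9] + (tab[k0 + 1, 9] - tab[k0, 9]) * fr
            S[i, IOI] = inf + (oi - inf) * rl
            inf = tab[k0, 10] + (tab[k0 + 1, 10] - tab[k0, 10]) * fr
            rl = tab[k0, 11] + (tab[k0 + 1, 11] - tab[k0, 11]) * fr
            S[i, IUA] = inf + (ua - inf) * rl
            inf = tab[k0, 12] + (tab[k0 + 1, 12] - tab[k0, 12]) * fr
            rl = tab[k0, 13] + (tab[k0 + 1, 13] - tab[k0, 13]) * fr
            S[i, IUI] = inf + (ui - inf) * rl
            inf = tab[k0, 14] + (tab[k0 + 1, 14] - tab[k0, 14]) * fr
            rl = tab[k0, 15] + (tab[k0 + 1, 15] - tab[k0, 15]) * fr
            S[i, IXR] = inf + (xr - inf) * rl
            inf = tab[k0, 16] + (tab[k0 + 1, 16] - tab[k0, 16]) * fr
            rl = tab[k0, 17] + (tab[k0 + 1, 17] - tab[k0, 17]) * fr
            S[i, IXS] = inf + (xs - inf) * rl
            inf = tab[k0, 18] + (tab[k0 + 1, 18] - tab[k0, 18]) * fr
            rl = tab[k0, 19] + (tab[k0 + 1, 19] - tab[k0, 19]) * fr
            S[i, ID] = inf + (dd - inf) * rl
            inf = tab[k0, 20] + (tab[k0 + 1, 20] - tab[k0, 20]) * fr
            rl = tab[k0, 21] + (tab[k0 + 1, 21] - tab[k0, 21]) * fr
            S[i, IF] = inf + (ff - inf) * rl
            inf = tab[k0, 22] + (tab[k0 + 1, 22] - tab[k0, 22]) * fr
            rl = tab[k0, 23] + (tab[k0 + 1, 23] - tab[k0, 23]) * fr
            S[i, IW] = inf + (ww - inf) * rl

            xu = (fn - 3.4175e-13) * (1.0 / 13.67e-16)
            pu = (xu - X_MIN) * (1.0 / DX_SIG)
            if pu < 0.0:
                pu = 0.0
            elif pu > N_SIG - 2:
                pu = float(N_SIG - 2)
            ku = int(pu)
            sig_u = (sig_tab[ku, 0]
                     + (sig_tab[ku + 1, 0] - sig_tab[ku, 0]) * (pu - ku))
            inv_tau_v = (sig_tab[ku, 1]
                         + (sig_tab[ku + 1, 1] - sig_tab[ku, 1]) * (pu - ku))
            xv = (fn - 6.835e-14) * (1.0 / 13.67e-16)
            pv = (xv - X_MIN) * (1.0 / DX_SIG)
            if pv < 0.0:
                pv = 0.0
            elif pv > N_SIG - 2:
                pv = float(N_SIG - 2)
            kv = int(pv)
            v_inf = 1.0 - (sig_tab[kv, 0]
                           + (sig_tab[kv + 1, 0] - sig_tab[kv, 0]) * (pv - kv))
            f_ca_inf = 0.00035 * ca_p * ca_u * rcp
            S[i, IU] = sig_u + (uu - sig_u) * u_rl
            S[i, IVG] = vv + dt * (v_inf - vv) * inv_tau_v
            S[i, IFCA] = f_ca_inf + (fca - f_ca_inf) * fca_rl

            # concentrations
            S[i, INAI] = nai - dt * (3.0 * i_nak + 3.0 * i_naca + i_bna + i_na) * conv
            S[i, IKI] += dt * (2.0 * i_nak - i_k1 - i_to - i_kur - i_kr - i_ks) * conv
            b1 = ((2.0 * i_naca - i_pca - i_cal - i_bca) * conv_ca
                  + (V_UP * (i_up_leak - i_up) + i_rel * V_REL) * (1.0 / V_I))
            # buffering factor with a single division:
            # b2 = 1 + A/p^2 + B/q^2  ->  dCai = b1 p^2 q^2 / (p^2q^2 + Aq^2 + Bp^2)
            pb = cai + KM_TRPN
            qb = cai + KM_CMDN
            p2 = pb * pb
            q2 = qb * qb
            S[i, ICAI] = cai + dt * b1 * p2 * q2 / (
                p2 * q2 + TRPN_MAX * KM_TRPN * q2 + CMDN_MAX * KM_CMDN * p2)
            S[i, ICAUP] += dt * (i_up - i_up_leak - i_tr * (V_REL / V_UP))
            crel = S[i, ICAREL] + KM_CSQN
            c2 = crel * crel
            S[i, ICAREL] += dt * (i_tr - i_rel) * c2 / (
                c2 + CSQN_MAX * KM_CSQN)

            v_new = v + dt * (diff_d * lap[i] - i_ion - istim[i])
            Vbuf[i] = v_new
            if abs(v_new) > 300.0:
                return step + 1
        if (step + 1) % sample_every == 0:
            row = (step + 1) // sample_every - 1
            for i in range(n):
                v_samples[row, i] = Vbuf[i]
    for i in range(n):
        S[i, IV] = Vbuf[i]
    return 0
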