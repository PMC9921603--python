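"""Jitted numerical kernels: forward dynamics integration and DTW.

The formulas here mirror the reference NumPy implementations in
:mod:`elbowstiff.hill` and :mod:`elbowstiff.dynamics`; the test suite asserts
that the recorded torque components of a simulation agree with the reference
functions evaluated at the recorded states.

Parameter vector layout (canonical order, see ``parameters.PARAM_NAMES``)::

    0 F_max  1 w      2 l_mopt 3 a_f   4 v_max
    5 k_te   6 k_tl   7 k_t    8 l_tc  9 l_ts
    10 k_ml  11 k_me  12 k_m   13 l_mc 14 l_ms
    15 B_m   16 M_m
    17 k_1   18 k_2   19 k_4   20 k_5  21 q_1  22 q_2  23 B_p

Segment array layout::

    0 m  1 r_cm  2 M  3 r_p  4 g  5 load_mass  6 load_arm
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by simulate_kernel
OK = 0
NONFINITE = 1
ANGLE_GUARD = 2
NEGATIVE_TENDON = 3

# recorded columns
COLS = (
    "q", "q_dot", "tau_p", "tau_d", "tau_G", "tau_AG", "tau_ANT", "tau_J",
    "lm_ag", "vm_ag", "lt_ag", "lm_ant", "vm_ant", "lt_ant",
)


@njit(cache=True)
def _toe_linear(x, slack, onset, k_toe, k_shape, k_lin):
    if x < slack:
        return 0.0
    ratio = k_toe / k_shape
    if x <= onset:
        return ratio * (np.exp(k_shape * (x - slack)) - 1.0)
    f_onset = ratio * (np.exp(k_shape * (onset - slack)) - 1.0)
    return f_onset + k_lin * (x - onset)


@njit(cache=True)
def _fv(v_short, vmax, af, ecc_limit):
    v = v_short / vmax
    if v >= 1.0:
        return 0.0
    den = 1.0 + v / af
    if den <= 0.0:
        return ecc_limit
    g = (1.0 - v) / den
    if g > ecc_limit:
        return ecc_limit
    if g < 0.0:
        return 0.0
    return g


@njit(cache=True)
def _eval(y, a_f, a_e, th, seg, mu, gravity_on, ecc_limit, out):
    """Derivatives + torque components at state y = (q, qd, lmf, vmf, lme, vme).

    Writes 6 derivatives into out[0:6] and
    (tau_p, tau_d, tau_G, tau_ag, tau_ant, tau_J, lt_f, lt_e) into out[6:14].
    """
    q = y[0]
    qd = y[1]
    lmf = y[2]
    vmf = y[3]
    lme = y[4]
    vme = y[5]

    rp = seg[3]
    meff = seg[2] + seg[5] * seg[6] * seg[6]

    # flexor (agonist): moment-arm sign -1; extensor (antagonist): +1
    lt_f = th[14] + th[9] - rp * q - lmf
    lt_e = th[14] + th[9] + rp * q - lme

    fse_f = _toe_linear(lt_f, th[9], th[8], th[6], th[5], th[7])
    fse_e = _toe_linear(lt_e, th[9], th[8], th[6], th[5], th[7])

    flw = np.exp(-(((lmf / th[2]) - 1.0) / th[1]) ** 2)
    fle = np.exp(-(((lme / th[2]) - 1.0) / th[1]) ** 2)
    fce_f = th[0] * a_f * flw * _fv(-vmf, th[4], th[3], ecc_limit)
    fce_e = th[0] * a_e * fle * _fv(-vme, th[4], th[3], ecc_limit)

    fpe_f = _toe_linear(lmf, th[14], th[13], th[10], th[11], th[12]) + th[15] * vmf
    fpe_e = _toe_linear(lme, th[14], th[13], th[10], th[11], th[12]) + th[15] * vme

    dvmf = (fse_f - fce_f - fpe_f) / th[16]
    dvme = (fse_e - fce_e - fpe_e) / th[16]

    tau_ag = fse_f * rp
    tau_ant = fse_e * rp
    tau_p = th[17] * np.exp(-th[18] * (q - th[22])) - th[19] * np.exp(-th[20] * (th[21] - q))
    tau_d = -th[23] * qd
    tau_g = gravity_on * seg[0] * seg[4] * seg[1] * np.sin(np.pi / 2.0 - q)
    tau_j = tau_p + tau_d + tau_g + mu * (tau_ag - tau_ant)

    out[0] = qd
    out[1] = tau_j / meff
    out[2] = vmf
    out[3] = dvmf
    out[4] = vme
    out[5] = dvme
    out[6] = tau_p
    out[7] = tau_d
    out[8] = tau_g
    out[9] = tau_ag
    out[10] = tau_ant
    out[11] = tau_j
    out[12] = lt_f
    out[13] = lt_e


@njit(cache=True)
def simulate_kernel(th, seg, mu, gravity_on, q_guard, ecc_limit, integrator,
                    a_ag, a_ant, dt_out, n_sub, lm0_ag, lm0_ant):
    """Fixed-step integration of the two-muscle elbow on the activation grid.

    Activations are linearly interpolated over the ``n_sub`` substeps of each
    output interval.  Returns (record, status, bad_index) where record has one
    row per activation sample and the columns of ``COLS``.
    """
    n = a_ag.shape[0]
    rec = np.empty((n, 14))
    y = np.empty(6)
    y[0] = 0.0
    y[1] = 0.0
    y[2] = lm0_ag
    y[3] = 0.0
    y[4] = lm0_ant
    y[5] = 0.0

    scratch = np.empty(14)
    k1 = np.empty(6)
    k2 = np.empty(6)
    k3 = np.empty(6)
    k4 = np.empty(6)
    yt = np.empty(6)

    _eval(y, a_ag[0], a_ant[0], th, seg, mu, gravity_on, ecc_limit, scratch)
    rec[0, 0] = y[0]
    rec[0, 1] = y[1]
    for c in range(6):
        rec[0, 2 + c] = scratch[6 + c]
    rec[0, 8] = y[2]
    rec[0, 9] = y[3]
    rec[0, 10] = scratch[12]
    rec[0, 11] = y[4]
    rec[0, 12] = y[5]
    rec[0, 13] = scratch[13]

    h = dt_out / n_sub
    status = OK
    bad = -1
    for i in range(n - 1):
        a0f = a_ag[i]
        a1f = a_ag[i + 1]
        a0e = a_ant[i]
        a1e = a_ant[i + 1]
        for j in range(n_sub):
            f0 = j / n_sub
            fm = (j + 0.5) / n_sub
            f1 = (j + 1.0) / n_sub
            af0 = a0f + (a1f - a0f) * f0
            afm = a0f + (a1f - a0f) * fm
            af1 = a0f + (a1f - a0f) * f1
            ae0 = a0e + (a1e - a0e) * f0
            aem = a0e + (a1e - a0e) * fm
            ae1 = a0e + (a1e - a0e) * f1
            if integrator == 0:
                _eval(y, af0, ae0, th, seg, mu, gravity_on, ecc_limit, scratch)
                for s in range(6):
                    k1[s] = scratch[s]
                    yt[s] = y[s] + 0.5 * h * k1[s]
                _eval(yt, afm, aem, th, seg, mu, gravity_on, ecc_limit, scratch)
                for s in range(6):
                    k2[s] = scratch[s]
                    yt[s] = y[s] + 0.5 * h * k2[s]
                _eval(yt, afm, aem, th, seg, mu, gravity_on, ecc_limit, scratch)
                for s in range(6):
                    k3[s] = scratch[s]
                    yt[s] = y[s] + h * k3[s]
                _eval(yt, af1, ae1, th, seg, mu, gravity_on, ecc_limit, scratch)
                for s in range(6):
                    k4[s] = scratch[s]
                    y[s] = y[s] + (h / 6.0) * (k1[s] + 2.0 * k2[s] + 2.0 * k3[s] + k4[s])
            else:
                _eval(y, af0, ae0, th, seg, mu, gravity_on, ecc_limit, scratch)
                for s in range(6):
                    y[s] = y[s] + h * scratch[s]

        _eval(y, a1f, a1e, th, seg, mu, gravity_on, ecc_limit, scratch)
        ok = True
        for s in range(6):
            if not np.isfinite(y[s]):
                status = NONFINITE
                ok = False
        if ok and (y[0] > q_guard or y[0] < -q_guard):
            status = ANGLE_GUARD
            ok = False
        if ok and (scratch[12] < 0.0 or scratch[13] < 0.0):
            status = NEGATIVE_TENDON
            ok = False
        rec[i + 1, 0] = y[0]
        rec[i + 1, 1] = y[1]
        for c in range(6):
            rec[i + 1, 2 + c] = scratch[6 + c]
        rec[i + 1, 8] = y[2]
        rec[i + 1, 9] = y[3]
        rec[i + 1, 10] = scratch[12]
        rec[i + 1, 11] = y[4]
        rec[i + 1, 12] = y[5]
        rec[i + 1, 13] = scratch[13]
        if not ok:
            bad = i + 1
            for r in range(i + 2, n):
                for c in range(14):
                    rec[r, c] = np.nan
            break
    return rec, status, bad


@njit(cache=True)
def dtw_cost(x, y):
    """Accumulated optimal-path DTW cost with |xi - yj| local cost.

    Symmetric step pattern (diagonal, vertical, horizontal), no window.
    Memory O(m) via two rolling rows.
    """
    n = x.shape[0]
    m = y.shape[0]
    prev = np.empty(m)
    cur = np.empty(m)
    prev[0] = abs(x[0] - y[0])
    for j in range(1, m):
        prev[j] = prev[j - 1] + abs(x[0] - y[j])
    for i in range(1, n):
        cur[0] = prev[0] + abs(x[i] - y[0])
        for j in range(1, m):
            d = abs(x[i] - y[j])
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = d + best
        for j in range(m):
            prev[j] = cur[j]
    return prev[m - 1]
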