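"""Numba-compiled integrators for the gap-junction coupled MN network.

The parameter vector layout matches ``MNParameters.to_vector()``:

    0 C_m, 1 g_L, 2 E_L, 3 g_Na, 4 E_Na, 5 g_shab, 6 E_K,
    7 v_half_m, 8 v_half_h, 9 v_half_b, 10 z_m, 11 z_h, 12 z_b,
    13 tau_b_amp, 14 tau_b_min, 15 tau_h_amp, 16 tau_h_min, 17 Q,
    18 zt_b (tau_b bell width charge; 0 -> z_b), 19 zt_h (0 -> z_h)

Units: mV, ms, pA, pF, nS.  Noise strength sigma is in pA*sqrt(ms); the
stochastic (Heun) scheme applies the same Wiener increment in the predictor
and corrector stage.  Spikes are detected online as upward 0 mV crossings
with a 2 ms refractory window and linear interpolation of the crossing time.
"""

import numpy as np
from numba import njit

METHOD_HEUN = 0
METHOD_RK4 = 1

SPIKE_THRESH = 0.0   # mV
REFRACTORY = 2.0     # ms
BLOWUP_MV = 200.0


@njit(cache=True, fastmath=True)
def _derivs(p, G, I_ext, v, b, h, dv, db, dh):
    n = v.shape[0]
    C_m = p[0]; g_L = p[1]; E_L = p[2]; g_Na = p[3]; E_Na = p[4]
    g_shab = p[5]; E_K = p[6]
    vm = p[7]; vh = p[8]; vb = p[9]
    zm = p[10]; zh = p[11]; zb = p[12]
    tba = p[13]; tbm = p[14]; tha = p[15]; thm = p[16]; q = p[17]
    ztb = p[18] if p[18] > 0.0 else zb
    zth = p[19] if p[19] > 0.0 else zh
    for i in range(n):
        vi = v[i]
        m_inf = 1.0 / (1.0 + np.exp(-zm * q * (vi - vm)))
        h_inf = 1.0 / (1.0 + np.exp(-zh * q * (vi - vh)))
        b_inf = 1.0 / (1.0 + np.exp(-zb * q * (vi - vb)))
        tau_b = tbm + tba / np.cosh(ztb * q * (vi - vb) * 0.5)
        tau_h = thm + tha / np.cosh(zth * q * (vi - vh) * 0.5)
        i_l = g_L * (vi - E_L)
        bb = b[i] * b[i]
        i_shab = g_shab * bb * bb * (vi - E_K)
        i_na = g_Na * m_inf * m_inf * m_inf * (1.0 - h[i]) * (vi - E_Na)
        i_gap = 0.0
        for j in range(n):
            if j != i:
                i_gap += G[i, j] * (v[j] - vi)
        dv[i] = (I_ext[i] - i_l - i_shab - i_na + i_gap) / C_m
        db[i] = (b_inf - b[i]) / tau_b
        dh[i] = (h_inf - h[i]) / tau_h


@njit(cache=True, fastmath=True)
def integrate(p, G, I_ext, v0, b0, h0, dt, n_steps, sigma, seed, method,
              record_stride):
    """Integrate the N-neuron network for ``n_steps`` steps of ``dt`` ms.

    Returns (spike_times, spike_counts, v, b, h, recorded_v, fail_step);
    ``fail_step`` is -1 on success, else the step index where |v| exceeded
    200 mV.  ``recorded_v`` has shape (n_rec, N, 3) with columns (v, b, h)
    when ``record_stride > 0``, else shape (0, N, 3).
    """
    n = v0.shape[0]
    v = v0.copy(); b = b0.copy(); h = h0.copy()
    dv1 = np.empty(n); db1 = np.empty(n); dh1 = np.empty(n)
    dv2 = np.empty(n); db2 = np.empty(n); dh2 = np.empty(n)
    dv3 = np.empty(n); db3 = np.empty(n); dh3 = np.empty(n)
    dv4 = np.empty(n); db4 = np.empty(n); dh4 = np.empty(n)
    vt = np.empty(n); bt = np.empty(n); ht = np.empty(n)
    xi = np.zeros(n)

    max_spikes = int(n_steps * dt * 0.5) + 32  # caps at 500 Hz per neuron
    spikes = np.zeros((n, max_spikes))
    counts = np.zeros(n, dtype=np.int64)
    last_spike = np.full(n, -1e9)

    if record_stride > 0:
        n_rec = n_steps // record_stride + 1
    else:
        n_rec = 0
    rec = np.zeros((n_rec, n, 3))
    if n_rec > 0:
        for i in range(n):
            rec[0, i, 0] = v[i]; rec[0, i, 1] = b[i]; rec[0, i, 2] = h[i]
    rec_k = 1

    if sigma > 0.0:
        np.random.seed(seed)
    noise_amp = sigma * np.sqrt(dt) / p[0]  # direct voltage increment, mV

    for step in range(n_steps):
        t = step * dt
        if method == METHOD_HEUN:
            if sigma > 0.0:
                for i in range(n):
                    xi[i] = noise_amp * np.random.standard_normal()
            _derivs(p, G, I_ext, v, b, h, dv1, db1, dh1)
            for i in range(n):
                vt[i] = v[i] + dt * dv1[i] + xi[i]
                bt[i] = b[i] + dt * db1[i]
                ht[i] = h[i] + dt * dh1[i]
            _derivs(p, G, I_ext, vt, bt, ht, dv2, db2, dh2)
            for i in range(n):
                vold = v[i]
                v[i] = v[i] + 0.5 * dt * (dv1[i] + dv2[i]) + xi[i]
                b[i] = b[i] + 0.5 * dt * (db1[i] + db2[i])
                h[i] = h[i] + 0.5 * dt * (dh1[i] + dh2[i])
                if vold < SPIKE_THRESH and v[i] >= SPIKE_THRESH:
                    if t - last_spike[i] > REFRACTORY:
                        ts = t + dt * (SPIKE_THRESH - vold) / (v[i] - vold)
                        if counts[i] < max_spikes:
                            spikes[i, counts[i]] = ts
                            counts[i] += 1
                        last_spike[i] = ts
        else:  # RK4
            _derivs(p, G, I_ext, v, b, h, dv1, db1, dh1)
            for i in range(n):
                vt[i] = v[i] + 0.5 * dt * dv1[i]
                bt[i] = b[i] + 0.5 * dt * db1[i]
                ht[i] = h[i] + 0.5 * dt * dh1[i]
            _derivs(p, G, I_ext, vt, bt, ht, dv2, db2, dh2)
            for i in range(n):
                vt[i] = v[i] + 0.5 * dt * dv2[i]
                bt[i] = b[i] + 0.5 * dt * db2[i]
                ht[i] = h[i] + 0.5 * dt * dh2[i]
            _derivs(p, G, I_ext, vt, bt, ht, dv3, db3, dh3)
            for i in range(n):
                vt[i] = v[i] + dt * dv3[i]
                bt[i] = b[i] + dt * db3[i]
                ht[i] = h[i] + dt * dh3[i]
            _derivs(p, G, I_ext, vt, bt, ht, dv4, db4, dh4)
            for i in range(n):
                vold = v[i]
                v[i] = v[i] + dt / 6.0 * (dv1[i] + 2 * dv2[i] + 2 * dv3[i] + dv4[i])
                b[i] = b[i] + dt / 6.0 * (db1[i] + 2 * db2[i] + 2 * db3[i] + db4[i])
                h[i] = h[i] + dt / 6.0 * (dh1[i] + 2 * dh2[i] + 2 * dh3[i] + dh4[i])
                if vold < SPIKE_THRESH and v[i] >= SPIKE_THRESH:
                    if t - last_spike[i] > REFRACTORY:
                        ts = t + dt * (SPIKE_THRESH - vold) / (v[i] - vold)
                        if counts[i] < max_spikes:
                            spikes[i, counts[i]] = ts
                            counts[i] += 1
                        last_spike[i] = ts

        for i in range(n):
            if np.abs(v[i]) > BLOWUP_MV:
                return spikes, counts, v, b, h, rec, step
        if record_stride > 0 and (step + 1) % record_stride == 0 and rec_k < n_rec:
            for i in range(n):
                rec[rec_k, i, 0] = v[i]; rec[rec_k, i, 1] = b[i]; rec[rec_k, i, 2] = h[i]
            rec_k += 1

    return spikes, counts, v, b, h, rec, -1
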