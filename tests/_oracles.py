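"""Independent brute-force oracles for the forward signal model.

These deliberately avoid the package's matrix-exponential code path: the
steady state is found by explicit time-stepping of the coupled
longitudinal ODEs over many TRs, and pulse power by dense numerical
integration of the envelope.
"""

import numpy as np
from scipy.integrate import solve_ivp

from mpfmap.model import saturation_rates


def ode_steady_state_signal(f, r1, protocol, constraints, pd=1.0,
                            max_tr=2000, rel_tol=1e-10):
    """Periodic steady-state signal by time-stepping integration."""
    tr = protocol.repetition_time
    alpha = np.radians(protocol.excitation_flip_angle)
    rr = constraints.cross_relaxation_rate
    kf, kb = rr * f, rr * (1 - f)
    b = np.array([r1 * (1 - f) * pd, r1 * f * pd])
    if protocol.mt_pulse is not None:
        tm = protocol.mt_pulse.duration
        wf, wb = saturation_rates(protocol.mt_pulse, constraints, r1)
    else:
        tm, wf, wb = 0.0, 0.0, 0.0
    a_free = np.array([[-(r1 + kf), kb], [kf, -(r1 + kb)]])
    a_sat = a_free - np.diag([wf, wb])

    m = np.array([(1 - f) * pd, f * pd])
    m_plus = m
    prev = None
    for _ in range(max_tr):
        if tm > 0:
            sol = solve_ivp(lambda t, y: a_sat @ y + b, (0.0, tm), m,
                            rtol=1e-12, atol=1e-14)
            m = sol.y[:, -1]
        m_plus = m.copy()
        m = np.array([m[0] * np.cos(alpha), m[1]])
        sol = solve_ivp(lambda t, y: a_free @ y + b, (0.0, tr - tm), m,
                        rtol=1e-12, atol=1e-14)
        m = sol.y[:, -1]
        if prev is not None:
            scale = max(np.max(np.abs(m)), 1e-30)
            if np.max(np.abs(m - prev)) / scale < rel_tol:
                break
        prev = m.copy()
    return np.sin(alpha) * m_plus[0]


def numeric_pulse_rms(pulse, n_samples=200_000):
    """RMS amplitude by dense discretization of the envelope."""
    t = np.linspace(-pulse.duration / 2, pulse.duration / 2, n_samples)
    if pulse.envelope_shape == "rectangular":
        env = np.ones_like(t)
    else:
        sigma = (pulse.duration / 2) / np.sqrt(
            2.0 * np.log(1.0 / pulse.truncation_level))
        env = np.exp(-t ** 2 / (2 * sigma ** 2))
    theta = np.radians(pulse.effective_flip_angle)
    amp = theta / np.trapezoid(env, t)
    w1 = amp * env
    return np.sqrt(np.trapezoid(w1 ** 2, t) / pulse.duration)
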