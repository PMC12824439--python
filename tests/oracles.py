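"""Independent oracles: brute-force / closed-form implementations used only
to cross-check the package. Everything here is written directly from the
underlying formulas, without calling the code paths under test."""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import fsolve


def viscosity_oracle(eta_ref: float, T_ref: float, xi0: float, xi1: float, T: float) -> float:
    """One-line evaluation of the viscosity power law."""
    tr = T / T_ref
    return eta_ref * tr ** (xi0 + xi1 * (tr - 1.0))


def fsg_oracle(M_solute, M_gas, V_solute, V_gas, T, p_Pa) -> float:
    """Fuller-Schettler-Giddings estimate, m^2/s, coded independently."""
    p_atm = p_Pa / 101325.0
    d = (
        1e-3
        * T**1.75
        * math.sqrt(1.0 / M_solute + 1.0 / M_gas)
        / (p_atm * (V_solute ** (1 / 3) + V_gas ** (1 / 3)) ** 2)
    )
    return d * 1e-4  # cm^2/s -> m^2/s


def golay_oracle(k, u, d, df, DM, DS) -> float:
    """Golay plate height, coded independently."""
    b = 2.0 * DM / u
    cm = (1 + 6 * k + 11 * k**2) / (96.0 * (1 + k) ** 2) * d**2 * u / DM
    cs = (2.0 / 3.0) * k / (1 + k) ** 2 * df**2 * u / DS
    return b + cm + cs


def kcentric_oracle(Tchar, thetachar, DeltaCp, T, phi, phi_ref) -> float:
    """K-centric retention factor, coded independently."""
    R = 8.31446261815324
    lnk = (
        math.log(phi / phi_ref)
        + (DeltaCp / R + Tchar / thetachar) * (Tchar / T - 1.0)
        + DeltaCp / R * math.log(T / Tchar)
    )
    return math.exp(lnk)


def series_junction_oracle(p_in, p_out, kappa1, kappa2) -> float:
    """Junction pressure of two restrictions in series (squared-pressure
    closed form): p_j^2 = (kappa2 p_in^2 + kappa1 p_out^2)/(kappa1+kappa2)."""
    return math.sqrt((kappa2 * p_in**2 + kappa1 * p_out**2) / (kappa1 + kappa2))


def holdup_oracle(eta, L, d, p_in, p_out) -> float:
    """Closed-form hold-up time of a uniform capillary."""
    return (
        (128.0 / 3.0)
        * eta
        * L**2
        / d**2
        * (p_in**3 - p_out**3)
        / (p_in**2 - p_out**2) ** 2
    )


def nonlinear_flow_oracle(n_unknown, edges, known_p, x0):
    """Brute-force network solve: root-find the molar balances in the plain
    (non-squared) pressures.

    edges: list of (source, target, kappa) where vertices are either ints
    (unknown index) or floats via known_p mapping; known_p: dict vertex->Pa.
    Returns array of unknown pressures.
    """

    def pressure(v, p):
        if v in known_p:
            return known_p[v]
        return p[v]

    def balance(p):
        out = np.zeros(n_unknown)
        for s, t, kappa in edges:
            f = (pressure(s, p) ** 2 - pressure(t, p) ** 2) / kappa
            if s not in known_p:
                out[s] -= f
            if t not in known_p:
                out[t] += f
        return out

    sol, info, ier, msg = fsolve(balance, x0, full_output=True, xtol=1e-13)
    assert ier == 1, msg
    return sol


def euler_migrate_oracle(
    L, dx, t0, tau2_0, T_of_t, k_of_T, u_of_xt, H_of=None, dt_fd=1e-3
):
    """Fixed-step Euler integration of the migration/broadening ODEs.

    dt/dx = (1+k)/u; dtau2/dx = H r^2 + 2 tau2 dr/dt. ``u_of_xt(x, t)`` is
    the local velocity, ``H_of(x, t, k, u)`` the plate height (variance ODE
    skipped when None).
    """
    n = int(round(L / dx))
    t, tau2 = t0, tau2_0
    for i in range(n):
        x = (i + 0.5) * dx  # midpoint in x for a touch more accuracy
        T = T_of_t(t)
        k = k_of_T(T)
        u = u_of_xt(x, t)
        r = (1.0 + k) / u
        if H_of is not None:
            rp = (1.0 + k_of_T(T_of_t(t + dt_fd))) / u_of_xt(x, t + dt_fd)
            rm = (1.0 + k_of_T(T_of_t(t - dt_fd))) / u_of_xt(x, t - dt_fd)
            drdt = (rp - rm) / (2.0 * dt_fd)
            H = H_of(x, t, k, u)
            tau2 += (H * r * r + 2.0 * tau2 * drdt) * dx
        t += r * dx
    return t, tau2


def bruteforce_modulator_pass(
    graph, field, edge, settings, oven_program, k_of_T, D_of, entry_t, entry_tau2,
    dt=1e-5, max_time=200.0, ds_ratio=5e4,
):
    """Time-stepping ODE pass of a band through the modulator segment with
    the rectangular temperature function (trap on cold, release on hot).

    Independent of the simplified release model: integrates dx = u/(1+k) dt
    and the same variance equation, with k evaluated at the instantaneous
    rectangular modulator temperature.
    """
    from gcxgcsim.modulator import modulator_temperature

    L = edge.length
    area = math.pi * edge.diameter**2 / 4.0
    p_ref, T_ref = graph.p_ref, graph.T_ref

    def u_of(x, t):
        pin2, pout2, F = field.edge_state(edge.id, t)
        p = math.sqrt(pin2 - (pin2 - pout2) * x / L)
        T = modulator_temperature(settings, oven_program, t)
        return F * (p_ref / p) * (T / T_ref) / area, p, T

    from gcxgcsim.migration import golay_plate_height

    t, x, tau2 = entry_t, 0.0, entry_tau2
    dt_fd = 1e-3
    while x < L:
        if t - entry_t > max_time:
            raise RuntimeError("band did not clear the modulator")
        u, p, T = u_of(x, t)
        k = k_of_T(T)
        r = (1.0 + k) / u
        # central-difference dr/dt across the rectangular function
        up, _, Tp = u_of(x, t + dt_fd)
        um, _, Tm = u_of(x, t - dt_fd)
        rp = (1.0 + k_of_T(Tp)) / up
        rm = (1.0 + k_of_T(Tm)) / um
        drdt = (rp - rm) / (2.0 * dt_fd)
        DM = D_of(T, p)
        H = golay_plate_height(k, u, edge.diameter, edge.film, DM, DM / ds_ratio)
        dx_full = u / (1.0 + k) * dt
        if x + dx_full >= L:
            dx = L - x
            tau2 = max(tau2 + (H * r * r + 2.0 * tau2 * drdt) * dx, 0.0)
            t += dx * r
            x = L
        else:
            tau2 = max(tau2 + (H * r * r + 2.0 * tau2 * drdt) * dx_full, 0.0)
            t += dt
            x += dx_full
    return t, tau2
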