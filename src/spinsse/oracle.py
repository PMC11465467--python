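"""Dense Liouville–von Neumann reference solver for small systems.

Integrates dρ/dt = −i[H, ρ] − {K̂, ρ} from ρ(0) = P_Θinit/Z with a
high-order dense ODE scheme and evaluates yields on the same time grid and
with the same trapezoid quadrature as the SSE path, so that any
discrepancy measures propagation error, not quadrature differences.  This
is the independent cross-check for every fast path; it refuses Hilbert
dimensions above a small cap.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .interactions import InteractionSet, assemble_hamiltonian
from .kinetics import RateScheme, haberkorn_operator
from .spin_space import (
    ELECTRONIC_STATES,
    ELECTRONIC_VECTORS,
    SpinSystem,
    build_operators,
)
from .yields import YieldResult

DENSE_DIM_CAP = 256


def dense_populations(
    system: SpinSystem,
    interactions: InteractionSet,
    rates: RateScheme,
    theta_init: str,
    times_ns: np.ndarray,
    *,
    H_of_t: "Callable[[float], np.ndarray] | None" = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> dict[str, np.ndarray]:
    """p_Θ(t) = Tr[P̂_Θ ρ(t)] (plus trace) on the requested time grid.

    ``H_of_t`` optionally supplies a smoothly time-dependent dense
    Hamiltonian (rad µs⁻¹) overriding the static assembly; time-dependent
    rate coefficients are taken from ``rates`` directly.
    """
    dim = system.dimension
    if dim > DENSE_DIM_CAP:
        raise ValueError(
            f"dense oracle refuses dimension {dim} > {DENSE_DIM_CAP}"
        )
    ops = build_operators(system)
    H_static = (
        assemble_hamiltonian(system, interactions, ops=ops).toarray()
        if H_of_t is None
        else None
    )
    static_K = rates.is_static
    K_static = haberkorn_operator(rates, ops).toarray() if static_K else None
    projectors = {s: P.toarray() for s, P in ops.projectors.items()}

    z = system.nuclear_dimension
    elec = ELECTRONIC_VECTORS[theta_init]
    rho0 = np.kron(np.outer(elec, elec.conj()), np.eye(z, dtype=complex)) / z

    def rhs(t_us: float, y: np.ndarray) -> np.ndarray:
        rho = (y[: dim * dim] + 1j * y[dim * dim :]).reshape(dim, dim)
        t_ns = t_us * 1e3
        H = H_static if H_of_t is None else H_of_t(t_ns)
        K = K_static if static_K else haberkorn_operator(rates, ops, t_ns).toarray()
        drho = -1j * (H @ rho - rho @ H) - (K @ rho + rho @ K)
        return np.concatenate([drho.real.ravel(), drho.imag.ravel()])

    times_us = np.asarray(times_ns, dtype=float) * 1e-3
    y0 = np.concatenate([rho0.real.ravel(), rho0.imag.ravel()])
    sol = solve_ivp(
        rhs,
        (times_us[0], times_us[-1]),
        y0,
        method="DOP853",
        t_eval=times_us,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"dense oracle integration failed: {sol.message}")
    out: dict[str, np.ndarray] = {s: np.empty(len(times_us)) for s in ELECTRONIC_STATES}
    out["trace"] = np.empty(len(times_us))
    for i in range(len(times_us)):
        rho = (sol.y[: dim * dim, i] + 1j * sol.y[dim * dim :, i]).reshape(dim, dim)
        for s in ELECTRONIC_STATES:
            out[s][i] = float(np.real(np.trace(projectors[s] @ rho)))
        out["trace"][i] = float(np.real(np.trace(rho)))
    return out


def dense_yield(
    system: SpinSystem,
    interactions: InteractionSet,
    rates: RateScheme,
    theta_init: str = "S",
    *,
    T_ns: float,
    dt_ns: float = 1.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> YieldResult:
    """Reference yields Φ_Θ = ∫ k_Θ(t)·Tr[P̂_Θ ρ(t)] dt (trapezoid, same grid
    convention as the SSE yield functions)."""
    n_steps = int(round(T_ns / dt_ns))
    times_ns = dt_ns * np.arange(n_steps + 1)
    pops = dense_populations(
        system, interactions, rates, theta_init, times_ns, rtol=rtol, atol=atol
    )
    t_us = times_ns * 1e-3
    phi = {}
    for s in ELECTRONIC_STATES:
        k_t = np.array([rates.rate(s, t) for t in times_ns])
        phi[s] = float(np.trapezoid(k_t * pops[s], t_us))
    return YieldResult(
        phi=phi,
        stderr=None,
        meta={"mode": "dense_oracle", "T_ns": T_ns, "dt_ns": dt_ns},
    )
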