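"""State-vector propagation under the non-Hermitian SSE generator.

A state is advanced over one step as exp(Ω δt)·ψ with Ω = −iH − K̂ held
piecewise constant over the step (first-order Magnus: for time-dependent
generators, Ω is evaluated at the step start by default, neglecting
time-ordering within a step; a midpoint rule is available).  The matrix
exponential is never formed for large systems — only its action on the
state, via either

* ``expm_action`` — scipy's accuracy-controlled ``expm_multiply``;
* ``krylov_arnoldi`` — an adaptive Arnoldi (Krylov-subspace) approximation
  with an a-posteriori error estimate against the tolerance ε;
* ``krylov_lanczos`` — the Hermitian Lanczos recurrence, valid when the
  Hermitian part of Ω is a uniform multiple of the identity (pure spin
  evolution, or uniform decay which is factored out analytically);
* ``auto`` (default) — a dense cached propagator for small dimensions,
  ``expm_action`` otherwise.

Norms are never restored after a step: the norm loss is the reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply

_METHODS = ("auto", "expm_action", "krylov_arnoldi", "krylov_lanczos")


@dataclass
class PropagatorConfig:
    """Numerical parameters of the propagation."""

    dt_ns: float = 1.0
    method: str = "auto"
    epsilon: float = 1e-6  # relative per-step tolerance for the Krylov methods
    krylov_cap: int = 64  # maximal Krylov subspace size before step splitting
    dense_threshold: int = 600  # 'auto' densifies exp(Ω δt) at or below this dim
    time_sampling: str = "start"  # 'start' (zero-order hold) or 'midpoint'

    def __post_init__(self):
        if self.dt_ns <= 0:
            raise ValueError("dt_ns must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.time_sampling not in ("start", "midpoint"):
            raise ValueError("time_sampling must be 'start' or 'midpoint'")


def _arnoldi_expv(
    A: sp.spmatrix, v: np.ndarray, tol: float, cap: int
) -> np.ndarray:
    """exp(A)·v by adaptive Arnoldi iteration; splits the step on failure."""
    beta = np.linalg.norm(v)
    if beta == 0.0:
        return v.copy()
    n = A.shape[0]
    cap = min(cap, n)
    V = np.zeros((n, cap + 1), dtype=complex)
    Hm = np.zeros((cap + 1, cap), dtype=complex)
    V[:, 0] = v / beta
    for m in range(cap):
        w = A @ V[:, m]
        # modified Gram-Schmidt with one reorthogonalization pass
        for _ in range(2):
            for j in range(m + 1):
                c = np.vdot(V[:, j], w)
                Hm[j, m] += c
                w -= c * V[:, j]
        h = np.linalg.norm(w)
        Hm[m + 1, m] = h
        eH = scipy.linalg.expm(Hm[: m + 1, : m + 1])
        if h < 1e-14:  # happy breakdown: Krylov space is invariant, result exact
            return beta * (V[:, : m + 1] @ eH[:, 0])
        err = abs(h * eH[m, 0])
        if err <= tol:
            return beta * (V[:, : m + 1] @ eH[:, 0])
        V[:, m + 1] = w / h
    # not converged within the cap: halve the step recursively
    half = _arnoldi_expv(A * 0.5, v, tol / 2, cap)
    return _arnoldi_expv(A * 0.5, half, tol / 2, cap)


def _uniform_decay_rate(omega: sp.spmatrix) -> float:
    """γ such that Ω + Ω† = −γ·1, or raise if the Hermitian part is not uniform."""
    herm = (omega + omega.conj().T).tocsr()
    diag = herm.diagonal()
    gamma = -float(np.real(diag[0]))
    off = herm - sp.diags(diag)
    scale = max(1.0, abs(gamma))
    if (abs(off).max() if off.nnz else 0.0) > 1e-10 * scale or not np.allclose(
        diag, diag[0], atol=1e-10 * scale
    ):
        raise ValueError(
            "krylov_lanczos requires the Hermitian part of the generator to be "
            "a uniform multiple of the identity; use krylov_arnoldi or expm_action"
        )
    return gamma


def _lanczos_expv(
    omega: sp.spmatrix, v: np.ndarray, tol: float, cap: int
) -> np.ndarray:
    """exp(Ω)·v for Ω = −iH − (γ/2)·1 via Hermitian Lanczos on H."""
    gamma = _uniform_decay_rate(omega)
    # H = i(Ω + (γ/2)1): Hermitian
    n = omega.shape[0]
    Hop = (1j * (omega + (gamma / 2.0) * sp.identity(n, dtype=complex))).tocsr()
    beta = np.linalg.norm(v)
    if beta == 0.0:
        return v.copy()
    cap = min(cap, n)
    V = np.zeros((n, cap + 1), dtype=complex)
    alphas: list[float] = []
    betas: list[float] = []
    V[:, 0] = v / beta
    prev = np.zeros(n, dtype=complex)
    b_prev = 0.0
    for m in range(cap):
        w = Hop @ V[:, m] - b_prev * prev
        a = float(np.real(np.vdot(V[:, m], w)))
        w -= a * V[:, m]
        # full reorthogonalization for numerical robustness at small cap
        for j in range(m + 1):
            w -= np.vdot(V[:, j], w) * V[:, j]
        alphas.append(a)
        b = np.linalg.norm(w)
        T = np.diag(alphas).astype(complex)
        if betas:
            bd = np.array(betas)
            T += np.diag(bd, 1) + np.diag(bd, -1)
        eT = scipy.linalg.expm(-1j * T)
        decay = np.exp(-gamma / 2.0)
        if b < 1e-14:
            return decay * beta * (V[:, : m + 1] @ eT[:, 0])
        err = abs(b * eT[m, 0])
        if err <= tol:
            return decay * beta * (V[:, : m + 1] @ eT[:, 0])
        betas.append(float(b))
        prev = V[:, m]
        b_prev = b
        V[:, m + 1] = w / b
    half = _lanczos_expv(omega * 0.5, v, tol / 2, cap)
    return _lanczos_expv(omega * 0.5, half, tol / 2, cap)


def step(
    state: np.ndarray,
    omega: sp.spmatrix,
    config: PropagatorConfig,
    dt_ns: float | None = None,
) -> np.ndarray:
    """One propagation step: approximation to exp(Ω δt)·state.

    ``state`` may be a single vector or a (dim, ncols) batch.  Ω is in µs⁻¹
    (rad µs⁻¹ for the coherent part), δt in ns.
    """
    dt_us = (config.dt_ns if dt_ns is None else dt_ns) * 1e-3
    A = omega * dt_us
    n = omega.shape[0]
    method = config.method
    if method == "auto":
        method = "dense" if n <= config.dense_threshold else "expm_action"
    if method == "dense":
        U = scipy.linalg.expm(A.toarray() if sp.issparse(A) else A)
        out = U @ state
    elif method == "expm_action":
        out = expm_multiply(A.tocsc(), state)
    elif method in ("krylov_arnoldi", "krylov_lanczos"):
        func = _arnoldi_expv if method == "krylov_arnoldi" else _lanczos_expv
        if state.ndim == 1:
            tol = config.epsilon * max(np.linalg.norm(state), 1e-300)
            out = func(A, state, tol, config.krylov_cap)
        else:
            out = np.empty_like(state)
            for c in range(state.shape[1]):
                col = state[:, c]
                tol = config.epsilon * max(np.linalg.norm(col), 1e-300)
                out[:, c] = func(A, col, tol, config.krylov_cap)
    else:  # pragma: no cover - guarded by PropagatorConfig
        raise ValueError(method)
    if not np.all(np.isfinite(out)):
        raise RuntimeError(
            "non-finite amplitudes after a propagation step "
            f"(dim={n}, dt={dt_us*1e3} ns, method={method})"
        )
    return out


@dataclass
class EvolutionResult:
    """Observable time series from an SSE propagation."""

    times_ns: np.ndarray
    populations: dict[str, np.ndarray]  # label → (n_times, ncols)
    norms_sq: np.ndarray  # (n_times, ncols) survival probability per state vector

    def mean_populations(self) -> dict[str, np.ndarray]:
        return {k: v.mean(axis=1) for k, v in self.populations.items()}

    def mean_norms_sq(self) -> np.ndarray:
        return self.norms_sq.mean(axis=1)


def _observe(
    states: np.ndarray, observables: Mapping[str, sp.spmatrix]
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    pops = {
        name: np.real(np.einsum("ij,ij->j", states.conj(), P @ states))
        for name, P in observables.items()
    }
    norms = np.real(np.einsum("ij,ij->j", states.conj(), states))
    return pops, norms


def evolve(
    states: np.ndarray,
    *,
    n_steps: int,
    config: PropagatorConfig,
    observables: Mapping[str, sp.spmatrix],
    omega: sp.spmatrix | None = None,
    omega_of_t: Callable[[float], sp.spmatrix] | None = None,
) -> EvolutionResult:
    """Propagate a batch of state vectors, recording <ψ|P|ψ> at every step.

    Exactly one of ``omega`` (static generator) or ``omega_of_t`` (generator
    at time t in ns, held constant over each step) must be given.  For the
    static case with small dimension the step propagator exp(Ω δt) is built
    densely once and applied as a matrix product; otherwise each step uses
    the method selected in ``config``.
    """
    if (omega is None) == (omega_of_t is None):
        raise ValueError("give exactly one of omega or omega_of_t")
    if states.ndim == 1:
        states = states[:, None]
    states = np.ascontiguousarray(states, dtype=complex)
    dim, _ = states.shape
    dt = config.dt_ns
    times = dt * np.arange(n_steps + 1)

    pops0, norms0 = _observe(states, observables)
    pop_series = {k: [v] for k, v in pops0.items()}
    norm_series = [norms0]

    dense_static = (
        omega is not None
        and config.method in ("auto",)
        and dim <= config.dense_threshold
    )
    U = None
    if dense_static:
        U = scipy.linalg.expm(omega.toarray() * (dt * 1e-3))

    psi = states
    for n in range(n_steps):
        t = times[n]
        if omega is not None:
            if U is not None:
                psi = U @ psi
            else:
                psi = step(psi, omega, config)
        else:
            t_eval = t + (0.5 * dt if config.time_sampling == "midpoint" else 0.0)
            psi = step(psi, omega_of_t(t_eval), config)
        if not np.all(np.isfinite(psi)):
            raise RuntimeError(f"non-finite amplitudes at step {n + 1} (t={times[n+1]} ns)")
        p, nr = _observe(psi, observables)
        for k in pop_series:
            pop_series[k].append(p[k])
        norm_series.append(nr)

    return EvolutionResult(
        times_ns=times,
        populations={k: np.stack(v) for k, v in pop_series.items()},
        norms_sq=np.stack(norm_series),
    )
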