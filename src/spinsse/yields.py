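"""Quantum reaction yields: direct and stochastic trace evaluation, the
finite-time correction factor, and derived scan quantities.

The singlet (triplet) quantum yield is

    Φ_Θ = ∫₀^T k_Θ(t) · p_Θ(t) dt,    p_Θ(t) = (1/Z) Σ_n <ψ_n(t)|P̂_Θ|ψ_n(t)>,

where the ψ_n are the Z nuclear-basis initial states (direct method) or
M ≪ Z sampled SU(Z) coherent states (stochastic method, with the sample
mean replacing the 1/Z-weighted sum; the two normalizations cancel so the
estimator is simply the average per-sample yield).  Populations are
integrated by the trapezoid rule on the propagation grid.

For symmetric rates (k_S = k_T = k_sym) the reaction factorizes out of the
coherent evolution, ρ(t) = e^(−k_sym t)·ρ₀(t), which yields the
finite-time correction factor

    Φ_Θ(∞) ≈ [k_sym ∫₀^T e^(−k_sym t) p_Θ(t) dt] / (1 − e^(−k_sym T))

with p_Θ from a reaction-free propagation: the missing tail is completed
by the k-weighted average of p_Θ accumulated so far.  The factor is exact
for constant p_Θ, tends to 1 as T → ∞, and lets T be shortened
several-fold without biasing the yield.  (Numerator and denominator use
the same trapezoid rule, so constant-p exactness and Σ_Θ Φ_Θ = 1 hold to
machine precision at any step size.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .interactions import (
    TWO_PI,
    DrivenGeometry,
    InteractionSet,
    DynamicHamiltonian,
    TrajectorySeries,
    assemble_hamiltonian,
    _pair_term,
)
from .kinetics import RateScheme, effective_generator, haberkorn_operator
from .propagate import EvolutionResult, PropagatorConfig, evolve
from .spin_space import (
    ELECTRONIC_STATES,
    ELECTRONIC_VECTORS,
    OperatorSet,
    SpinSystem,
    build_operators,
    sample_su_z,
)


@dataclass
class YieldResult:
    """Quantum yields per electronic channel, with Monte-Carlo errors."""

    phi: dict[str, float]
    stderr: dict[str, float] | None = None
    meta: dict | None = None

    def total(self) -> float:
        return float(sum(self.phi.values()))


@dataclass
class ScanResult:
    """A table of yields over a scan axis, plus reproducibility metadata."""

    table: pd.DataFrame
    meta: dict

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            for key in sorted(self.meta):
                fh.write(f"# {key} = {self.meta[key]}\n")
            self.table.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# propagation engine


def _initial_matrix(system: SpinSystem, theta_init: str, nuclear_vectors: np.ndarray):
    """Batch of full-space initial vectors |Θ_init> ⊗ |ν_m> as columns."""
    elec = ELECTRONIC_VECTORS[theta_init]
    return np.kron(elec[:, None], nuclear_vectors)


def _driven_exchange_op(ops: OperatorSet) -> sp.csr_matrix:
    # H_J(t) = J(t)·op with op = −2π(2 S1·S2 + ½·1)
    s_dot_s = _pair_term(ops.electron[0], ops.electron[1], np.eye(3))
    return (-TWO_PI * (2.0 * s_dot_s + 0.5 * ops.identity)).tocsr()


def _population_series(
    system: SpinSystem,
    interactions: InteractionSet,
    rates: RateScheme,
    theta_init: str,
    nuclear_vectors: np.ndarray,
    T_ns: float,
    config: PropagatorConfig,
    ops: OperatorSet | None = None,
    trajectory: TrajectorySeries | None = None,
    driven: DrivenGeometry | None = None,
    include_reaction: bool = True,
) -> EvolutionResult:
    """Propagate a batch of initial nuclear vectors and record <P_Θ>(t)."""
    if ops is None:
        ops = build_operators(system)
    n_steps = int(round(T_ns / config.dt_ns))
    if abs(n_steps * config.dt_ns - T_ns) > 1e-6 * max(T_ns, 1.0):
        raise ValueError(f"T={T_ns} ns is not a multiple of dt={config.dt_ns} ns")
    if trajectory is not None and trajectory.span_ns[1] + 1e-9 < T_ns:
        raise ValueError(
            f"trajectory ends at {trajectory.span_ns[1]} ns but the propagation "
            f"needs {T_ns} ns"
        )
    states = _initial_matrix(system, theta_init, nuclear_vectors)
    observables = ops.projectors

    time_dep = (
        trajectory is not None
        or driven is not None
        or (include_reaction and not rates.is_static)
    )
    if driven is not None and interactions.j_MHz != 0.0:
        raise ValueError(
            "driven runs supply J(t); declare the static exchange as J0 in the "
            "DrivenGeometry, not in the InteractionSet"
        )
    if not time_dep:
        H = assemble_hamiltonian(system, interactions, ops=ops)
        K = (
            haberkorn_operator(rates, ops)
            if include_reaction
            else sp.csr_matrix(H.shape, dtype=complex)
        )
        return evolve(
            states,
            n_steps=n_steps,
            config=config,
            observables=observables,
            omega=effective_generator(H, K),
        )

    dyn = (
        DynamicHamiltonian(system, interactions, trajectory, ops=ops)
        if trajectory is not None
        else None
    )
    H_static = (
        assemble_hamiltonian(system, interactions, ops=ops) if dyn is None else None
    )
    exch_op = _driven_exchange_op(ops) if driven is not None else None

    def omega_of_t(t_ns: float) -> sp.csr_matrix:
        H = dyn.at(t_ns) if dyn is not None else H_static
        if driven is not None:
            _, J_MHz, _ = driven.at(t_ns)
            H = H + J_MHz * exch_op
        if include_reaction:
            K = haberkorn_operator(rates, ops, t_ns)
        else:
            K = sp.csr_matrix(H.shape, dtype=complex)
        return effective_generator(H, K)

    return evolve(
        states,
        n_steps=n_steps,
        config=config,
        observables=observables,
        omega_of_t=omega_of_t,
    )


# ---------------------------------------------------------------------------
# yield integration


def corrected_yield(times_ns: np.ndarray, p: np.ndarray, k_sym_per_us: float) -> float:
    """Infinite-time yield from a reaction-free population series p(t) on [0, T].

    Φ ≈ [k_sym ∫₀^T e^(−k_sym t) p(t) dt] / (1 − e^(−k_sym T)), exact for
    constant p (for any T ≥ 0) and converging to the uncorrected infinite-T
    integral as T grows.
    """
    t_us = np.asarray(times_ns, dtype=float) * 1e-3
    p = np.asarray(p, dtype=float)
    if len(t_us) < 2 or k_sym_per_us * t_us[-1] == 0.0:
        return float(p[0])
    kw = k_sym_per_us * np.exp(-k_sym_per_us * t_us)
    return float(np.trapezoid(kw * p, t_us) / np.trapezoid(kw, t_us))


def _phi_per_column(
    result: EvolutionResult,
    rates: RateScheme,
    correction: bool,
) -> dict[str, np.ndarray]:
    t_us = result.times_ns * 1e-3
    phi: dict[str, np.ndarray] = {}
    if correction:
        k = rates.k_sym
        kw = (k * np.exp(-k * t_us))[:, None]
        denom = np.trapezoid(kw[:, 0], t_us)
        for state in ELECTRONIC_STATES:
            p = result.populations[state]
            phi[state] = np.trapezoid(kw * p, t_us, axis=0) / denom
    else:
        for state in ELECTRONIC_STATES:
            k_t = np.array([rates.rate(state, t) for t in result.times_ns])
            phi[state] = np.trapezoid(
                k_t[:, None] * result.populations[state], t_us, axis=0
            )
    return phi


def _check_correction_applicable(rates: RateScheme, correction: bool) -> None:
    if not correction:
        return
    if not rates.is_symmetric:
        raise ValueError(
            "the correction factor is derived for symmetric rates "
            "(k_S = k_T, constant); refuse to apply it otherwise"
        )
    if (not callable(rates.k_f)) and float(rates.k_f) != 0.0:
        raise ValueError("the correction factor assumes no separate forward rate")


def yield_direct(
    system: SpinSystem,
    interactions: InteractionSet,
    rates: RateScheme,
    theta_init: str = "S",
    *,
    T_ns: float,
    config: PropagatorConfig | None = None,
    ops: OperatorSet | None = None,
    trajectory: TrajectorySeries | None = None,
    driven: DrivenGeometry | None = None,
    correction: bool = False,
    z_cap: int = 8192,
) -> YieldResult:
    """Quantum yields by propagating all Z nuclear basis states (exact trace)."""
    config = config or PropagatorConfig()
    z = system.nuclear_dimension
    if z > z_cap:
        raise ValueError(
            f"Z={z} exceeds the direct-method cap ({z_cap}); use yield_stochastic "
            "(Monte-Carlo trace sampling) for large spin systems"
        )
    _check_correction_applicable(rates, correction)
    nuclear = np.eye(z, dtype=complex)
    result = _population_series(
        system,
        interactions,
        rates,
        theta_init,
        nuclear,
        T_ns,
        config,
        ops=ops,
        trajectory=trajectory,
        driven=driven,
        include_reaction=not correction,
    )
    per_col = _phi_per_column(result, rates, correction)
    phi = {s: float(v.mean()) for s, v in per_col.items()}
    return YieldResult(
        phi=phi,
        stderr=None,
        meta={
            "mode": "direct",
            "Z": z,
            "T_ns": T_ns,
            "dt_ns": config.dt_ns,
            "theta_init": theta_init,
            "correction": correction,
        },
    )


def yield_stochastic(
    system: SpinSystem,
    interactions: InteractionSet,
    rates: RateScheme,
    theta_init: str = "S",
    *,
    T_ns: float,
    M: int,
    seed: int,
    config: PropagatorConfig | None = None,
    ops: OperatorSet | None = None,
    trajectory: TrajectorySeries | None = None,
    driven: DrivenGeometry | None = None,
    correction: bool = False,
    nuclear_states: Sequence[np.ndarray] | None = None,
) -> YieldResult:
    """Monte-Carlo yields from M sampled SU(Z) coherent states.

    The estimator is the mean of the per-sample yields; the reported
    standard error is the sample standard deviation over the M samples
    divided by √M.  ``nuclear_states`` overrides the sampler with explicit
    nuclear vectors (e.g. an orthonormal basis, for which the estimator
    coincides with the direct method).
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    config = config or PropagatorConfig()
    z = system.nuclear_dimension
    if nuclear_states is None:
        if M > z:
            warnings.warn(
                f"M={M} exceeds Z={z}: the stochastic gain is lost for small "
                "systems (M should be well below Z); consider yield_direct",
                stacklevel=2,
            )
        nuclear = np.stack(
            [sample_su_z(z, seed, m).amplitudes for m in range(M)], axis=1
        )
    else:
        nuclear = np.stack([np.asarray(v, dtype=complex) for v in nuclear_states], axis=1)
        M = nuclear.shape[1]
    _check_correction_applicable(rates, correction)
    result = _population_series(
        system,
        interactions,
        rates,
        theta_init,
        nuclear,
        T_ns,
        config,
        ops=ops,
        trajectory=trajectory,
        driven=driven,
        include_reaction=not correction,
    )
    per_col = _phi_per_column(result, rates, correction)
    phi = {s: float(v.mean()) for s, v in per_col.items()}
    stderr = {
        s: (float(v.std(ddof=1) / np.sqrt(M)) if M > 1 else float("nan"))
        for s, v in per_col.items()
    }
    return YieldResult(
        phi=phi,
        stderr=stderr,
        meta={
            "mode": "stochastic",
            "Z": z,
            "M": M,
            "seed": seed,
            "T_ns": T_ns,
            "dt_ns": config.dt_ns,
            "theta_init": theta_init,
            "correction": correction,
        },
    )


# ---------------------------------------------------------------------------
# derived scan quantities


def _survival(
    system: SpinSystem,
    interactions: InteractionSet,
    rates: RateScheme,
    theta_init: str,
    t_obs_ns: float,
    config: PropagatorConfig,
    ops: OperatorSet | None = None,
) -> float:
    """Radical-pair survival probability Tr ρ(t_obs) by the direct method."""
    z = system.nuclear_dimension
    nuclear = np.eye(z, dtype=complex)
    result = _population_series(
        system, interactions, rates, theta_init, nuclear, t_obs_ns, config, ops=ops
    )
    return float(result.mean_norms_sq()[-1])


def relative_yield(
    system: SpinSystem,
    interactions: InteractionSet,
    rates: RateScheme,
    B_mT: float,
    t_obs_ns: float,
    *,
    theta_init: str = "S",
    direction: Sequence[float] = (0.0, 0.0, 1.0),
    config: PropagatorConfig | None = None,
    ops: OperatorSet | None = None,
) -> float:
    """Φ_RP(B, t)/Φ_RP(0, t): surviving radical-pair fraction at the
    observation time, normalized by its zero-field value."""
    config = config or PropagatorConfig()
    if ops is None:
        ops = build_operators(system)
    if t_obs_ns <= 0:
        raise ValueError("t_obs must be positive")
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    s_B = _survival(
        system, interactions.with_field(B_mT * d), rates, theta_init, t_obs_ns,
        config, ops,
    )
    s_0 = _survival(
        system, interactions.with_field(0.0 * d), rates, theta_init, t_obs_ns,
        config, ops,
    )
    return s_B / s_0


def field_scan(
    system: SpinSystem,
    interactions: InteractionSet,
    rates: RateScheme,
    B_grid_mT: Sequence[float],
    t_obs_ns: float,
    *,
    theta_init: str = "S",
    direction: Sequence[float] = (0.0, 0.0, 1.0),
    config: PropagatorConfig | None = None,
) -> ScanResult:
    """MARY curve: relative radical-pair yield vs field strength.

    The reference Φ_RP(0, t) is taken from the B = 0 grid point if present,
    otherwise computed separately.  The minimum is located by grid argmin —
    its resolution is the grid step (reported in the metadata).
    """
    config = config or PropagatorConfig()
    B_grid = np.asarray(B_grid_mT, dtype=float)
    if B_grid.ndim != 1 or np.any(np.diff(B_grid) <= 0):
        raise ValueError("B grid must be strictly increasing")
    ops = build_operators(system)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    surv = np.array(
        [
            _survival(
                system, interactions.with_field(b * d), rates, theta_init,
                t_obs_ns, config, ops,
            )
            for b in B_grid
        ]
    )
    if np.any(np.isclose(B_grid, 0.0)):
        s0 = surv[np.argmin(np.abs(B_grid))]
    else:
        s0 = _survival(
            system, interactions.with_field(0.0 * d), rates, theta_init,
            t_obs_ns, config, ops,
        )
    rel = surv / s0
    table = pd.DataFrame(
        {"field_mT": B_grid, "survival": surv, "relative_yield": rel}
    )
    argmin = int(np.argmin(rel))
    meta = {
        "scan": "field",
        "t_obs_ns": t_obs_ns,
        "dt_ns": config.dt_ns,
        "theta_init": theta_init,
        "grid_step_mT": float(np.min(np.diff(B_grid))) if len(B_grid) > 1 else 0.0,
        "argmin_field_mT": float(B_grid[argmin]),
    }
    return ScanResult(table=table, meta=meta)


def anisotropy_chi(phi_par: float, phi_perp: float) -> float:
    """Relative anisotropy χ = (Φ_∥ − Φ_⊥)/((Φ_∥ + Φ_⊥)/2).

    Zero iff the two yields are equal; antisymmetric under swapping the
    orientations.
    """
    if phi_par < 0 or phi_perp < 0:
        raise ValueError("yields must be non-negative")
    s = phi_par + phi_perp
    if s == 0.0:
        raise ValueError("both yields are zero; anisotropy undefined")
    return float((phi_par - phi_perp) / (0.5 * s))


def orientation_scan(
    system: SpinSystem,
    interactions: InteractionSet,
    rates: RateScheme,
    theta_grid_deg: Sequence[float],
    *,
    mode: str = "direct",
    theta_init: str = "S",
    T_ns: float,
    B_mT: float | None = None,
    M: int = 1,
    seed: int = 0,
    config: PropagatorConfig | None = None,
    trajectory: TrajectorySeries | None = None,
    correction: bool = False,
) -> ScanResult:
    """Φ_Θ(θ) with the field rotated in the molecular z–x plane.

    ``B_mT`` defaults to the magnitude of the declared field.  In
    stochastic mode the same M seeds are reused at every orientation, so
    the curve is smooth in the Monte-Carlo noise.
    """
    config = config or PropagatorConfig()
    thetas = np.asarray(theta_grid_deg, dtype=float)
    if thetas.ndim != 1 or (len(thetas) > 1 and np.any(np.diff(thetas) <= 0)):
        raise ValueError("theta grid must be strictly increasing")
    if B_mT is None:
        B_mT = float(np.linalg.norm(interactions.field_mT))
    ops = build_operators(system)
    rows = []
    for th in thetas:
        ints_th = interactions.with_field_orientation(B_mT, th)
        if mode == "direct":
            res = yield_direct(
                system, ints_th, rates, theta_init, T_ns=T_ns, config=config,
                ops=ops, trajectory=trajectory, correction=correction,
            )
        elif mode == "stochastic":
            res = yield_stochastic(
                system, ints_th, rates, theta_init, T_ns=T_ns, M=M, seed=seed,
                config=config, ops=ops, trajectory=trajectory,
                correction=correction,
            )
        else:
            raise ValueError("mode must be 'direct' or 'stochastic'")
        row = {"theta_deg": th}
        row.update({f"phi_{s}": res.phi[s] for s in ELECTRONIC_STATES})
        if res.stderr is not None:
            row.update({f"stderr_{s}": res.stderr[s] for s in ELECTRONIC_STATES})
        rows.append(row)
    table = pd.DataFrame(rows)
    meta = {
        "scan": "orientation",
        "mode": mode,
        "B_mT": B_mT,
        "T_ns": T_ns,
        "dt_ns": config.dt_ns,
        "theta_init": theta_init,
        "correction": correction,
    }
    if mode == "stochastic":
        meta.update({"M": M, "seed": seed})
    return ScanResult(table=table, meta=meta)


def driven_singlet_yields(
    system: SpinSystem,
    interactions: InteractionSet,
    driven: DrivenGeometry,
    k_f_per_us: float,
    *,
    T_ns: float,
    theta_init: str = "S",
    config: PropagatorConfig | None = None,
    ops: OperatorSet | None = None,
) -> tuple[float, float, float]:
    """(Φ_∥, Φ_⊥, χ) for the driven radical-pair model.

    The singlet recombines through the distance-modulated backward channel
    k_b(t); all four states share the forward rate k_f.  Φ_∥ (Φ_⊥) uses the
    declared field magnitude along the molecular z (x) axis — parallel or
    perpendicular to the hyperfine symmetry axis.
    """
    config = config or PropagatorConfig()
    if ops is None:
        ops = build_operators(system)
    rates = RateScheme(k_S=lambda t: driven.at(t)[2], k_f=k_f_per_us)
    B = float(np.linalg.norm(interactions.field_mT))
    phis = []
    for theta in (0.0, 90.0):
        ints_th = interactions.with_field_orientation(B, theta)
        res = yield_direct(
            system, ints_th, rates, theta_init, T_ns=T_ns, config=config,
            ops=ops, driven=driven,
        )
        phis.append(res.phi["S"])
    phi_par, phi_perp = phis
    return phi_par, phi_perp, anisotropy_chi(phi_par, phi_perp)
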