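"""Spin-selective reaction kinetics: Haberkorn operators and SSE generators.

The reaction superoperator acts as −{K̂, ρ} with K̂ = Σ_Θ (k_Θ/2)·P̂_Θ
(+ k_f/2 for a spin-independent escape channel), so a uniform rate k gives
population decay exactly e^(−kt).  The non-Hermitian SSE generator is
Ω = −iH − K̂; its Hermitian part is negative semidefinite, so propagated
state norms never grow (norm loss encodes the reaction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import scipy.sparse as sp

from .spin_space import ELECTRONIC_STATES, OperatorSet

Rate = "float | Callable[[float], float]"


def _eval_rate(r, t_ns: float) -> float:
    v = float(r(t_ns)) if callable(r) else float(r)
    if v < 0:
        raise ValueError(f"negative rate {v} at t={t_ns} ns")
    return v


@dataclass(frozen=True)
class RateScheme:
    """Per-electronic-state rate coefficients k_Θ (µs⁻¹), constant or k(t_ns).

    ``k_f`` is an optional spin-independent forward/escape rate applied to
    every electronic state on top of the selective ones.
    """

    k_S: "float | Callable" = 0.0
    k_T0: "float | Callable" = 0.0
    k_Tp: "float | Callable" = 0.0
    k_Tm: "float | Callable" = 0.0
    k_f: "float | Callable" = 0.0

    @classmethod
    def symmetric(cls, k_sym: float, k_f: float = 0.0) -> "RateScheme":
        return cls(k_S=k_sym, k_T0=k_sym, k_Tp=k_sym, k_Tm=k_sym, k_f=k_f)

    @classmethod
    def singlet_triplet(cls, k_S, k_T, k_f: float = 0.0) -> "RateScheme":
        return cls(k_S=k_S, k_T0=k_T, k_Tp=k_T, k_Tm=k_T, k_f=k_f)

    def rate(self, state: str, t_ns: float = 0.0) -> float:
        if state not in ELECTRONIC_STATES:
            raise KeyError(f"unknown electronic state {state!r}")
        return _eval_rate(getattr(self, "k_" + state), t_ns)

    def forward_rate(self, t_ns: float = 0.0) -> float:
        return _eval_rate(self.k_f, t_ns)

    @property
    def is_static(self) -> bool:
        return not any(
            callable(getattr(self, "k_" + s)) for s in ELECTRONIC_STATES
        ) and not callable(self.k_f)

    @property
    def is_symmetric(self) -> bool:
        """True when all four selective rates are equal constants."""
        if not self.is_static:
            return False
        vals = {float(getattr(self, "k_" + s)) for s in ELECTRONIC_STATES}
        return len(vals) == 1

    @property
    def k_sym(self) -> float:
        if not self.is_symmetric:
            raise ValueError("rate scheme is not symmetric (k_S = k_T required)")
        return float(self.k_S)


def haberkorn_operator(
    rates: RateScheme,
    projectors: "Mapping[str, sp.spmatrix] | OperatorSet",
    t_ns: float = 0.0,
) -> sp.csr_matrix:
    """K̂(t) = Σ_Θ (k_Θ(t)/2)·P̂_Θ + (k_f(t)/2)·1, sparse Hermitian PSD, µs⁻¹."""
    if isinstance(projectors, OperatorSet):
        projectors = projectors.projectors
    K = None
    for state in ELECTRONIC_STATES:
        k = rates.rate(state, t_ns)
        if k != 0.0:
            term = (0.5 * k) * projectors[state]
            K = term if K is None else K + term
    dim = next(iter(projectors.values())).shape[0]
    kf = rates.forward_rate(t_ns)
    if kf != 0.0:
        term = (0.5 * kf) * sp.identity(dim, format="csr", dtype=complex)
        K = term if K is None else K + term
    if K is None:
        K = sp.csr_matrix((dim, dim), dtype=complex)
    return K.tocsr()


def effective_generator(H: sp.spmatrix, K: sp.spmatrix) -> sp.csr_matrix:
    """Ω = −iH − K̂ (rad µs⁻¹ / µs⁻¹): anti-Hermitian part −iH, Hermitian part −K̂."""
    if H.shape != K.shape:
        raise ValueError(f"dimension mismatch: H {H.shape} vs K {K.shape}")
    return (-1j * H - K).tocsr()
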