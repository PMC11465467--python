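"""Hilbert-space structure for a two-electron radical pair with coupled nuclei.

A radical pair consists of two electron spins (one per radical) and an
arbitrary set of nuclear spins, each attached to one of the radicals.  This
module builds the tensor-product Hilbert space, the spin operators of every
spin embedded in the full space as sparse matrices, the electronic
singlet/triplet projection operators, initial states, and the SU(Z)
coherent states used for Monte-Carlo trace sampling.

Basis ordering (fixed throughout the package):

    electron 1  ⊗  electron 2  ⊗  nuclei of radical 1  ⊗  nuclei of radical 2

with nuclei in declaration order within each radical, and the magnetic
quantum number of every spin running from +I down to −I (so index 0 of a
spin-1/2 site is the "α" state).  The two-electron singlet/triplet states
are defined in this product basis as

    |T+1> = |αα>,  |T0>,|S> = (|αβ> ± |βα>)/√2,  |T−1> = |ββ>.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce
from typing import Sequence

import numpy as np
import scipy.sparse as sp

#: Electronic state labels used everywhere (CSV columns use phi_S, phi_T0, ...).
ELECTRONIC_STATES = ("S", "T0", "Tp", "Tm")

_SUPPORTED_SPINS = (0.5, 1.0)
_AXES = ("x", "y", "z")


def spin_matrices(I: float) -> dict[str, np.ndarray]:
    """Dense Cartesian spin matrices for a single spin of quantum number ``I``.

    Only I = 1/2 and I = 1 are supported (¹H and ¹⁴N cover all systems of
    interest here); anything else is rejected loudly.
    """
    if not any(abs(I - s) < 1e-9 for s in _SUPPORTED_SPINS):
        raise ValueError(
            f"unsupported spin quantum number I={I}; only I=1/2 and I=1 are supported"
        )
    d = int(round(2 * I + 1))
    m = I - np.arange(d)  # +I ... −I
    sz = np.diag(m).astype(complex)
    # raising operator in the m-descending basis: <m+1|S+|m> = sqrt(I(I+1) − m(m+1))
    sp_ = np.zeros((d, d), dtype=complex)
    for j in range(1, d):
        mm = m[j]
        sp_[j - 1, j] = np.sqrt(I * (I + 1) - mm * (mm + 1))
    sx = (sp_ + sp_.conj().T) / 2
    sy = (sp_ - sp_.conj().T) / 2j
    return {"x": sx, "y": sy, "z": sz}


@dataclass(frozen=True)
class Nucleus:
    """A nuclear spin attached to radical 1 or 2."""

    label: str
    radical: int  # 1 or 2
    spin: float  # I, in {1/2, 1}

    def __post_init__(self):
        if self.radical not in (1, 2):
            raise ValueError(f"nucleus {self.label!r}: radical must be 1 or 2")
        if not any(abs(self.spin - s) < 1e-9 for s in _SUPPORTED_SPINS):
            raise ValueError(
                f"nucleus {self.label!r}: unsupported I={self.spin}; only 1/2 and 1"
            )

    @property
    def multiplicity(self) -> int:
        return int(round(2 * self.spin + 1))


@dataclass(frozen=True)
class SpinSystem:
    """Two electron spins plus an ordered list of nuclei.

    ``g`` holds the g-values of the two radicals (free-electron value by
    default).  The total Hilbert dimension is 4 × Π(2I_k + 1).
    """

    nuclei: tuple[Nucleus, ...] = ()
    g: tuple[float, float] = (2.0023, 2.0023)

    def __post_init__(self):
        if len(self.g) != 2:
            raise ValueError("exactly two electrons (two g-values) are required")
        object.__setattr__(self, "nuclei", tuple(self.nuclei))
        labels = [n.label for n in self.nuclei]
        if len(set(labels)) != len(labels):
            raise ValueError("nucleus labels must be unique")

    @property
    def ordered_nuclei(self) -> tuple[Nucleus, ...]:
        """Nuclei in basis order: radical 1 (declaration order), then radical 2."""
        return tuple(n for n in self.nuclei if n.radical == 1) + tuple(
            n for n in self.nuclei if n.radical == 2
        )

    @property
    def nuclear_dimension(self) -> int:
        """Z = Π_k (2I_k + 1), dimension of the nuclear subspace."""
        z = 1
        for n in self.nuclei:
            z *= n.multiplicity
        return z

    @property
    def dimension(self) -> int:
        """Total Hilbert dimension, 4 × Z."""
        return 4 * self.nuclear_dimension

    def nucleus(self, label: str) -> Nucleus:
        for n in self.nuclei:
            if n.label == label:
                return n
        raise KeyError(f"no nucleus labelled {label!r} in this system")


def hilbert_dimension(system: SpinSystem) -> int:
    """Total Hilbert-space dimension of the radical pair, 4 × Π(2I_k+1)."""
    return system.dimension


def _embed(op: np.ndarray, site: int, dims: Sequence[int]) -> sp.csr_matrix:
    """Embed a single-site operator into the full product space (sparse)."""
    left = int(np.prod(dims[:site], initial=1))
    right = int(np.prod(dims[site + 1 :], initial=1))
    out = sp.kron(
        sp.kron(sp.identity(left, format="csr"), sp.csr_matrix(op), format="csr"),
        sp.identity(right, format="csr"),
        format="csr",
    )
    out.eliminate_zeros()
    return out


# Two-electron singlet/triplet basis vectors in the |e1 e2> product basis
# (index 0 = α = m_s +1/2):  |αα>, |αβ>, |βα>, |ββ>.
_SQ2 = 1.0 / np.sqrt(2.0)
ELECTRONIC_VECTORS: dict[str, np.ndarray] = {
    "Tp": np.array([1.0, 0.0, 0.0, 0.0], dtype=complex),
    "T0": np.array([0.0, _SQ2, _SQ2, 0.0], dtype=complex),
    "S": np.array([0.0, _SQ2, -_SQ2, 0.0], dtype=complex),
    "Tm": np.array([0.0, 0.0, 0.0, 1.0], dtype=complex),
}


@dataclass
class OperatorSet:
    """Sparse spin operators and electronic projectors in the full space."""

    system: SpinSystem
    dims: tuple[int, ...]
    electron: tuple[dict[str, sp.csr_matrix], dict[str, sp.csr_matrix]]
    nuclear: dict[str, dict[str, sp.csr_matrix]]  # keyed by nucleus label
    projectors: dict[str, sp.csr_matrix] = field(default_factory=dict)

    @property
    def identity(self) -> sp.csr_matrix:
        return sp.identity(self.system.dimension, format="csr", dtype=complex)


def build_operators(system: SpinSystem) -> OperatorSet:
    """Construct all embedded spin operators and electronic projectors.

    Memory grows with the Hilbert dimension; for the very large rosters used
    for dimension counting only, call :func:`hilbert_dimension` instead.
    """
    ordered = system.ordered_nuclei
    dims = (2, 2) + tuple(n.multiplicity for n in ordered)
    electron = tuple(
        {ax: _embed(spin_matrices(0.5)[ax], i, dims) for ax in _AXES} for i in (0, 1)
    )
    nuclear = {
        n.label: {
            ax: _embed(spin_matrices(n.spin)[ax], 2 + k, dims) for ax in _AXES
        }
        for k, n in enumerate(ordered)
    }
    z = system.nuclear_dimension
    id_nuc = sp.identity(z, format="csr", dtype=complex)
    projectors = {}
    for name, vec in ELECTRONIC_VECTORS.items():
        p4 = sp.csr_matrix(np.outer(vec, vec.conj()))
        projectors[name] = sp.kron(p4, id_nuc, format="csr")
    return OperatorSet(
        system=system,
        dims=dims,
        electron=electron,  # type: ignore[arg-type]
        nuclear=nuclear,
        projectors=projectors,
    )


def initial_state(
    system: SpinSystem,
    electronic_state: str,
    nuclear_part: "int | np.ndarray | SampledState",
) -> np.ndarray:
    """|Θ_init> ⊗ |nuclear>, a unit-norm full-space state vector.

    ``nuclear_part`` is either a nuclear basis index, a normalized complex
    vector over the nuclear subspace, or a :class:`SampledState`.  Mixed
    electronic initial states are not representable as a single state vector;
    simulate them by combining runs for each pure component.
    """
    if electronic_state not in ELECTRONIC_VECTORS:
        raise ValueError(
            f"electronic_state must be one of {ELECTRONIC_STATES}, got "
            f"{electronic_state!r}; mixed initial states are handled by combining runs"
        )
    z = system.nuclear_dimension
    if isinstance(nuclear_part, SampledState):
        nuc = nuclear_part.amplitudes
    elif isinstance(nuclear_part, (int, np.integer)):
        if not 0 <= nuclear_part < z:
            raise ValueError(f"nuclear basis index {nuclear_part} outside [0, {z})")
        nuc = np.zeros(z, dtype=complex)
        nuc[nuclear_part] = 1.0
    else:
        nuc = np.asarray(nuclear_part, dtype=complex)
        if nuc.shape != (z,):
            raise ValueError(f"nuclear vector must have length Z={z}")
        nrm = np.linalg.norm(nuc)
        if abs(nrm - 1.0) > 1e-8:
            raise ValueError("nuclear part must be normalized")
    return np.kron(ELECTRONIC_VECTORS[electronic_state], nuc)


@dataclass(frozen=True)
class SampledState:
    """An SU(Z) coherent state: a random unit vector on the complex hypersphere."""

    amplitudes: np.ndarray
    index: int = 0


def sample_su_z(Z: int, seed: int, index: int = 0) -> SampledState:
    """Draw one SU(Z) coherent state |Z>, reproducibly.

    Amplitudes are Z_n = (X_n + iY_n)/|Z| with X_n, Y_n independent standard
    normal deviates, which is exactly the uniform distribution on the unit
    hypersphere <Z|Z> = 1.  The stream is keyed by (seed, index), so sample
    ``m`` is identical no matter how many samples are drawn or in what order.
    """
    if Z < 1:
        raise ValueError("Z must be >= 1")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(index),))
    rng = np.random.default_rng(ss)
    z = rng.standard_normal(Z) + 1j * rng.standard_normal(Z)
    z /= np.linalg.norm(z)
    return SampledState(amplitudes=z, index=index)
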