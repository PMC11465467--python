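"""Spin Hamiltonians: Zeeman, hyperfine, exchange and dipolar couplings.

Units at the API surface follow magnetic-resonance convention: magnetic
fields in mT, coupling tensors/constants in MHz (or mT for isotropic
hyperfines and the exchange, converted via the electron gyromagnetic
ratio), rates in µs⁻¹ and times in ns.  Internally every Hamiltonian is an
angular frequency in rad µs⁻¹, i.e. MHz values are multiplied by 2π and
fields by g·μ_B/ℏ.

Exchange convention: H_ex = −J (2 S₁·S₂ + ½), so the singlet–triplet
splitting is exactly 2J.  Configurations may specify either ``J`` or ``2J``
(the quantity quoted for molecular wires, e.g. 2J = 6.4 mT) — use the
explicit helpers to avoid the classic factor-of-two trap.  When a combined
electron–electron coupling tensor C = D − 2J·1 is supplied it replaces the
separate J and D terms (they differ only by a physically irrelevant
multiple of the identity).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import constants

from .spin_space import OperatorSet, SpinSystem, build_operators

_AXES = ("x", "y", "z")

#: rad µs⁻¹ per mT per unit g-value: μ_B/ℏ × 10⁻⁹ (T→mT and s→µs).
_MU_B_OVER_HBAR_RAD_PER_US_MT = (
    constants.value("Bohr magneton") / constants.hbar * 1e-9
)

#: Default (free-electron) g-value.
G_E = 2.0023

TWO_PI = 2.0 * np.pi


def gyromagnetic_rad_per_us_mT(g: float = G_E) -> float:
    """Electron gyromagnetic ratio g·μ_B/ℏ in rad µs⁻¹ mT⁻¹."""
    return g * _MU_B_OVER_HBAR_RAD_PER_US_MT


def mT_to_MHz(value_mT: float, g: float = G_E) -> float:
    """Convert a coupling expressed as a field (mT) to a frequency (MHz)."""
    return value_mT * gyromagnetic_rad_per_us_mT(g) / TWO_PI


def MHz_to_mT(value_MHz: float, g: float = G_E) -> float:
    return value_MHz * TWO_PI / gyromagnetic_rad_per_us_mT(g)


def _as_tensor(value) -> np.ndarray:
    t = np.asarray(value, dtype=float)
    if t.shape == ():
        t = float(t) * np.eye(3)
    if t.shape != (3, 3):
        raise ValueError(f"tensor must be 3x3 (or scalar), got shape {t.shape}")
    return t


@dataclass(frozen=True)
class Hyperfine:
    """Hyperfine coupling of one nucleus to its radical's electron."""

    nucleus: str
    tensor_MHz: np.ndarray
    dynamic: str | None = None  # trajectory tag, if this tensor fluctuates

    def __post_init__(self):
        object.__setattr__(self, "tensor_MHz", _as_tensor(self.tensor_MHz))

    @classmethod
    def isotropic(
        cls,
        nucleus: str,
        a_MHz: float | None = None,
        a_mT: float | None = None,
        g: float = G_E,
        dynamic: str | None = None,
    ) -> "Hyperfine":
        if (a_MHz is None) == (a_mT is None):
            raise ValueError("give exactly one of a_MHz or a_mT")
        a = a_MHz if a_MHz is not None else mT_to_MHz(a_mT, g)
        return cls(nucleus=nucleus, tensor_MHz=a * np.eye(3), dynamic=dynamic)


@dataclass(frozen=True)
class InteractionSet:
    """All couplings plus the external field for one radical-pair model."""

    field_mT: np.ndarray = field(default_factory=lambda: np.zeros(3))
    hyperfines: tuple[Hyperfine, ...] = ()
    j_MHz: float = 0.0  # exchange J; singlet-triplet gap = 2J
    dipolar_MHz: np.ndarray | None = None  # traceless symmetric, electron-electron
    coupling_MHz: np.ndarray | None = None  # combined C = D − 2J·1; overrides J/D
    dipolar_dynamic: str | None = None  # trajectory tag for D (or C)

    def __post_init__(self):
        object.__setattr__(
            self, "field_mT", np.asarray(self.field_mT, dtype=float).reshape(3)
        )
        object.__setattr__(self, "hyperfines", tuple(self.hyperfines))
        for name in ("dipolar_MHz", "coupling_MHz"):
            t = getattr(self, name)
            if t is not None:
                t = _as_tensor(t)
                object.__setattr__(self, name, t)
        d = self.dipolar_MHz
        if d is not None:
            if not np.allclose(d, d.T, atol=1e-9):
                raise ValueError("dipolar tensor must be symmetric")
            if abs(np.trace(d)) > 1e-6 * max(1.0, np.abs(d).max()):
                raise ValueError("dipolar tensor must be traceless")

    @classmethod
    def exchange_two_j_mT(cls, two_j_mT: float, g: float = G_E, **kwargs):
        """Build with the exchange given as 2J in mT (the wire convention)."""
        return cls(j_MHz=mT_to_MHz(two_j_mT, g) / 2.0, **kwargs)

    def with_field(self, field_mT) -> "InteractionSet":
        return replace(self, field_mT=np.asarray(field_mT, dtype=float))

    def with_field_orientation(self, B_mT: float, theta_deg: float) -> "InteractionSet":
        """Field of magnitude ``B_mT`` at angle θ from the molecular z-axis, in
        the z–x plane (the orientation-scan convention: tensors stay fixed,
        the field rotates)."""
        th = np.deg2rad(theta_deg)
        return self.with_field(B_mT * np.array([np.sin(th), 0.0, np.cos(th)]))

    def hyperfine(self, nucleus: str) -> Hyperfine:
        for hf in self.hyperfines:
            if hf.nucleus == nucleus:
                return hf
        raise KeyError(f"no hyperfine declared for nucleus {nucleus!r}")

    @property
    def dynamic_tags(self) -> tuple[str, ...]:
        tags = [hf.dynamic for hf in self.hyperfines if hf.dynamic]
        if self.dipolar_dynamic:
            tags.append(self.dipolar_dynamic)
        return tuple(tags)


def _pair_term(
    ops_a: Mapping[str, sp.csr_matrix],
    ops_b: Mapping[str, sp.csr_matrix],
    tensor: np.ndarray,
) -> sp.csr_matrix:
    """Σ_ab T_ab · A_a B_b as a sparse matrix (tensor in plain frequency units)."""
    acc = None
    for a, ax_a in enumerate(_AXES):
        for b, ax_b in enumerate(_AXES):
            c = tensor[a, b]
            if c == 0.0:
                continue
            term = c * (ops_a[ax_a] @ ops_b[ax_b])
            acc = term if acc is None else acc + term
    if acc is None:
        dim = ops_a["x"].shape[0]
        return sp.csr_matrix((dim, dim), dtype=complex)
    return acc.tocsr()


def assemble_hamiltonian(
    system: SpinSystem,
    interactions: InteractionSet,
    ops: OperatorSet | None = None,
    overrides: Mapping[str, np.ndarray] | None = None,
) -> sp.csr_matrix:
    """Assemble the full static spin Hamiltonian, in rad µs⁻¹ (sparse, Hermitian).

    H = Σ_i [g_i μ_B/ℏ B·S_i + Σ_k 2π S_i·A_ik·I_ik] + H_ee,
    where H_ee is 2π S₁·C·S₂ if a combined tensor C is declared, and
    otherwise 2π S₁·D·S₂ − 2π J (2 S₁·S₂ + ½) from the separate terms.

    ``overrides`` maps a trajectory tag to the 3×3 tensor value (MHz) to use
    for the correspondingly tagged interaction — the hook used for
    time-dependent Hamiltonians.
    """
    if ops is None:
        ops = build_operators(system)
    overrides = overrides or {}
    dim = system.dimension
    H = sp.csr_matrix((dim, dim), dtype=complex)

    B = interactions.field_mT
    if np.any(B != 0.0):
        for i in (0, 1):
            gamma = gyromagnetic_rad_per_us_mT(system.g[i])
            for a, ax in enumerate(_AXES):
                if B[a] != 0.0:
                    H = H + gamma * B[a] * ops.electron[i][ax]

    for hf in interactions.hyperfines:
        nuc = system.nucleus(hf.nucleus)
        tensor = hf.tensor_MHz
        if hf.dynamic and hf.dynamic in overrides:
            tensor = _as_tensor(overrides[hf.dynamic])
        e_ops = ops.electron[nuc.radical - 1]
        H = H + TWO_PI * _pair_term(e_ops, ops.nuclear[hf.nucleus], tensor)

    e1, e2 = ops.electron
    if interactions.coupling_MHz is not None:
        C = interactions.coupling_MHz
        if interactions.dipolar_dynamic and interactions.dipolar_dynamic in overrides:
            C = _as_tensor(overrides[interactions.dipolar_dynamic])
        H = H + TWO_PI * _pair_term(e1, e2, C)
    else:
        D = interactions.dipolar_MHz
        if interactions.dipolar_dynamic and interactions.dipolar_dynamic in overrides:
            D = _as_tensor(overrides[interactions.dipolar_dynamic])
        if D is not None:
            H = H + TWO_PI * _pair_term(e1, e2, D)
        J = interactions.j_MHz
        if J != 0.0:
            s_dot_s = _pair_term(e1, e2, np.eye(3))
            H = H - TWO_PI * J * (2.0 * s_dot_s + 0.5 * ops.identity)
    H.eliminate_zeros()
    return H.tocsr()


@dataclass
class TrajectorySeries:
    """Uniformly sampled time series of interaction tensors or scalars.

    ``data`` maps a tag to either an (n, 3, 3) tensor series (MHz) or an
    (n,) scalar coefficient series.  Lookup uses a zero-order hold: the
    value at time t is the sample at the grid point at-or-before t; times
    beyond the final sample raise (no extrapolation).
    """

    times_ns: np.ndarray
    data: dict[str, np.ndarray]

    def __post_init__(self):
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        if self.times_ns.ndim != 1 or len(self.times_ns) == 0:
            raise ValueError("times_ns must be a non-empty 1-D array")
        if np.any(np.diff(self.times_ns) <= 0):
            raise ValueError("times_ns must be strictly increasing")
        n = len(self.times_ns)
        for tag, series in self.data.items():
            series = np.asarray(series, dtype=float)
            if series.shape not in ((n,), (n, 3, 3)):
                raise ValueError(
                    f"series {tag!r} must have shape ({n},) or ({n},3,3), "
                    f"got {series.shape}"
                )
            if not np.all(np.isfinite(series)):
                raise ValueError(f"series {tag!r} contains non-finite values")
            self.data[tag] = series

    @property
    def span_ns(self) -> tuple[float, float]:
        return float(self.times_ns[0]), float(self.times_ns[-1])

    def index_at(self, t_ns: float) -> int:
        t0, t1 = self.span_ns
        if t_ns < t0 - 1e-9 or t_ns > t1 + 1e-9:
            raise ValueError(
                f"time {t_ns} ns outside trajectory span [{t0}, {t1}] ns "
                "(no extrapolation)"
            )
        idx = int(np.searchsorted(self.times_ns, t_ns + 1e-9, side="right") - 1)
        return max(idx, 0)

    def value(self, tag: str, t_ns: float) -> np.ndarray | float:
        series = self.data[tag]
        v = series[self.index_at(t_ns)]
        return float(v) if np.ndim(v) == 0 else v

    def values_at(self, t_ns: float) -> dict[str, np.ndarray | float]:
        idx = self.index_at(t_ns)
        return {
            tag: (float(s[idx]) if s.ndim == 1 else s[idx])
            for tag, s in self.data.items()
        }

    # --- text round-trip -------------------------------------------------
    _COMPONENTS = tuple(a + b for a in "xyz" for b in "xyz")

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"time_ns": self.times_ns}
        for tag, series in self.data.items():
            if series.ndim == 1:
                cols[tag] = series
            else:
                flat = series.reshape(len(series), 9)
                for c, comp in enumerate(self._COMPONENTS):
                    cols[f"{tag}.{comp}"] = flat[:, c]
        return pd.DataFrame(cols)

    def write(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrajectorySeries":
        if "time_ns" not in frame.columns:
            raise ValueError("trajectory file must have a 'time_ns' column")
        times = frame["time_ns"].to_numpy(dtype=float)
        tensors: dict[str, dict[str, np.ndarray]] = {}
        scalars: dict[str, np.ndarray] = {}
        for col in frame.columns:
            if col == "time_ns":
                continue
            if "." in col:
                tag, comp = col.rsplit(".", 1)
                if comp not in cls._COMPONENTS:
                    raise ValueError(f"unknown tensor component column {col!r}")
                tensors.setdefault(tag, {})[comp] = frame[col].to_numpy(dtype=float)
            else:
                scalars[col] = frame[col].to_numpy(dtype=float)
        data: dict[str, np.ndarray] = dict(scalars)
        for tag, comps in tensors.items():
            missing = set(cls._COMPONENTS) - set(comps)
            if missing:
                raise ValueError(f"tag {tag!r} missing components {sorted(missing)}")
            stack = np.stack([comps[c] for c in cls._COMPONENTS], axis=1)
            data[tag] = stack.reshape(len(times), 3, 3)
        return cls(times_ns=times, data=data)

    @classmethod
    def read(cls, path, sep: str | None = None) -> "TrajectorySeries":
        frame = pd.read_csv(path, sep=sep, engine="python")
        return cls.from_frame(frame)


def hamiltonian_at_time(
    system: SpinSystem,
    interactions: InteractionSet,
    trajectory: TrajectorySeries,
    t_ns: float,
    ops: OperatorSet | None = None,
) -> sp.csr_matrix:
    """Static parts + tagged tensors held at their trajectory value covering t."""
    overrides = trajectory.values_at(t_ns)
    return assemble_hamiltonian(system, interactions, ops=ops, overrides=overrides)


class DynamicHamiltonian:
    """H(t) = H_static + Σ_tags Σ_ab c_ab(t)·O_ab, precomputed for fast stepping.

    Equivalent to re-assembling :func:`hamiltonian_at_time` at every step
    (verified by test), but the component operators S_a I_b of every tagged
    interaction are built once.
    """

    def __init__(
        self,
        system: SpinSystem,
        interactions: InteractionSet,
        trajectory: TrajectorySeries,
        ops: OperatorSet | None = None,
    ):
        self.system = system
        self.interactions = interactions
        self.trajectory = trajectory
        self.ops = ops if ops is not None else build_operators(system)
        tags = interactions.dynamic_tags
        missing = [t for t in tags if t not in trajectory.data]
        if missing:
            raise ValueError(f"trajectory lacks series for tags {missing}")
        # static part: tagged tensors zeroed out
        zero = {t: np.zeros((3, 3)) for t in tags}
        self._static = assemble_hamiltonian(
            system, interactions, ops=self.ops, overrides=zero
        )
        # component operators per tag (includes the 2π MHz→rad µs⁻¹ factor)
        self._components: dict[str, list[sp.csr_matrix]] = {}
        for hf in interactions.hyperfines:
            if not hf.dynamic:
                continue
            e_ops = self.ops.electron[system.nucleus(hf.nucleus).radical - 1]
            n_ops = self.ops.nuclear[hf.nucleus]
            self._components[hf.dynamic] = [
                TWO_PI * (e_ops[a] @ n_ops[b]) for a in _AXES for b in _AXES
            ]
        if interactions.dipolar_dynamic:
            e1, e2 = self.ops.electron
            self._components[interactions.dipolar_dynamic] = [
                TWO_PI * (e1[a] @ e2[b]) for a in _AXES for b in _AXES
            ]

    def at(self, t_ns: float) -> sp.csr_matrix:
        H = self._static
        idx = self.trajectory.index_at(t_ns)
        for tag, comps in self._components.items():
            coeffs = self.trajectory.data[tag][idx].reshape(9)
            for c, op in zip(coeffs, comps):
                if c != 0.0:
                    H = H + c * op
        return H.tocsr()


@dataclass(frozen=True)
class DrivenGeometry:
    """Coherently modulated inter-radical distance with exponential distance laws.

    r(t) = r0 + (Δ_d/2)(1 − cos 2π v_d t) oscillates with period 1/v_d and
    peak-to-peak amplitude Δ_d, starting from the contact distance r0.  The
    singlet recombination rate and the exchange follow the same exponential
    law, k_b(t) = k_b0·e^(−β(r−r0)) and J(t) = J0·e^(−β(r−r0)), so
    J(t)/J0 = k_b(t)/k_b0 at all times and max/min = e^(βΔ_d) over a period.
    """

    J0_MHz: float
    v_d_MHz: float = 0.0
    r0_A: float = 17.8
    delta_d_A: float = 3.0
    beta_per_A: float = 1.4
    k_b0_per_us: float = 2.0

    def __post_init__(self):
        if self.delta_d_A < 0:
            raise ValueError("delta_d must be non-negative")
        if self.v_d_MHz < 0:
            raise ValueError("driving frequency must be non-negative")
        if self.beta_per_A <= 0:
            raise ValueError("beta must be positive")

    def distance_A(self, t_ns: float) -> float:
        if self.v_d_MHz == 0.0:
            return self.r0_A
        phase = TWO_PI * self.v_d_MHz * t_ns * 1e-3  # MHz × ns → cycles ×2π
        return self.r0_A + 0.5 * self.delta_d_A * (1.0 - np.cos(phase))

    def at(self, t_ns: float) -> tuple[float, float, float]:
        """(r(t) Å, J(t) MHz, k_b(t) µs⁻¹)."""
        r = self.distance_A(t_ns)
        factor = float(np.exp(-self.beta_per_A * (r - self.r0_A)))
        return r, self.J0_MHz * factor, self.k_b0_per_us * factor


def driven_geometry(t_ns: float, params: DrivenGeometry) -> tuple[float, float, float]:
    """Functional wrapper: (r Å, J MHz, k_b µs⁻¹) at time t."""
    return params.at(t_ns)
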