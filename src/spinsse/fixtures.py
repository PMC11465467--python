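"""Built-in model systems and a synthetic tensor-fluctuation generator.

The fluctuation generator emulates the statistical character of
interaction-tensor time series obtained from MD geometries with quantum-
chemical tensor evaluation (sampled every 50 ps in production use):
each tensor component follows an independent stationary
Ornstein–Uhlenbeck process around its mean.  It does not reproduce any
particular molecular trajectory — it is the minimal stationary Gaussian
model with a single correlation time.

The hyperfine tensors shipped with the ``fad_trp_12``/``fad_trp_14``
rosters are SYNTHETIC stand-ins with physically plausible magnitudes and
symmetries (axial ¹⁴N tensors of flavin-like size, scattered isotropic ¹H
couplings); the literature tensors for the flavin–tryptophan pair are not
reproduced here and real applications should supply their own via the
``tensors`` argument or a trajectory/tensor file.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .interactions import DrivenGeometry, Hyperfine, InteractionSet, TrajectorySeries
from .kinetics import RateScheme
from .spin_space import Nucleus, SpinSystem


@dataclass(frozen=True)
class FluctuationSpec:
    """Ornstein–Uhlenbeck fluctuation of a 3×3 interaction tensor."""

    mean_MHz: np.ndarray  # 3×3 mean tensor (or scalar, broadcast on the diagonal)
    sigma_MHz: float  # stationary std per component
    tau_ps: float  # correlation time
    step_ps: float = 50.0  # sampling interval
    length_ns: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        m = np.asarray(self.mean_MHz, dtype=float)
        if m.shape == ():
            m = float(m) * np.eye(3)
        if m.shape != (3, 3):
            raise ValueError("mean tensor must be 3x3 or scalar")
        object.__setattr__(self, "mean_MHz", m)
        if self.tau_ps <= 0:
            raise ValueError("correlation time must be positive")
        if self.step_ps <= 0:
            raise ValueError("sampling step must be positive")
        if self.sigma_MHz < 0:
            raise ValueError("sigma must be non-negative")


def generate_fluctuating_tensor(spec: FluctuationSpec, tag: str) -> TrajectorySeries:
    """Sample a tensor time series with the exact OU update.

    x_{n+1} = μ + (x_n − μ)·e^(−Δ/τ) + σ·sqrt(1 − e^(−2Δ/τ))·ξ_n, with the
    initial sample drawn from the stationary distribution N(μ, σ²), so the
    whole series is stationary.  Reproducible for a given seed.
    """
    n = int(np.floor(spec.length_ns * 1e3 / spec.step_ps)) + 1
    times_ns = np.arange(n) * spec.step_ps * 1e-3
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(spec.seed)))
    mu = spec.mean_MHz.reshape(9)
    if spec.sigma_MHz == 0.0:
        series = np.tile(mu, (n, 1))
    else:
        rho = np.exp(-spec.step_ps / spec.tau_ps)
        noise_scale = spec.sigma_MHz * np.sqrt(1.0 - rho * rho)
        series = np.empty((n, 9))
        series[0] = mu + spec.sigma_MHz * rng.standard_normal(9)
        for i in range(1, n):
            series[i] = (
                mu
                + (series[i - 1] - mu) * rho
                + noise_scale * rng.standard_normal(9)
            )
    return TrajectorySeries(
        times_ns=times_ns, data={tag: series.reshape(n, 3, 3)}
    )


# ---------------------------------------------------------------------------
# built-in model systems

#: Axial N5-like ¹⁴N hyperfine tensor (MHz): the dominant flavin coupling.
N5_TENSOR_MHZ = np.diag([-2.6, -2.6, 49.2])

#: Default driven-geometry parameters for the single-nitrogen driven model.
DRIVEN_N5_GEOMETRY = DrivenGeometry(
    J0_MHz=10.0, v_d_MHz=0.0, r0_A=17.8, delta_d_A=3.0, beta_per_A=1.4,
    k_b0_per_us=2.0,
)

_BUILTIN_NAMES = ("driven_n5", "wire_toy", "fad_trp_12", "fad_trp_14")


def _synthetic_fad_trp_tensors(labels: list[str]) -> dict[str, np.ndarray]:
    """Deterministic synthetic hyperfine tensors (MHz) for the FAD/Trp rosters.

    Axial nitrogen tensors of flavin-like magnitude; proton couplings are
    isotropic with alternating signs and sub-mT sizes.  Synthetic — see the
    module docstring.
    """
    tensors: dict[str, np.ndarray] = {}
    n_count = 0
    h_values = [-4.0, 2.5, -1.5, 8.0, -6.5, 5.0, -3.0, 1.0, 4.5, -2.0, 7.0]
    h_count = 0
    for label in labels:
        if label.startswith("N"):
            # axial, dominant z component, traceful like real ¹⁴N hyperfines
            big = [49.2, 25.0, 18.0, 30.0][n_count % 4]
            small = [-2.6, -1.0, 0.5, -1.8][n_count % 4]
            tensors[label] = np.diag([small, small, big])
            n_count += 1
        else:
            a = h_values[h_count % len(h_values)]
            tensors[label] = a * np.eye(3)
            h_count += 1
    return tensors


def fad_trp_coupling_synthetic() -> np.ndarray:
    """A synthetic combined electron–electron coupling tensor C = D − 2J·1 (MHz).

    Axial traceless dipolar part of ~−11 MHz (z principal value) plus an
    exchange of 1.4 MHz — representative magnitudes for a protein radical
    pair at ~2 nm separation, not literature values.
    """
    D = np.diag([5.6, 5.6, -11.2])
    J = 1.4
    return D - 2.0 * J * np.eye(3)


_FAD_TRP_12_ROSTER = [
    # FAD radical (radical 1): N5, N10, H6, 3×H8, Hβ
    ("N5", 1, 1.0), ("N10", 1, 1.0), ("H6", 1, 0.5),
    ("H8a", 1, 0.5), ("H8b", 1, 0.5), ("H8c", 1, 0.5), ("Hbeta", 1, 0.5),
    # TrpH radical (radical 2): N1, H1, H2, H4, H6
    ("N1", 2, 1.0), ("W_H1", 2, 0.5), ("W_H2", 2, 0.5),
    ("W_H4", 2, 0.5), ("W_H6", 2, 0.5),
]

_FAD_TRP_14_ROSTER = _FAD_TRP_12_ROSTER + [
    ("W_H7", 2, 0.5), ("W_Hbeta1", 2, 0.5),
]


def builtin_system(
    name: str,
    tensors: dict[str, np.ndarray] | None = None,
    include_coupling: bool = False,
) -> tuple[SpinSystem, InteractionSet, RateScheme]:
    """Return a named (SpinSystem, InteractionSet, RateScheme) parameterization.

    * ``driven_n5`` — one axial I=1 nucleus (−2.6/−2.6/49.2 MHz), B = 50 µT,
      singlet backward rate k_b0 = 2 µs⁻¹ at the contact distance, forward
      rate k_f = 0.5 µs⁻¹ (driven runs replace k_S and J with the
      distance-modulated k_b(t), J(t); see DRIVEN_N5_GEOMETRY).
    * ``wire_toy`` — a reduced donor–bridge–acceptor pair: three isotropic
      sub-mT proton couplings, exchange declared as 2J = 6.4 mT,
      k_T = 350 µs⁻¹, k_S = 2.45 µs⁻¹.
    * ``fad_trp_12`` / ``fad_trp_14`` — flavin/tryptophan nucleus rosters
      (3 resp. 3 ¹⁴N and 9 resp. 11 ¹H) with pluggable hyperfine tensors
      (synthetic defaults); ``include_coupling`` adds the synthetic combined
      electron–electron tensor.
    """
    if name == "driven_n5":
        system = SpinSystem(nuclei=(Nucleus("N5", 1, 1.0),))
        ints = InteractionSet(
            field_mT=np.array([0.0, 0.0, 0.05]),
            hyperfines=(Hyperfine("N5", N5_TENSOR_MHZ),),
        )
        rates = RateScheme(k_S=DRIVEN_N5_GEOMETRY.k_b0_per_us, k_f=0.5)
        return system, ints, rates
    if name == "wire_toy":
        system = SpinSystem(
            nuclei=(
                Nucleus("H_D", 1, 0.5),
                Nucleus("H_A1", 2, 0.5),
                Nucleus("H_A2", 2, 0.5),
            )
        )
        ints = InteractionSet.exchange_two_j_mT(
            6.4,
            hyperfines=(
                Hyperfine.isotropic("H_D", a_mT=0.4),
                Hyperfine.isotropic("H_A1", a_mT=0.3),
                Hyperfine.isotropic("H_A2", a_mT=0.2),
            ),
        )
        rates = RateScheme.singlet_triplet(k_S=2.45, k_T=350.0)
        return system, ints, rates
    if name in ("fad_trp_12", "fad_trp_14"):
        roster = _FAD_TRP_12_ROSTER if name == "fad_trp_12" else _FAD_TRP_14_ROSTER
        system = SpinSystem(nuclei=tuple(Nucleus(*row) for row in roster))
        labels = [row[0] for row in roster]
        tensor_map = dict(_synthetic_fad_trp_tensors(labels))
        if tensors:
            tensor_map.update({k: np.asarray(v, dtype=float) for k, v in tensors.items()})
        ints = InteractionSet(
            field_mT=np.array([0.0, 0.0, 0.05]),
            hyperfines=tuple(Hyperfine(lbl, tensor_map[lbl]) for lbl in labels),
            coupling_MHz=fad_trp_coupling_synthetic() if include_coupling else None,
        )
        rates = RateScheme.symmetric(1.0)
        return system, ints, rates
    raise KeyError(f"unknown builtin system {name!r}; choose from {_BUILTIN_NAMES}")
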