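"""Hamiltonian assembly, unit conversions, trajectories, driven geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import constants

from spinsse import (
    DrivenGeometry,
    Hyperfine,
    InteractionSet,
    MHz_to_mT,
    Nucleus,
    SpinSystem,
    TrajectorySeries,
    assemble_hamiltonian,
    build_operators,
    driven_geometry,
    hamiltonian_at_time,
    mT_to_MHz,
)
from spinsse.interactions import DynamicHamiltonian, gyromagnetic_rad_per_us_mT


def test_empty_interactions_give_zero_operator():
    system = SpinSystem(nuclei=(Nucleus("H", 1, 0.5),))
    H = assemble_hamiltonian(system, InteractionSet())
    assert H.nnz == 0


def test_zeeman_splitting_matches_codata():
    """1 mT along z splits each electron's levels by g·μ_B·B/ℏ."""
    g = 2.0023
    system = SpinSystem(g=(g, g))
    ints = InteractionSet(field_mT=[0.0, 0.0, 1.0])
    H = assemble_hamiltonian(system, ints).toarray()
    eigs = np.sort(np.linalg.eigvalsh(H))
    gamma = g * constants.value("Bohr magneton") / constants.hbar * 1e-9  # rad/µs/mT
    assert np.allclose(eigs, [-gamma, 0.0, 0.0, gamma], rtol=1e-12)


def test_isotropic_hyperfine_two_spin_levels():
    """a(S·I) for two spins-1/2 has eigenvalues a/4 (triplet) and −3a/4 (singlet)."""
    a_MHz = 5.0
    system = SpinSystem(nuclei=(Nucleus("H", 1, 0.5),))
    ints = InteractionSet(hyperfines=(Hyperfine.isotropic("H", a_MHz=a_MHz),))
    H = assemble_hamiltonian(system, ints).toarray()
    w = 2 * np.pi * a_MHz
    uniq = np.unique(np.round(np.linalg.eigvalsh(H), 9))
    assert np.allclose(uniq, [-0.75 * w, 0.25 * w], atol=1e-9)


def test_exchange_singlet_triplet_gap_is_two_j():
    J = 3.0  # MHz
    system = SpinSystem()
    H = assemble_hamiltonian(system, InteractionSet(j_MHz=J)).toarray()
    uniq = np.unique(np.round(np.linalg.eigvalsh(H), 9))
    assert np.allclose(uniq, [-2 * np.pi * J, 2 * np.pi * J], atol=1e-9)
    # the 2J convention helper halves the declared value
    ints = InteractionSet.exchange_two_j_mT(6.4)
    assert np.isclose(ints.j_MHz, mT_to_MHz(6.4) / 2)


def test_combined_coupling_equals_dipolar_minus_exchange_up_to_identity():
    """S1·(D − 2J·1)·S2 differs from the explicit J+D assembly only by a
    multiple of the identity (a global energy offset)."""
    D = np.diag([1.0, 1.0, -2.0])
    J = 2.5
    system = SpinSystem(nuclei=(Nucleus("H", 1, 0.5),))
    ops = build_operators(system)
    H_sep = assemble_hamiltonian(
        system, InteractionSet(j_MHz=J, dipolar_MHz=D), ops
    ).toarray()
    H_cmb = assemble_hamiltonian(
        system, InteractionSet(coupling_MHz=D - 2 * J * np.eye(3)), ops
    ).toarray()
    diff = H_sep - H_cmb
    off = diff - np.eye(len(diff)) * diff[0, 0]
    assert np.abs(off).max() < 1e-9


def test_unit_round_trip():
    a = 0.731  # mT
    assert np.isclose(MHz_to_mT(mT_to_MHz(a)), a, rtol=1e-9)
    # field → rad/µs agrees with mT→MHz→rad/µs
    assert np.isclose(
        gyromagnetic_rad_per_us_mT() * a, mT_to_MHz(a) * 2 * np.pi, rtol=1e-9
    )


def test_dipolar_validation():
    with pytest.raises(ValueError, match="traceless"):
        InteractionSet(dipolar_MHz=np.eye(3))
    with pytest.raises(ValueError, match="symmetric"):
        InteractionSet(dipolar_MHz=np.array([[0, 1, 0], [0, 0, 0], [0, 0, 0.0]]))


def test_hyperfine_for_undeclared_spin_rejected():
    system = SpinSystem(nuclei=(Nucleus("H", 1, 0.5),))
    ints = InteractionSet(hyperfines=(Hyperfine.isotropic("Hx", a_MHz=1.0),))
    with pytest.raises(KeyError, match="Hx"):
        assemble_hamiltonian(system, ints)


@settings(max_examples=20, deadline=None)
@given(data=st.data())
def test_assembled_hamiltonian_is_hermitian(data):
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    system = SpinSystem(nuclei=(Nucleus("N", 1, 1.0), Nucleus("H", 2, 0.5)))
    A = rng.normal(scale=10, size=(3, 3))
    d = rng.normal(scale=3, size=3)
    D = np.diag([d[0], d[1], -d[0] - d[1]])
    ints = InteractionSet(
        field_mT=rng.normal(scale=1, size=3),
        hyperfines=(
            Hyperfine("N", A),
            Hyperfine.isotropic("H", a_MHz=float(rng.normal(scale=5))),
        ),
        j_MHz=float(rng.normal(scale=2)),
        dipolar_MHz=D,
    )
    H = assemble_hamiltonian(system, ints)
    assert abs(H - H.conj().T).max() < 1e-10


# --- trajectories ---------------------------------------------------------


def _mini_traj(times, rng):
    return TrajectorySeries(
        times_ns=times,
        data={"hf": rng.normal(scale=5, size=(len(times), 3, 3))},
    )


def test_constant_trajectory_equals_static_assembly():
    system = SpinSystem(nuclei=(Nucleus("N", 1, 1.0),))
    A = np.diag([-2.6, -2.6, 49.2])
    ints = InteractionSet(hyperfines=(Hyperfine("N", A, dynamic="hf"),))
    traj = TrajectorySeries(
        times_ns=np.arange(5) * 0.05, data={"hf": np.tile(A, (5, 1, 1))}
    )
    H_t = hamiltonian_at_time(system, ints, traj, 0.12)
    H_s = assemble_hamiltonian(system, InteractionSet(hyperfines=(Hyperfine("N", A),)))
    assert abs(H_t - H_s).max() == 0.0


def test_zero_order_hold_and_bounds():
    rng = np.random.default_rng(3)
    times = np.arange(6) * 0.05
    traj = _mini_traj(times, rng)
    # exactly on a grid point → that sample
    assert np.array_equal(traj.value("hf", 0.15), traj.data["hf"][3])
    # between samples → previous sample
    assert np.array_equal(traj.value("hf", 0.174), traj.data["hf"][3])
    with pytest.raises(ValueError, match="no extrapolation"):
        traj.value("hf", 0.3)
    with pytest.raises(ValueError, match="strictly increasing"):
        TrajectorySeries(times_ns=np.zeros(3), data={})


def test_dynamic_hamiltonian_matches_reassembly_oracle():
    """H(t) from the cached component-operator path equals a from-scratch
    static assembly with the held tensor values substituted."""
    rng = np.random.default_rng(11)
    system = SpinSystem(
        nuclei=(Nucleus("N", 1, 1.0), Nucleus("H", 2, 0.5))
    )
    times = np.arange(8) * 0.05
    traj = TrajectorySeries(
        times_ns=times,
        data={
            "hfN": rng.normal(scale=8, size=(8, 3, 3)),
            "dd": np.stack([_traceless_sym(rng) for _ in range(8)]),
        },
    )
    ints = InteractionSet(
        field_mT=[0, 0, 1.0],
        hyperfines=(
            Hyperfine("N", np.zeros((3, 3)), dynamic="hfN"),
            Hyperfine.isotropic("H", a_MHz=3.0),
        ),
        dipolar_MHz=np.diag([1.0, 1.0, -2.0]),
        dipolar_dynamic="dd",
    )
    dyn = DynamicHamiltonian(system, ints, traj)
    for t in rng.uniform(0, times[-1], size=5):
        H_fast = dyn.at(t)
        H_ref = hamiltonian_at_time(system, ints, traj, t)
        assert abs(H_fast - H_ref).max() < 1e-9


def _traceless_sym(rng):
    M = rng.normal(scale=2, size=(3, 3))
    M = (M + M.T) / 2
    return M - np.trace(M) / 3 * np.eye(3)


def test_trajectory_text_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    times = np.arange(4) * 0.05
    traj = TrajectorySeries(
        times_ns=times,
        data={"hf": rng.normal(size=(4, 3, 3)), "scale": rng.normal(size=4)},
    )
    path = tmp_path / "traj.tsv"
    traj.write(path)
    back = TrajectorySeries.read(path)
    assert np.allclose(back.times_ns, traj.times_ns)
    assert np.allclose(back.data["hf"], traj.data["hf"])
    assert np.allclose(back.data["scale"], traj.data["scale"])


# --- driven geometry ------------------------------------------------------


def test_driven_static_limit():
    geo = DrivenGeometry(J0_MHz=10.0, v_d_MHz=0.0)
    for t in (0.0, 13.7, 500.0):
        r, J, kb = driven_geometry(t, geo)
        assert (r, J, kb) == (17.8, 10.0, 2.0)


def test_driven_shared_distance_factor_and_amplitude():
    geo = DrivenGeometry(J0_MHz=10.0, v_d_MHz=5.0, delta_d_A=3.0)
    t_grid = np.linspace(0.0, 200.0, 4001)  # one period at 5 MHz
    out = np.array([geo.at(t) for t in t_grid])
    r, J, kb = out[:, 0], out[:, 1], out[:, 2]
    assert np.allclose(J / geo.J0_MHz, kb / geo.k_b0_per_us, rtol=1e-12)
    assert np.isclose(r.max() - r.min(), 3.0, atol=1e-6)
    assert np.isclose(kb.max() / kb.min(), np.exp(1.4 * 3.0), rtol=1e-4)
    # periodicity: 1/v_d = 200 ns
    assert np.isclose(geo.at(17.3)[0], geo.at(217.3)[0], atol=1e-9)


def test_driven_validation():
    with pytest.raises(ValueError, match="delta_d"):
        DrivenGeometry(J0_MHz=1.0, delta_d_A=-1.0)
    with pytest.raises(ValueError, match="frequency"):
        DrivenGeometry(J0_MHz=1.0, v_d_MHz=-2.0)
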