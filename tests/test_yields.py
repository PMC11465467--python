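"""Yield integration: direct vs stochastic traces, correction factor, scans."""

import numpy as np
import pytest

from spinsse import (
    Hyperfine,
    InteractionSet,
    Nucleus,
    RateScheme,
    SpinSystem,
    anisotropy_chi,
    corrected_yield,
    dense_yield,
    orientation_scan,
    relative_yield,
    sample_su_z,
    yield_direct,
    yield_stochastic,
)
from spinsse.propagate import PropagatorConfig


def test_trivial_singlet_only_reaction(fast_config):
    """H = 0, singlet-born, only k_S: all the yield goes to the singlet."""
    system = SpinSystem(nuclei=(Nucleus("H", 1, 0.5),))
    rates = RateScheme(k_S=1.0)
    res = yield_direct(
        system, InteractionSet(), rates, "S", T_ns=12_000.0, config=fast_config
    )
    assert res.phi["S"] == pytest.approx(1.0, abs=1e-5)
    assert res.phi["T0"] == res.phi["Tp"] == res.phi["Tm"] == 0.0


def test_direct_matches_dense_oracle(one_nucleus_pair, sym_rates):
    system, ints = one_nucleus_pair
    cfg = PropagatorConfig(dt_ns=1.0)
    yd = yield_direct(system, ints, sym_rates, "S", T_ns=2000.0, config=cfg)
    yo = dense_yield(system, ints, sym_rates, "S", T_ns=2000.0, dt_ns=1.0)
    for s in yd.phi:
        assert yd.phi[s] == pytest.approx(yo.phi[s], abs=1e-6)


def test_stochastic_with_basis_states_equals_direct(one_nucleus_pair, sym_rates, fast_config):
    """Feeding the orthonormal nuclear basis as 'samples' reproduces the
    direct trace exactly (M = Z resolution of the identity)."""
    system, ints = one_nucleus_pair
    z = system.nuclear_dimension
    basis = list(np.eye(z, dtype=complex).T)
    yd = yield_direct(system, ints, sym_rates, "S", T_ns=500.0, config=fast_config)
    ys = yield_stochastic(
        system, ints, sym_rates, "S", T_ns=500.0, M=z, seed=0,
        config=fast_config, nuclear_states=basis,
    )
    for s in yd.phi:
        assert ys.phi[s] == pytest.approx(yd.phi[s], abs=1e-12)


def test_stochastic_agrees_with_direct_within_errors(four_proton_pair, sym_rates, fast_config):
    system, ints = four_proton_pair
    yd = yield_direct(
        system, ints, sym_rates, "S", T_ns=1500.0, config=fast_config, correction=True
    )
    ys = yield_stochastic(
        system, ints, sym_rates, "S", T_ns=1500.0, M=10, seed=7,
        config=fast_config, correction=True,
    )
    assert abs(ys.phi["S"] - yd.phi["S"]) < 3 * ys.stderr["S"]


def test_stochastic_estimator_is_unbiased(sym_rates, fast_config):
    """Mean over independent seeds approaches the direct value (3-nucleus pair)."""
    system = SpinSystem(
        nuclei=(Nucleus("H1", 1, 0.5), Nucleus("H2", 2, 0.5), Nucleus("H3", 2, 0.5))
    )
    ints = InteractionSet(
        field_mT=[0, 0, 0.3],
        hyperfines=(
            Hyperfine.isotropic("H1", a_mT=0.5),
            Hyperfine.isotropic("H2", a_mT=-0.3),
            Hyperfine.isotropic("H3", a_mT=0.2),
        ),
    )
    yd = yield_direct(
        system, ints, sym_rates, "S", T_ns=1000.0, config=fast_config, correction=True
    )
    vals = [
        yield_stochastic(
            system, ints, sym_rates, "S", T_ns=1000.0, M=4, seed=50_000 + 31 * r,
            config=fast_config, correction=True,
        ).phi["S"]
        for r in range(50)
    ]
    vals = np.asarray(vals)
    pooled_se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - yd.phi["S"]) < 3 * pooled_se


def test_m_larger_than_z_warns(one_nucleus_pair, sym_rates, fast_config):
    system, ints = one_nucleus_pair
    with pytest.warns(UserWarning, match="stochastic gain"):
        yield_stochastic(
            system, ints, sym_rates, "S", T_ns=10.0, M=4, seed=0, config=fast_config
        )


def test_direct_cap_points_to_stochastic(sym_rates, fast_config):
    system = SpinSystem(
        nuclei=tuple(Nucleus(f"H{i}", 1 + i % 2, 0.5) for i in range(14))
    )
    with pytest.raises(ValueError, match="yield_stochastic"):
        yield_direct(
            system, InteractionSet(), sym_rates, "S", T_ns=10.0,
            config=fast_config, z_cap=4096,
        )


# --- correction factor ----------------------------------------------------


def test_corrected_yield_exact_for_constant_population():
    for T, k in ((0.0, 1.0), (50.0, 1.0), (5000.0, 0.3)):
        n = max(int(T), 1)
        times = np.linspace(0.0, T, n + 1)
        assert corrected_yield(times, np.full(n + 1, 0.37), k) == pytest.approx(
            0.37, abs=1e-12
        )


def test_corrected_converges_to_uncorrected(one_nucleus_pair, sym_rates):
    system, ints = one_nucleus_pair
    cfg = PropagatorConfig(dt_ns=0.25)
    T = 20_000.0  # 20/k: the correction factor is 1 to ~2e-9
    yc = yield_direct(system, ints, sym_rates, "S", T_ns=T, config=cfg, correction=True)
    yu = yield_direct(system, ints, sym_rates, "S", T_ns=T, config=cfg)
    assert abs(yc.phi["S"] - yu.phi["S"]) < 1e-6


def test_corrected_short_run_matches_long_uncorrected(one_nucleus_pair, sym_rates):
    """Corrected at T = 1/k within 1e-3 of uncorrected at T = 10/k."""
    system, ints = one_nucleus_pair
    cfg = PropagatorConfig(dt_ns=0.25)
    yc = yield_direct(
        system, ints, sym_rates, "S", T_ns=1000.0, config=cfg, correction=True
    )
    yu = yield_direct(system, ints, sym_rates, "S", T_ns=10_000.0, config=cfg)
    assert abs(yc.phi["S"] - yu.phi["S"]) < 1e-3


def test_corrected_yields_conserve_probability(mixed_pair, fast_config):
    system, ints = mixed_pair
    res = yield_direct(
        system, ints, RateScheme.symmetric(1.0), "S", T_ns=1000.0,
        config=fast_config, correction=True,
    )
    assert res.total() == pytest.approx(1.0, abs=1e-4)


def test_correction_refuses_asymmetric_rates(one_nucleus_pair, fast_config):
    system, ints = one_nucleus_pair
    with pytest.raises(ValueError, match="symmetric"):
        yield_direct(
            system, ints, RateScheme.singlet_triplet(1.0, 2.0), "S",
            T_ns=100.0, config=fast_config, correction=True,
        )


# --- derived quantities ---------------------------------------------------


def test_relative_yield_trivial_limits(fast_config):
    system = SpinSystem(nuclei=(Nucleus("H", 1, 0.5),))
    ints = InteractionSet(hyperfines=(Hyperfine.isotropic("H", a_mT=0.3),))
    rates = RateScheme.singlet_triplet(2.45, 350.0)
    assert relative_yield(
        system, ints, rates, 0.0, 50.0, config=fast_config
    ) == pytest.approx(1.0, abs=1e-12)
    # vanishing observation time: nothing has reacted yet in either run
    assert relative_yield(
        system, ints, rates, 5.0, 2.0, config=PropagatorConfig(dt_ns=1.0)
    ) == pytest.approx(1.0, abs=1e-3)


def test_anisotropy_chi_contract():
    assert anisotropy_chi(0.4, 0.4) == 0.0
    assert anisotropy_chi(0.5, 0.3) == pytest.approx(-anisotropy_chi(0.3, 0.5))
    assert anisotropy_chi(0.6, 0.2) == pytest.approx((0.6 - 0.2) / 0.4)
    with pytest.raises(ValueError, match="both yields are zero"):
        anisotropy_chi(0.0, 0.0)


def test_orientation_scan_isotropic_system_is_flat(sym_rates, fast_config):
    system = SpinSystem(nuclei=(Nucleus("H", 1, 0.5),))
    ints = InteractionSet(
        field_mT=[0, 0, 0.5], hyperfines=(Hyperfine.isotropic("H", a_mT=0.5),)
    )
    scan = orientation_scan(
        system, ints, sym_rates, np.linspace(0, 180, 7), T_ns=500.0,
        config=fast_config, correction=True,
    )
    phi = scan.table["phi_S"].to_numpy()
    assert phi.max() - phi.min() < 1e-10


def test_orientation_scan_zx_mirror_symmetry(sym_rates, fast_config):
    """θ and 180°−θ give equal yields when every tensor is diagonal."""
    system = SpinSystem(nuclei=(Nucleus("N", 1, 1.0),))
    ints = InteractionSet(
        field_mT=[0, 0, 0.05],
        hyperfines=(Hyperfine("N", np.diag([-2.6, -2.6, 49.2])),),
    )
    thetas = np.array([30.0, 60.0, 120.0, 150.0])
    scan = orientation_scan(
        system, ints, sym_rates, thetas, T_ns=1000.0, config=fast_config,
        correction=True,
    )
    phi = scan.table["phi_S"].to_numpy()
    assert phi[0] == pytest.approx(phi[3], abs=1e-9)
    assert phi[1] == pytest.approx(phi[2], abs=1e-9)


def test_electron_coupling_attenuates_anisotropy(sym_rates, fast_config):
    """Adding an exchange+dipolar coupling tensor shrinks the orientation-scan
    amplitude (the spike-attenuation effect) on a reduced flavin-like model."""
    from spinsse.fixtures import N5_TENSOR_MHZ, fad_trp_coupling_synthetic

    system = SpinSystem(
        nuclei=(Nucleus("N5", 1, 1.0), Nucleus("H1", 1, 0.5), Nucleus("H2", 2, 0.5))
    )
    hfs = (
        Hyperfine("N5", N5_TENSOR_MHZ),
        Hyperfine.isotropic("H1", a_MHz=4.0),
        Hyperfine.isotropic("H2", a_MHz=-3.0),
    )
    thetas = np.linspace(0, 180, 10)
    amps = {}
    for key, coupling in (("no", None), ("with", fad_trp_coupling_synthetic())):
        ints = InteractionSet(
            field_mT=[0, 0, 0.05], hyperfines=hfs, coupling_MHz=coupling
        )
        phi = orientation_scan(
            system, ints, sym_rates, thetas, T_ns=2000.0, config=fast_config,
            correction=True,
        ).table["phi_S"]
        amps[key] = phi.max() - phi.min()
    assert amps["with"] < amps["no"]


def test_stochastic_scan_reuses_seeds_for_smooth_curves(four_proton_pair, sym_rates, fast_config):
    system, ints = four_proton_pair
    scan = orientation_scan(
        system, ints, sym_rates, np.array([0.0, 90.0]), mode="stochastic",
        T_ns=500.0, M=4, seed=3, config=fast_config, correction=True,
    )
    assert {"phi_S", "stderr_S"} <= set(scan.table.columns)
    # same seeds at every grid point → metadata records them
    assert scan.meta["seed"] == 3 and scan.meta["M"] == 4
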