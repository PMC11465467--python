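"""Declarative run configuration: TOML parsing and scan orchestration.

A run file has sections ``[system]``, ``[interactions]``, ``[kinetics]``,
``[propagation]``, ``[simulation]`` and ``[scan]``.  ``[system]`` may name a
built-in model (``builtin = "wire_toy"``) which pre-fills the interaction
and kinetics sections; explicitly given sections replace the built-in ones.
Angles are degrees and times nanoseconds in files and outputs.

Every scan writes a CSV whose ``#``-prefixed header records the version,
seed and all parameters needed to reproduce it; two runs of the same file
produce byte-identical output.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .fixtures import builtin_system
from .interactions import (
    DrivenGeometry,
    Hyperfine,
    InteractionSet,
    TrajectorySeries,
    mT_to_MHz,
)
from .kinetics import RateScheme
from .propagate import PropagatorConfig
from .spin_space import Nucleus, SpinSystem
from .yields import (
    ScanResult,
    driven_singlet_yields,
    field_scan,
    orientation_scan,
)


class ConfigError(ValueError):
    """A configuration schema violation, reported with its key path."""


def _require(table: dict, key: str, section: str):
    if key not in table:
        raise ConfigError(f"missing required key [{section}] {key}")
    return table[key]


def _build_system(sec: dict) -> SpinSystem:
    nuclei = tuple(
        Nucleus(
            label=_require(n, "label", "system.nuclei"),
            radical=int(_require(n, "radical", "system.nuclei")),
            spin=float(_require(n, "spin", "system.nuclei")),
        )
        for n in sec.get("nuclei", [])
    )
    g = tuple(sec.get("g", (2.0023, 2.0023)))
    return SpinSystem(nuclei=nuclei, g=g)


def _build_hyperfine(entry: dict) -> Hyperfine:
    nucleus = _require(entry, "nucleus", "interactions.hyperfine")
    dynamic = entry.get("dynamic")
    if "tensor_MHz" in entry:
        return Hyperfine(nucleus, np.asarray(entry["tensor_MHz"], float), dynamic)
    if "a_MHz" in entry:
        return Hyperfine.isotropic(nucleus, a_MHz=float(entry["a_MHz"]), dynamic=dynamic)
    if "a_mT" in entry:
        return Hyperfine.isotropic(nucleus, a_mT=float(entry["a_mT"]), dynamic=dynamic)
    raise ConfigError(
        f"hyperfine for {nucleus!r} needs one of tensor_MHz / a_MHz / a_mT"
    )


def _build_interactions(sec: dict, g: float) -> InteractionSet:
    j_keys = [k for k in ("j_MHz", "j_mT", "two_j_MHz", "two_j_mT") if k in sec]
    if len(j_keys) > 1:
        raise ConfigError(f"give at most one exchange key, found {j_keys}")
    j_MHz = 0.0
    if j_keys:
        key, val = j_keys[0], float(sec[j_keys[0]])
        j_MHz = {
            "j_MHz": lambda v: v,
            "j_mT": lambda v: mT_to_MHz(v, g),
            "two_j_MHz": lambda v: v / 2.0,
            "two_j_mT": lambda v: mT_to_MHz(v, g) / 2.0,
        }[key](val)
    return InteractionSet(
        field_mT=np.asarray(sec.get("field_mT", [0.0, 0.0, 0.0]), float),
        hyperfines=tuple(_build_hyperfine(h) for h in sec.get("hyperfine", [])),
        j_MHz=j_MHz,
        dipolar_MHz=np.asarray(sec["dipolar_MHz"], float) if "dipolar_MHz" in sec else None,
        coupling_MHz=np.asarray(sec["coupling_MHz"], float) if "coupling_MHz" in sec else None,
        dipolar_dynamic=sec.get("dipolar_dynamic"),
    )


def _build_rates(sec: dict) -> RateScheme:
    if "k_sym" in sec:
        return RateScheme.symmetric(float(sec["k_sym"]), k_f=float(sec.get("k_f", 0.0)))
    if "k_T" in sec:
        return RateScheme.singlet_triplet(
            float(sec.get("k_S", 0.0)), float(sec["k_T"]), k_f=float(sec.get("k_f", 0.0))
        )
    return RateScheme(
        k_S=float(sec.get("k_S", 0.0)),
        k_T0=float(sec.get("k_T0", 0.0)),
        k_Tp=float(sec.get("k_Tp", 0.0)),
        k_Tm=float(sec.get("k_Tm", 0.0)),
        k_f=float(sec.get("k_f", 0.0)),
    )


@dataclass
class RunConfig:
    """A fully resolved run: model objects plus scan instructions."""

    system: SpinSystem
    interactions: InteractionSet
    rates: RateScheme
    propagation: PropagatorConfig
    simulation: dict
    scan: dict
    trajectory: TrajectorySeries | None = None
    source: str = ""


def load_config(path) -> RunConfig:
    path = Path(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)

    sys_sec = raw.get("system", {})
    system = interactions = rates = None
    if "builtin" in sys_sec:
        system, interactions, rates = builtin_system(sys_sec["builtin"])
    if system is None or sys_sec.get("nuclei"):
        system = _build_system(sys_sec)
    if "interactions" in raw or interactions is None:
        interactions = _build_interactions(raw.get("interactions", {}), g=system.g[0])
    if "kinetics" in raw or rates is None:
        rates = _build_rates(raw.get("kinetics", {}))

    prop_sec = raw.get("propagation", {})
    propagation = PropagatorConfig(
        dt_ns=float(prop_sec.get("dt_ns", 1.0)),
        method=prop_sec.get("method", "auto"),
        epsilon=float(prop_sec.get("epsilon", 1e-6)),
        krylov_cap=int(prop_sec.get("krylov_cap", 64)),
        time_sampling=prop_sec.get("time_sampling", "start"),
    )

    sim = dict(raw.get("simulation", {}))
    sim.setdefault("mode", "direct")
    sim.setdefault("theta_init", "S")
    sim.setdefault("M", 1)
    sim.setdefault("seed", 0)
    sim.setdefault("correction", False)
    if sim["mode"] not in ("direct", "stochastic"):
        raise ConfigError("[simulation] mode must be 'direct' or 'stochastic'")

    trajectory = None
    if "trajectory" in sim:
        traj_path = Path(sim["trajectory"])
        if not traj_path.is_absolute():
            traj_path = path.parent / traj_path
        if not traj_path.exists():
            raise ConfigError(f"trajectory file not found: {traj_path}")
        trajectory = TrajectorySeries.read(traj_path)

    scan = dict(raw.get("scan", {}))
    kind = scan.get("kind")
    if kind not in ("field", "orientation", "driven"):
        raise ConfigError("[scan] kind must be 'field', 'orientation' or 'driven'")
    return RunConfig(
        system=system,
        interactions=interactions,
        rates=rates,
        propagation=propagation,
        simulation=sim,
        scan=scan,
        trajectory=trajectory,
        source=str(path),
    )


def execute(cfg: RunConfig) -> ScanResult:
    """Run the configured scan and return its table + metadata."""
    scan, sim = cfg.scan, cfg.simulation
    kind = scan["kind"]
    if kind == "field":
        grid = np.arange(
            float(_require(scan, "B_start_mT", "scan")),
            float(_require(scan, "B_stop_mT", "scan")) + 1e-12,
            float(_require(scan, "B_step_mT", "scan")),
        )
        result = field_scan(
            cfg.system,
            cfg.interactions,
            cfg.rates,
            grid,
            float(_require(scan, "t_obs_ns", "scan")),
            theta_init=sim["theta_init"],
            config=cfg.propagation,
        )
    elif kind == "orientation":
        thetas = np.linspace(
            float(scan.get("theta_start_deg", 0.0)),
            float(scan.get("theta_stop_deg", 180.0)),
            int(_require(scan, "n_theta", "scan")),
        )
        result = orientation_scan(
            cfg.system,
            cfg.interactions,
            cfg.rates,
            thetas,
            mode=sim["mode"],
            theta_init=sim["theta_init"],
            T_ns=float(_require(scan, "T_ns", "scan")),
            B_mT=scan.get("B_mT"),
            M=int(sim["M"]),
            seed=int(sim["seed"]),
            config=cfg.propagation,
            trajectory=cfg.trajectory,
            correction=bool(sim["correction"]),
        )
    else:  # driven
        import pandas as pd

        v_d_values = [float(v) for v in _require(scan, "v_d_MHz", "scan")]
        geometry = DrivenGeometry(
            J0_MHz=float(_require(scan, "J0_MHz", "scan")),
            v_d_MHz=0.0,
            r0_A=float(scan.get("r0_A", 17.8)),
            delta_d_A=float(scan.get("delta_d_A", 3.0)),
            beta_per_A=float(scan.get("beta_per_A", 1.4)),
            k_b0_per_us=float(scan.get("k_b0_per_us", 2.0)),
        )
        k_f = float(scan.get("k_f_per_us", 0.5))
        rows = []
        for v_d in v_d_values:
            geo = DrivenGeometry(
                J0_MHz=geometry.J0_MHz,
                v_d_MHz=v_d,
                r0_A=geometry.r0_A,
                delta_d_A=geometry.delta_d_A,
                beta_per_A=geometry.beta_per_A,
                k_b0_per_us=geometry.k_b0_per_us,
            )
            par, perp, chi = driven_singlet_yields(
                cfg.system,
                cfg.interactions,
                geo,
                k_f,
                T_ns=float(_require(scan, "T_ns", "scan")),
                theta_init=sim["theta_init"],
                config=cfg.propagation,
            )
            rows.append(
                {
                    "v_d_MHz": v_d,
                    "J0_MHz": geometry.J0_MHz,
                    "phi_par": par,
                    "phi_perp": perp,
                    "chi": chi,
                }
            )
        result = ScanResult(
            table=pd.DataFrame(rows),
            meta={"scan": "driven", "k_f_per_us": k_f, "T_ns": scan["T_ns"]},
        )
    result.meta.update(
        {
            "spinsse_version": __version__,
            "config": cfg.source,
            "mode": sim["mode"],
            "seed": sim["seed"],
            "dt_ns": cfg.propagation.dt_ns,
            "method": cfg.propagation.method,
            "epsilon": cfg.propagation.epsilon,
        }
    )
    return result


def run(config_path, out_path) -> ScanResult:
    """Load, execute and write one configured scan; returns the result."""
    cfg = load_config(config_path)
    result = execute(cfg)
    result.to_csv(out_path)
    return result
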