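"""Named sensitivity-study scenarios and a batch runner.

Thirteen presets vary one factor at a time around the baseline
(D = 0.20 mm, k = 0.025 J/g, tau = 1, law E1):

* material law: S1 (E2), S2 (E3);
* spatial influence parameter D: S3 (0.10), S4 (0.15), S5 (0.25),
  S6 (0.30) mm;
* reference stimulus k: S7 (0.005), S8 (0.015), S9 (0.035),
  S10 (0.045) J/g;
* rate constant tau: S11 (0.5), S12 (2.0).

``scaled=True`` substitutes a 10^3-element mesh and a 50-iteration
budget for desk-scale testing; full scale is the printed 20^3-element,
200-iteration setup.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .io import RunConfig, persist_run
from .material import builtin_laws
from .remodeling import RemodelParams, SimulationTrace, run_simulation

__all__ = ["Scenario", "preset", "scenario_labels", "scenario_config", "run_batch"]


@dataclass(frozen=True)
class Scenario:
    label: str
    D: float  # mm
    k: float  # J/g
    tau: float
    law_label: str  # E1 | E2 | E3


_PRESETS = {
    s.label: s
    for s in [
        Scenario("Baseline", 0.20, 0.025, 1.0, "E1"),
        Scenario("S1", 0.20, 0.025, 1.0, "E2"),
        Scenario("S2", 0.20, 0.025, 1.0, "E3"),
        Scenario("S3", 0.10, 0.025, 1.0, "E1"),
        Scenario("S4", 0.15, 0.025, 1.0, "E1"),
        Scenario("S5", 0.25, 0.025, 1.0, "E1"),
        Scenario("S6", 0.30, 0.025, 1.0, "E1"),
        Scenario("S7", 0.20, 0.005, 1.0, "E1"),
        Scenario("S8", 0.20, 0.015, 1.0, "E1"),
        Scenario("S9", 0.20, 0.035, 1.0, "E1"),
        Scenario("S10", 0.20, 0.045, 1.0, "E1"),
        Scenario("S11", 0.20, 0.025, 0.5, "E1"),
        Scenario("S12", 0.20, 0.025, 2.0, "E1"),
    ]
}


def scenario_labels() -> list[str]:
    return list(_PRESETS)


def preset(label: str) -> Scenario:
    """Look up a sensitivity-study scenario by label."""
    try:
        return _PRESETS[label]
    except KeyError:
        raise ValueError(
            f"unknown scenario {label!r}; valid labels: {', '.join(_PRESETS)}"
        ) from None


def scenario_config(
    label: str, base: RunConfig | None = None, scaled: bool = False
) -> RunConfig:
    """Run configuration for a scenario, optionally at desk scale."""
    s = preset(label)
    cfg = base if base is not None else RunConfig()
    params = replace(cfg.remodeling, D=s.D, k=s.k, tau=s.tau)
    cfg = replace(cfg, law=builtin_laws()[s.law_label], remodeling=params)
    if scaled:
        cfg = replace(
            cfg,
            element_edge_mm=cfg.cube_edge_mm / 10.0,
            remodeling=replace(cfg.remodeling, max_iter=50),
        )
    return cfg


def run_batch(
    labels,
    base: RunConfig | None = None,
    scaled: bool = False,
    persist: bool = False,
    progress=None,
) -> dict[str, SimulationTrace]:
    """Run scenarios independently; UNSOLVABLE runs are recorded, not fatal."""
    traces: dict[str, SimulationTrace] = {}
    for label in labels:
        cfg = scenario_config(label, base, scaled)
        mesh = cfg.build_mesh()
        trace = run_simulation(
            mesh,
            cfg.law,
            cfg.remodeling,
            cfg.load,
            snapshot_every=cfg.snapshot_every if persist else 0,
            progress=progress,
        )
        if persist:
            persist_run(mesh, trace, cfg, label)
        traces[label] = trace
    return traces
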