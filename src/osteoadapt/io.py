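"""Run persistence: config parsing, VTK snapshots, CSV traces, JSON summaries.

Snapshots are legacy-ASCII VTK unstructured grids (hexahedron cells,
density and SED as cell data).  The legacy dialect is used because it is
self-contained to write *and* re-read without a VTK dependency; any
standard 3D viewer (ParaView, VisIt) opens it directly.  Floats are
printed with repr-exact precision, so write -> read -> write is
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fem import LoadCase
from .material import MaterialLaw, builtin_laws
from .mesh import GridMesh, build_grid
from .remodeling import RemodelParams, SimulationTrace

__all__ = [
    "RunConfig",
    "RunArtifacts",
    "read_config",
    "config_to_dict",
    "write_snapshot",
    "read_snapshot",
    "write_trace_csv",
    "write_summary_json",
    "persist_run",
]


@dataclass(frozen=True)
class RunConfig:
    """Fully validated run configuration; defaults are the cube baseline."""

    cube_edge_mm: float = 5.0
    element_edge_mm: float = 0.25
    law: MaterialLaw = field(default_factory=lambda: builtin_laws()["E1"])
    load: LoadCase = field(default_factory=lambda: LoadCase(p_max=10.0))
    remodeling: RemodelParams = field(default_factory=RemodelParams)
    output_directory: str = "output"
    snapshot_every: int = 50

    def build_mesh(self) -> GridMesh:
        return build_grid(self.cube_edge_mm, self.element_edge_mm)


_SECTIONS = {"geometry", "material", "load", "remodeling", "output"}
_REMODEL_KEYS = {
    "D",
    "k",
    "tau",
    "rho0",
    "rho_min",
    "rho_max",
    "max_iter",
    "tol",
    "cutoff_multiple",
}


def _fail(key: str, why: str):
    raise ValueError(f"invalid configuration key {key!r}: {why}")


def config_from_dict(raw: dict | None) -> RunConfig:
    """Validate a nested configuration dict; missing keys take defaults."""
    raw = dict(raw or {})
    unknown = set(raw) - _SECTIONS
    if unknown:
        _fail(sorted(unknown)[0], f"unknown section (expected {sorted(_SECTIONS)})")

    geom = raw.get("geometry") or {}
    cube = float(geom.get("cube_edge_mm", 5.0))
    elem = float(geom.get("element_edge_mm", 0.25))
    try:
        build_grid(cube, elem)  # divisibility / positivity check
    except ValueError as exc:
        _fail("geometry", str(exc))

    mat = raw.get("material") or {}
    if "label" in mat:
        label = mat["label"]
        laws = builtin_laws()
        if label not in laws:
            _fail("material.label", f"must be one of {sorted(laws)}")
        law = laws[label]
    elif mat:
        try:
            law = MaterialLaw(
                coefficient_mpa=float(mat["a"]),
                exponent=float(mat["b"]),
                poisson_ratio=float(mat.get("nu", 0.3)),
                label="custom",
            )
        except KeyError as exc:
            _fail(f"material.{exc.args[0]}", "required for a custom law")
        except ValueError as exc:
            _fail("material", str(exc))
    else:
        law = builtin_laws()["E1"]

    ld = raw.get("load") or {}
    try:
        load = LoadCase(
            p_max=float(ld.get("p_max", 10.0)), profile=ld.get("profile", "graded")
        )
    except ValueError as exc:
        _fail("load", str(exc))

    rm = raw.get("remodeling") or {}
    unknown = set(rm) - _REMODEL_KEYS
    if unknown:
        _fail(f"remodeling.{sorted(unknown)[0]}", "unknown parameter")
    try:
        cutoff = rm.get("cutoff_multiple", 5.0)
        params = RemodelParams(
            D=float(rm.get("D", 0.20)),
            k=float(rm.get("k", 0.025)),
            tau=float(rm.get("tau", 1.0)),
            rho0=float(rm.get("rho0", 0.87)),
            rho_min=float(rm.get("rho_min", 0.0174)),
            rho_max=float(rm.get("rho_max", 1.74)),
            max_iter=int(rm.get("max_iter", 200)),
            tol=float(rm.get("tol", 0.01)),
            cutoff_multiple=None if cutoff is None else float(cutoff),
        )
    except ValueError as exc:
        _fail("remodeling", str(exc))

    out = raw.get("output") or {}
    return RunConfig(
        cube_edge_mm=cube,
        element_edge_mm=elem,
        law=law,
        load=load,
        remodeling=params,
        output_directory=str(out.get("directory", "output")),
        snapshot_every=int(out.get("snapshot_every", 50)),
    )


def read_config(path) -> RunConfig:
    """Read and validate a YAML run configuration.

    An empty file yields the full baseline defaults (5 mm cube, 0.25 mm
    elements, law E1, p_max = 10 N/mm^2, D = 0.20 mm, k = 0.025 J/g,
    tau = 1, rho0 = 0.87, clamps 0.0174/1.74 g/cm^3).
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is not None and not isinstance(raw, dict):
        raise ValueError(f"configuration root must be a mapping, got {type(raw)}")
    return config_from_dict(raw)


def config_to_dict(cfg: RunConfig) -> dict:
    """Nested plain dict representation (round-trips through YAML/JSON)."""
    law = {"label": cfg.law.label}
    if cfg.law.label == "custom":
        law = {
            "a": cfg.law.coefficient_mpa,
            "b": cfg.law.exponent,
            "nu": cfg.law.poisson_ratio,
        }
    return {
        "geometry": {
            "cube_edge_mm": cfg.cube_edge_mm,
            "element_edge_mm": cfg.element_edge_mm,
        },
        "material": law,
        "load": {"p_max": cfg.load.p_max, "profile": cfg.load.profile},
        "remodeling": {
            "D": cfg.remodeling.D,
            "k": cfg.remodeling.k,
            "tau": cfg.remodeling.tau,
            "rho0": cfg.remodeling.rho0,
            "rho_min": cfg.remodeling.rho_min,
            "rho_max": cfg.remodeling.rho_max,
            "max_iter": cfg.remodeling.max_iter,
            "tol": cfg.remodeling.tol,
            "cutoff_multiple": cfg.remodeling.cutoff_multiple,
        },
        "output": {
            "directory": cfg.output_directory,
            "snapshot_every": cfg.snapshot_every,
        },
    }


# ---------------------------------------------------------------------------
# VTK legacy unstructured grid


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_snapshot(
    mesh: GridMesh,
    density,
    sed=None,
    iteration: int = 0,
    path=None,
) -> Path:
    """Write density (and optionally SED) as VTK hexahedron cell data."""
    rho = np.asarray(getattr(density, "values", density), dtype=float)
    path = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        f"osteoadapt snapshot iteration {iteration}",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [" ".join(_fmt(c) for c in p) for p in mesh.node_coordinates]
    lines.append(f"CELLS {mesh.n_elements} {mesh.n_elements * 9}")
    lines += ["8 " + " ".join(str(i) for i in conn) for conn in mesh.element_connectivity]
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines += ["12"] * mesh.n_elements
    lines.append(f"CELL_DATA {mesh.n_elements}")
    fields = {"density": rho}
    if sed is not None:
        fields["sed"] = np.asarray(sed, dtype=float)
    for name, values in fields.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [_fmt(v) for v in values]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_snapshot(path):
    """Minimal legacy-VTK reader: returns (points, connectivity, cell_data)."""
    tokens = Path(path).read_text().split("\n")
    points = None
    cells = None
    cell_data: dict[str, np.ndarray] = {}
    i = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            points = np.array(
                [[float(v) for v in tokens[i + 1 + r].split()] for r in range(n)]
            )
            i += n
        elif line.startswith("CELLS"):
            n = int(line.split()[1])
            cells = np.array(
                [[int(v) for v in tokens[i + 1 + r].split()[1:]] for r in range(n)],
                dtype=np.int64,
            )
            i += n
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            n = cells.shape[0]
            # skip LOOKUP_TABLE line
            cell_data[name] = np.array(
                [float(tokens[i + 2 + r]) for r in range(n)]
            )
            i += n + 1
        i += 1
    return points, cells, cell_data


# ---------------------------------------------------------------------------
# trace / summary persistence


def trace_dataframe(trace: SimulationTrace) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in trace.records])


def write_trace_csv(trace: SimulationTrace, path) -> Path:
    path = Path(path)
    trace_dataframe(trace).to_csv(path, index=False)
    return path


def write_summary_json(trace: SimulationTrace, cfg: RunConfig, path, label=None) -> Path:
    path = Path(path)
    last = asdict(trace.records[-1]) if trace.records else None
    summary = {
        "scenario": label,
        "status": trace.status,
        "n_iterations": trace.n_iterations,
        "first_tol_iteration": trace.first_tol_iteration,
        "message": trace.message,
        "final": last,
        "config": config_to_dict(cfg),
    }
    path.write_text(json.dumps(summary, indent=2) + "\n")
    return path


@dataclass
class RunArtifacts:
    """Paths of everything a persisted run wrote."""

    directory: Path
    config_path: Path
    trace_path: Path
    summary_path: Path
    snapshot_paths: list[Path]


def persist_run(
    mesh: GridMesh, trace: SimulationTrace, cfg: RunConfig, label: str | None = None
) -> RunArtifacts:
    """Write config copy, CSV trace, VTK snapshots and JSON summary."""
    out = Path(cfg.output_directory)
    if label:
        out = out / label
    out.mkdir(parents=True, exist_ok=True)

    config_path = out / "config.yaml"
    config_path.write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))
    trace_path = write_trace_csv(trace, out / "trace.csv")
    snapshot_paths = []
    for it, rho in sorted(trace.snapshots.items()):
        sed = trace.final_sed if it == max(trace.snapshots) else None
        snapshot_paths.append(
            write_snapshot(mesh, rho, sed, it, out / f"snapshot_{it:04d}.vtk")
        )
    if trace.final_density is not None and not trace.snapshots:
        snapshot_paths.append(
            write_snapshot(
                mesh,
                trace.final_density,
                trace.final_sed,
                trace.n_iterations,
                out / "snapshot_final.vtk",
            )
        )
    summary_path = write_summary_json(trace, cfg, out / "summary.json", label)
    return RunArtifacts(out, config_path, trace_path, summary_path, snapshot_paths)
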