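"""Mesh/table I/O, pipeline configuration and the end-to-end runner.

Meshes travel as OBJ or PLY plus a sidecar CSV of per-vertex chart
coordinates ``(vertex_id, s, phi)``; tables are tidy CSV; configuration is a
JSON document with an explicit seed for every stochastic stage.  Output CSVs
carry a comment header with the configuration hash and seed so any table can
be traced to the run that produced it; reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from . import cells as C
from . import kinematics as K
from . import shear as S
from .geometry import TubeSurface, centerline, enclosed_volume, surface_area
from .synthetic import (
    CellFieldSpec,
    Constriction,
    TubeSpec,
    make_cell_tessellation,
    make_constricting_tube,
)

__all__ = [
    "read_mesh",
    "write_mesh",
    "chart_path",
    "PipelineConfig",
    "run_pipeline",
]

FLOAT_FMT = "%.10g"


def chart_path(mesh_path: Path) -> Path:
    mesh_path = Path(mesh_path)
    return mesh_path.with_suffix(mesh_path.suffix + ".chart.csv")


def write_mesh(surface: TubeSurface, path) -> Path:
    """Write a surface as OBJ/PLY (by extension) with its chart sidecar CSV."""
    path = Path(path)
    mesh = trimesh.Trimesh(
        vertices=surface.vertices, faces=surface.faces, process=False
    )
    if path.suffix.lower() == ".ply":
        path.write_bytes(mesh.export(file_type="ply", encoding="ascii"))
    elif path.suffix.lower() == ".obj":
        path.write_text(mesh.export(file_type="obj"))
    else:
        raise ValueError(f"unsupported mesh format: {path.suffix}")
    if surface.has_chart:
        df = pd.DataFrame(
            {
                "vertex_id": np.arange(surface.n_vertices),
                "s": surface.s,
                "phi": surface.phi,
            }
        )
        df.to_csv(chart_path(path), index=False, float_format=FLOAT_FMT)
    return path


def read_mesh(path, require_chart: bool = True) -> TubeSurface:
    """Read an OBJ/PLY mesh and its chart sidecar into a TubeSurface."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mesh = trimesh.load(
        str(path), file_type=path.suffix.lstrip("."), process=False,
        maintain_order=True,
    )
    s = phi = None
    cpath = chart_path(path)
    if cpath.exists():
        df = pd.read_csv(cpath).sort_values("vertex_id")
        if len(df) != len(mesh.vertices):
            raise ValueError(
                f"chart sidecar has {len(df)} rows for {len(mesh.vertices)} vertices"
            )
        s = df["s"].to_numpy()
        phi = df["phi"].to_numpy()
    elif require_chart:
        raise FileNotFoundError(
            f"chart required: no sidecar {cpath.name} next to {path.name}"
        )
    return TubeSurface(
        vertices=np.asarray(mesh.vertices, dtype=float),
        faces=np.asarray(mesh.faces, dtype=np.int64),
        s=s,
        phi=phi,
    )


# ---------------------------------------------------------------------------
# configuration


_DEFAULT_CONFIG = {
    "seed": 1,
    "stages": ["simulate", "kinematics", "shear", "cells"],
    "tube": {
        "R0": 30.0,
        "L0": 200.0,
        "constrictions": [{"center": 100.0, "depth": 18.0, "width": 15.0}],
        "n_s": 64,
        "n_phi": 32,
        "dt": 1.0,
        "n_t": 30,
    },
    "kinematics": {"n_s_bins": 20, "n_phi_bins": 16},
    "shear": {"n_s_bins": 40},
    "cells": {"n_cells": 600, "aspect": 2.5, "jitter": 0.1},
}


class PipelineConfig:
    """JSON-backed pipeline configuration with an explicit seed.

    Round-trips losslessly: ``PipelineConfig.from_json(cfg.to_json())`` has
    identical content.
    """

    def __init__(self, data: dict | None = None):
        self.data = json.loads(json.dumps(_DEFAULT_CONFIG))
        if data:
            for k, v in data.items():
                if isinstance(v, dict) and isinstance(self.data.get(k), dict):
                    self.data[k].update(v)
                else:
                    self.data[k] = v
        if "seed" not in self.data:
            raise ValueError("config must carry an explicit seed")

    def to_json(self) -> str:
        return json.dumps(self.data, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(json.loads(text))

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        return cls.from_json(Path(path).read_text())

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def sha(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    def tube_spec(self) -> TubeSpec:
        t = self.data["tube"]
        return TubeSpec(
            R0=t["R0"],
            L0=t["L0"],
            constrictions=[
                Constriction(c["center"], c["depth"], c["width"])
                for c in t["constrictions"]
            ],
            n_s=t["n_s"],
            n_phi=t["n_phi"],
            dt=t["dt"],
            n_t=t["n_t"],
            seed=self.seed,
        )


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    header = f"# config_sha={config.sha()} seed={config.seed}\n"
    path.write_text(header + df.to_csv(index=False, float_format=FLOAT_FMT))


def read_output_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# runner


def _n_hoops(config: PipelineConfig) -> int:
    # equal-width s-bins cannot outnumber the mesh's s-rings
    return max(2, min(100, config.data["tube"]["n_s"] // 2))


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the configured stages in dependency order and write outputs.

    Stages: ``simulate`` (constricting tube + meshes), ``kinematics``
    (per-patch fields CSV and incompressibility summary), ``shear``
    (material-frame kymograph CSV), ``cells`` (tessellation measurement CSV).
    Returns the report dict that is also written to ``report.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.data["stages"]
    report: dict = {"config_sha": config.sha(), "seed": config.seed}

    if "simulate" not in stages:
        raise ValueError("pipeline currently starts from the simulate stage")
    seq, fields, flow = make_constricting_tube(config.tube_spec())
    mesh_dir = outdir / "meshes"
    mesh_dir.mkdir(exist_ok=True)
    for k, surf in enumerate(seq.surfaces):
        write_mesh(surf, mesh_dir / f"tube_t{k:03d}.obj")
    report["simulate"] = {
        "n_t": len(seq),
        "surface_area_t0": surface_area(seq[0]),
        "enclosed_volume_t0": enclosed_volume(seq[0]),
        "centerline_length_t0": centerline(seq[0], _n_hoops(config)).length,
        "centerline_length_final": centerline(seq[-1], _n_hoops(config)).length,
    }

    if "kinematics" in stages:
        kcfg = config.data["kinematics"]
        dfs = [
            K.incompressibility_fields(
                seq, k, kcfg["n_s_bins"], kcfg["n_phi_bins"]
            )
            for k in range(len(seq) - 1)
        ]
        patches = pd.concat(dfs, ignore_index=True)
        _write_csv(patches, outdir / "kinematics_patches.csv", config)
        r, slope = K.incompressibility_correlation(patches)
        report["kinematics"] = {
            "pearson_r": r,
            "slope": slope,
            "max_abs_residual": float(patches["residual"].abs().max()),
        }

    if "shear" in stages:
        chart = S.build_material_chart(seq[0])
        n_bins = min(
            config.data["shear"]["n_s_bins"], config.data["tube"]["n_s"] // 2
        )
        ky = S.shear_kymograph(seq, chart, n_bins)
        _write_csv(ky, outdir / "shear_kymograph.csv", config)
        from .plots import save_shear_kymograph

        save_shear_kymograph(ky, outdir / "shear_kymograph.png")
        last = ky[ky["t"] == ky["t"].max()]
        report["shear"] = {
            "reference_residual_mu": chart.residual_mu,
            "max_abs_mu_final": float(last["abs_mu"].max()),
            "peak_s": float(last.loc[last["abs_mu"].idxmax(), "s_center"]),
        }

    if "cells" in stages:
        ccfg = config.data["cells"]
        cspec = CellFieldSpec(
            n_cells=ccfg["n_cells"],
            aspect_profile=ccfg["aspect"],
            jitter=ccfg["jitter"],
            seed=config.seed,
        )
        gcells = make_cell_tessellation(cspec, seq[0])
        recs = C.measure_cells(gcells, seq[0])
        df = pd.DataFrame(
            [
                {
                    "cell_id": r.cell_id,
                    "t": r.time,
                    "area": r.area,
                    "aspect": r.aspect,
                    "theta": r.theta,
                    "s": r.s,
                }
                for r in recs
            ]
        )
        _write_csv(df, outdir / "cell_shapes.csv", config)
        report["cells"] = {
            "n_cells": len(recs),
            "weighted_mean_aspect": C.weighted_mean_aspect(recs),
            "bootstrap_se": C.bootstrap_se(
                [r.aspect for r in recs],
                [r.area for r in recs],
                seed=config.seed,
            ),
        }

    (outdir / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    return report
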