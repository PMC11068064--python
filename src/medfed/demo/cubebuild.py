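"""Builders for the demo benchmark's reference cubes.

Each builder writes a self-contained cube directory — ``cube.yaml``
manifest, digest-pinned ``run.py`` entrypoint and ``parameters.yaml`` —
ready for registration and execution by the local runner.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from ..cubes import (
    CubeKind,
    CubeManifest,
    AssetRef,
    KIND_TASKS,
    MANIFEST_FILENAME,
    PARAMETERS_FILENAME,
    manifest_to_dict,
)
from ..hashing import sha256_file
from .metrics import METRIC_NAMES

_RUN_PY = '''\
"""Entrypoint of the {name} cube ({kind} task interface)."""
import sys

from medfed.demo.taskmain import main

raise SystemExit(main(sys.argv[1:]))
'''


def write_cube(
    cube_dir: Path | str,
    name: str,
    kind: CubeKind,
    parameters: dict,
    version: str = "1.0",
) -> CubeManifest:
    """Write a cube directory with pinned run.py + parameters.yaml assets."""
    cube_dir = Path(cube_dir)
    cube_dir.mkdir(parents=True, exist_ok=True)
    (cube_dir / "run.py").write_text(_RUN_PY.format(name=name, kind=kind.value))
    (cube_dir / PARAMETERS_FILENAME).write_text(yaml.safe_dump(parameters))

    assets = tuple(
        AssetRef(path=rel, digest=sha256_file(cube_dir / rel))
        for rel in ("run.py", PARAMETERS_FILENAME)
    )
    manifest = CubeManifest(
        name=name,
        kind=kind,
        version=version,
        entrypoint="{python} {cube_dir}/run.py",
        tasks={task: [] for task in KIND_TASKS[kind]},
        assets=assets,
    )
    (cube_dir / MANIFEST_FILENAME).write_text(
        yaml.safe_dump(manifest_to_dict(manifest), sort_keys=False)
    )
    return manifest


def build_demo_cubes(
    dest: Path | str,
    target_size: int = 64,
    threshold: float = 0.5,
) -> dict[CubeKind, Path]:
    """Build the three reference cubes under ``dest``; returns kind → dir."""
    dest = Path(dest)
    dirs = {
        CubeKind.DATA_PREP: dest / "data_prep",
        CubeKind.MODEL: dest / "model",
        CubeKind.METRICS: dest / "metrics",
    }
    write_cube(
        dirs[CubeKind.DATA_PREP],
        "demo-lesion-prep",
        CubeKind.DATA_PREP,
        {"target_height": target_size, "target_width": target_size},
    )
    write_cube(
        dirs[CubeKind.MODEL],
        "demo-threshold-model",
        CubeKind.MODEL,
        {"threshold": threshold},
    )
    write_cube(
        dirs[CubeKind.METRICS],
        "demo-overlap-metrics",
        CubeKind.METRICS,
        {"metric_names": list(METRIC_NAMES)},
    )
    return dirs


def build_incompatible_model_cube(
    cube_dir: Path | str, threshold: float = 0.5, output_size: int = 32
) -> CubeManifest:
    """A candidate model that emits masks of the wrong shape.

    Useful for exercising the compatibility test's failure path: the
    pipeline runs, but evaluation rejects the prediction schema.
    """
    return write_cube(
        Path(cube_dir),
        "demo-badshape-model",
        CubeKind.MODEL,
        {"threshold": threshold, "output_size": output_size},
    )
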