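"""The portable unit of benchmark code ("cube"): manifest format, digest
verification, kind-specific task interfaces, and a sandboxed local runner.

A cube is a directory holding a ``cube.yaml`` manifest, an optional
``parameters.yaml``, and digest-pinned code assets.  Three kinds exist,
each with a fixed task interface:

==========  =====================================
kind        tasks
==========  =====================================
DATA_PREP   prepare, sanity_check, statistics
MODEL       infer
METRICS     evaluate
==========  =====================================

The default runner executes the manifest's entrypoint as a local
subprocess in a scratch working directory.  It refuses to run anything
whose assets fail digest verification, passes no network configuration to
the workload, and checks after the run that nothing outside the declared
output bindings was created or modified.  A container-engine backend can
implement the same interface; the local backend is what every test uses.
"""

from __future__ import annotations

import os
import shlex
import subprocess
import sys
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path, PurePosixPath
from typing import Mapping, Sequence

import yaml

from .errors import ContractError, IntegrityError, ValidationError
from .hashing import is_digest, sha256_file
from . import hashing

MANIFEST_FILENAME = "cube.yaml"
PARAMETERS_FILENAME = "parameters.yaml"


class CubeKind(str, Enum):
    DATA_PREP = "DATA_PREP"
    MODEL = "MODEL"
    METRICS = "METRICS"


#: the fixed task interface of each cube kind.
KIND_TASKS: dict[CubeKind, tuple[str, ...]] = {
    CubeKind.DATA_PREP: ("prepare", "sanity_check", "statistics"),
    CubeKind.MODEL: ("infer",),
    CubeKind.METRICS: ("evaluate",),
}

#: per-task logical binding names: (input names, output names).
TASK_BINDINGS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "prepare": (("raw_data", "labels"), ("prepared_data",)),
    "sanity_check": (("prepared_data",), ("report",)),
    "statistics": (("prepared_data",), ("statistics_file",)),
    "infer": (("prepared_data",), ("predictions",)),
    "evaluate": (("predictions", "prepared_labels"), ("results_file",)),
}


def required_tasks(kind: CubeKind | str) -> list[str]:
    """The task names a cube of ``kind`` must expose — nothing more or less."""
    try:
        kind = CubeKind(kind)
    except ValueError:
        raise ContractError(f"unknown cube kind {kind!r}") from None
    return list(KIND_TASKS[kind])


@dataclass(frozen=True)
class AssetRef:
    """One digest-pinned file of a cube: path relative to the cube root."""

    path: str
    digest: str


@dataclass(frozen=True)
class CubeManifest:
    name: str
    kind: CubeKind
    version: str
    entrypoint: str
    tasks: dict[str, list[str]]
    assets: tuple[AssetRef, ...]

    def task_names(self) -> list[str]:
        return list(self.tasks)


def _validate_asset_path(raw: str) -> str:
    p = PurePosixPath(raw)
    if p.is_absolute() or ".." in p.parts:
        raise ValidationError(f"assets[{raw!r}]: path escapes the cube directory")
    if not p.parts:
        raise ValidationError("assets: empty path")
    return p.as_posix()


def manifest_from_dict(data: Mapping, source: str = "cube.yaml") -> CubeManifest:
    """Build and validate a manifest; errors name the offending field."""
    if not isinstance(data, Mapping):
        raise ValidationError(f"{source}: manifest must be a mapping")

    def need(key: str):
        if key not in data:
            raise ValidationError(f"{source}: missing field {key!r}")
        return data[key]

    try:
        kind = CubeKind(str(need("kind")))
    except ValueError:
        raise ValidationError(f"{source}: unknown kind {data.get('kind')!r}") from None

    tasks_raw = need("tasks")
    if not isinstance(tasks_raw, Mapping):
        raise ValidationError(f"{source}: tasks must be a mapping")
    tasks = {str(t): [str(p) for p in (params or [])] for t, params in tasks_raw.items()}
    expected = set(KIND_TASKS[kind])
    declared = set(tasks)
    if declared != expected:
        missing = sorted(expected - declared)
        extra = sorted(declared - expected)
        parts = []
        if missing:
            parts.append(f"missing tasks {missing}")
        if extra:
            parts.append(f"unsupported tasks {extra}")
        raise ValidationError(
            f"{source}: {kind.value} interface mismatch: " + "; ".join(parts)
        )

    assets_raw = need("assets")
    if not isinstance(assets_raw, Sequence) or isinstance(assets_raw, (str, bytes)):
        raise ValidationError(f"{source}: assets must be a list")
    if not assets_raw:
        raise ValidationError(f"{source}: assets list is empty")
    assets = []
    for entry in assets_raw:
        if not isinstance(entry, Mapping) or "path" not in entry or "digest" not in entry:
            raise ValidationError(f"{source}: each asset needs 'path' and 'digest'")
        path = _validate_asset_path(str(entry["path"]))
        digest = entry["digest"]
        if not is_digest(digest):
            raise ValidationError(
                f"{source}: assets[{path}]: digest must be 64 lowercase hex chars"
            )
        assets.append(AssetRef(path=path, digest=digest))

    return CubeManifest(
        name=str(need("name")),
        kind=kind,
        version=str(data.get("version", "0")),
        entrypoint=str(need("entrypoint")),
        tasks=tasks,
        assets=tuple(assets),
    )


def load_manifest(path: Path | str) -> CubeManifest:
    """Parse and validate a ``cube.yaml`` file."""
    path = Path(path)
    if not path.is_file():
        raise ValidationError(f"manifest not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValidationError(f"{path}: invalid YAML: {exc}") from exc
    return manifest_from_dict(data, source=str(path))


def manifest_to_dict(manifest: CubeManifest) -> dict:
    return {
        "name": manifest.name,
        "kind": manifest.kind.value,
        "version": manifest.version,
        "entrypoint": manifest.entrypoint,
        "tasks": {t: list(p) for t, p in manifest.tasks.items()},
        "assets": [{"path": a.path, "digest": a.digest} for a in manifest.assets],
    }


# ---------------------------------------------------------------------------
# integrity verification


@dataclass(frozen=True)
class AssetCheck:
    path: str
    expected: str
    actual: str | None  # None when the file is missing
    matched: bool


@dataclass(frozen=True)
class VerificationReport:
    checks: tuple[AssetCheck, ...]
    passed: bool

    def mismatches(self) -> list[AssetCheck]:
        return [c for c in self.checks if not c.matched]


def verify_assets(manifest: CubeManifest, cube_dir: Path | str) -> VerificationReport:
    """Check every pinned asset under ``cube_dir`` against its digest.

    A missing file is reported as a mismatch entry (actual=None), not an
    exception; the report passes iff every asset matches.
    """
    cube_dir = Path(cube_dir)
    checks = []
    for asset in manifest.assets:
        target = cube_dir / asset.path
        if not target.is_file():
            checks.append(AssetCheck(asset.path, asset.digest, None, False))
            continue
        actual = sha256_file(target)
        checks.append(AssetCheck(asset.path, asset.digest, actual, actual == asset.digest))
    return VerificationReport(tuple(checks), all(c.matched for c in checks))


@dataclass(frozen=True)
class CubeValidation:
    passed: bool
    findings: tuple[str, ...]
    manifest: CubeManifest | None = None
    verification: VerificationReport | None = None


def validate_cube(cube_dir: Path | str) -> CubeValidation:
    """Pre-flight a cube directory: manifest parse + interface + digests.

    Never raises; all problems come back as findings.
    """
    cube_dir = Path(cube_dir)
    try:
        manifest = load_manifest(cube_dir / MANIFEST_FILENAME)
    except ValidationError as exc:
        return CubeValidation(False, (str(exc),))
    report = verify_assets(manifest, cube_dir)
    findings = tuple(
        f"asset {c.path}: "
        + ("missing" if c.actual is None else f"digest mismatch ({c.actual[:12]}…)")
        for c in report.mismatches()
    )
    return CubeValidation(report.passed, findings, manifest, report)


# ---------------------------------------------------------------------------
# local-process runner


@dataclass
class TaskRun:
    """Outcome of one task execution."""

    task: str
    input_bindings: dict[str, str]
    output_bindings: dict[str, str]
    success: bool
    log_path: str
    failure_reason: str | None = None
    returncode: int | None = None


def _snapshot(roots: Sequence[Path]) -> dict[str, str]:
    snap: dict[str, str] = {}
    for root in roots:
        root = Path(root)
        if root.is_file():
            snap[str(root)] = sha256_file(root)
        elif root.is_dir():
            for p in sorted(q for q in root.rglob("*") if q.is_file()):
                snap[str(p)] = sha256_file(p)
    return snap


def run_task(
    manifest: CubeManifest,
    cube_dir: Path | str,
    task: str,
    inputs: Mapping[str, Path | str],
    outputs: Mapping[str, Path | str],
    workdir: Path | str,
    *,
    extra_args: Sequence[str] = (),
) -> TaskRun:
    """Execute one cube task as an isolated local subprocess.

    * refuses to start unless asset verification passes (integrity gate);
    * validates the binding names against the task's declared interface;
    * runs with cwd inside a scratch directory under ``workdir``, with
      proxy/network environment stripped (the runner configures no network);
    * captures stdout+stderr to a log file, which is always retained
      locally and never uploaded;
    * after the run, verifies that input bindings and cube assets were not
      modified and that every output binding exists and is non-empty.

    Process failure or a post-condition violation yields a failed
    :class:`TaskRun`, except integrity failure which raises
    :class:`IntegrityError` before anything executes.
    """
    cube_dir = Path(cube_dir).resolve()
    workdir = Path(workdir)
    if task not in manifest.tasks:
        raise ContractError(f"task {task!r} not in manifest for {manifest.name}")
    expected_in, expected_out = TASK_BINDINGS[task]
    if set(inputs) != set(expected_in):
        raise ContractError(
            f"{task}: input bindings {sorted(inputs)} != expected {sorted(expected_in)}"
        )
    if set(outputs) != set(expected_out):
        raise ContractError(
            f"{task}: output bindings {sorted(outputs)} != expected {sorted(expected_out)}"
        )
    for name, path in inputs.items():
        if not Path(path).exists():
            raise ValidationError(f"{task}: input binding {name} missing: {path}")

    report = verify_assets(manifest, cube_dir)
    if not report.passed:
        bad = ", ".join(c.path for c in report.mismatches())
        raise IntegrityError(
            f"cube {manifest.name}: asset verification failed ({bad}); refusing to run"
        )

    workdir.mkdir(parents=True, exist_ok=True)
    scratch = workdir / f"scratch_{task}"
    scratch.mkdir(parents=True, exist_ok=True)
    log_path = workdir / f"{task}.log"

    argv = [
        part.replace("{python}", sys.executable).replace("{cube_dir}", str(cube_dir))
        for part in shlex.split(manifest.entrypoint)
    ]
    argv.append(task)
    for name, path in inputs.items():
        argv.append(f"--in:{name}={Path(path).resolve()}")
    out_paths = {name: Path(path).resolve() for name, path in outputs.items()}
    for name, path in out_paths.items():
        path.parent.mkdir(parents=True, exist_ok=True)
        argv.append(f"--out:{name}={path}")
    params = cube_dir / PARAMETERS_FILENAME
    if params.is_file():
        argv.append(f"--parameters={params.resolve()}")
    argv.extend(extra_args)

    # no proxy or network configuration reaches the workload
    env = {
        k: v
        for k, v in os.environ.items()
        if not k.lower().endswith("_proxy") and k.lower() != "no_proxy"
    }
    env["MEDFED_TASK"] = task

    before = _snapshot([Path(p) for p in inputs.values()] + [cube_dir])

    with open(log_path, "wb") as log:
        proc = subprocess.run(
            argv, cwd=scratch, env=env, stdout=log, stderr=subprocess.STDOUT
        )

    run = TaskRun(
        task=task,
        input_bindings={k: str(v) for k, v in inputs.items()},
        output_bindings={k: str(v) for k, v in out_paths.items()},
        success=False,
        log_path=str(log_path),
        returncode=proc.returncode,
    )

    after = _snapshot([Path(p) for p in inputs.values()] + [cube_dir])
    if before != after:
        changed = sorted(set(before.items()) ^ set(after.items()))
        run.failure_reason = (
            "contract violation: task modified read-only inputs or cube assets: "
            + ", ".join(sorted({p for p, _ in changed})[:5])
        )
        return run

    if proc.returncode != 0:
        run.failure_reason = f"task exited with status {proc.returncode}"
        return run

    for name, path in out_paths.items():
        if not path.exists():
            run.failure_reason = f"declared output {name!r} was not produced"
            return run
        if path.is_file() and path.stat().st_size == 0:
            run.failure_reason = f"declared output {name!r} is empty"
            return run
        if path.is_dir() and not any(path.iterdir()):
            run.failure_reason = f"declared output {name!r} is empty"
            return run

    run.success = True
    return run


def parse_task_args(argv: Sequence[str]):
    """Parse the runner's task argv convention inside a cube entrypoint.

    Returns ``(task, inputs, outputs, parameters_path)``.
    """
    if not argv:
        raise SystemExit("usage: <entrypoint> TASK --in:name=path --out:name=path")
    task = argv[0]
    inputs: dict[str, str] = {}
    outputs: dict[str, str] = {}
    parameters = None
    for arg in argv[1:]:
        if arg.startswith("--in:"):
            name, _, value = arg[5:].partition("=")
            inputs[name] = value
        elif arg.startswith("--out:"):
            name, _, value = arg[6:].partition("=")
            outputs[name] = value
        elif arg.startswith("--parameters="):
            parameters = arg.split("=", 1)[1]
        else:
            raise SystemExit(f"unrecognized task argument {arg!r}")
    return task, inputs, outputs, parameters


def cube_fingerprint(manifest: CubeManifest) -> str:
    """A single digest pinning the whole cube (manifest + asset digests)."""
    canon = yaml.safe_dump(manifest_to_dict(manifest), sort_keys=True)
    return hashing.sha256_bytes(canon.encode())
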