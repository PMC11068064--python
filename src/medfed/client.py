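"""The orchestration client: executes the platform workflows against a
server handle and locally held data.

Data never leaves the site: models and metrics run locally on the
prepared dataset; only aggregate statistics (with explicit consent) and
owner-approved metric payloads are ever uploaded, and both pass the same
privacy guards client-side that the server enforces.  All server
interaction goes through a :class:`~medfed.transport.Transport`, so a
spy can audit — or a disabled transport can forbid — every byte that
would leave the machine.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .cubes import (
    CubeKind,
    CubeManifest,
    MANIFEST_FILENAME,
    PARAMETERS_FILENAME,
    load_manifest,
    run_task,
    validate_cube,
)
from .demo.tasks import PREPARED_MANIFEST
from .errors import (
    IntegrityError,
    NotFoundError,
    StateError,
    ValidationError,
)
from .hashing import sha256_file, sha256_tree
from .privacy import scan_payload
from .transport import Transport


@dataclass
class VerifiedCube:
    """A cube fetched into the local cache with all digests checked."""

    cube_id: str
    record: dict
    manifest: CubeManifest
    cube_dir: Path


@dataclass
class PreparedDataset:
    """Local state of a dataset moving through the preparation pipeline.

    Stage flags are monotone: ``prepared`` → ``sanity_ok`` →
    ``statistics_done``; a later flag is never set without the earlier
    ones, and a sanity failure freezes the pipeline with the report kept
    for review.
    """

    local_root: Path
    benchmark_id: str
    name: str
    prepared: bool = False
    sanity_ok: bool = False
    statistics_done: bool = False
    statistics: dict = field(default_factory=dict)
    sanity_report: dict = field(default_factory=dict)
    manifest_digest: str = ""
    server_id: str | None = None
    failure: str | None = None


@dataclass
class LocalResult:
    """One model's local evaluation output, pending owner review."""

    benchmark_id: str
    model_cube_id: str
    dataset: PreparedDataset
    results_path: Path | None
    fingerprint: dict[str, str]
    success: bool
    owner_approved: bool = False
    failure: str | None = None
    log_path: str | None = None


class Client:
    """Per-user workspace + transport; implements the four workflows."""

    def __init__(self, workspace: Path | str, transport: Transport):
        self.workspace = Path(workspace)
        for sub in ("cubes", "datasets", "results", "scratch"):
            (self.workspace / sub).mkdir(parents=True, exist_ok=True)
        self.transport = transport

    # -- cube registration and retrieval -----------------------------------

    def submit_cube_from_dir(self, cube_dir: Path | str, manifest_url: str | None = None) -> dict:
        """Register a locally built cube: digests only, never code."""
        cube_dir = Path(cube_dir)
        manifest = load_manifest(cube_dir / MANIFEST_FILENAME)
        draft = {
            "name": manifest.name,
            "kind": manifest.kind.value,
            "manifest_url": manifest_url or str(cube_dir.resolve()),
            "manifest_digest": sha256_file(cube_dir / MANIFEST_FILENAME),
            "asset_digests": [[a.path, a.digest] for a in manifest.assets],
        }
        return self.transport.request("POST", "/cubes", draft)

    def fetch_and_verify_cube(self, cube_id: str) -> VerifiedCube:
        """Fetch a registered cube into the cache and verify every digest.

        The manifest file must hash to the registered ``manifest_digest``
        and every asset to its pinned digest; any mismatch makes the cube
        unusable (the cache copy is removed and ``IntegrityError`` raised).
        """
        record = self.transport.request("GET", f"/cubes/{cube_id}")
        source = Path(record["manifest_url"])
        if not source.is_dir():
            raise NotFoundError(f"cube {cube_id}: locator {source} is not available")
        cache_dir = self.workspace / "cubes" / str(cube_id)
        if cache_dir.exists():
            shutil.rmtree(cache_dir)
        shutil.copytree(source, cache_dir)

        try:
            actual_manifest_digest = sha256_file(cache_dir / MANIFEST_FILENAME)
            if actual_manifest_digest != record["manifest_digest"]:
                raise IntegrityError(f"cube {cube_id}: manifest digest mismatch")
            manifest = load_manifest(cache_dir / MANIFEST_FILENAME)
            registered = {path: digest for path, digest in record["asset_digests"]}
            local = {a.path: a.digest for a in manifest.assets}
            if registered != local:
                raise IntegrityError(
                    f"cube {cube_id}: manifest asset list differs from registration"
                )
            validation = validate_cube(cache_dir)
            if not validation.passed:
                raise IntegrityError(
                    f"cube {cube_id}: verification failed: " + "; ".join(validation.findings)
                )
        except Exception:
            shutil.rmtree(cache_dir, ignore_errors=True)
            raise
        return VerifiedCube(str(cube_id), record, manifest, cache_dir)

    # -- dataset preparation ------------------------------------------------

    def prepare_dataset(
        self,
        prep_cube: VerifiedCube,
        raw_dir: Path | str,
        labels_dir: Path | str,
        name: str,
        benchmark_id: str,
    ) -> PreparedDataset:
        """Run prepare → sanity_check → statistics, halting at first failure."""
        if prep_cube.manifest.kind is not CubeKind.DATA_PREP:
            raise ValidationError("prepare_dataset needs a DATA_PREP cube")
        root = self.workspace / "datasets" / name
        if root.exists():
            shutil.rmtree(root)
        prepared_dir = root / "prepared"
        workdir = root / "runs"
        state = PreparedDataset(local_root=root, benchmark_id=str(benchmark_id), name=name)

        run = run_task(
            prep_cube.manifest,
            prep_cube.cube_dir,
            "prepare",
            {"raw_data": raw_dir, "labels": labels_dir},
            {"prepared_data": prepared_dir},
            workdir,
        )
        if not run.success:
            state.failure = f"prepare: {run.failure_reason}"
            return state
        state.prepared = True

        report_path = root / "sanity_report.json"
        run = run_task(
            prep_cube.manifest,
            prep_cube.cube_dir,
            "sanity_check",
            {"prepared_data": prepared_dir},
            {"report": report_path},
            workdir,
        )
        if not run.success:
            state.failure = f"sanity_check: {run.failure_reason}"
            return state
        state.sanity_report = json.loads(report_path.read_text())
        if not state.sanity_report.get("pass"):
            state.failure = "sanity_check: findings reported"
            return state
        state.sanity_ok = True

        stats_path = root / "statistics.json"
        run = run_task(
            prep_cube.manifest,
            prep_cube.cube_dir,
            "statistics",
            {"prepared_data": prepared_dir},
            {"statistics_file": stats_path},
            workdir,
        )
        if not run.success:
            state.failure = f"statistics: {run.failure_reason}"
            return state
        state.statistics = json.loads(stats_path.read_text())
        state.statistics_done = True
        state.manifest_digest = sha256_file(prepared_dir / PREPARED_MANIFEST)
        self._save_dataset_state(state)
        return state

    def _save_dataset_state(self, state: PreparedDataset) -> None:
        index = {
            "name": state.name,
            "benchmark_id": state.benchmark_id,
            "prepared": state.prepared,
            "sanity_ok": state.sanity_ok,
            "statistics_done": state.statistics_done,
            "statistics": state.statistics,
            "manifest_digest": state.manifest_digest,
            "server_id": state.server_id,
        }
        (state.local_root / "state.json").write_text(json.dumps(index, indent=1))

    def prepared_dir(self, state: PreparedDataset) -> Path:
        return state.local_root / "prepared"

    def register_prepared_dataset(
        self,
        state: PreparedDataset,
        prep_cube: VerifiedCube,
        consent: bool,
    ) -> str | None:
        """Upload name + aggregate statistics + digest — given consent.

        Without consent nothing is sent at all (no server call is made);
        with consent the payload is guarded to contain metadata only.
        """
        if not state.statistics_done:
            raise StateError("dataset statistics are not computed; register refused")
        if not consent:
            return None
        draft = {
            "name": state.name,
            "data_prep_cube_id": prep_cube.cube_id,
            "statistics": state.statistics,
            "input_digest": state.manifest_digest,
        }
        scan_payload(draft, "dataset registration")
        record = self.transport.request("POST", "/datasets", draft)
        state.server_id = record["id"]
        self._save_dataset_state(state)
        return record["id"]

    # -- compatibility testing and association -------------------------------

    def fetch_demo_dataset(self, benchmark: Mapping) -> Path:
        """Resolve and digest-verify a benchmark's public demo dataset."""
        demo_dir = Path(benchmark["demo_dataset_locator"])
        if not demo_dir.is_dir():
            raise NotFoundError(f"demo dataset not available at {demo_dir}")
        actual = sha256_tree(demo_dir)
        if actual != benchmark["demo_dataset_digest"]:
            raise IntegrityError("demo dataset digest mismatch; refusing to use it")
        return demo_dir

    def run_compatibility_test(
        self,
        benchmark: Mapping,
        prep_cube: VerifiedCube,
        model_cube: VerifiedCube,
        metrics_cube: VerifiedCube,
        scratch: Path | str | None = None,
    ) -> dict:
        """Execute the full pipeline on the benchmark's demo data.

        Passes iff every stage succeeds, predictions exist one-per-case
        with the declared shape/binary schema, and evaluation emits finite
        values for exactly the benchmark's declared metric names.
        """
        scratch = Path(scratch) if scratch else self.workspace / "scratch" / "compat"
        if scratch.exists():
            shutil.rmtree(scratch)
        scratch.mkdir(parents=True)
        report: dict = {"pass": False, "failed_stage": None, "stages": {}}

        demo_dir = self.fetch_demo_dataset(benchmark)

        def fail(stage: str, reason: str) -> dict:
            report["failed_stage"] = stage
            report["stages"][stage] = f"fail: {reason}"
            return report

        prepared = scratch / "prepared"
        run = run_task(
            prep_cube.manifest, prep_cube.cube_dir, "prepare",
            {"raw_data": demo_dir, "labels": demo_dir / "labels"},
            {"prepared_data": prepared}, scratch / "runs",
        )
        if not run.success:
            return fail("prepare", run.failure_reason or "failed")
        report["stages"]["prepare"] = "pass"

        sanity_path = scratch / "sanity.json"
        run = run_task(
            prep_cube.manifest, prep_cube.cube_dir, "sanity_check",
            {"prepared_data": prepared}, {"report": sanity_path}, scratch / "runs",
        )
        if not run.success or not json.loads(sanity_path.read_text()).get("pass"):
            return fail("sanity_check", run.failure_reason or "sanity findings")
        report["stages"]["sanity_check"] = "pass"

        predictions = scratch / "predictions"
        run = run_task(
            model_cube.manifest, model_cube.cube_dir, "infer",
            {"prepared_data": prepared}, {"predictions": predictions}, scratch / "runs",
        )
        if not run.success:
            return fail("infer", run.failure_reason or "failed")
        report["stages"]["infer"] = "pass"

        schema_problem = self._check_prediction_schema(prepared, predictions)
        if schema_problem:
            return fail("prediction_schema", schema_problem)
        report["stages"]["prediction_schema"] = "pass"

        results_path = scratch / "results.json"
        run = run_task(
            metrics_cube.manifest, metrics_cube.cube_dir, "evaluate",
            {"predictions": predictions, "prepared_labels": prepared / "labels"},
            {"results_file": results_path}, scratch / "runs",
        )
        if not run.success:
            return fail("evaluate", run.failure_reason or "failed")
        report["stages"]["evaluate"] = "pass"

        declared = self._declared_metric_names(metrics_cube)
        results = json.loads(results_path.read_text())
        aggregate = results.get("aggregate", {})
        observed = sorted(aggregate)
        if declared is not None and observed != sorted(declared):
            return fail(
                "metric_schema",
                f"metrics {observed} != declared {sorted(declared)}",
            )
        import math

        bad = [k for k, v in aggregate.items() if not isinstance(v, (int, float)) or not math.isfinite(v)]
        if bad:
            return fail("metric_schema", f"non-finite metrics: {bad}")
        report["stages"]["metric_schema"] = "pass"
        report["metric_names"] = observed
        report["pass"] = True
        return report

    @staticmethod
    def _declared_metric_names(metrics_cube: VerifiedCube) -> list[str] | None:
        params_file = metrics_cube.cube_dir / PARAMETERS_FILENAME
        if not params_file.is_file():
            return None
        params = yaml.safe_load(params_file.read_text()) or {}
        names = params.get("metric_names")
        return [str(n) for n in names] if names else None

    @staticmethod
    def _check_prediction_schema(prepared: Path, predictions: Path) -> str | None:
        import numpy as np
        from PIL import Image

        manifest = json.loads((prepared / PREPARED_MANIFEST).read_text())
        shape = (manifest["image_height"], manifest["image_width"])
        for case in manifest["cases"]:
            pred = predictions / f"{case['case_id']}.png"
            if not pred.is_file():
                return f"missing prediction for case {case['case_id']}"
            with Image.open(pred) as img:
                arr = np.asarray(img)
            if arr.shape != shape:
                return (
                    f"case {case['case_id']}: prediction shape {arr.shape} "
                    f"!= prepared shape {shape}"
                )
            if not np.isin(arr, (0, 255)).all():
                return f"case {case['case_id']}: prediction is not binary"
        return None

    def associate(
        self, kind: str, subject_id: str, benchmark_id: str, report: Mapping
    ) -> dict:
        """Request an association; a failing report is refused locally."""
        if not report.get("pass"):
            raise ValidationError(
                "compatibility report does not pass "
                f"(failed at {report.get('failed_stage', 'unknown')}); "
                "association not requested"
            )
        return self.transport.request(
            "POST",
            "/associations",
            {
                "kind": kind,
                "subject_id": str(subject_id),
                "benchmark_id": str(benchmark_id),
                "compatibility_report": dict(report),
            },
        )

    # -- benchmark execution -------------------------------------------------

    def execute_benchmark(
        self,
        benchmark: Mapping,
        prepared: PreparedDataset,
        model_cubes: Sequence[VerifiedCube],
        metrics_cube: VerifiedCube,
    ) -> list[LocalResult]:
        """Run infer + evaluate for each model on the prepared dataset.

        Entirely local: no server communication happens here (callers may
        hand this client a disabled transport to prove it).  Each model is
        isolated — one failing cube does not block the others.
        """
        if not prepared.sanity_ok:
            raise StateError("dataset has not passed the sanity check")
        prepared_dir = self.prepared_dir(prepared)
        results: list[LocalResult] = []
        for model_cube in model_cubes:
            run_root = (
                self.workspace / "results" / prepared.name / f"model_{model_cube.cube_id}"
            )
            if run_root.exists():
                shutil.rmtree(run_root)
            run_root.mkdir(parents=True)
            fingerprint = {
                "data_prep": benchmark and self._record_digest(benchmark, "data_prep_cube_id"),
                "model": model_cube.record["manifest_digest"],
                "metrics": metrics_cube.record["manifest_digest"],
            }
            fingerprint = {k: v for k, v in fingerprint.items() if v}
            result = LocalResult(
                benchmark_id=str(benchmark["id"]),
                model_cube_id=model_cube.cube_id,
                dataset=prepared,
                results_path=None,
                fingerprint=fingerprint,
                success=False,
            )
            predictions = run_root / "predictions"
            run = run_task(
                model_cube.manifest, model_cube.cube_dir, "infer",
                {"prepared_data": prepared_dir}, {"predictions": predictions}, run_root,
            )
            result.log_path = run.log_path
            if not run.success:
                result.failure = f"infer: {run.failure_reason}"
                results.append(result)
                continue
            results_path = run_root / "results.json"
            run = run_task(
                metrics_cube.manifest, metrics_cube.cube_dir, "evaluate",
                {"predictions": predictions, "prepared_labels": prepared_dir / "labels"},
                {"results_file": results_path}, run_root,
            )
            if not run.success:
                result.failure = f"evaluate: {run.failure_reason}"
                results.append(result)
                continue
            result.results_path = results_path
            result.success = True
            results.append(result)
        return results

    def _record_digest(self, benchmark: Mapping, slot: str) -> str | None:
        # best effort: fingerprint the prep cube via its cached record if present
        cube_id = benchmark.get(slot)
        cached = self.workspace / "cubes" / str(cube_id) / MANIFEST_FILENAME
        if cached.is_file():
            return sha256_file(cached)
        return None

    # -- result review and upload ---------------------------------------------

    def approve_and_submit_result(self, result: LocalResult, approve: bool) -> str | None:
        """Owner review gate: upload metrics only after explicit approval.

        ``approve=False`` leaves everything on the machine.  The uploaded
        payload carries aggregate metrics, a per-case metric table with
        opaque case identifiers, and the execution fingerprint — and is
        privacy-scanned before leaving.
        """
        if not approve:
            return None
        if not result.success or result.results_path is None:
            raise StateError("cannot submit a failed result")
        results = json.loads(Path(result.results_path).read_text())
        per_case = [
            {"case": hashlib.sha256(row["case_id"].encode()).hexdigest()[:16],
             **{k: v for k, v in row.items() if k != "case_id"}}
            for row in results.get("per_case", [])
        ]
        result.owner_approved = True
        draft = {
            "benchmark_id": result.benchmark_id,
            "model_cube_id": result.model_cube_id,
            "dataset_id": result.dataset.server_id,
            "metrics": results["aggregate"],
            "per_case": per_case,
            "fingerprint": result.fingerprint,
        }
        if draft["dataset_id"] is None:
            raise StateError("dataset is not registered on the server")
        scan_payload(draft, "result upload")
        record = self.transport.request("POST", "/results", draft)
        return record["id"]
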