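"""The coordination server: persistent registry of accounts, cubes,
benchmarks, datasets, associations and results.

The server stores the minimal metadata needed to coordinate a federation
— how to obtain and verify cubes, which datasets are associated with
which benchmarks, which models were evaluated where and under which
metrics — and an append-only audit trail of who did what.  No code assets
and no raw data are ever stored; privacy guards reject payloads that try.

Persistence is a single-file relational database (sqlite), with schema
creation/migration on startup.  The service is exposed two ways with one
implementation: direct method calls (the in-process binding used by most
tests) and an HTTP+JSON router (:meth:`CoordinationServer.handle_request`)
served by :mod:`medfed.httpapi`.

Every *mutating* call — successful or rejected — appends exactly one
audit event with a gap-free sequence number.  Read-only queries are not
audited.
"""

from __future__ import annotations

import json
import re
import secrets
import sqlite3
import threading
import time
from pathlib import Path
from typing import Any, Callable, Mapping

from .cubes import CubeKind
from .errors import (
    AuthenticationError,
    AuthorizationError,
    ContractError,
    DuplicateError,
    MedfedError,
    NotFoundError,
    StateError,
    ValidationError,
)
from .hashing import is_digest
from .privacy import MAX_PER_CASE_ROWS, check_statistics, scan_payload
from .records import (
    Association,
    AuditEvent,
    BenchmarkRecord,
    CubeRecord,
    DatasetRecord,
    ResultRecord,
)
from .registry import (
    ApprovalStatus,
    ResourceRef,
    ResultSharingPolicy,
    Role,
    UserAccount,
    authorize,
)

_SCHEMA = """
CREATE TABLE IF NOT EXISTS accounts (
    id INTEGER PRIMARY KEY,
    name TEXT UNIQUE NOT NULL,
    roles TEXT NOT NULL,
    token TEXT UNIQUE NOT NULL
);
CREATE TABLE IF NOT EXISTS records (
    kind TEXT NOT NULL,
    id INTEGER NOT NULL,
    data TEXT NOT NULL,
    PRIMARY KEY (kind, id)
);
CREATE TABLE IF NOT EXISTS audit (
    seq INTEGER PRIMARY KEY,
    data TEXT NOT NULL
);
PRAGMA user_version = 1;
"""

_MUTATING_ACTIONS = {
    "create_account",
    "submit_cube",
    "submit_benchmark",
    "approve_benchmark",
    "register_dataset",
    "request_association",
    "approve_association",
    "submit_result",
}

ASSOCIATION_KINDS = ("DATASET_BENCHMARK", "MODEL_BENCHMARK")


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())


class CoordinationServer:
    """Registry + coordination service with token authentication."""

    def __init__(self, db_path: str | Path = ":memory:"):
        # served over HTTP the handlers run on worker threads; one lock
        # serializes all access so sqlite stays the single source of truth
        self._lock = threading.RLock()
        self._db = sqlite3.connect(str(db_path), check_same_thread=False)
        self._db.executescript(_SCHEMA)
        self._db.commit()

    # -- storage helpers ---------------------------------------------------

    def _next_id(self, kind: str) -> int:
        row = self._db.execute(
            "SELECT COALESCE(MAX(id), 0) + 1 FROM records WHERE kind = ?", (kind,)
        ).fetchone()
        return int(row[0])

    def _put(self, kind: str, record_id: str, data: Mapping) -> None:
        self._db.execute(
            "INSERT OR REPLACE INTO records (kind, id, data) VALUES (?, ?, ?)",
            (kind, int(record_id), json.dumps(dict(data))),
        )
        self._db.commit()

    def _get(self, kind: str, record_id: str) -> dict:
        try:
            key = int(record_id)
        except (TypeError, ValueError):
            raise NotFoundError(f"no such {kind}: {record_id!r}") from None
        row = self._db.execute(
            "SELECT data FROM records WHERE kind = ? AND id = ?", (kind, key)
        ).fetchone()
        if row is None:
            raise NotFoundError(f"no such {kind}: {record_id}")
        return json.loads(row[0])

    def _all(self, kind: str) -> list[dict]:
        rows = self._db.execute(
            "SELECT data FROM records WHERE kind = ? ORDER BY id", (kind,)
        ).fetchall()
        return [json.loads(r[0]) for r in rows]

    # -- authentication and audit ------------------------------------------

    def _actor(self, token: str | None) -> UserAccount:
        if not token:
            raise AuthenticationError("missing bearer token")
        row = self._db.execute(
            "SELECT id, name, roles FROM accounts WHERE token = ?", (token,)
        ).fetchone()
        if row is None:
            raise AuthenticationError("unknown token")
        return UserAccount(
            id=str(row[0]),
            name=row[1],
            roles=frozenset(Role(r) for r in json.loads(row[2])),
        )

    def _append_audit(
        self, actor: UserAccount, action: str, resource_id: str, outcome: str, detail: str
    ) -> None:
        row = self._db.execute("SELECT COALESCE(MAX(seq), 0) + 1 FROM audit").fetchone()
        event = AuditEvent(
            sequence_number=int(row[0]),
            actor_id=actor.id,
            action=action,
            resource_id=resource_id,
            outcome=outcome,
            timestamp=_now(),
            detail=detail,
        )
        self._db.execute(
            "INSERT INTO audit (seq, data) VALUES (?, ?)",
            (event.sequence_number, json.dumps(event.to_dict())),
        )
        self._db.commit()

    def _audited(
        self, actor: UserAccount, action: str, fn: Callable[[], tuple[str, Any]]
    ) -> Any:
        """Run a mutating operation; always append exactly one audit event."""
        assert action in _MUTATING_ACTIONS
        try:
            resource_id, value = fn()
        except MedfedError as exc:
            self._append_audit(actor, action, "", "rejected", exc.message[:200])
            raise
        self._append_audit(actor, action, resource_id, "accepted", "")
        return value

    # -- accounts ----------------------------------------------------------

    def bootstrap_admin(self, name: str = "admin") -> dict:
        """Provision the initial platform-admin account (idempotent refusal).

        Deployment-time provisioning, before the platform is in service;
        not part of the audited workflow.
        """
        if self._db.execute("SELECT 1 FROM accounts LIMIT 1").fetchone():
            raise StateError("server already has accounts; bootstrap refused")
        return self._insert_account(name, [Role.PLATFORM_ADMIN.value])

    def _insert_account(self, name: str, roles: list[str]) -> dict:
        if not name or not isinstance(name, str):
            raise ValidationError("account name must be a non-empty string")
        if not roles:
            raise ValidationError("role set must be non-empty")
        try:
            parsed = sorted({Role(r).value for r in roles})
        except ValueError:
            raise ValidationError(f"unknown role in {roles!r}") from None
        if self._db.execute("SELECT 1 FROM accounts WHERE name = ?", (name,)).fetchone():
            raise DuplicateError(f"account name {name!r} already registered")
        row = self._db.execute(
            "SELECT COALESCE(MAX(id), 0) + 1 FROM accounts"
        ).fetchone()
        account_id = int(row[0])
        token = secrets.token_hex(16)
        self._db.execute(
            "INSERT INTO accounts (id, name, roles, token) VALUES (?, ?, ?, ?)",
            (account_id, name, json.dumps(parsed), token),
        )
        self._db.commit()
        return {"id": str(account_id), "name": name, "roles": parsed, "token": token}

    def create_account(self, token: str, name: str, roles: list[str]) -> dict:
        actor = self._actor(token)

        def op():
            if not authorize(actor, "create_account", ResourceRef()):
                raise AuthorizationError("only the platform admin manages accounts")
            account = self._insert_account(name, roles)
            return account["id"], account

        return self._audited(actor, "create_account", op)

    def get_account(self, token: str, account_id: str) -> dict:
        self._actor(token)
        row = self._db.execute(
            "SELECT id, name, roles FROM accounts WHERE id = ?", (int(account_id),)
        ).fetchone()
        if row is None:
            raise NotFoundError(f"no such account: {account_id}")
        return {"id": str(row[0]), "name": row[1], "roles": json.loads(row[2])}

    # -- cubes -------------------------------------------------------------

    def submit_cube(self, token: str, draft: Mapping) -> dict:
        actor = self._actor(token)

        def op():
            if not authorize(actor, "submit_cube", ResourceRef()):
                raise AuthorizationError("cube registration needs a model-owner or committee role")
            scan_payload(draft, "cube")
            allowed = {"name", "kind", "manifest_url", "manifest_digest", "asset_digests"}
            extra = set(draft) - allowed
            if extra:
                raise ValidationError(f"cube: unsupported fields {sorted(extra)}")
            try:
                kind = CubeKind(str(draft.get("kind")))
            except ValueError:
                raise ValidationError(f"cube: unknown kind {draft.get('kind')!r}") from None
            if not draft.get("name"):
                raise ValidationError("cube: name required")
            if not draft.get("manifest_url"):
                raise ValidationError("cube: manifest_url required")
            if not is_digest(draft.get("manifest_digest")):
                raise ValidationError("cube: manifest_digest must be 64 lowercase hex chars")
            assets = draft.get("asset_digests") or []
            if not assets:
                raise ValidationError("cube: asset_digests must be non-empty")
            pairs = []
            for entry in assets:
                if not isinstance(entry, (list, tuple)) or len(entry) != 2:
                    raise ValidationError("cube: asset_digests entries are (path, digest) pairs")
                path, digest = entry
                if not is_digest(digest):
                    raise ValidationError(f"cube: asset {path!r}: malformed digest")
                pairs.append((str(path), digest))
            record = CubeRecord(
                id=str(self._next_id("cube")),
                owner_id=actor.id,
                kind=kind,
                name=str(draft["name"]),
                manifest_url=str(draft["manifest_url"]),
                manifest_digest=draft["manifest_digest"],
                asset_digests=pairs,
            )
            self._put("cube", record.id, record.to_dict())
            return record.id, record.to_dict()

        return self._audited(actor, "submit_cube", op)

    def get_cube(self, token: str, cube_id: str) -> dict:
        self._actor(token)
        return self._get("cube", cube_id)

    # -- benchmarks --------------------------------------------------------

    def submit_benchmark(self, token: str, draft: Mapping) -> dict:
        actor = self._actor(token)

        def op():
            if not authorize(actor, "submit_benchmark", ResourceRef()):
                raise AuthorizationError("benchmark submission needs the committee role")
            scan_payload(draft, "benchmark")
            slots = {
                "data_prep_cube_id": CubeKind.DATA_PREP,
                "reference_model_cube_id": CubeKind.MODEL,
                "metrics_cube_id": CubeKind.METRICS,
            }
            cube_ids = []
            for slot, expected_kind in slots.items():
                cube_id = draft.get(slot)
                if cube_id is None:
                    raise ValidationError(f"benchmark: {slot} required")
                cube = CubeRecord.from_dict(self._get("cube", cube_id))
                if cube.kind is not expected_kind:
                    raise ValidationError(
                        f"benchmark: {slot} references a {cube.kind.value} cube; "
                        f"expected {expected_kind.value}"
                    )
                cube_ids.append(str(cube_id))
            if len(set(cube_ids)) != 3:
                raise ValidationError("benchmark: the three cube ids must be distinct")
            if not draft.get("name"):
                raise ValidationError("benchmark: name required")
            if not is_digest(draft.get("demo_dataset_digest")):
                raise ValidationError("benchmark: demo_dataset_digest missing or malformed")
            if not draft.get("demo_dataset_locator"):
                raise ValidationError("benchmark: demo_dataset_locator required")
            policy = ResultSharingPolicy(
                draft.get("sharing_policy", ResultSharingPolicy.COMMITTEE_ONLY.value)
            )
            record = BenchmarkRecord(
                id=str(self._next_id("benchmark")),
                committee_id=actor.id,
                name=str(draft["name"]),
                specification=str(draft.get("specification", "")),
                data_prep_cube_id=cube_ids[0],
                reference_model_cube_id=cube_ids[1],
                metrics_cube_id=cube_ids[2],
                demo_dataset_locator=str(draft["demo_dataset_locator"]),
                demo_dataset_digest=draft["demo_dataset_digest"],
                approval=ApprovalStatus.PENDING,
                sharing_policy=policy,
                docs_url=str(draft.get("docs_url", "")),
            )
            self._put("benchmark", record.id, record.to_dict())
            return record.id, record.to_dict()

        return self._audited(actor, "submit_benchmark", op)

    def _benchmark(self, benchmark_id: str) -> BenchmarkRecord:
        return BenchmarkRecord.from_dict(self._get("benchmark", benchmark_id))

    def _benchmark_visible(self, actor: UserAccount, record: BenchmarkRecord) -> bool:
        return authorize(
            actor,
            "read_benchmark",
            ResourceRef(committee_id=record.committee_id, approval=record.approval),
        )

    def get_benchmark(self, token: str, benchmark_id: str) -> dict:
        actor = self._actor(token)
        record = self._benchmark(benchmark_id)
        if not self._benchmark_visible(actor, record):
            raise NotFoundError(f"no such benchmark: {benchmark_id}")
        return record.to_dict()

    def set_benchmark_approval(self, token: str, benchmark_id: str, decision: str) -> dict:
        actor = self._actor(token)

        def op():
            record = self._benchmark(benchmark_id)
            if not authorize(
                actor,
                "approve_benchmark",
                ResourceRef(committee_id=record.committee_id, approval=record.approval),
            ):
                raise AuthorizationError("benchmark approval is the platform admin's call")
            try:
                target = ApprovalStatus(decision)
            except ValueError:
                raise ValidationError(f"unknown decision {decision!r}") from None
            record.approval = record.approval.transition(target)
            self._put("benchmark", record.id, record.to_dict())
            return record.id, record.to_dict()

        return self._audited(actor, "approve_benchmark", op)

    # -- datasets ----------------------------------------------------------

    def register_dataset(self, token: str, draft: Mapping) -> dict:
        actor = self._actor(token)

        def op():
            if not authorize(actor, "register_dataset", ResourceRef()):
                raise AuthorizationError("dataset registration needs the data-owner role")
            allowed = {"name", "data_prep_cube_id", "statistics", "input_digest"}
            extra = set(draft) - allowed
            if extra:
                # notably rejects any attempt to upload a locator or data
                raise ValidationError(f"dataset: unsupported fields {sorted(extra)}")
            scan_payload(draft, "dataset")
            if not draft.get("name"):
                raise ValidationError("dataset: name required")
            self._get("cube", draft.get("data_prep_cube_id"))
            stats = draft.get("statistics")
            if stats is None:
                raise ValidationError("dataset: statistics required")
            check_statistics(stats)
            if not is_digest(draft.get("input_digest")):
                raise ValidationError("dataset: input_digest missing or malformed")
            record = DatasetRecord(
                id=str(self._next_id("dataset")),
                owner_id=actor.id,
                name=str(draft["name"]),
                data_prep_cube_id=str(draft["data_prep_cube_id"]),
                statistics=dict(stats),
                input_digest=draft["input_digest"],
            )
            self._put("dataset", record.id, record.to_dict())
            return record.id, record.to_dict()

        return self._audited(actor, "register_dataset", op)

    # -- associations ------------------------------------------------------

    def _subject_owner(self, kind: str, subject_id: str) -> str:
        if kind == "DATASET_BENCHMARK":
            return DatasetRecord.from_dict(self._get("dataset", subject_id)).owner_id
        return CubeRecord.from_dict(self._get("cube", subject_id)).owner_id

    def request_association(
        self,
        token: str,
        kind: str,
        subject_id: str,
        benchmark_id: str,
        compatibility_report: Mapping,
    ) -> dict:
        actor = self._actor(token)

        def op():
            if kind not in ASSOCIATION_KINDS:
                raise ContractError(f"unknown association kind {kind!r}")
            owner_id = self._subject_owner(kind, subject_id)
            if not authorize(
                actor,
                "request_association",
                ResourceRef(owner_id=owner_id, association_kind=kind),
            ):
                raise AuthorizationError("association may only be requested by the subject's owner")
            benchmark = self._benchmark(benchmark_id)
            if benchmark.approval is not ApprovalStatus.APPROVED:
                raise StateError(f"benchmark {benchmark_id} is not approved")
            if not isinstance(compatibility_report, Mapping) or "pass" not in compatibility_report:
                raise ValidationError("compatibility report with a 'pass' flag is required")
            scan_payload(compatibility_report, "compatibility_report")
            if not compatibility_report["pass"]:
                stage = compatibility_report.get("failed_stage", "unknown stage")
                raise ValidationError(
                    f"compatibility test did not pass (failed at {stage}); "
                    "association refused"
                )
            for existing in self._all("association"):
                assoc = Association.from_dict(existing)
                if (
                    assoc.kind == kind
                    and assoc.subject_id == str(subject_id)
                    and assoc.benchmark_id == str(benchmark_id)
                    and assoc.approval is not ApprovalStatus.REJECTED
                ):
                    raise DuplicateError(
                        f"a non-rejected association for this ({kind.lower()}) "
                        "pair already exists"
                    )
            record = Association(
                id=str(self._next_id("association")),
                kind=kind,
                subject_id=str(subject_id),
                benchmark_id=str(benchmark_id),
                approval=ApprovalStatus.PENDING,
                compatibility_report=dict(compatibility_report),
            )
            self._put("association", record.id, record.to_dict())
            return record.id, record.to_dict()

        return self._audited(actor, "request_association", op)

    def set_association_approval(self, token: str, association_id: str, decision: str) -> dict:
        actor = self._actor(token)

        def op():
            record = Association.from_dict(self._get("association", association_id))
            benchmark = self._benchmark(record.benchmark_id)
            if not authorize(
                actor,
                "approve_association",
                ResourceRef(committee_id=benchmark.committee_id),
            ):
                raise AuthorizationError(
                    "only the benchmark's committee decides its associations"
                )
            try:
                target = ApprovalStatus(decision)
            except ValueError:
                raise ValidationError(f"unknown decision {decision!r}") from None
            if target is ApprovalStatus.APPROVED and not record.compatibility_report.get(
                "pass"
            ):
                raise StateError(
                    "cannot approve an association whose compatibility report fails"
                )
            record.approval = record.approval.transition(target)
            self._put("association", record.id, record.to_dict())
            return record.id, record.to_dict()

        return self._audited(actor, "approve_association", op)

    def _association_status(self, kind: str, subject_id: str, benchmark_id: str) -> ApprovalStatus | None:
        for data in self._all("association"):
            assoc = Association.from_dict(data)
            if (
                assoc.kind == kind
                and assoc.subject_id == str(subject_id)
                and assoc.benchmark_id == str(benchmark_id)
                and assoc.approval is not ApprovalStatus.REJECTED
            ):
                return assoc.approval
        return None

    # -- results -----------------------------------------------------------

    def submit_result(self, token: str, draft: Mapping) -> dict:
        actor = self._actor(token)

        def op():
            scan_payload(draft, "result")
            for key in ("benchmark_id", "model_cube_id", "dataset_id", "metrics", "fingerprint"):
                if key not in draft:
                    raise ValidationError(f"result: {key} required")
            dataset = DatasetRecord.from_dict(self._get("dataset", draft["dataset_id"]))
            if not authorize(
                actor, "submit_result", ResourceRef(owner_id=dataset.owner_id)
            ):
                raise AuthorizationError("results are submitted by the evaluating data owner")
            benchmark = self._benchmark(draft["benchmark_id"])
            self._get("cube", draft["model_cube_id"])

            for kind, subject in (
                ("DATASET_BENCHMARK", draft["dataset_id"]),
                ("MODEL_BENCHMARK", draft["model_cube_id"]),
            ):
                status = self._association_status(kind, subject, benchmark.id)
                if status is not ApprovalStatus.APPROVED:
                    raise StateError(
                        f"{kind} association is {status.value if status else 'absent'}; "
                        "both associations must be APPROVED before results are accepted"
                    )

            metrics = draft["metrics"]
            if not isinstance(metrics, Mapping) or not metrics:
                raise ValidationError("result: metrics must be a non-empty mapping")
            import math

            for name, value in metrics.items():
                if not isinstance(value, (int, float)) or isinstance(value, bool) or not math.isfinite(value):
                    raise ValidationError(f"result: metric {name!r} is not a finite number")
            per_case = draft.get("per_case")
            if per_case is not None:
                if not isinstance(per_case, list) or len(per_case) > MAX_PER_CASE_ROWS:
                    raise ValidationError(
                        f"result: per_case table capped at {MAX_PER_CASE_ROWS} rows"
                    )
            fingerprint = draft["fingerprint"]
            if not isinstance(fingerprint, Mapping) or not all(
                is_digest(v) for v in fingerprint.values()
            ):
                raise ValidationError("result: fingerprint must map cube names to digests")

            record = ResultRecord(
                id=str(self._next_id("result")),
                benchmark_id=str(draft["benchmark_id"]),
                model_cube_id=str(draft["model_cube_id"]),
                dataset_id=str(draft["dataset_id"]),
                owner_id=actor.id,
                metrics={k: float(v) for k, v in metrics.items()},
                per_case=per_case,
                fingerprint=dict(fingerprint),
                submitted_at=_now(),
            )
            self._put("result", record.id, record.to_dict())
            return record.id, record.to_dict()

        return self._audited(actor, "submit_result", op)

    # -- queries -----------------------------------------------------------

    def query(self, token: str, selector: str, filter: Mapping | None = None) -> list[dict]:
        actor = self._actor(token)
        filter = dict(filter or {})

        if selector == "benchmarks":
            return [
                b.to_dict()
                for b in map(BenchmarkRecord.from_dict, self._all("benchmark"))
                if self._benchmark_visible(actor, b)
            ]

        if selector in ("benchmark_models", "benchmark_datasets"):
            benchmark_id = filter.get("benchmark_id")
            if benchmark_id is None:
                raise ContractError(f"{selector} query requires benchmark_id")
            benchmark = self._benchmark(benchmark_id)
            if not self._benchmark_visible(actor, benchmark):
                raise NotFoundError(f"no such benchmark: {benchmark_id}")
            kind = "MODEL_BENCHMARK" if selector == "benchmark_models" else "DATASET_BENCHMARK"
            return [
                a.to_dict()
                for a in map(Association.from_dict, self._all("association"))
                if a.benchmark_id == str(benchmark_id)
                and a.kind == kind
                and a.approval is ApprovalStatus.APPROVED
            ]

        if selector == "results":
            benchmark_id = filter.get("benchmark_id")
            results = [ResultRecord.from_dict(d) for d in self._all("result")]
            if benchmark_id is not None:
                results = [r for r in results if r.benchmark_id == str(benchmark_id)]
            visible = []
            for result in results:
                benchmark = self._benchmark(result.benchmark_id)
                participants = tuple(
                    self._subject_owner(a.kind, a.subject_id)
                    for a in map(Association.from_dict, self._all("association"))
                    if a.benchmark_id == result.benchmark_id
                    and a.approval is ApprovalStatus.APPROVED
                )
                ref = ResourceRef(
                    owner_id=result.owner_id,
                    committee_id=benchmark.committee_id,
                    sharing_policy=benchmark.sharing_policy,
                    participant_ids=participants,
                )
                if authorize(actor, "read_results", ref):
                    visible.append(result.to_dict())
            return visible

        raise ContractError(f"unknown query selector {selector!r}")

    # -- audit -------------------------------------------------------------

    def audit_trail(self, token: str, filter: Mapping | None = None) -> list[dict]:
        actor = self._actor(token)
        filter = dict(filter or {})
        benchmark_id = filter.get("benchmark_id")

        if benchmark_id is not None:
            benchmark = self._benchmark(benchmark_id)
            ref = ResourceRef(committee_id=benchmark.committee_id)
        else:
            ref = ResourceRef()
        if not authorize(actor, "read_audit", ref):
            raise AuthorizationError("audit trail restricted to the admin or owning committee")

        rows = self._db.execute("SELECT data FROM audit ORDER BY seq").fetchall()
        events = [json.loads(r[0]) for r in rows]
        if benchmark_id is not None:
            scoped = {str(benchmark_id)}
            for data in self._all("association"):
                if data["benchmark_id"] == str(benchmark_id):
                    scoped.add(data["id"])
            for data in self._all("result"):
                if data["benchmark_id"] == str(benchmark_id):
                    scoped.add(data["id"])
            events = [e for e in events if e["resource_id"] in scoped]
        if "actor_id" in filter:
            events = [e for e in events if e["actor_id"] == str(filter["actor_id"])]
        if "action" in filter:
            events = [e for e in events if e["action"] == filter["action"]]
        return events

    # -- HTTP-style router -------------------------------------------------

    _ROUTES: list[tuple[str, re.Pattern]] = [
        ("POST", re.compile(r"^/accounts$")),
        ("POST", re.compile(r"^/cubes$")),
        ("POST", re.compile(r"^/benchmarks$")),
        ("POST", re.compile(r"^/datasets$")),
        ("POST", re.compile(r"^/associations$")),
        ("POST", re.compile(r"^/results$")),
        ("PUT", re.compile(r"^/benchmarks/(?P<id>[^/]+)/approval$")),
        ("PUT", re.compile(r"^/associations/(?P<id>[^/]+)/approval$")),
        ("GET", re.compile(r"^/benchmarks$")),
        ("GET", re.compile(r"^/benchmarks/(?P<id>[^/]+)$")),
        ("GET", re.compile(r"^/benchmarks/(?P<id>[^/]+)/models$")),
        ("GET", re.compile(r"^/benchmarks/(?P<id>[^/]+)/datasets$")),
        ("GET", re.compile(r"^/benchmarks/(?P<id>[^/]+)/results$")),
        ("GET", re.compile(r"^/cubes/(?P<id>[^/]+)$")),
        ("GET", re.compile(r"^/accounts/(?P<id>[^/]+)$")),
        ("GET", re.compile(r"^/audit$")),
    ]

    def handle_request(
        self, method: str, path: str, body: Mapping | None, token: str | None
    ) -> tuple[int, Any]:
        """Single entry point shared by the HTTP and in-process transports.

        Returns ``(status, payload)``; errors become ``{code, message}``.
        """
        try:
            with self._lock:
                return 200, self._route(method.upper(), path, body or {}, token)
        except MedfedError as exc:
            return exc.http_status, {"code": exc.code, "message": exc.message}

    def _route(self, method: str, path: str, body: Mapping, token: str | None) -> Any:
        for verb, pattern in self._ROUTES:
            if verb != method:
                continue
            match = pattern.match(path)
            if not match:
                continue
            rid = match.groupdict().get("id")
            key = (verb, pattern.pattern)
            if key == ("POST", r"^/accounts$"):
                return self.create_account(token, body.get("name"), body.get("roles") or [])
            if key == ("POST", r"^/cubes$"):
                return self.submit_cube(token, body)
            if key == ("POST", r"^/benchmarks$"):
                return self.submit_benchmark(token, body)
            if key == ("POST", r"^/datasets$"):
                return self.register_dataset(token, body)
            if key == ("POST", r"^/associations$"):
                return self.request_association(
                    token,
                    body.get("kind"),
                    body.get("subject_id"),
                    body.get("benchmark_id"),
                    body.get("compatibility_report") or {},
                )
            if key == ("POST", r"^/results$"):
                return self.submit_result(token, body)
            if verb == "PUT" and "benchmarks" in pattern.pattern:
                return self.set_benchmark_approval(token, rid, body.get("decision"))
            if verb == "PUT" and "associations" in pattern.pattern:
                return self.set_association_approval(token, rid, body.get("decision"))
            if key == ("GET", r"^/benchmarks$"):
                return self.query(token, "benchmarks", body)
            if key == ("GET", r"^/benchmarks/(?P<id>[^/]+)$"):
                return self.get_benchmark(token, rid)
            if pattern.pattern.endswith("/models$"):
                return self.query(token, "benchmark_models", {"benchmark_id": rid})
            if pattern.pattern.endswith("/datasets$"):
                return self.query(token, "benchmark_datasets", {"benchmark_id": rid})
            if pattern.pattern.endswith("/results$"):
                return self.query(token, "results", {"benchmark_id": rid})
            if key == ("GET", r"^/cubes/(?P<id>[^/]+)$"):
                return self.get_cube(token, rid)
            if key == ("GET", r"^/accounts/(?P<id>[^/]+)$"):
                return self.get_account(token, rid)
            if key == ("GET", r"^/audit$"):
                return self.audit_trail(token, body)
        raise NotFoundError(f"no route for {method} {path}")

    # -- introspection used by storage audits --------------------------------

    def dump_rows(self) -> list[str]:
        """Every persisted value as text (for privacy/storage audits)."""
        rows = []
        for table, column in (("records", "data"), ("audit", "data")):
            for (value,) in self._db.execute(f"SELECT {column} FROM {table}"):
                rows.append(value)
        for (name, roles) in self._db.execute("SELECT name, roles FROM accounts"):
            rows.append(name)
            rows.append(roles)
        return rows
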