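"""Server-side record types and their JSON forms.

Every record stores *metadata only*: locators and digests for code,
aggregate statistics for datasets, metric values for results.  Raw data
and code payloads never appear here — that invariant is enforced at the
API boundary (see :mod:`medfed.privacy`) and re-checked by storage audits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from .cubes import CubeKind
from .registry import ApprovalStatus, ResultSharingPolicy


@dataclass
class CubeRecord:
    """Registration of one cube: how to obtain and verify it, never its code."""

    id: str
    owner_id: str
    kind: CubeKind
    name: str
    manifest_url: str
    manifest_digest: str
    asset_digests: list[tuple[str, str]]

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "owner_id": self.owner_id,
            "kind": self.kind.value,
            "name": self.name,
            "manifest_url": self.manifest_url,
            "manifest_digest": self.manifest_digest,
            "asset_digests": [list(pair) for pair in self.asset_digests],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CubeRecord":
        return cls(
            id=data["id"],
            owner_id=data["owner_id"],
            kind=CubeKind(data["kind"]),
            name=data["name"],
            manifest_url=data["manifest_url"],
            manifest_digest=data["manifest_digest"],
            asset_digests=[tuple(pair) for pair in data["asset_digests"]],
        )


@dataclass
class BenchmarkRecord:
    """The seven-asset benchmark bundle with its approval state."""

    id: str
    committee_id: str
    name: str
    specification: str
    data_prep_cube_id: str
    reference_model_cube_id: str
    metrics_cube_id: str
    demo_dataset_locator: str
    demo_dataset_digest: str
    approval: ApprovalStatus = ApprovalStatus.PENDING
    sharing_policy: ResultSharingPolicy = ResultSharingPolicy.COMMITTEE_ONLY
    docs_url: str = ""

    def to_dict(self) -> dict:
        data = self.__dict__.copy()
        data["approval"] = self.approval.value
        data["sharing_policy"] = self.sharing_policy.value
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "BenchmarkRecord":
        data = dict(data)
        data["approval"] = ApprovalStatus(data["approval"])
        data["sharing_policy"] = ResultSharingPolicy(data["sharing_policy"])
        return cls(**data)


@dataclass
class DatasetRecord:
    """Dataset registration: name, provenance, aggregate statistics, digest.

    Deliberately has no locator field — the server never learns where the
    data lives.
    """

    id: str
    owner_id: str
    name: str
    data_prep_cube_id: str
    statistics: dict[str, Any]
    input_digest: str

    def to_dict(self) -> dict:
        return self.__dict__.copy()

    @classmethod
    def from_dict(cls, data: dict) -> "DatasetRecord":
        return cls(**data)


@dataclass
class Association:
    """Approval-gated link between a dataset or model and a benchmark."""

    id: str
    kind: str  # DATASET_BENCHMARK | MODEL_BENCHMARK
    subject_id: str
    benchmark_id: str
    approval: ApprovalStatus
    compatibility_report: dict[str, Any]

    def to_dict(self) -> dict:
        data = self.__dict__.copy()
        data["approval"] = self.approval.value
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "Association":
        data = dict(data)
        data["approval"] = ApprovalStatus(data["approval"])
        return cls(**data)


@dataclass
class ResultRecord:
    """Owner-approved metrics plus the fingerprint of the exact cubes run."""

    id: str
    benchmark_id: str
    model_cube_id: str
    dataset_id: str
    owner_id: str
    metrics: dict[str, float]
    per_case: list[dict] | None
    fingerprint: dict[str, str]
    submitted_at: str

    def to_dict(self) -> dict:
        return self.__dict__.copy()

    @classmethod
    def from_dict(cls, data: dict) -> "ResultRecord":
        return cls(**data)


@dataclass
class AuditEvent:
    """One entry of the append-only, gap-free experiment trail."""

    sequence_number: int
    actor_id: str
    action: str
    resource_id: str
    outcome: str  # accepted | rejected
    timestamp: str
    detail: str = ""

    def to_dict(self) -> dict:
        return self.__dict__.copy()

    @classmethod
    def from_dict(cls, data: dict) -> "AuditEvent":
        return cls(**data)
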