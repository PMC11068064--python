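"""Shared domain vocabulary: roles, approval lifecycle, result-sharing
policies, and the role/permission matrix used by both server and client.

The permission model is deliberately a *pure function*: ``authorize`` looks
only at the actor's roles, the action name, and a static description of the
resource (ownership, committee, sharing policy, participants).  It is total
over the action vocabulary — every (role set, action) combination has a
defined, deterministic decision — and denies by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .errors import ContractError, StateError


class Role(str, Enum):
    """The four participant roles of a benchmarking federation.

    A single organization may hold several roles at once (e.g. a hospital
    that both owns evaluation data and fields its own model), so accounts
    carry a non-empty *set* of roles.
    """

    PLATFORM_ADMIN = "PLATFORM_ADMIN"
    BENCHMARK_COMMITTEE = "BENCHMARK_COMMITTEE"
    DATA_OWNER = "DATA_OWNER"
    MODEL_OWNER = "MODEL_OWNER"


class ApprovalStatus(str, Enum):
    """Lifecycle of anything that needs sign-off (benchmarks, associations).

    PENDING may move to APPROVED or REJECTED; both of those are terminal,
    which keeps the audit trail append-only and the state machine acyclic.
    """

    PENDING = "PENDING"
    APPROVED = "APPROVED"
    REJECTED = "REJECTED"

    @property
    def terminal(self) -> bool:
        return self is not ApprovalStatus.PENDING

    def transition(self, decision: "ApprovalStatus") -> "ApprovalStatus":
        """Validate and perform a state transition; terminal states are final."""
        if self.terminal:
            raise StateError(
                f"approval state {self.value} is terminal; cannot move to {decision.value}"
            )
        if decision is ApprovalStatus.PENDING:
            raise StateError("cannot transition back to PENDING")
        return decision


class ResultSharingPolicy(str, Enum):
    """Who may read a benchmark's submitted results.

    COMMITTEE_ONLY (the default) restricts reads to the benchmark committee
    and the submitting owner; PARTICIPANTS extends to every account with an
    approved association to the benchmark; PUBLIC opens reads to all users.
    """

    COMMITTEE_ONLY = "COMMITTEE_ONLY"
    PARTICIPANTS = "PARTICIPANTS"
    PUBLIC = "PUBLIC"


@dataclass(frozen=True)
class UserAccount:
    """A registered participant; ``roles`` is non-empty by construction."""

    id: str
    name: str
    roles: frozenset[Role]

    def __post_init__(self) -> None:
        if not self.roles:
            raise ContractError("account must hold at least one role")

    def has(self, role: Role) -> bool:
        return role in self.roles


@dataclass(frozen=True)
class ResourceRef:
    """Static facts about a resource that permission decisions may consult.

    All fields are optional; an absent fact simply cannot grant access
    (deny-by-default).  ``participant_ids`` are accounts holding an APPROVED
    association to the benchmark the resource belongs to.
    """

    owner_id: str | None = None
    committee_id: str | None = None
    sharing_policy: ResultSharingPolicy | None = None
    approval: ApprovalStatus | None = None
    association_kind: str | None = None
    participant_ids: tuple[str, ...] = field(default=())


#: the complete action vocabulary; authorize() rejects anything else.
ACTIONS = frozenset(
    {
        "create_account",
        "submit_cube",
        "submit_benchmark",
        "approve_benchmark",
        "register_dataset",
        "request_association",
        "approve_association",
        "submit_result",
        "read_results",
        "read_benchmark",
        "read_audit",
    }
)


def authorize(actor: UserAccount, action: str, resource: ResourceRef) -> bool:
    """Decide whether ``actor`` may perform ``action`` on ``resource``.

    Pure and total: depends only on the arguments, defined for every action
    in :data:`ACTIONS`, and denies any combination not explicitly allowed.
    Raises :class:`ContractError` for an action outside the vocabulary.
    """
    if action not in ACTIONS:
        raise ContractError(f"unknown action {action!r}")

    is_admin = actor.has(Role.PLATFORM_ADMIN)
    is_owner = resource.owner_id is not None and resource.owner_id == actor.id
    is_committee = (
        resource.committee_id is not None and resource.committee_id == actor.id
    )

    if action == "create_account":
        return is_admin
    if action == "approve_benchmark":
        # Admin sign-off is always required, even for the submitting committee.
        return is_admin
    if action == "read_audit":
        # Global trail: admin.  Benchmark-scoped trail: that benchmark's committee.
        return is_admin or (actor.has(Role.BENCHMARK_COMMITTEE) and is_committee)
    if action == "submit_cube":
        # Model owners register model cubes; committees register benchmark assets.
        return actor.has(Role.MODEL_OWNER) or actor.has(Role.BENCHMARK_COMMITTEE)
    if action == "submit_benchmark":
        return actor.has(Role.BENCHMARK_COMMITTEE)
    if action == "register_dataset":
        return actor.has(Role.DATA_OWNER)
    if action == "request_association":
        if not is_owner:
            return False
        if resource.association_kind == "DATASET_BENCHMARK":
            return actor.has(Role.DATA_OWNER)
        if resource.association_kind == "MODEL_BENCHMARK":
            # committees associate their own reference model; owners their candidates
            return actor.has(Role.MODEL_OWNER) or actor.has(Role.BENCHMARK_COMMITTEE)
        return False
    if action == "approve_association":
        # Only the committee that owns the benchmark (or the admin) decides.
        return is_admin or (actor.has(Role.BENCHMARK_COMMITTEE) and is_committee)
    if action == "submit_result":
        return actor.has(Role.DATA_OWNER) and is_owner
    if action == "read_benchmark":
        if resource.approval is ApprovalStatus.APPROVED:
            return True
        return is_admin or is_committee
    if action == "read_results":
        if is_admin or is_committee or is_owner:
            return True
        if resource.sharing_policy is ResultSharingPolicy.PUBLIC:
            return True
        if resource.sharing_policy is ResultSharingPolicy.PARTICIPANTS:
            return actor.id in resource.participant_ids
        return False
    raise AssertionError(f"unhandled action {action}")  # pragma: no cover
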