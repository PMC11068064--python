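"""Coordination-server semantics: registration, approval gating,
visibility, result gating, audit completeness, storage privacy."""

import base64
import json

import pytest
from hypothesis import given, settings, strategies as st

from medfed.errors import (
    AuthenticationError,
    AuthorizationError,
    ContractError,
    DuplicateError,
    PrivacyError,
    StateError,
    ValidationError,
)
from medfed.hashing import sha256_bytes
from medfed.privacy import PNG_MAGIC
from medfed.registry import ApprovalStatus, Role
from medfed.server import CoordinationServer

DIG = sha256_bytes(b"x")


def cube_draft(kind="MODEL", name="m1"):
    return {
        "name": name,
        "kind": kind,
        "manifest_url": f"/tmp/{name}",
        "manifest_digest": DIG,
        "asset_digests": [["run.py", DIG]],
    }


def benchmark_draft(prep, model, metrics, **extra):
    return {
        "name": extra.pop("name", "bench"),
        "data_prep_cube_id": prep,
        "reference_model_cube_id": model,
        "metrics_cube_id": metrics,
        "demo_dataset_locator": "/tmp/demo",
        "demo_dataset_digest": DIG,
        **extra,
    }


def submit_three_cubes(server, token):
    prep = server.submit_cube(token, cube_draft("DATA_PREP", "prep"))
    model = server.submit_cube(token, cube_draft("MODEL", "model"))
    metrics = server.submit_cube(token, cube_draft("METRICS", "metrics"))
    return prep["id"], model["id"], metrics["id"]


# -- accounts ----------------------------------------------------------------


def test_account_lifecycle(server, accounts):
    admin_token = accounts["admin"]["token"]
    created = server.create_account(admin_token, "org-b", ["DATA_OWNER", "MODEL_OWNER"])
    fetched = server.get_account(admin_token, created["id"])
    assert fetched["name"] == "org-b"
    assert sorted(fetched["roles"]) == ["DATA_OWNER", "MODEL_OWNER"]
    with pytest.raises(DuplicateError):
        server.create_account(admin_token, "org-b", ["DATA_OWNER"])
    with pytest.raises(ValidationError):
        server.create_account(admin_token, "org-c", [])
    with pytest.raises(AuthorizationError):
        server.create_account(accounts["data_owner"]["token"], "org-d", ["DATA_OWNER"])
    with pytest.raises(AuthenticationError):
        server.create_account("bogus-token", "org-e", ["DATA_OWNER"])
    with pytest.raises(StateError):
        server.bootstrap_admin()  # only on an empty server


# -- cubes -------------------------------------------------------------------


def test_cube_submission_validation(server, accounts):
    token = accounts["model_owner"]["token"]
    record = server.submit_cube(token, cube_draft())
    assert record["id"] and record["owner_id"] == accounts["model_owner"]["id"]

    bad = cube_draft(name="short-digest")
    bad["manifest_digest"] = "ab" * 31 + "c"  # 63 chars
    with pytest.raises(ValidationError):
        server.submit_cube(token, bad)

    smuggle = cube_draft(name="smuggle")
    smuggle["asset_digests"] = [["blob.py", DIG]]
    smuggle["manifest_url"] = base64.b64encode(PNG_MAGIC + b"payload" * 400).decode()
    with pytest.raises(PrivacyError):
        server.submit_cube(token, smuggle)

    with pytest.raises(AuthorizationError):
        server.submit_cube(accounts["data_owner"]["token"], cube_draft(name="x"))


# -- benchmarks --------------------------------------------------------------


def test_benchmark_submission_and_kind_checks(server, accounts):
    token = accounts["committee"]["token"]
    prep, model, metrics = submit_three_cubes(server, token)

    swapped = benchmark_draft(metrics, model, prep)  # prep slot gets a METRICS cube
    with pytest.raises(ValidationError, match="METRICS"):
        server.submit_benchmark(token, swapped)

    no_digest = benchmark_draft(prep, model, metrics)
    no_digest.pop("demo_dataset_digest")
    with pytest.raises(ValidationError, match="demo_dataset_digest"):
        server.submit_benchmark(token, no_digest)

    with pytest.raises(AuthorizationError):
        server.submit_benchmark(
            accounts["model_owner"]["token"], benchmark_draft(prep, model, metrics)
        )

    record = server.submit_benchmark(token, benchmark_draft(prep, model, metrics))
    assert record["approval"] == "PENDING"
    assert record["sharing_policy"] == "COMMITTEE_ONLY"


def test_benchmark_visibility_gated_on_approval(server, accounts):
    committee_token = accounts["committee"]["token"]
    prep, model, metrics = submit_three_cubes(server, committee_token)
    record = server.submit_benchmark(
        committee_token, benchmark_draft(prep, model, metrics)
    )

    owner_token = accounts["data_owner"]["token"]
    assert server.query(owner_token, "benchmarks") == []  # pending: invisible
    assert [b["id"] for b in server.query(committee_token, "benchmarks")] == [record["id"]]

    with pytest.raises(AuthorizationError):
        server.set_benchmark_approval(committee_token, record["id"], "APPROVED")
    server.set_benchmark_approval(accounts["admin"]["token"], record["id"], "APPROVED")
    assert [b["id"] for b in server.query(owner_token, "benchmarks")] == [record["id"]]

    with pytest.raises(StateError):  # terminal
        server.set_benchmark_approval(accounts["admin"]["token"], record["id"], "REJECTED")


# -- datasets ----------------------------------------------------------------


def test_dataset_registration_guards(server, accounts):
    committee_token = accounts["committee"]["token"]
    prep, _, _ = submit_three_cubes(server, committee_token)
    owner_token = accounts["data_owner"]["token"]

    good = {
        "name": "hospital-a-data",
        "data_prep_cube_id": prep,
        "statistics": {"n_cases": 20, "mean_foreground_fraction": 0.07},
        "input_digest": DIG,
    }
    record = server.register_dataset(owner_token, good)
    assert record["statistics"]["n_cases"] == 20

    per_case = dict(good, name="d2", statistics={"pixels": list(range(50))})
    with pytest.raises(PrivacyError):
        server.register_dataset(owner_token, per_case)

    located = dict(good, name="d3", locator="/data/secret")
    with pytest.raises(ValidationError, match="unsupported fields"):
        server.register_dataset(owner_token, located)

    with pytest.raises(AuthorizationError):
        server.register_dataset(accounts["model_owner"]["token"], dict(good, name="d4"))


# -- associations ------------------------------------------------------------


def approved_benchmark(server, accounts):
    committee_token = accounts["committee"]["token"]
    prep, model, metrics = submit_three_cubes(server, committee_token)
    record = server.submit_benchmark(committee_token, benchmark_draft(prep, model, metrics))
    server.set_benchmark_approval(accounts["admin"]["token"], record["id"], "APPROVED")
    return record["id"], prep, model, metrics


def register_owned_dataset(server, accounts, prep):
    return server.register_dataset(
        accounts["data_owner"]["token"],
        {
            "name": "ds",
            "data_prep_cube_id": prep,
            "statistics": {"n_cases": 6},
            "input_digest": DIG,
        },
    )["id"]


PASSING = {"pass": True, "stages": {"all": "pass"}}


def test_association_workflow_and_invariants(server, accounts):
    benchmark_id, prep, model, metrics = approved_benchmark(server, accounts)
    dataset_id = register_owned_dataset(server, accounts, prep)
    owner_token = accounts["data_owner"]["token"]

    with pytest.raises(ValidationError, match="did not pass"):
        server.request_association(
            owner_token, "DATASET_BENCHMARK", dataset_id, benchmark_id,
            {"pass": False, "failed_stage": "sanity_check"},
        )

    assoc = server.request_association(
        owner_token, "DATASET_BENCHMARK", dataset_id, benchmark_id, PASSING
    )
    assert assoc["approval"] == "PENDING"

    with pytest.raises(DuplicateError):  # one non-rejected association per pair
        server.request_association(
            owner_token, "DATASET_BENCHMARK", dataset_id, benchmark_id, PASSING
        )

    with pytest.raises(AuthorizationError):  # subject must be owned by caller
        server.request_association(
            accounts["model_owner"]["token"], "DATASET_BENCHMARK", dataset_id,
            benchmark_id, PASSING,
        )

    with pytest.raises(AuthorizationError):  # only the owning committee decides
        server.set_association_approval(owner_token, assoc["id"], "APPROVED")

    decided = server.set_association_approval(
        accounts["committee"]["token"], assoc["id"], "REJECTED"
    )
    assert decided["approval"] == "REJECTED"

    # re-request after rejection is allowed
    again = server.request_association(
        owner_token, "DATASET_BENCHMARK", dataset_id, benchmark_id, PASSING
    )
    server.set_association_approval(accounts["committee"]["token"], again["id"], "APPROVED")

    with pytest.raises(ContractError):
        server.request_association(owner_token, "FRIENDSHIP", dataset_id, benchmark_id, PASSING)


def test_association_requires_approved_benchmark(server, accounts):
    committee_token = accounts["committee"]["token"]
    prep, model, metrics = submit_three_cubes(server, committee_token)
    pending = server.submit_benchmark(committee_token, benchmark_draft(prep, model, metrics))
    dataset_id = register_owned_dataset(server, accounts, prep)
    with pytest.raises(StateError, match="not approved"):
        server.request_association(
            accounts["data_owner"]["token"], "DATASET_BENCHMARK", dataset_id,
            pending["id"], PASSING,
        )


def test_wrong_committee_cannot_decide(server, accounts):
    benchmark_id, prep, model, metrics = approved_benchmark(server, accounts)
    dataset_id = register_owned_dataset(server, accounts, prep)
    assoc = server.request_association(
        accounts["data_owner"]["token"], "DATASET_BENCHMARK", dataset_id,
        benchmark_id, PASSING,
    )
    other = server.create_account(
        accounts["admin"]["token"], "committee-2", [Role.BENCHMARK_COMMITTEE.value]
    )
    with pytest.raises(AuthorizationError):
        server.set_association_approval(other["token"], assoc["id"], "APPROVED")


# -- results: the gating oracle ----------------------------------------------


def result_draft(benchmark_id, model_id, dataset_id):
    return {
        "benchmark_id": benchmark_id,
        "model_cube_id": model_id,
        "dataset_id": dataset_id,
        "metrics": {"dice": 0.9, "iou": 0.82},
        "fingerprint": {"model": DIG},
    }


@pytest.mark.parametrize("dataset_state", [None, "PENDING", "REJECTED", "APPROVED"])
@pytest.mark.parametrize("model_state", [None, "PENDING", "REJECTED", "APPROVED"])
def test_result_gating_matches_association_predicate(server, accounts, dataset_state, model_state):
    """A result is accepted iff both associations are APPROVED — checked
    against the predicate recomputed independently from the association
    states we constructed."""
    benchmark_id, prep, _, _ = approved_benchmark(server, accounts)
    model_id = server.submit_cube(accounts["model_owner"]["token"], cube_draft(name="cand"))["id"]
    dataset_id = register_owned_dataset(server, accounts, prep)
    committee_token = accounts["committee"]["token"]

    def set_state(kind, subject, owner_key, state):
        if state is None:
            return
        assoc = server.request_association(
            accounts[owner_key]["token"], kind, subject, benchmark_id, PASSING
        )
        if state != "PENDING":
            server.set_association_approval(committee_token, assoc["id"], state)

    set_state("DATASET_BENCHMARK", dataset_id, "data_owner", dataset_state)
    set_state("MODEL_BENCHMARK", model_id, "model_owner", model_state)

    should_accept = dataset_state == "APPROVED" and model_state == "APPROVED"
    draft = result_draft(benchmark_id, model_id, dataset_id)
    if should_accept:
        record = server.submit_result(accounts["data_owner"]["token"], draft)
        assert record["metrics"]["dice"] == 0.9
    else:
        with pytest.raises(StateError):
            server.submit_result(accounts["data_owner"]["token"], draft)


def test_result_validation(server, accounts):
    benchmark_id, prep, _, _ = approved_benchmark(server, accounts)
    model_id = server.submit_cube(accounts["model_owner"]["token"], cube_draft(name="cand"))["id"]
    dataset_id = register_owned_dataset(server, accounts, prep)
    committee_token = accounts["committee"]["token"]
    for kind, subject, owner in (
        ("DATASET_BENCHMARK", dataset_id, "data_owner"),
        ("MODEL_BENCHMARK", model_id, "model_owner"),
    ):
        assoc = server.request_association(
            accounts[owner]["token"], kind, subject, benchmark_id, PASSING
        )
        server.set_association_approval(committee_token, assoc["id"], "APPROVED")

    draft = result_draft(benchmark_id, model_id, dataset_id)
    draft["metrics"] = {"dice": float("nan")}
    with pytest.raises(ValidationError, match="finite"):
        server.submit_result(accounts["data_owner"]["token"], draft)

    draft["metrics"] = {"dice": 0.5}
    with pytest.raises(AuthorizationError):  # only the evaluating owner submits
        server.submit_result(accounts["model_owner"]["token"], draft)


# -- result visibility per sharing policy -------------------------------------


def test_result_visibility_policies(server, accounts):
    benchmark_id, prep, _, _ = approved_benchmark(server, accounts)
    model_id = server.submit_cube(accounts["model_owner"]["token"], cube_draft(name="cand"))["id"]
    dataset_id = register_owned_dataset(server, accounts, prep)
    committee_token = accounts["committee"]["token"]
    for kind, subject, owner in (
        ("DATASET_BENCHMARK", dataset_id, "data_owner"),
        ("MODEL_BENCHMARK", model_id, "model_owner"),
    ):
        assoc = server.request_association(
            accounts[owner]["token"], kind, subject, benchmark_id, PASSING
        )
        server.set_association_approval(committee_token, assoc["id"], "APPROVED")
    server.submit_result(
        accounts["data_owner"]["token"], result_draft(benchmark_id, model_id, dataset_id)
    )

    unrelated = server.create_account(
        accounts["admin"]["token"], "hospital-b", [Role.DATA_OWNER.value]
    )
    filt = {"benchmark_id": benchmark_id}
    # COMMITTEE_ONLY: committee and submitting owner see it; an unrelated owner does not
    assert len(server.query(committee_token, "results", filt)) == 1
    assert len(server.query(accounts["data_owner"]["token"], "results", filt)) == 1
    assert server.query(unrelated["token"], "results", filt) == []
    # the participating model owner sees it only under PARTICIPANTS
    assert server.query(accounts["model_owner"]["token"], "results", filt) == []

    with pytest.raises(ContractError):
        server.query(committee_token, "everything")


# -- audit trail ---------------------------------------------------------------


def test_audit_completeness_and_order(server, accounts):
    """Every mutating call (accepted or rejected) appends exactly one
    event; sequence numbers are gap-free; reads append nothing."""
    admin_token = accounts["admin"]["token"]
    base = len(server.audit_trail(admin_token))

    committee_token = accounts["committee"]["token"]
    mutating = 0
    prep, model, metrics = submit_three_cubes(server, committee_token)
    mutating += 3
    record = server.submit_benchmark(committee_token, benchmark_draft(prep, model, metrics))
    mutating += 1
    with pytest.raises(AuthorizationError):
        server.set_benchmark_approval(committee_token, record["id"], "APPROVED")
    mutating += 1  # rejected calls are audited too
    server.set_benchmark_approval(admin_token, record["id"], "APPROVED")
    mutating += 1
    with pytest.raises(ValidationError):
        server.submit_cube(committee_token, {"name": "bad", "kind": "MODEL"})
    mutating += 1

    server.query(committee_token, "benchmarks")  # read: not audited
    events = server.audit_trail(admin_token)
    assert len(events) - base == mutating
    seqs = [e["sequence_number"] for e in events]
    assert seqs == list(range(1, len(seqs) + 1))

    outcomes = [e["outcome"] for e in events[base:]]
    assert outcomes.count("rejected") == 2

    # actor filter preserves order
    mine = server.audit_trail(admin_token, {"actor_id": accounts["committee"]["id"]})
    assert [e["sequence_number"] for e in mine] == sorted(e["sequence_number"] for e in mine)

    with pytest.raises(AuthorizationError):
        server.audit_trail(accounts["data_owner"]["token"])


# -- storage privacy audit -----------------------------------------------------


@settings(max_examples=25, deadline=None)
@given(data=st.data())
def test_storage_never_holds_blobs(data):
    """After a randomized mix of valid and adversarial API calls, no
    persisted value exceeds 10 KB and none contains PNG bytes."""
    server = CoordinationServer(":memory:")
    admin = server.bootstrap_admin()
    committee = server.create_account(admin["token"], "c", ["BENCHMARK_COMMITTEE"])
    owner = server.create_account(admin["token"], "o", ["DATA_OWNER"])
    prep = server.submit_cube(committee["token"], cube_draft("DATA_PREP", "p"))

    payload_strategies = st.one_of(
        st.text(max_size=30),
        st.integers(-10, 10),
        st.just(base64.b64encode(PNG_MAGIC + b"\x00" * 64).decode()),
        st.just(PNG_MAGIC.decode("latin-1") * 3),
        st.just("B" * 4000),
        st.lists(st.integers(0, 255), max_size=40),
    )
    for _ in range(data.draw(st.integers(3, 8))):
        call = data.draw(st.sampled_from(["dataset", "cube", "benchmark"]))
        blob = data.draw(payload_strategies)
        try:
            if call == "dataset":
                server.register_dataset(
                    owner["token"],
                    {
                        "name": data.draw(st.text(min_size=1, max_size=10)),
                        "data_prep_cube_id": prep["id"],
                        "statistics": {"n_cases": 5, "extra": blob},
                        "input_digest": DIG,
                    },
                )
            elif call == "cube":
                draft = cube_draft(name=data.draw(st.text(min_size=1, max_size=10)))
                draft["manifest_url"] = blob if isinstance(blob, str) else str(blob)
                server.submit_cube(committee["token"], draft)
            else:
                draft = benchmark_draft(prep["id"], prep["id"], prep["id"])
                draft["specification"] = blob if isinstance(blob, str) else str(blob)
                server.submit_benchmark(committee["token"], draft)
        except Exception:
            pass  # rejection is the expected defence

    for row in server.dump_rows():
        assert len(row.encode()) <= 10 * 1024 + 2048  # row = record + envelope slack
        assert PNG_MAGIC.decode("latin-1") not in row
        assert base64.b64encode(PNG_MAGIC).decode()[:8] not in row
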