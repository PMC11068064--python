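"""Owner-client workflows: verified fetch, staged preparation,
consent-gated registration, compatibility testing, offline execution and
owner-approved upload."""

import json
import shutil

import pytest

from medfed.client import Client
from medfed.cubes import CubeKind
from medfed.demo.cubebuild import build_incompatible_model_cube, write_cube
from medfed.demo.generator import GeneratorConfig, generate_raw_dataset
from medfed.errors import (
    IntegrityError,
    NotFoundError,
    StateError,
    TransportDisabledError,
    ValidationError,
)
from medfed.privacy import PNG_MAGIC
from medfed.transport import TransportSpy


@pytest.fixture()
def spy_client(tmp_path, transports):
    spy = TransportSpy(transports["data_owner"])
    return Client(tmp_path / "ws", spy), spy


@pytest.fixture()
def mo_client(tmp_path, transports):
    return Client(tmp_path / "mo_ws", transports["model_owner"])


# -- fetch and verify ---------------------------------------------------------


def test_fetch_and_verify_intact_cube(spy_client, registered_benchmark):
    client, _ = spy_client
    cube = client.fetch_and_verify_cube(registered_benchmark["prep_cube_id"])
    assert cube.manifest.kind is CubeKind.DATA_PREP
    assert (cube.cube_dir / "run.py").is_file()


def test_fetch_refuses_post_registration_tampering(
    spy_client, registered_benchmark, demo_cube_dirs
):
    client, _ = spy_client
    source = demo_cube_dirs[CubeKind.MODEL]
    run_py = source / "run.py"
    original = run_py.read_bytes()
    try:
        run_py.write_bytes(original + b"\n# altered after registration\n")
        with pytest.raises(IntegrityError):
            client.fetch_and_verify_cube(registered_benchmark["reference_model_cube_id"])
        cache = client.workspace / "cubes" / registered_benchmark["reference_model_cube_id"]
        assert not cache.exists()  # unusable cube is not cached
    finally:
        run_py.write_bytes(original)


def test_fetch_unknown_cube(spy_client):
    client, _ = spy_client
    with pytest.raises(NotFoundError):
        client.fetch_and_verify_cube("9999")


# -- staged preparation -------------------------------------------------------


def test_prepare_dataset_full_pipeline(spy_client, registered_benchmark, raw_dataset):
    client, _ = spy_client
    prep = client.fetch_and_verify_cube(registered_benchmark["prep_cube_id"])
    state = client.prepare_dataset(
        prep, raw_dataset, raw_dataset / "labels", "ds1",
        registered_benchmark["benchmark"]["id"],
    )
    assert state.prepared and state.sanity_ok and state.statistics_done
    assert state.statistics["n_cases"] == 6
    assert state.manifest_digest


def test_prepare_halts_at_sanity_failure(spy_client, registered_benchmark, raw_dataset, tmp_path):
    """A non-binary mask stops the pipeline: sanity_ok=False and
    statistics are never computed (stage monotonicity)."""
    import numpy as np
    from PIL import Image

    broken = tmp_path / "broken_raw"
    shutil.copytree(raw_dataset, broken)
    victim = next((broken / "labels").glob("*.png"))
    arr = np.asarray(Image.open(victim)).copy()
    arr[3, 3] = 119
    Image.fromarray(arr, "L").save(victim)

    client, _ = spy_client
    prep = client.fetch_and_verify_cube(registered_benchmark["prep_cube_id"])
    state = client.prepare_dataset(
        prep, broken, broken / "labels", "ds-broken",
        registered_benchmark["benchmark"]["id"],
    )
    assert state.prepared is True
    assert state.sanity_ok is False
    assert state.statistics_done is False
    assert state.statistics == {}
    assert any("non-binary" in f for f in state.sanity_report["findings"])


def test_prepare_fails_on_empty_raw_dir(spy_client, registered_benchmark, tmp_path):
    empty = tmp_path / "empty"
    (empty / "labels").mkdir(parents=True)
    client, _ = spy_client
    prep = client.fetch_and_verify_cube(registered_benchmark["prep_cube_id"])
    state = client.prepare_dataset(
        prep, empty, empty / "labels", "ds-empty",
        registered_benchmark["benchmark"]["id"],
    )
    assert not state.prepared and "prepare" in state.failure


# -- consent-gated registration ----------------------------------------------


def test_register_without_consent_makes_no_server_call(
    spy_client, registered_benchmark, raw_dataset
):
    client, spy = spy_client
    prep = client.fetch_and_verify_cube(registered_benchmark["prep_cube_id"])
    state = client.prepare_dataset(
        prep, raw_dataset, raw_dataset / "labels", "ds2",
        registered_benchmark["benchmark"]["id"],
    )
    calls_before = len(spy.calls)
    assert client.register_prepared_dataset(state, prep, consent=False) is None
    assert len(spy.calls) == calls_before  # transport spy saw nothing

    dataset_id = client.register_prepared_dataset(state, prep, consent=True)
    assert dataset_id is not None
    payload = spy.calls[-1].body_bytes
    assert PNG_MAGIC not in payload
    assert len(payload) < 10 * 1024


def test_register_unprepared_dataset_is_a_state_error(spy_client, registered_benchmark):
    from medfed.client import PreparedDataset

    client, _ = spy_client
    state = PreparedDataset(
        local_root=client.workspace, benchmark_id="1", name="nope"
    )
    with pytest.raises(StateError):
        client.register_prepared_dataset(state, None, consent=True)


# -- compatibility test -------------------------------------------------------


@pytest.fixture()
def benchmark_cubes(mo_client, registered_benchmark):
    return {
        "prep": mo_client.fetch_and_verify_cube(registered_benchmark["prep_cube_id"]),
        "model": mo_client.fetch_and_verify_cube(
            registered_benchmark["reference_model_cube_id"]
        ),
        "metrics": mo_client.fetch_and_verify_cube(registered_benchmark["metrics_cube_id"]),
    }


def test_reference_model_passes_compatibility(mo_client, registered_benchmark, benchmark_cubes):
    report = mo_client.run_compatibility_test(
        registered_benchmark["benchmark"],
        benchmark_cubes["prep"], benchmark_cubes["model"], benchmark_cubes["metrics"],
    )
    assert report["pass"] is True
    assert report["metric_names"] == ["dice", "iou", "sensitivity", "specificity"]
    assert report["stages"]["prediction_schema"] == "pass"


def test_wrong_shape_model_fails_at_schema_stage(
    mo_client, registered_benchmark, benchmark_cubes, tmp_path
):
    bad_dir = tmp_path / "bad_cube"
    build_incompatible_model_cube(bad_dir)
    record = mo_client.submit_cube_from_dir(bad_dir)
    bad_cube = mo_client.fetch_and_verify_cube(record["id"])
    report = mo_client.run_compatibility_test(
        registered_benchmark["benchmark"],
        benchmark_cubes["prep"], bad_cube, benchmark_cubes["metrics"],
    )
    assert report["pass"] is False
    assert report["failed_stage"] == "prediction_schema"
    with pytest.raises(ValidationError, match="association not requested"):
        mo_client.associate(
            "MODEL_BENCHMARK", record["id"],
            registered_benchmark["benchmark"]["id"], report,
        )


def test_demo_data_digest_gate(mo_client, registered_benchmark, benchmark_cubes, raw_dataset):
    tampered = dict(registered_benchmark["benchmark"])
    tampered["demo_dataset_digest"] = "0" * 64
    with pytest.raises(IntegrityError, match="demo dataset"):
        mo_client.run_compatibility_test(
            tampered, benchmark_cubes["prep"], benchmark_cubes["model"],
            benchmark_cubes["metrics"],
        )


# -- execution (offline) ------------------------------------------------------


@pytest.fixture()
def approved_setup(server, accounts, spy_client, registered_benchmark, raw_dataset):
    """Dataset prepared+registered+associated and the reference model
    associated — everything approved, ready for execution."""
    client, spy = spy_client
    benchmark = registered_benchmark["benchmark"]
    prep = client.fetch_and_verify_cube(registered_benchmark["prep_cube_id"])
    state = client.prepare_dataset(
        prep, raw_dataset, raw_dataset / "labels", "ds-exec", benchmark["id"]
    )
    dataset_id = client.register_prepared_dataset(state, prep, consent=True)
    assoc = client.associate(
        "DATASET_BENCHMARK", dataset_id, benchmark["id"],
        {"pass": True, "stages": {"prepare": "pass"}},
    )
    server.set_association_approval(accounts["committee"]["token"], assoc["id"], "APPROVED")

    model_assoc = server.request_association(
        accounts["committee"]["token"], "MODEL_BENCHMARK",
        registered_benchmark["reference_model_cube_id"], benchmark["id"],
        {"pass": True},
    )
    server.set_association_approval(
        accounts["committee"]["token"], model_assoc["id"], "APPROVED"
    )
    model = client.fetch_and_verify_cube(registered_benchmark["reference_model_cube_id"])
    metrics = client.fetch_and_verify_cube(registered_benchmark["metrics_cube_id"])
    return client, spy, benchmark, state, model, metrics


def test_execute_benchmark_is_fully_offline(approved_setup):
    """Execution succeeds with the transport disabled: the workload needs
    no network; results appear locally, unapproved."""
    client, spy, benchmark, state, model, metrics = approved_setup
    spy.enabled = False
    try:
        results = client.execute_benchmark(benchmark, state, [model], metrics)
    finally:
        spy.enabled = True
    assert len(results) == 1 and results[0].success
    assert results[0].owner_approved is False
    aggregate = json.loads(results[0].results_path.read_text())["aggregate"]
    assert aggregate["dice"] == 1.0  # noise-free fixture, threshold model

    # and a disabled transport really refuses traffic
    spy.enabled = False
    with pytest.raises(TransportDisabledError):
        spy.request("GET", "/benchmarks")
    spy.enabled = True


def test_model_failures_are_isolated(approved_setup, mo_client, tmp_path):
    """A crashing candidate does not block the other models in the run."""
    client, spy, benchmark, state, model, metrics = approved_setup
    crash_dir = tmp_path / "crash_cube"
    write_cube(crash_dir, "crasher", CubeKind.MODEL, {"threshold": 7.0})  # invalid θ
    crash_record = mo_client.submit_cube_from_dir(crash_dir)
    crash = client.fetch_and_verify_cube(crash_record["id"])

    results = client.execute_benchmark(benchmark, state, [crash, model], metrics)
    assert [r.success for r in results] == [False, True]
    assert "infer" in results[0].failure
    assert results[1].results_path is not None


def test_execute_requires_sane_dataset(approved_setup):
    client, spy, benchmark, state, model, metrics = approved_setup
    state.sanity_ok = False
    with pytest.raises(StateError):
        client.execute_benchmark(benchmark, state, [model], metrics)


# -- result approval and upload ----------------------------------------------


def test_result_upload_requires_owner_approval(approved_setup):
    client, spy, benchmark, state, model, metrics = approved_setup
    [result] = client.execute_benchmark(benchmark, state, [model], metrics)

    calls_before = len(spy.calls)
    assert client.approve_and_submit_result(result, approve=False) is None
    assert len(spy.calls) == calls_before  # nothing left the machine

    result_id = client.approve_and_submit_result(result, approve=True)
    assert result_id is not None
    payload = json.loads(spy.calls[-1].body_bytes)
    assert PNG_MAGIC.decode("latin-1") not in spy.calls[-1].body_bytes.decode()
    assert set(payload["metrics"]) == {"dice", "iou", "sensitivity", "specificity"}
    # per-case ids are opaque hashes, not raw case identifiers
    assert all(not row["case"].startswith("fix_case") for row in payload["per_case"])


def test_failed_result_cannot_be_submitted(approved_setup):
    client, spy, benchmark, state, model, metrics = approved_setup
    from medfed.client import LocalResult

    failed = LocalResult(
        benchmark_id=benchmark["id"], model_cube_id="1", dataset=state,
        results_path=None, fingerprint={}, success=False,
    )
    with pytest.raises(StateError):
        client.approve_and_submit_result(failed, approve=True)
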