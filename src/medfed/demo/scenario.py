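"""Scripted end-to-end federation scenario on the synthetic benchmark.

One call exercises every workflow of the platform against a single
server: committee setup, cube + benchmark submission, admin approval, a
model owner running the compatibility test (one passing candidate, one
deliberately schema-incompatible candidate that is refused locally),
multiple data owners preparing, registering and associating seeded
site datasets, fully offline benchmark execution, owner-approved result
upload, and result listing.

Every client→server call travels through one shared transport spy, so the
scenario summary can report — from observation, not assumption — how many
bytes left the sites, whether any payload carried image bytes, and that
the execution window was network-silent.
"""

from __future__ import annotations

import time
from pathlib import Path

from ..client import Client
from ..cubes import CubeKind
from ..errors import AuthorizationError, ValidationError
from ..hashing import sha256_file, sha256_tree
from ..privacy import PNG_MAGIC
from ..registry import ApprovalStatus, Role
from ..server import CoordinationServer
from ..transport import InProcessTransport, SpyCall, TransportSpy
from .cubebuild import build_demo_cubes, build_incompatible_model_cube, write_cube
from .generator import GeneratorConfig, generate_raw_dataset


def site_config(seed: int, site_index: int, n_cases: int = 20) -> GeneratorConfig:
    """Per-site generator settings: same task, site-specific statistics.

    Sites differ in acquisition noise and background level, emulating
    scanner/protocol variation across institutions, while the lesion
    geometry and 64×64 grid stay benchmark-wide.
    """
    return GeneratorConfig(
        n_cases=n_cases,
        noise_sigma=0.05 + 0.05 * site_index,
        background_level=0.08 + 0.02 * site_index,
        site_id=f"site{site_index}",
        seed=seed * 1000 + site_index,
    )


def run_demo_scenario(
    seed: int,
    sites: int = 3,
    workdir: Path | str = "demo_workspace",
    n_cases: int = 20,
) -> dict:
    """Run the full scripted scenario; returns a summary of observed state."""
    start = time.perf_counter()
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)

    server = CoordinationServer(db_path=workdir / "server.db")
    admin = server.bootstrap_admin("platform-admin")

    shared_calls: list[SpyCall] = []

    def make_transport(token: str) -> TransportSpy:
        return TransportSpy(InProcessTransport(server, token), calls=shared_calls)

    admin_t = make_transport(admin["token"])
    committee = admin_t.request(
        "POST", "/accounts", {"name": "benchmark-committee", "roles": [Role.BENCHMARK_COMMITTEE.value]}
    )
    model_owner = admin_t.request(
        "POST", "/accounts", {"name": "model-owner", "roles": [Role.MODEL_OWNER.value]}
    )
    data_owners = [
        admin_t.request(
            "POST", "/accounts", {"name": f"hospital-{i}", "roles": [Role.DATA_OWNER.value]}
        )
        for i in range(sites)
    ]

    # --- committee: reference cubes, demo data, benchmark submission -------
    committee_client = Client(workdir / "committee_ws", make_transport(committee["token"]))
    cube_dirs = build_demo_cubes(workdir / "assets" / "cubes")
    demo_dir = workdir / "assets" / "demo_data"
    generate_raw_dataset(
        GeneratorConfig(n_cases=n_cases, site_id="demo", seed=seed * 1000 + 999),
        demo_dir,
    )
    prep_rec = committee_client.submit_cube_from_dir(cube_dirs[CubeKind.DATA_PREP])
    refmodel_rec = committee_client.submit_cube_from_dir(cube_dirs[CubeKind.MODEL])
    metrics_rec = committee_client.submit_cube_from_dir(cube_dirs[CubeKind.METRICS])
    benchmark = committee_client.transport.request(
        "POST",
        "/benchmarks",
        {
            "name": "synthetic-lesion-segmentation",
            "specification": "binary lesion segmentation on 64x64 greyscale imagery; "
            "metrics: dice, iou, sensitivity, specificity",
            "data_prep_cube_id": prep_rec["id"],
            "reference_model_cube_id": refmodel_rec["id"],
            "metrics_cube_id": metrics_rec["id"],
            "demo_dataset_locator": str(demo_dir.resolve()),
            "demo_dataset_digest": sha256_tree(demo_dir),
        },
    )

    # a data owner jumping the queue is rejected (and audited as such)
    premature_approvals = 0
    try:
        make_transport(data_owners[0]["token"]).request(
            "PUT", f"/benchmarks/{benchmark['id']}/approval", {"decision": "APPROVED"}
        )
    except AuthorizationError:
        premature_approvals = 1

    admin_t.request(
        "PUT", f"/benchmarks/{benchmark['id']}/approval", {"decision": "APPROVED"}
    )
    benchmark = committee_client.transport.request("GET", f"/benchmarks/{benchmark['id']}")

    # --- model owner: candidates + compatibility test ----------------------
    mo_client = Client(workdir / "model_owner_ws", make_transport(model_owner["token"]))
    good_dir = workdir / "assets" / "candidate_good"
    bad_dir = workdir / "assets" / "candidate_bad"
    write_cube(good_dir, "candidate-threshold-model", CubeKind.MODEL, {"threshold": 0.5})
    build_incompatible_model_cube(bad_dir)
    good_rec = mo_client.submit_cube_from_dir(good_dir)
    bad_rec = mo_client.submit_cube_from_dir(bad_dir)

    prep_cube = mo_client.fetch_and_verify_cube(prep_rec["id"])
    metrics_cube = mo_client.fetch_and_verify_cube(metrics_rec["id"])
    good_cube = mo_client.fetch_and_verify_cube(good_rec["id"])
    bad_cube = mo_client.fetch_and_verify_cube(bad_rec["id"])

    good_report = mo_client.run_compatibility_test(
        benchmark, prep_cube, good_cube, metrics_cube
    )
    assoc = mo_client.associate(
        "MODEL_BENCHMARK", good_rec["id"], benchmark["id"], good_report
    )
    committee_client.transport.request(
        "PUT", f"/associations/{assoc['id']}/approval", {"decision": "APPROVED"}
    )

    bad_report = mo_client.run_compatibility_test(
        benchmark, prep_cube, bad_cube, metrics_cube
    )
    rejected_candidates = 0
    try:
        mo_client.associate("MODEL_BENCHMARK", bad_rec["id"], benchmark["id"], bad_report)
    except ValidationError:
        rejected_candidates = 1

    # --- data owners: prepare, register, associate, execute, submit --------
    result_ids: list[str] = []
    dice_per_site: dict[str, float] = {}
    results_digests: dict[str, str] = {}
    raw_digests: dict[str, str] = {}
    offline_calls = 0

    for i, owner in enumerate(data_owners):
        spy = make_transport(owner["token"])
        client = Client(workdir / f"owner{i}_ws", spy)
        raw_dir = workdir / "assets" / f"raw_site{i}"
        config = site_config(seed, i, n_cases=n_cases)
        generate_raw_dataset(config, raw_dir)
        raw_digests[config.site_id] = sha256_tree(raw_dir)

        own_prep = client.fetch_and_verify_cube(prep_rec["id"])
        prepared = client.prepare_dataset(
            own_prep, raw_dir, raw_dir / "labels", f"dataset-{config.site_id}", benchmark["id"]
        )
        assert prepared.statistics_done, prepared.failure
        dataset_id = client.register_prepared_dataset(prepared, own_prep, consent=True)
        ds_report = {
            "pass": prepared.sanity_ok and prepared.statistics_done,
            "stages": {"prepare": "pass", "sanity_check": "pass", "statistics": "pass"},
        }
        ds_assoc = client.associate(
            "DATASET_BENCHMARK", dataset_id, benchmark["id"], ds_report
        )
        committee_client.transport.request(
            "PUT", f"/associations/{ds_assoc['id']}/approval", {"decision": "APPROVED"}
        )

        approved_models = spy.request("GET", f"/benchmarks/{benchmark['id']}/models")
        model_cubes = [client.fetch_and_verify_cube(a["subject_id"]) for a in approved_models]
        own_metrics = client.fetch_and_verify_cube(metrics_rec["id"])

        # execution is offline by contract: unplug the transport and count
        calls_before = len(shared_calls)
        spy.enabled = False
        local_results = client.execute_benchmark(
            benchmark, prepared, model_cubes, own_metrics
        )
        spy.enabled = True
        offline_calls += len(shared_calls) - calls_before

        for local in local_results:
            assert local.success, local.failure
            results_digests[config.site_id] = sha256_file(local.results_path)
            import json as _json

            aggregate = _json.loads(Path(local.results_path).read_text())["aggregate"]
            dice_per_site[config.site_id] = aggregate["dice"]
            result_ids.append(client.approve_and_submit_result(local, approve=True))

    # --- final state -------------------------------------------------------
    committee_results = committee_client.transport.request(
        "GET", f"/benchmarks/{benchmark['id']}/results"
    )
    model_assocs = committee_client.transport.request(
        "GET", f"/benchmarks/{benchmark['id']}/models"
    )
    dataset_assocs = committee_client.transport.request(
        "GET", f"/benchmarks/{benchmark['id']}/datasets"
    )
    audit = admin_t.request("GET", "/audit")
    benchmarks_listed = admin_t.request("GET", "/benchmarks")

    mutating = [c for c in shared_calls if c.method in ("POST", "PUT")]
    png_payloads = sum(1 for c in shared_calls if PNG_MAGIC in c.body_bytes)
    dataset_payload_sizes = [
        len(c.body_bytes) for c in shared_calls if c.path == "/datasets"
    ]
    seqs = [e["sequence_number"] for e in audit]

    return {
        "seed": seed,
        "sites": sites,
        "n_cases": n_cases,
        "benchmark_id": benchmark["id"],
        "approved_benchmarks": sum(
            1 for b in benchmarks_listed if b["approval"] == ApprovalStatus.APPROVED.value
        ),
        "approved_model_associations": len(model_assocs),
        "rejected_model_candidates": rejected_candidates,
        "approved_dataset_associations": len(dataset_assocs),
        "result_records": len(committee_results),
        "result_ids": result_ids,
        "premature_approval_rejections": premature_approvals,
        "dice_per_site": dice_per_site,
        "mean_dice": sum(dice_per_site.values()) / max(len(dice_per_site), 1),
        "uploaded_bytes": sum(len(c.body_bytes) for c in shared_calls),
        "png_payloads": png_payloads,
        "max_dataset_payload_bytes": max(dataset_payload_sizes, default=0),
        "mutating_calls": len(mutating),
        "audit_events": len(audit),
        "audit_gap_free": seqs == list(range(1, len(seqs) + 1)),
        "offline_calls_during_execution": offline_calls,
        "raw_dataset_digests": raw_digests,
        "results_digests": results_digests,
        "elapsed_seconds": time.perf_counter() - start,
    }
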