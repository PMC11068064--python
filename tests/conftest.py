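"""Shared fixtures: an in-memory server with seeded accounts, demo cube
directories, and synthetic raw datasets — everything generated at test
time, nothing stored in the repository."""

from __future__ import annotations

import pytest

from medfed.cubes import CubeKind
from medfed.demo.cubebuild import build_demo_cubes
from medfed.demo.generator import GeneratorConfig, generate_raw_dataset
from medfed.hashing import sha256_tree
from medfed.registry import Role
from medfed.server import CoordinationServer
from medfed.transport import InProcessTransport


@pytest.fixture()
def server():
    return CoordinationServer(db_path=":memory:")


@pytest.fixture()
def accounts(server):
    """Bootstrap admin plus one account per non-admin role; returns tokens."""
    admin = server.bootstrap_admin("platform-admin")
    committee = server.create_account(
        admin["token"], "committee", [Role.BENCHMARK_COMMITTEE.value]
    )
    model_owner = server.create_account(
        admin["token"], "model-owner", [Role.MODEL_OWNER.value]
    )
    data_owner = server.create_account(
        admin["token"], "hospital-a", [Role.DATA_OWNER.value]
    )
    # token lives alongside each account dict (create_account returns it)
    return {
        "admin": admin,
        "committee": committee,
        "model_owner": model_owner,
        "data_owner": data_owner,
    }


@pytest.fixture()
def transports(server, accounts):
    return {
        name: InProcessTransport(server, account["token"])
        for name, account in accounts.items()
    }


@pytest.fixture(scope="session")
def demo_cube_dirs(tmp_path_factory):
    """The three reference cube directories (session-scoped, read-only)."""
    return build_demo_cubes(tmp_path_factory.mktemp("cubes"))


@pytest.fixture(scope="session")
def raw_dataset(tmp_path_factory):
    """A small noise-free raw dataset: deterministic, 6 cases, 64x64."""
    out = tmp_path_factory.mktemp("raw") / "data"
    config = GeneratorConfig(n_cases=6, noise_sigma=0.0, site_id="fix", seed=7)
    generate_raw_dataset(config, out)
    return out


@pytest.fixture()
def registered_benchmark(server, accounts, transports, demo_cube_dirs, raw_dataset):
    """Cubes + benchmark registered and admin-approved; returns ids."""
    from medfed.client import Client

    committee_client = Client(
        raw_dataset.parent / "committee_ws", transports["committee"]
    )
    prep = committee_client.submit_cube_from_dir(demo_cube_dirs[CubeKind.DATA_PREP])
    refmodel = committee_client.submit_cube_from_dir(demo_cube_dirs[CubeKind.MODEL])
    metrics = committee_client.submit_cube_from_dir(demo_cube_dirs[CubeKind.METRICS])
    benchmark = server.submit_benchmark(
        accounts["committee"]["token"],
        {
            "name": "fixture-benchmark",
            "data_prep_cube_id": prep["id"],
            "reference_model_cube_id": refmodel["id"],
            "metrics_cube_id": metrics["id"],
            "demo_dataset_locator": str(raw_dataset),
            "demo_dataset_digest": sha256_tree(raw_dataset),
        },
    )
    server.set_benchmark_approval(accounts["admin"]["token"], benchmark["id"], "APPROVED")
    return {
        "benchmark": server.get_benchmark(accounts["committee"]["token"], benchmark["id"]),
        "prep_cube_id": prep["id"],
        "reference_model_cube_id": refmodel["id"],
        "metrics_cube_id": metrics["id"],
    }
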