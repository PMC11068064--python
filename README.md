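# medfed — federated evaluation of medical-AI models, at desk scale

Evaluating a medical-AI model on data from many institutions usually
founders on the data: hospitals cannot ship patient imagery to a central
benchmark. **medfed** inverts the flow — *the model travels to the data*.
Benchmark code is packaged into digest-pinned, portable task units
("cubes"), executed locally by each data owner, and only owner-approved
aggregate metrics ever reach the coordination server. The package is a
complete, self-contained implementation of that platform for researchers
who want to study, teach or prototype federated *evaluation* (as opposed
to federated training):

* a **coordination server** — a registry of users, cubes, benchmarks,
  datasets, associations and results, with role-based permissions, an
  approval-gated workflow state machine, and an append-only audit trail.
  It stores metadata only: no code assets, no pixels, ever.
* an **orchestration client** — fetches and digest-verifies cubes,
  runs the preparation pipeline (prepare → sanity check → statistics),
  runs compatibility tests, executes benchmarks fully offline, and
  uploads results only after explicit owner approval.
* a **cube contract** — `cube.yaml` manifests with SHA-256-pinned
  assets, fixed task interfaces per cube kind (data preparation:
  `prepare`/`sanity_check`/`statistics`; model: `infer`; metrics:
  `evaluate`), and a sandboxed local runner that refuses tampered code
  and checks that tasks write only where declared.
* a **synthetic lesion-segmentation benchmark** — a seeded generator of
  multi-site 8-bit greyscale imagery with binary masks, a threshold
  reference model, and an overlap-metrics evaluator, so the entire
  system runs end-to-end with no external data.

## The quantities at the core

For a predicted mask *P* and truth mask *T* on the same pixel grid, the
evaluator reports per case and as dataset means:

    Dice = 2|P∩T| / (|P|+|T|)        IoU  = |P∩T| / |P∪T|
    sensitivity = |P∩T| / |T|        specificity = |¬P∩¬T| / |¬T|

with the degenerate conventions documented in `docs/methods.md`
(both-empty ⇒ 1, etc.), and the algebraic identity Dice = 2·IoU/(1+IoU)
holding exactly.

Just as central are the platform's *invariants*, which the test suite
treats as first-class results: results are accepted only when both the
dataset–benchmark and model–benchmark associations are APPROVED; a
pending benchmark is invisible to non-committee users; every mutating
API call (accepted or rejected) appends exactly one gap-free audit
event; no payload reaching the server contains image bytes or exceeds
the 10 KB statistics budget; and a single flipped byte in any cube asset
makes the client refuse to run it.

## Worked example

One command runs a whole federation — committee setup, benchmark
registration and admin approval, a model owner whose passing candidate
is associated (and whose mis-shaped candidate is refused by the
compatibility test), three hospitals with site-specific noise levels
preparing and registering data, offline execution, and approved result
upload:

```bash
medfed demo e2e --seed 1 --sites 3
```

Key lines of the printed summary (seed 1):

```
"approved_benchmarks": 1,
"approved_model_associations": 1,
"rejected_model_candidates": 1,
"approved_dataset_associations": 3,
"result_records": 3,
"dice_per_site": {"site0": 1.0, "site1": 0.99972, "site2": 0.90887},
"uploaded_bytes": 12789,
"png_payloads": 0,
"mutating_calls": 27,
"audit_events": 27,
"offline_calls_during_execution": 0
```

Reading it: the federation converged to one approved benchmark with one
approved model and three approved site datasets; the threshold model's
Dice degrades as site noise grows (site0 σ=0.05 … site2 σ=0.15); the
three sites together uploaded ~11 KB of pure metadata — zero image
payloads — and every one of the 27 state-changing calls is mirrored by
exactly one audit event, with no network traffic at all during model
execution.

The same workflows are available as individual commands (`medfed cube
submit`, `medfed benchmark submit|approve`, `medfed dataset
prepare|register|associate`, `medfed model associate`, `medfed run
execute|submit-result`, `medfed server serve`) or as library calls
(`medfed.Client`, `medfed.CoordinationServer`).

## Layout

```
src/medfed/
  registry.py    roles, approval lifecycle, permission matrix
  server.py      coordination server (sqlite persistence, audit trail)
  httpapi.py     HTTP binding; transport.py  in-process binding + spy
  cubes.py       manifest schema, digest verification, sandboxed runner
  client.py      owner workflows (fetch/verify, prepare, associate, run)
  demo/          synthetic benchmark: generator, tasks, metrics, scenario
  cli.py         command-line surface; config.py  configuration/logging
docs/methods.md  models, conventions, parameters, limitations
```
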