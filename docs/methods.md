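# Methods

## The system model

medfed implements *federated evaluation*: trained models are delivered
to data-owning sites as portable, digest-pinned code units and executed
there; the coordinating server receives only registry metadata,
aggregate dataset statistics (with explicit consent) and owner-approved
metric payloads. The design goal is that a reviewer can verify, from the
artifacts alone, three properties: the right code ran (integrity), only
metadata moved (privacy), and every step is attributable (auditability).

The platform has three parts. The **server** persists accounts, cube
registrations (locators + SHA-256 digests, never code), benchmark
bundles, dataset registrations (aggregate statistics + a digest of the
prepared manifest, never a data locator), approval-gated associations,
results and the audit trail, in a single-file sqlite database with
schema creation on startup. The **client** mediates every workflow over
a transport abstraction: an in-process binding (used by tests and the
scripted scenario — requests still round-trip through JSON so nothing
unserializable can sneak through) and an HTTP+JSON binding on the
standard library. A transport spy can wrap either to observe, byte for
byte, what would leave the site, and can be disabled outright to prove
an operation needs no network. The **cube contract** fixes three cube
kinds with frozen task interfaces — data preparation
(`prepare`, `sanity_check`, `statistics`), model (`infer`), metrics
(`evaluate`) — and a local-process runner. A container-engine backend
would present the identical interface; the local backend keeps the
whole system runnable on one CPU with no daemon, which is the scale
this package targets.

## Roles, permissions and the workflow state machine

Four roles exist: platform admin, benchmark committee, data owner,
model owner; an account holds a non-empty *set* of roles, since one
organization may occupy several. Authorization is a pure, total
function of (role set, action, static resource facts) with deny by
default. Two deliberate choices:

* **Admin approval is always required for benchmarks**, including a
  committee's own submission. Whether a committee may self-approve is
  genuinely open; requiring the admin makes the four-eyes property
  unconditional.
* **Committees may request model associations for cubes they own** (the
  reference model is a benchmark asset); other model associations
  require the model-owner role, and every association request requires
  subject ownership.

Approval states form an acyclic machine: PENDING → APPROVED or
REJECTED, both terminal. There is no revocation; the audit trail stays
append-only, and a rejected association may simply be re-requested
(uniqueness is enforced only among non-rejected associations).

Results are gated by the conjunction *both associations APPROVED*,
re-checked server-side against the association table at submission
time, plus finiteness of every metric value.

## Privacy guards

The server's stance — no patient data, ever — is operationalized as
concrete payload rules, enforced server-side and mirrored client-side:

* any value carrying PNG content (raw signature bytes, or a base64
  prefix decoding to the signature) is rejected;
* any string over 2 048 characters is rejected (blob smuggling guard);
* dataset statistics must be a flat map of scalars/short strings —
  aggregates only, no per-case arrays — serializing to ≤ 10 KB;
* per-case metric tables in results are capped at 1 000 rows and use
  opaque hashed case identifiers;
* dataset registrations accept no locator field at all: the server
  never learns where data lives.

The thresholds (2 048 chars, 10 KB, 1 000 rows) are this package's
choices; generous for honest metadata, far too small for imagery.

## Audit trail

Every mutating call — accepted *or rejected* — appends exactly one
event with a strictly consecutive sequence number; reads append
nothing. The one exception is initial admin bootstrap, which is
deployment-time provisioning before the platform is in service.
Benchmark-scoped trails are visible to the owning committee; the global
trail is admin-only.

## The cube runner

`run_task` refuses to start unless every pinned asset matches its
SHA-256 digest (verification is re-run on every invocation; it is
cheap at this scale). The task runs as a subprocess in a scratch
directory, with proxy/network environment stripped and bindings passed
as explicit `--in:`/`--out:` arguments. Afterwards the runner re-hashes
the input bindings and cube assets — any modification fails the run as
a contract violation — and checks that every declared output exists and
is non-empty. Logs are kept locally next to the run and are never
upload-eligible; only the evaluator's results file is.

Determinism is whole-pipeline: identical cube, inputs and parameters
give byte-identical output trees (the PNG encoder and JSON writers are
deterministic), which is what makes execution fingerprintable.

## The compatibility test

The claim "this model is compatible with this benchmark" is made
concrete as: on the benchmark's digest-verified public demo data,
prepare → sanity-check → infer all succeed; predictions exist one per
case, binary, with the prepared grid shape; evaluation succeeds and
emits finite values for exactly the declared metric names (declared in
the metrics cube's digest-pinned `parameters.yaml`). A failing stage is
named in the report, and the client refuses to even request an
association with a failing report — the server independently refuses
one as well.

## The synthetic benchmark

The generator emulates the raw data a site would hold: per case, 1–3
filled disks (radius 3–8 px) of foreground intensity 0.9 on background
0.1, Gaussian noise of standard deviation σ added, clipped to [0, 1]
and quantized to 8 bits, over a 64×64 grid; binary masks are stored as
0/255 PNGs with a CSV case manifest. Defaults: 20 cases per site,
σ = 0.05; the scripted scenario gives site *i* σ = 0.05 + 0.05·i and a
slightly shifted background level, emulating scanner and protocol
variation across institutions. One seeded generator per dataset is
consumed in case order, so determinism is a whole-dataset property
(case *k* is not reproducible independently of `n_cases`).

Preparation resizes to the benchmark grid (bilinear for images,
nearest-neighbour for masks, so masks keep their exact values), then
min-max rescales each image to [0, 1] and re-quantizes. Masks pass
through preparation untouched: a non-binary mask is deliberately *not*
repaired, because detecting it is the sanity check's job. With σ = 0 the
two levels quantize to exactly 26 and 230, min-max rescaling maps them
to exactly 0 and 255, and the reference model — predict foreground
where intensity > θ, default θ = 0.5 — recovers every mask exactly;
this is the package's strongest end-to-end correctness probe, because
any pixel disturbed anywhere in the pipeline breaks exact recovery.

Metric conventions (no universal standard exists, so they are fixed
here): both masks empty ⇒ Dice = IoU = sensitivity = 1; empty truth
with non-empty prediction ⇒ sensitivity = 1, Dice = IoU = 0; all-truth
grid ⇒ specificity = 1. All outputs lie in [0, 1] and
Dice = 2·IoU/(1+IoU) holds identically. The evaluator is validated
against a brute-force pixel-enumeration oracle written independently of
the vectorized implementation.

**What the synthetic data does not show.** Disks on a flat background
with Gaussian noise exercise the *platform* — formats, digests,
approvals, privacy, determinism — not segmentation difficulty. Passing
tests demonstrate nothing about model quality on real anatomy,
multi-class tasks, volumetric formats (DICOM/NIfTI) or realistic label
noise; those are out of scope by design.

## Problem sizes and numerical choices

The scripted scenario uses 3 sites × 20 cases at 64×64 with one passing
and one schema-incompatible candidate model; the acceptance script runs
it twice (byte-level determinism check) plus a 50-corruption integrity
sweep, a 200-pair metrics-oracle comparison (tolerance 1e-12), and a
10-case noise-free recovery check — a few seconds in total, chosen so
the whole evidence chain is cheap to re-run. Digests are SHA-256
throughout. Identifiers are server-assigned increasing integers
rendered as opaque strings. Metric aggregation is the arithmetic mean
over cases. 8-bit quantization uses round-half-even (numpy's `rint`).

## Known limitations

Single server, no horizontal scaling or federation of servers; bearer
tokens without expiry, no OAuth/SSO; no container-image building or
registry authentication; no GPU passthrough; no differential privacy,
homomorphic encryption or trusted-execution attestation — the runner's
sandbox is observational (post-hoc filesystem verification), not an OS
enforcement boundary; result records are append-only with no
retraction; data owners' "review for safety" is an explicit approval
boolean with manifests and logs presented, not an automated scan.
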