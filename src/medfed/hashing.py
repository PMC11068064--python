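"""SHA-256 digest helpers used for asset pinning and fingerprints."""

from __future__ import annotations

import hashlib
import re
from pathlib import Path

DIGEST_RE = re.compile(r"^[0-9a-f]{64}$")


def is_digest(value: object) -> bool:
    return isinstance(value, str) and bool(DIGEST_RE.match(value))


def sha256_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def sha256_file(path: Path | str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_tree(root: Path | str) -> str:
    """Digest of a directory: hash of sorted (relative path, file hash) pairs.

    Stable across machines; changes if any file is added, removed, renamed
    or modified anywhere under ``root``.
    """
    root = Path(root)
    h = hashlib.sha256()
    for path in sorted(p for p in root.rglob("*") if p.is_file()):
        rel = path.relative_to(root).as_posix()
        h.update(rel.encode())
        h.update(b"\0")
        h.update(bytes.fromhex(sha256_file(path)))
        h.update(b"\0")
    return h.hexdigest()
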