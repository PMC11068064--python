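"""Metadata-only upload guards.

The platform's core privacy stance is that raw data never leaves a site:
the server stores registry metadata, aggregate statistics and metric
values — never pixels, never code payloads.  These guards operationalize
that stance at the server boundary (and symmetrically in the client, which
refuses to build an offending payload in the first place).

Concretely a payload is rejected when any value

* is raw bytes, or a string embedding a PNG signature (raw or base64);
* is a string long enough to smuggle a blob (``MAX_STRING_CHARS``);
* (for dataset statistics) is a nested container — statistics must be a
  flat map of scalars/short strings — or the serialized map exceeds
  ``MAX_STATISTICS_BYTES``.
"""

from __future__ import annotations

import base64
import binascii
import json
import math
from typing import Any, Mapping

from .errors import PrivacyError, ValidationError

PNG_MAGIC = b"\x89PNG\r\n\x1a\n"
#: base64 of the 8-byte PNG signature is determined by its first 6 bytes,
#: so any base64-encoded PNG starts with these 8 characters.
PNG_MAGIC_B64_PREFIX = base64.b64encode(PNG_MAGIC)[:8].decode("ascii")

MAX_STRING_CHARS = 2048
MAX_STATISTICS_BYTES = 10 * 1024
MAX_PER_CASE_ROWS = 1000


def looks_like_image(value: Any) -> bool:
    """True if ``value`` carries PNG content, raw or base64-encoded."""
    if isinstance(value, (bytes, bytearray)):
        return bytes(value[:8]) == PNG_MAGIC or PNG_MAGIC in bytes(value)
    if isinstance(value, str):
        if PNG_MAGIC.decode("latin-1") in value:
            return True
        head = value.lstrip()[:8]
        if head == PNG_MAGIC_B64_PREFIX:
            return True
        # defensive: decode a short prefix and look for the signature
        try:
            decoded = base64.b64decode(value.lstrip()[:16] + "==", validate=True)
        except (binascii.Error, ValueError):
            return False
        return decoded.startswith(PNG_MAGIC)
    return False


def scan_payload(obj: Any, context: str = "payload") -> None:
    """Recursively reject byte blobs, embedded images and oversized strings."""
    if isinstance(obj, (bytes, bytearray)):
        raise PrivacyError(f"{context}: raw bytes are not accepted")
    if isinstance(obj, str):
        if looks_like_image(obj):
            raise PrivacyError(f"{context}: value contains image bytes")
        if len(obj) > MAX_STRING_CHARS:
            raise PrivacyError(
                f"{context}: string of {len(obj)} chars exceeds the "
                f"{MAX_STRING_CHARS}-char metadata limit"
            )
        return
    if isinstance(obj, Mapping):
        for key, value in obj.items():
            scan_payload(key, context)
            scan_payload(value, f"{context}.{key}")
        return
    if isinstance(obj, (list, tuple)):
        for i, value in enumerate(obj):
            scan_payload(value, f"{context}[{i}]")
        return
    # numbers / bools / None are fine


def check_statistics(stats: Mapping[str, Any]) -> None:
    """Validate a dataset-registration statistics map.

    Statistics must be a flat map of metric name to scalar or short text —
    aggregates only, no per-case arrays — and serialize to at most 10 KB.
    """
    if not isinstance(stats, Mapping):
        raise ValidationError("statistics must be a mapping")
    for key, value in stats.items():
        if not isinstance(key, str):
            raise ValidationError("statistics keys must be strings")
        if isinstance(value, (list, tuple, dict, set)):
            raise PrivacyError(
                f"statistics[{key}]: per-case or nested values are not accepted; "
                "upload aggregates only"
            )
        if isinstance(value, bool) or value is None:
            continue
        if isinstance(value, (int, float)):
            if isinstance(value, float) and not math.isfinite(value):
                raise ValidationError(f"statistics[{key}]: non-finite value")
            continue
        if isinstance(value, str):
            scan_payload(value, f"statistics[{key}]")
            continue
        raise ValidationError(
            f"statistics[{key}]: unsupported type {type(value).__name__}"
        )
    payload = json.dumps(dict(stats)).encode()
    if len(payload) > MAX_STATISTICS_BYTES:
        raise PrivacyError(
            f"serialized statistics are {len(payload)} bytes; "
            f"limit is {MAX_STATISTICS_BYTES}"
        )
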