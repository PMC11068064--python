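"""Client→server transports.

One request surface (:meth:`CoordinationServer.handle_request`) is reached
two ways: :class:`InProcessTransport` calls it directly (no sockets — the
default for tests and the scripted demo) and the HTTP client in
:mod:`medfed.httpapi` speaks real HTTP to a served instance.

:class:`TransportSpy` wraps any transport and records every call with its
serialized payload, so scenarios can audit exactly what would have gone
over the wire — byte counts, payload contents, call timing — and can be
switched off entirely to prove an operation needs no network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Protocol

from .errors import TransportDisabledError, raise_for_code
from .server import CoordinationServer


class Transport(Protocol):
    """Anything that can carry an authenticated JSON request to the server."""

    def request(self, method: str, path: str, body: Mapping | None = None) -> Any:
        """Perform a request; raise the mapped ``MedfedError`` on failure."""


class InProcessTransport:
    """Direct binding to a server instance, still JSON-round-tripped.

    Payloads are serialized and parsed exactly as the HTTP transport would,
    so anything that would not survive the wire does not survive here.
    """

    def __init__(self, server: CoordinationServer, token: str | None):
        self._server = server
        self.token = token

    def request(self, method: str, path: str, body: Mapping | None = None) -> Any:
        payload = json.loads(json.dumps(body)) if body is not None else None
        status, response = self._server.handle_request(method, path, payload, self.token)
        if status >= 400:
            raise_for_code(response.get("code", "error"), response.get("message", ""))
        return response

    def with_token(self, token: str) -> "InProcessTransport":
        return InProcessTransport(self._server, token)


@dataclass
class SpyCall:
    method: str
    path: str
    body_bytes: bytes
    ok: bool


@dataclass
class TransportSpy:
    """Wraps a transport; records calls and can be disabled ("unplugged")."""

    inner: Transport
    calls: list[SpyCall] = field(default_factory=list)
    enabled: bool = True

    def request(self, method: str, path: str, body: Mapping | None = None) -> Any:
        if not self.enabled:
            raise TransportDisabledError(
                f"transport disabled; refused {method} {path}"
            )
        body_bytes = json.dumps(body).encode() if body is not None else b""
        try:
            response = self.inner.request(method, path, body)
        except Exception:
            self.calls.append(SpyCall(method, path, body_bytes, ok=False))
            raise
        self.calls.append(SpyCall(method, path, body_bytes, ok=True))
        return response

    @property
    def token(self):
        return getattr(self.inner, "token", None)

    def uploaded_bytes(self) -> int:
        """Total serialized request-body bytes across recorded calls."""
        return sum(len(c.body_bytes) for c in self.calls)

    def mutating_calls(self) -> list[SpyCall]:
        return [c for c in self.calls if c.method in ("POST", "PUT")]
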