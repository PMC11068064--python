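"""HTTP+JSON binding of the coordination server (stdlib only).

``serve_background`` runs a threaded HTTP server on localhost for local
deployments and parity tests; :class:`HTTPTransport` is the matching
client.  Both delegate all semantics to
:meth:`CoordinationServer.handle_request`, so HTTP and in-process callers
are indistinguishable to the registry.
"""

from __future__ import annotations

import json
import threading
import urllib.error
import urllib.parse
import urllib.request
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import Any, Mapping

from .errors import MedfedError, raise_for_code
from .server import CoordinationServer


def _make_handler(server: CoordinationServer):
    class Handler(BaseHTTPRequestHandler):
        protocol_version = "HTTP/1.1"

        def log_message(self, *args):  # quiet
            pass

        def _dispatch(self, method: str) -> None:
            parsed = urllib.parse.urlsplit(self.path)
            body: dict[str, Any] = {
                k: v[0] for k, v in urllib.parse.parse_qs(parsed.query).items()
            }
            length = int(self.headers.get("Content-Length") or 0)
            if length:
                try:
                    body.update(json.loads(self.rfile.read(length)))
                except json.JSONDecodeError:
                    self._reply(400, {"code": "contract", "message": "invalid JSON body"})
                    return
            auth = self.headers.get("Authorization", "")
            token = auth.removeprefix("Bearer ").strip() or None
            status, payload = server.handle_request(method, parsed.path, body, token)
            self._reply(status, payload)

        def _reply(self, status: int, payload) -> None:
            data = json.dumps(payload).encode()
            self.send_response(status)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(data)))
            self.end_headers()
            self.wfile.write(data)

        def do_GET(self):
            self._dispatch("GET")

        def do_POST(self):
            self._dispatch("POST")

        def do_PUT(self):
            self._dispatch("PUT")

    return Handler


def serve_background(
    server: CoordinationServer, host: str = "127.0.0.1", port: int = 0
) -> tuple[ThreadingHTTPServer, str]:
    """Start serving on a daemon thread; returns (httpd, base_url)."""
    httpd = ThreadingHTTPServer((host, port), _make_handler(server))
    thread = threading.Thread(target=httpd.serve_forever, daemon=True)
    thread.start()
    return httpd, f"http://{host}:{httpd.server_address[1]}"


def serve_forever(server: CoordinationServer, host: str = "127.0.0.1", port: int = 8080):
    """Blocking variant used by the ``medfed server serve`` command."""
    httpd = ThreadingHTTPServer((host, port), _make_handler(server))
    try:
        httpd.serve_forever()
    finally:  # pragma: no cover
        httpd.server_close()


class HTTPTransport:
    """JSON-over-HTTP client with bearer-token authentication."""

    def __init__(self, base_url: str, token: str | None):
        self.base_url = base_url.rstrip("/")
        self.token = token

    def request(self, method: str, path: str, body: Mapping | None = None) -> Any:
        data = json.dumps(body).encode() if body is not None else None
        req = urllib.request.Request(
            self.base_url + path, data=data, method=method.upper()
        )
        req.add_header("Content-Type", "application/json")
        if self.token:
            req.add_header("Authorization", f"Bearer {self.token}")
        try:
            with urllib.request.urlopen(req) as resp:
                return json.loads(resp.read())
        except urllib.error.HTTPError as exc:
            try:
                payload = json.loads(exc.read())
            except json.JSONDecodeError:
                raise MedfedError(f"HTTP {exc.code}") from exc
            raise_for_code(payload.get("code", "error"), payload.get("message", ""))

    def with_token(self, token: str) -> "HTTPTransport":
        return HTTPTransport(self.base_url, token)
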