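"""Exception hierarchy shared by server, client and cube runner.

Every error carries a short machine-readable ``code`` so that errors can
round-trip through the JSON transport and be re-raised client-side as the
same type.
"""

from __future__ import annotations


class MedfedError(Exception):
    """Base class; ``code`` identifies the error across the wire."""

    code = "error"
    http_status = 400

    def __init__(self, message: str):
        super().__init__(message)
        self.message = message


class AuthenticationError(MedfedError):
    code = "authentication"
    http_status = 401


class AuthorizationError(MedfedError):
    code = "authorization"
    http_status = 403


class NotFoundError(MedfedError):
    code = "not_found"
    http_status = 404


class ValidationError(MedfedError):
    code = "validation"
    http_status = 422


class StateError(MedfedError):
    """An operation attempted against a record in the wrong lifecycle state."""

    code = "state"
    http_status = 409


class DuplicateError(MedfedError):
    code = "duplicate"
    http_status = 409


class PrivacyError(MedfedError):
    """A payload violated the metadata-only upload contract."""

    code = "privacy"
    http_status = 422


class ContractError(MedfedError):
    """Caller broke a programmatic contract (unknown action, bad selector)."""

    code = "contract"
    http_status = 400


class IntegrityError(MedfedError):
    """Digest verification failed; the artifact must not be used."""

    code = "integrity"
    http_status = 409


class TransportDisabledError(MedfedError):
    """Raised by a disabled transport: proves an operation needs no network."""

    code = "transport_disabled"
    http_status = 503


#: code -> class, used to re-raise server errors client-side.
ERROR_TYPES = {
    cls.code: cls
    for cls in (
        MedfedError,
        AuthenticationError,
        AuthorizationError,
        NotFoundError,
        ValidationError,
        StateError,
        DuplicateError,
        PrivacyError,
        ContractError,
        IntegrityError,
        TransportDisabledError,
    )
}


def raise_for_code(code: str, message: str) -> None:
    raise ERROR_TYPES.get(code, MedfedError)(message)
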