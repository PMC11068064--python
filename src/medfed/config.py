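"""Client configuration and structured logging.

Configuration precedence: explicit flags > environment variables
(``MEDFED_*``) > config file (``medfed.yaml``) > defaults.  The bearer
token is treated as a secret: it is redacted from every log line.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ValidationError

LOG_LEVELS = ("DEBUG", "INFO", "WARNING", "ERROR")
CONFIG_FILENAME = "medfed.yaml"
_FIELDS = ("server_url", "token", "workspace", "log_level")


@dataclass
class ClientConfig:
    server_url: str = "http://127.0.0.1:8080"
    token: str = ""
    workspace: Path = Path.home() / ".medfed"
    log_level: str = "INFO"

    def validate(self) -> "ClientConfig":
        if self.log_level not in LOG_LEVELS:
            raise ValidationError(
                f"log_level: {self.log_level!r} is not one of {', '.join(LOG_LEVELS)}"
            )
        self.workspace = Path(self.workspace)
        return self


def load_config(
    path: str | os.PathLike | None = None,
    env: Mapping[str, str] | None = None,
    overrides: Mapping[str, object] | None = None,
) -> ClientConfig:
    """Merge defaults ← config file ← environment ← explicit overrides."""
    env = os.environ if env is None else env
    merged: dict = {}

    if path is not None:
        file_path = Path(path)
        if not file_path.is_file():
            raise ValidationError(f"config file not readable: {file_path}")
        try:
            data = yaml.safe_load(file_path.read_text()) or {}
        except yaml.YAMLError as exc:
            raise ValidationError(f"config file {file_path}: invalid YAML: {exc}") from exc
        if not isinstance(data, Mapping):
            raise ValidationError(f"config file {file_path}: expected a mapping")
        for key in data:
            if key not in _FIELDS:
                raise ValidationError(f"config file {file_path}: unknown key {key!r}")
        merged.update(data)

    for field_name in _FIELDS:
        env_key = f"MEDFED_{field_name.upper()}"
        if env_key in env:
            merged[field_name] = env[env_key]

    for key, value in (overrides or {}).items():
        if value is not None:
            merged[key] = value

    return ClientConfig(**{k: v for k, v in merged.items() if k in _FIELDS}).validate()


class _JsonLineFormatter(logging.Formatter):
    def __init__(self, secret: str):
        super().__init__()
        self._secret = secret

    def format(self, record: logging.LogRecord) -> str:
        message = record.getMessage()
        if self._secret:
            message = message.replace(self._secret, "[REDACTED]")
        return json.dumps(
            {
                "ts": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime(record.created)),
                "level": record.levelname,
                "logger": record.name,
                "message": message,
            }
        )


def setup_logging(config: ClientConfig) -> logging.Logger:
    """Line-delimited JSON logs in the workspace; token never written."""
    config.workspace.mkdir(parents=True, exist_ok=True)
    log_dir = config.workspace / "logs"
    log_dir.mkdir(exist_ok=True)
    logger = logging.getLogger("medfed")
    logger.setLevel(config.log_level)
    logger.handlers.clear()
    handler = logging.FileHandler(log_dir / "client.log")
    handler.setFormatter(_JsonLineFormatter(secret=config.token))
    logger.addHandler(handler)
    return logger
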