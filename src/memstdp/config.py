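"""YAML run-configuration loading with a simple ``extends`` mechanism."""

from __future__ import annotations

from pathlib import Path

import yaml

__all__ = ["load_config", "deep_merge"]


def deep_merge(base: dict, override: dict) -> dict:
    """Recursively merge ``override`` into ``base`` (override wins)."""
    out = dict(base)
    for key, value in override.items():
        if (
            key in out
            and isinstance(out[key], dict)
            and isinstance(value, dict)
        ):
            out[key] = deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path) -> dict:
    """Load a YAML config; an ``extends: <path>`` key pulls in a base file.

    The base path is resolved relative to the extending file; chains are
    followed recursively and cycles raise.
    """
    return _load(Path(path), seen=set())


def _load(path: Path, seen: set) -> dict:
    path = path.resolve()
    if path in seen:
        raise ValueError(f"config extends cycle involving {path}")
    seen.add(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    base_ref = raw.pop("extends", None)
    if base_ref is None:
        return raw
    base = _load((path.parent / base_ref), seen)
    return deep_merge(base, raw)
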