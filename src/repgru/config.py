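"""Flat ``key = value`` configuration files.

One dialect serves training, simulation and segmentation settings:
lines of ``key = value``, ``#`` comments, blank lines ignored.  Values
are parsed as int, float, bool or string (in that order of preference).
"""

from __future__ import annotations

from pathlib import Path

__all__ = ["parse_config", "read_config", "write_config"]

_BOOLEANS = {"true": True, "false": False, "yes": True, "no": False}


def _parse_value(text: str):
    text = text.strip()
    lowered = text.lower()
    if lowered in _BOOLEANS:
        return _BOOLEANS[lowered]
    if lowered in {"none", "null"}:
        return None
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


def parse_config(text: str) -> dict:
    config = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, value = line.split("=", 1)
        config[key.strip()] = _parse_value(value)
    return config


def read_config(path: str | Path) -> dict:
    return parse_config(Path(path).read_text())


def write_config(config: dict, path: str | Path) -> None:
    lines = [f"{key} = {value}\n" for key, value in config.items()]
    Path(path).write_text("".join(lines))
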