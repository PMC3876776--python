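"""Run configuration, plain key-value config files, and tabular output.

Every stochastic run records its seed and full parameter set in the output
metadata, so a recorded configuration re-runs to identical output.  Numbers
are serialized with ``repr`` (17 significant digits).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = ["RunConfig", "read_config", "write_config", "write_table",
           "config_hash"]

_FORMATS = ("csv", "json")


@dataclass
class RunConfig:
    """One CLI invocation: subcommand, parameters, seed, output routing."""

    subcommand: str
    params: dict
    seed: int = 0
    output: Optional[str] = None
    fmt: str = "csv"
    log_level: str = "info"

    def __post_init__(self):
        if self.subcommand not in ("isi", "simulate", "grid"):
            raise ValueError(f"unknown subcommand {self.subcommand!r}")
        if self.fmt not in _FORMATS:
            raise ValueError(f"format must be one of {_FORMATS}")

    def to_dict(self) -> dict:
        return {"subcommand": self.subcommand, "seed": self.seed,
                "output": self.output, "format": self.fmt,
                "log_level": self.log_level, **self.params}

    def hash(self) -> str:
        # hash what determines the computation, not where it is written
        return config_hash({"subcommand": self.subcommand, "seed": self.seed,
                            **self.params})


def config_hash(params: Mapping) -> str:
    """Stable short hash of a parameter mapping."""
    blob = json.dumps({k: params[k] for k in sorted(params)},
                      sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _parse_value(raw: str):
    raw = raw.strip()
    low = raw.lower()
    if low in ("true", "false"):
        return low == "true"
    if low in ("none", "null", ""):
        return None
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    return raw


def read_config(path, known_keys: Optional[Iterable[str]] = None) -> dict:
    """Read a plain ``key = value`` config file.

    Blank lines and ``#`` comments are ignored.  If ``known_keys`` is given,
    unknown keys raise with the full offending list.
    """
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(
                    f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, raw = line.split("=", 1)
            out[key.strip()] = _parse_value(raw)
    if known_keys is not None:
        unknown = sorted(set(out) - set(known_keys))
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    return out


def write_config(path, params: Mapping) -> None:
    """Write a mapping as ``key = value`` lines (round-trips read_config)."""
    with open(path, "w") as fh:
        for key in sorted(params):
            val = params[key]
            if isinstance(val, float):
                val = repr(val)
            elif val is None:
                val = "none"
            fh.write(f"{key} = {val}\n")


def _fmt_cell(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_table(records: Sequence[Mapping], path, fmt: str = "csv",
                metadata: Optional[Mapping] = None,
                columns: Optional[Sequence[str]] = None) -> None:
    """Write records to CSV (with ``#`` metadata header lines) or JSON."""
    if fmt not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}")
    records = list(records)
    if columns is None:
        columns = list(records[0].keys()) if records else []
    if fmt == "json":
        payload = {"metadata": dict(metadata or {}), "records": records}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=_fmt_cell)
            fh.write("\n")
        return
    with open(path, "w") as fh:
        for key in sorted(metadata or {}):
            fh.write(f"# {key}: {_fmt_cell((metadata or {})[key])}\n")
        fh.write(",".join(columns) + "\n")
        for rec in records:
            fh.write(",".join(_fmt_cell(rec[c]) for c in columns) + "\n")
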