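"""Schema-versioned CSV round-tripping.

Every data CSV the pipeline writes carries a single comment header line,

    # schema=icmreduce/<name> v<major>.<minor> seed=<seed> config=<sha12>

so artifacts are self-describing (which stage wrote them, under which seed
and configuration) and readers can reject files from an incompatible major
schema version.  The header carries no timestamps: identical runs produce
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import pandas as pd

from .errors import SchemaError

SCHEMA_MAJOR = 1
SCHEMA_MINOR = 0

_HEADER_RE = re.compile(
    r"^# schema=icmreduce/(?P<name>[\w.-]+) v(?P<major>\d+)\.(?P<minor>\d+)"
    r" seed=(?P<seed>-?\d+) config=(?P<config>[0-9a-f]+)$"
)


def config_hash(config: dict) -> str:
    """Stable 12-hex-digit digest of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path, name: str, seed: int, config_sha: str = "0") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (
        f"# schema=icmreduce/{name} v{SCHEMA_MAJOR}.{SCHEMA_MINOR} "
        f"seed={int(seed)} config={config_sha}\n"
    )
    with open(path, "w", newline="") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_csv(path, expect_name: str | None = None) -> tuple[pd.DataFrame, dict]:
    """Read a schema-versioned CSV; returns (table, header metadata)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    m = _HEADER_RE.match(first)
    if m is None:
        raise SchemaError(f"{path}: missing or malformed icmreduce schema header")
    meta = {
        "name": m["name"],
        "major": int(m["major"]),
        "minor": int(m["minor"]),
        "seed": int(m["seed"]),
        "config": m["config"],
    }
    if meta["major"] != SCHEMA_MAJOR:
        raise SchemaError(
            f"{path}: schema major version {meta['major']} unsupported (expected {SCHEMA_MAJOR})"
        )
    if expect_name is not None and meta["name"] != expect_name:
        raise SchemaError(f"{path}: expected schema {expect_name!r}, found {meta['name']!r}")
    df = pd.read_csv(path, skiprows=1)
    return df, meta
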