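"""Auditable run logs.

Every analysis writes a machine-parseable JSON record of the tool version,
the store content hash, the complete parameter set and a digest of the
input sample list.  Re-running with the logged parameters against the same
store reproduces byte-identical outputs, which is the reproducibility
contract the log exists to witness.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from datetime import datetime, timezone
from typing import Mapping, Optional, Sequence

from . import __version__
from .ped import SampleRecord


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def sample_list_digest(samples: Sequence[SampleRecord]) -> str:
    h = hashlib.sha256()
    for s in sorted(samples, key=lambda r: r.sample_id):
        h.update(json.dumps(asdict(s), sort_keys=True).encode())
    return h.hexdigest()


def write_run_log(
    path,
    command: str,
    params: Mapping,
    samples: Sequence[SampleRecord],
    store=None,
    output_files: Optional[Sequence[str]] = None,
) -> dict:
    """Write the audit record; returns the dict that was serialized."""
    record = {
        "tool": "atavlite",
        "version": __version__,
        "python": platform.python_version(),
        "command": command,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "params": json.loads(json.dumps(params, sort_keys=True, default=str)),
        "sample_list_digest": sample_list_digest(samples),
        "n_samples": len(samples),
        "store_digest": store.digest() if store is not None else None,
        "outputs": {str(p): file_digest(p) for p in (output_files or [])},
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=1, sort_keys=True)
    return record


def read_run_log(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
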