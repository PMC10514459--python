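"""Run manifests: enough metadata to reproduce any CLI run bit-for-bit."""

from __future__ import annotations

import hashlib
import json
import sys
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, Iterable, Optional

from . import __version__

__all__ = ["write_manifest"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    command: str,
    config: dict,
    base_seed: Optional[int],
    outputs: Iterable[Path],
    replicate_seeds: Optional[list] = None,
) -> Path:
    path = Path(path)
    doc = {
        "command": command,
        "argv": sys.argv,
        "package_version": __version__,
        "base_seed": base_seed,
        "replicate_seeds": replicate_seeds,
        "config": config,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "output_checksums": {str(p): _sha256(Path(p)) for p in outputs if Path(p).exists()},
    }
    path.write_text(json.dumps(doc, indent=2, default=str))
    return path
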