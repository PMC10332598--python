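"""Run manifests: what produced which artifact, from which inputs and seeds."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

from . import __version__

__all__ = ["write_manifest", "read_manifest"]


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for block in iter(lambda: handle.read(1 << 20), b""):
            digest.update(block)
    return digest.hexdigest()


def write_manifest(
    out_path: str | Path,
    stage: str,
    config: dict,
    inputs: list[str | Path] = (),
    outputs: list[str | Path] = (),
    seed: int | None = None,
) -> Path:
    """Write ``<out_path>.manifest.json`` describing one pipeline stage run."""
    manifest = {
        "stage": stage,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "config": config,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).is_file()},
        "outputs": [str(p) for p in outputs],
    }
    path = Path(str(out_path) + ".manifest.json")
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
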