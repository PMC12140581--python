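"""Run configuration, deterministic seed derivation, and run manifests.

Every stochastic stage of a batch run receives its own seed derived from the
global seed and the stage label via BLAKE2b, so parallel stages never share a
stream and a manifest (inputs + seeds + parameters) is enough to reproduce any
output bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Optional

import yaml

__all__ = ["derive_seed", "RunConfig", "write_manifest", "load_yaml_config"]


def derive_seed(global_seed: int, label: str) -> int:
    """Deterministic sub-seed from (global seed, operation label).

    BLAKE2b of ``"<seed>:<label>"`` truncated to 31 bits, so derived seeds are
    valid numpy seeds and uncorrelated across labels.
    """
    digest = hashlib.blake2b(
        f"{int(global_seed)}:{label}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class RunConfig:
    """Parameters for one CLI invocation plus global reproducibility state."""

    seed: int = 0
    out_dir: Path = Path(".")
    log_level: str = "INFO"
    params: dict[str, Any] = field(default_factory=dict)

    def seed_for(self, label: str) -> int:
        return derive_seed(self.seed, label)


def load_yaml_config(path) -> dict[str, Any]:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return data


def write_manifest(out_dir, command: str, seed: int, params: dict[str, Any],
                   outputs: Optional[list[str]] = None) -> Path:
    """Write a JSON manifest describing one run next to its outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "seed": int(seed),
        "params": {k: _jsonable(v) for k, v in params.items()},
        "outputs": outputs or [],
        "version": __version__,
        "python": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / f"manifest_{command.replace(' ', '_')}.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def _jsonable(v):
    if isinstance(v, Path):
        return str(v)
    if hasattr(v, "tolist"):
        return v.tolist()
    return v
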