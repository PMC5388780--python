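"""Result serialization: tidy CSV, JSON summary, run manifest.

Output is deterministic: fixed column order and float formatting, so
re-running the same configuration and seed produces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from . import __version__
from .experiments import ExperimentResult

__all__ = ["write_results"]

_FLOAT_FMT = "%.10g"


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items() if k != "traces"}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_results(result: ExperimentResult, outdir) -> dict:
    """Write per-trial CSV, summary CSV/JSON and a manifest; return manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trials_path = outdir / f"{result.name}_trials.csv"
    summary_path = outdir / f"{result.name}_summary.csv"
    result.trials.to_csv(trials_path, index=False, float_format=_FLOAT_FMT)
    result.summary.to_csv(summary_path, index=False, float_format=_FLOAT_FMT)

    params = _jsonable(result.params)
    cfg_hash = hashlib.sha256(
        json.dumps(params, sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest = {
        "experiment": result.name,
        "seed": result.seed,
        "params": params,
        "config_hash": cfg_hash,
        "version": __version__,
        "files": [trials_path.name, summary_path.name],
    }
    with open(outdir / f"{result.name}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
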