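"""Tabular I/O: FV curves, state distributions, trajectories, manifests.

CSV is the exchange format (column headers carry units); run manifests are
JSON documents holding the full parameter set, seed and package version so
any output can be replayed exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping, Optional

import pandas as pd

from .parameters import ModelParameters
from .steady_state import FVCurve, StateDistribution
from .montecarlo import Trajectory

__all__ = [
    "write_fv_csv",
    "read_fv_csv",
    "write_distribution_csv",
    "write_trajectory_csv",
    "write_manifest",
    "write_fit_json",
]


def write_fv_csv(curve: FVCurve, path: str | Path) -> None:
    curve.to_dataframe().to_csv(path, index=False, float_format="%.10g")


def read_fv_csv(path: str | Path, **meta: Any) -> FVCurve:
    return FVCurve.from_dataframe(pd.read_csv(path), **meta)


def write_distribution_csv(d: StateDistribution, path: str | Path) -> None:
    d.to_dataframe().to_csv(path, index=False, float_format="%.10g")


def write_trajectory_csv(tr: Trajectory, path: str | Path) -> None:
    tr.to_dataframe().to_csv(path, index=False, float_format="%.10g")


def write_fit_json(fit_dict: Mapping[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(dict(fit_dict), indent=2) + "\n")


def write_manifest(path: str | Path, p: ModelParameters, seed: int,
                   extra: Optional[Mapping[str, Any]] = None) -> None:
    """JSON manifest sufficient for exact replay of a run."""
    from . import __version__

    doc: dict[str, Any] = {
        "xbridge_version": __version__,
        "seed": seed,
        "parameters": p.to_dict(),
    }
    if extra:
        doc.update(dict(extra))
    Path(path).write_text(json.dumps(doc, indent=2, default=str) + "\n")
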