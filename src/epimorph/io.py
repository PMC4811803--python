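"""File formats: label TIFF stacks, link/lineage/rate CSV tables, JSON
sidecars.  All tables are long-format CSV; tensor maps carry a JSON
sidecar naming units and conventions."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

TENSOR_MAP_SIDECAR = {
    "format": "long CSV, one row per (m, n, frame)",
    "angle_convention": "counterclockwise from +x image axis, [0, pi)",
    "scalar_product": "normalized, (1/2) Tr(Q Q'); identity has norm 1",
    "units": {"rates": "per hour", "texture": "um^2", "stress": "a.u."},
}


def read_label_stack(path) -> np.ndarray:
    """Multi-page TIFF of integer labels -> (frames, H, W) array."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(np.uint32)


def write_label_stack(path, stack: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint32),
                     photometric="minisblack")


def write_tensor_map(path, table: pd.DataFrame, units: str = "per hour",
                     extra: dict | None = None) -> None:
    """Rate/stress map CSV plus a JSON sidecar describing conventions."""
    path = Path(path)
    # %.17g round-trips IEEE doubles exactly
    table.to_csv(path, index=False, float_format="%.17g")
    sidecar = dict(TENSOR_MAP_SIDECAR)
    sidecar["value_units"] = units
    if extra:
        sidecar.update(extra)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_tensor_map(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
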