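"""Tabular output: time series, histograms, snapshots and run metadata."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Conformation, Params, Phenotype
from .lattice import Lattice
from .observables import ClassRegions, histogram_frame, records_to_frame

__all__ = [
    "snapshot_frame",
    "lattice_from_snapshot",
    "write_run_outputs",
    "write_metadata",
    "write_surface_csv",
]


def write_surface_csv(path: "str | Path", params: Params, n: int = 101) -> None:
    """Tabulate the trade-off surface to CSV (columns e1, e2, C); points
    outside the feasible enzyme region carry an empty C."""
    from .core import surface_grid

    tab = surface_grid(params, n)
    pd.DataFrame(tab, columns=["e1", "e2", "C"]).to_csv(path, index=False)


def snapshot_frame(lat: Lattice) -> pd.DataFrame:
    """Occupied sites as rows (row, col, e1, e2, k, conformation)."""
    occ = lat.occupied
    rows, cols = np.nonzero(occ)
    return pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "e1": lat.e1[occ],
            "e2": lat.e2[occ],
            "k": lat.k[occ],
            "conformation": [Conformation(int(c)).name for c in lat.conf[occ]],
        }
    )


def lattice_from_snapshot(frame: pd.DataFrame, side: int, generation: int = 0) -> Lattice:
    lat = Lattice.empty(side)
    lat.generation = generation
    for rec in frame.itertuples(index=False):
        lat.set(
            (int(rec.row), int(rec.col)),
            Phenotype(float(rec.e1), float(rec.e2), float(rec.k), Conformation[rec.conformation]),
        )
    return lat


def write_metadata(path: Path, params: Params, regions: ClassRegions, extra: dict | None = None) -> None:
    meta = {"params": params.to_dict(), "class_regions": regions.to_dict()}
    if extra:
        meta.update(extra)
    path.write_text(json.dumps(meta, indent=2, default=str) + "\n")


def write_run_outputs(result, out_dir: "str | Path", prefix: str = "run") -> dict:
    """Write time series, final histogram, final snapshot and metadata
    CSVs/JSON for one `RunResult`; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "series": out / f"{prefix}_series.csv",
        "histogram": out / f"{prefix}_histogram.csv",
        "snapshot": out / f"{prefix}_snapshot.csv",
        "metadata": out / f"{prefix}_metadata.json",
    }
    records_to_frame(result.series).to_csv(paths["series"], index=False)
    histogram_frame(result.histogram, result.params.E_max).to_csv(
        paths["histogram"], index=False
    )
    snapshot_frame(result.lattice).to_csv(paths["snapshot"], index=False)
    write_metadata(
        paths["metadata"], result.params, result.regions,
        {"extinct_at": result.extinct_at},
    )
    return paths
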