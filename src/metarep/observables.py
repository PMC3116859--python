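"""Phenotype classification and per-generation observables.

The continuous (e1, e2) plane is partitioned into four phenotype classes:
*parasites* near the origin (little or no enzyme activity), *specialists*
near the axes (one strong activity), *generalists* near the 45-degree
line (two roughly equal activities), and *the rest*.  The region
boundaries are tunable (`ClassRegions`) and are applied in a fixed order
-- parasite, then specialist, then generalist -- so the classes partition
the plane.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .core import Params, Phenotype
from .lattice import Lattice

__all__ = [
    "ReplicatorClass",
    "ClassRegions",
    "SummaryRecord",
    "classify",
    "classify_arrays",
    "summarize",
    "phenotype_histogram",
    "quasi_equilibrium",
    "records_to_frame",
]


class ReplicatorClass(str, enum.Enum):
    PARASITE = "parasite"
    SPECIALIST = "specialist"
    GENERALIST = "generalist"
    REST = "rest"


@dataclass(frozen=True)
class ClassRegions:
    """Boundaries of the phenotype classes on the (e1, e2) plane.

    parasite_sum_max : occupants with ``e1 + e2 <= parasite_sum_max`` are
        parasites (default 1.0, i.e. a tenth of E_max = 10).
    specialist_minor_max : of the remaining, those with
        ``min(e1, e2) <= specialist_minor_max`` hug an axis and are
        specialists (band half-width 0.5 activity units).
    generalist_s_max : of the remaining, those with specialization
        ``s = |e1 - e2| / (e1 + e2) <= generalist_s_max`` hug the
        45-degree line and are generalists; everything else is "rest".
    """

    parasite_sum_max: float = 1.0
    specialist_minor_max: float = 0.5
    generalist_s_max: float = 0.2

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def classify(p: "Phenotype | tuple[float, float]", regions: ClassRegions = ClassRegions()) -> ReplicatorClass:
    """Class of one phenotype; only (e1, e2) matter, never k."""
    e1, e2 = (p.e1, p.e2) if isinstance(p, Phenotype) else (p[0], p[1])
    if e1 + e2 <= regions.parasite_sum_max:
        return ReplicatorClass.PARASITE
    if min(e1, e2) <= regions.specialist_minor_max:
        return ReplicatorClass.SPECIALIST
    if abs(e1 - e2) / (e1 + e2) <= regions.generalist_s_max:
        return ReplicatorClass.GENERALIST
    return ReplicatorClass.REST


def classify_arrays(e1: np.ndarray, e2: np.ndarray, regions: ClassRegions = ClassRegions()) -> np.ndarray:
    """Vectorized classification; returns an int array coded
    0 parasite, 1 specialist, 2 generalist, 3 rest."""
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    tot = e1 + e2
    out = np.full(e1.shape, 3, dtype=np.int8)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(tot > 0, np.abs(e1 - e2) / np.where(tot > 0, tot, 1.0), 1.0)
    generalist = s <= regions.generalist_s_max
    specialist = np.minimum(e1, e2) <= regions.specialist_minor_max
    parasite = tot <= regions.parasite_sum_max
    out[generalist] = 2
    out[specialist] = 1
    out[parasite] = 0
    return out


_CLASS_CODES = [
    ReplicatorClass.PARASITE,
    ReplicatorClass.SPECIALIST,
    ReplicatorClass.GENERALIST,
    ReplicatorClass.REST,
]


@dataclass(frozen=True)
class SummaryRecord:
    """Per-generation observables: occupancy, class frequencies (fractions
    of occupied sites) and trait means over occupants."""

    generation: int
    occupancy: float
    freq_specialist: float
    freq_generalist: float
    freq_parasite: float
    freq_rest: float
    mean_e1: float
    mean_e2: float
    mean_k: float
    extinct: bool = False

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def summarize(lat: Lattice, regions: ClassRegions = ClassRegions()) -> SummaryRecord:
    """Exact class counts and trait means over the occupied sites."""
    occ = lat.occupied
    n = int(np.count_nonzero(occ))
    total = occ.size
    if n == 0:
        return SummaryRecord(
            lat.generation, 0.0, 0.0, 0.0, 0.0, 0.0,
            math.nan, math.nan, math.nan, extinct=True,
        )
    e1 = lat.e1[occ]
    e2 = lat.e2[occ]
    codes = classify_arrays(e1, e2, regions)
    counts = np.bincount(codes, minlength=4)
    return SummaryRecord(
        generation=lat.generation,
        occupancy=n / total,
        freq_specialist=counts[1] / n,
        freq_generalist=counts[2] / n,
        freq_parasite=counts[0] / n,
        freq_rest=counts[3] / n,
        mean_e1=float(e1.mean()),
        mean_e2=float(e2.mean()),
        mean_k=float(lat.k[occ].mean()),
    )


def phenotype_histogram(lat: Lattice, bins: int, e_max: float = 10.0) -> np.ndarray:
    """Frequency table of occupants over a ``bins x bins`` grid spanning
    ``[0, e_max]^2`` in (e1, e2); sums to 1 when the lattice is occupied.
    Values at ``e_max`` fall in the last bin."""
    if bins < 1:
        raise ValueError("bins must be >= 1")
    occ = lat.occupied
    h, _, _ = np.histogram2d(
        lat.e1[occ], lat.e2[occ], bins=bins, range=[[0.0, e_max], [0.0, e_max]]
    )
    n = h.sum()
    return h / n if n > 0 else h


def histogram_frame(hist: np.ndarray, e_max: float = 10.0) -> pd.DataFrame:
    """Long-format view of a phenotype histogram:
    (e1_bin_low, e2_bin_low, frequency)."""
    bins = hist.shape[0]
    edges = np.linspace(0.0, e_max, bins + 1)[:-1]
    g1, g2 = np.meshgrid(edges, edges, indexing="ij")
    return pd.DataFrame(
        {"e1_bin_low": g1.ravel(), "e2_bin_low": g2.ravel(), "frequency": hist.ravel()}
    )


def quasi_equilibrium(series: "list[SummaryRecord]", window: float = 0.1) -> SummaryRecord:
    """Average class frequencies and trait means over the final ``window``
    fraction of the series (at least one record).

    The late-run mean stands in for the single late snapshot a long run
    would report; trait means over extinct records are NaN-skipped.
    """
    if not series:
        raise ValueError("series is empty")
    if not 0.0 < window <= 1.0:
        raise ValueError("window must be in (0, 1]")
    m = max(1, math.ceil(window * len(series)))
    tail = series[-m:]

    def mean(name):
        vals = np.array([getattr(r, name) for r in tail], dtype=float)
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if vals.size else math.nan

    return SummaryRecord(
        generation=tail[-1].generation,
        occupancy=mean("occupancy"),
        freq_specialist=mean("freq_specialist"),
        freq_generalist=mean("freq_generalist"),
        freq_parasite=mean("freq_parasite"),
        freq_rest=mean("freq_rest"),
        mean_e1=mean("mean_e1"),
        mean_e2=mean("mean_e2"),
        mean_k=mean("mean_k"),
        extinct=tail[-1].extinct,
    )


def records_to_frame(series: "list[SummaryRecord]") -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in series])
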