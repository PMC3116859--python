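"""Single runs, parameter sweeps and crossover estimation.

`run_single` drives one simulation and collects the time series of
`SummaryRecord`s, the final phenotype histogram and a final snapshot.
`run_sweep` repeats it along one parameter axis with replicate seeds, and
`crossover_estimate` locates the specialist-to-generalist dominance
change along a b-sweep by linear interpolation.
"""

from __future__ import annotations


from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import Params
from .lattice import Lattice, initialize, run_generation
from .observables import (
    ClassRegions,
    SummaryRecord,
    phenotype_histogram,
    quasi_equilibrium,
    records_to_frame,
    summarize,
)

__all__ = [
    "SweepSpec",
    "RunResult",
    "CrossoverResult",
    "run_single",
    "run_sweep",
    "crossover_estimate",
    "phase_params",
    "phase_sweep",
    "B_GRID",
]

# b grid of the phase-behaviour sweeps: spans the convex (strong) regime,
# the linear case b = 1 and the concave regime around the high-mobility
# dominance threshold.
B_GRID = (0.4, 0.6, 1.0, 1.4, 1.67, 2.0)


def _default_thin(generations: int) -> int:
    # summary every generation for short runs, every 10th beyond 1000
    return 1 if generations < 1000 else 10


@dataclass
class RunResult:
    params: Params
    series: list[SummaryRecord]
    histogram: np.ndarray
    lattice: Lattice
    regions: ClassRegions
    extinct_at: int | None = None

    @property
    def series_frame(self) -> pd.DataFrame:
        return records_to_frame(self.series)

    def quasi_equilibrium(self, window: float = 0.1) -> SummaryRecord:
        return quasi_equilibrium(self.series, window)


def run_single(
    params: Params,
    regions: ClassRegions = ClassRegions(),
    *,
    thin: int | None = None,
    histogram_bins: int = 50,
    stop_on_extinction: bool = True,
) -> RunResult:
    """Run one simulation, deterministic given ``(params, params.seed)``.

    Summaries are recorded at generation 0, every ``thin`` generations,
    and at the final generation.  The all-empty lattice is absorbing, so
    after extinction the remaining records are synthesized rather than
    simulated (``stop_on_extinction=False`` disables the shortcut).
    """
    params.validate()
    thin = _default_thin(params.generations) if thin is None else max(1, int(thin))
    rng = np.random.default_rng(params.seed)
    lat = initialize(params, rng)
    series = [summarize(lat, regions)]
    extinct_at: int | None = 0 if lat.n_occupied == 0 else None
    extinct_record: SummaryRecord | None = series[0] if extinct_at == 0 else None
    for t in range(1, params.generations + 1):
        if extinct_at is not None and stop_on_extinction:
            # the all-empty lattice is absorbing; synthesize the record
            if t % thin == 0 or t == params.generations:
                series.append(replace(extinct_record, generation=t))
            continue
        run_generation(lat, params, rng)
        if extinct_at is None and lat.n_occupied == 0:
            extinct_at = t
            extinct_record = summarize(lat, regions)
        if t % thin == 0 or t == params.generations:
            series.append(summarize(lat, regions))
    if extinct_at is not None and stop_on_extinction:
        lat.generation = params.generations
    hist = phenotype_histogram(lat, histogram_bins, params.E_max)
    return RunResult(params, series, hist, lat, regions, extinct_at)


@dataclass(frozen=True)
class SweepSpec:
    """One-axis parameter sweep with replicate seeds.

    ``axis`` names a Params field; each of ``values`` is run
    ``replicates`` times.  Seeds are either given explicitly (one per
    replicate, shared across values) or derived from ``base.seed`` as
    ``base.seed + r``.
    """

    base: Params
    axis: str
    values: tuple
    replicates: int = 5
    seeds: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "values", tuple(self.values))
        if self.seeds is not None:
            object.__setattr__(self, "seeds", tuple(self.seeds))
        if not self.values:
            raise ValueError("values must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not hasattr(self.base, self.axis):
            raise ValueError(f"axis {self.axis!r} is not a Params field")
        if self.seeds is not None and len(self.seeds) != self.replicates:
            raise ValueError("seeds must have one entry per replicate")

    def replicate_seeds(self) -> tuple:
        if self.seeds is not None:
            return self.seeds
        return tuple(self.base.seed + r for r in range(self.replicates))


def run_sweep(
    spec: SweepSpec,
    regions: ClassRegions = ClassRegions(),
    *,
    window: float = 0.1,
    thin: int | None = None,
) -> pd.DataFrame:
    """Quasi-equilibrium summaries along the sweep axis.

    One row per (value, replicate).  A failing run is recorded in its row's
    ``error`` column and the sweep continues.
    """
    rows = []
    for value in spec.values:
        for rep, seed in enumerate(spec.replicate_seeds()):
            row = {spec.axis: value, "replicate": rep, "seed": seed, "error": ""}
            try:
                p = spec.base.replace(**{spec.axis: value, "seed": seed})
                res = run_single(p, regions, thin=thin)
                qe = res.quasi_equilibrium(window)
                row.update(qe.to_dict())
                row["extinct_at"] = res.extinct_at
            except Exception as exc:  # noqa: BLE001 - per-row fault isolation
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CrossoverResult:
    """Location of the specialist/generalist dominance change.

    ``value`` is the interpolated axis value where the mean specialist and
    generalist frequencies cross; ``censored`` is None, "below-min"
    (generalists dominate everywhere) or "above-max" (specialists dominate
    everywhere), in which case ``value`` is the corresponding range end.
    """

    value: float
    censored: str | None = None


def crossover_estimate(table: pd.DataFrame, axis: str = "b") -> CrossoverResult:
    """Linear-interpolation estimate of the axis value where specialist
    and generalist mean frequencies cross, from a sweep table."""
    ok = table[table["error"] == ""] if "error" in table else table
    if ok.empty:
        raise ValueError("sweep table holds no successful runs")
    means = (
        ok.groupby(axis)[["freq_specialist", "freq_generalist"]]
        .mean()
        .sort_index()
    )
    if len(means) < 3:
        raise ValueError("need >= 3 sweep values straddling a dominance change")
    x = means.index.to_numpy(dtype=float)
    d = (means["freq_specialist"] - means["freq_generalist"]).to_numpy()
    exact = np.flatnonzero(d == 0.0)
    if exact.size:
        return CrossoverResult(float(x[exact[0]]))
    sign_change = np.flatnonzero(np.sign(d[:-1]) != np.sign(d[1:]))
    if sign_change.size == 0:
        if d[0] > 0:  # specialists dominate across the whole range
            return CrossoverResult(float(x[-1]), censored="above-max")
        return CrossoverResult(float(x[0]), censored="below-min")
    i = int(sign_change[0])
    frac = d[i] / (d[i] - d[i + 1])
    return CrossoverResult(float(x[i] + frac * (x[i + 1] - x[i])))


def phase_params(
    D: float,
    b: float,
    *,
    full_scale: bool = False,
    seed: int = 0,
    **overrides,
) -> Params:
    """Parameter preset of the phase-behaviour experiments:
    p_m = 0.01, g = 1.0, k_max = 2.5, p_d = 0.1, W_e = 20, at the given
    diffusion intensity and e1/e2 trade-off shape.

    Desk scale is L = 100 with 10,000 generations; ``full_scale`` switches
    to the 300 x 300 lattice and 150,000 generations.
    """
    base = dict(
        L=300 if full_scale else 100,
        generations=150_000 if full_scale else 10_000,
        p_d=0.1, p_m=0.01, g=1.0, k_min=2.0, k_max=2.5,
        E_max=10.0, W_e=20.0, D=D, b=b, seed=seed,
    )
    base.update(overrides)
    return Params(**base)


def phase_sweep(
    D: float,
    *,
    b_values: tuple = B_GRID,
    replicates: int = 5,
    full_scale: bool = False,
    seed: int = 0,
    **overrides,
) -> SweepSpec:
    """b-sweep preset at fixed diffusion intensity."""
    return SweepSpec(
        base=phase_params(D, b_values[0], full_scale=full_scale, seed=seed, **overrides),
        axis="b",
        values=b_values,
        replicates=replicates,
    )
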