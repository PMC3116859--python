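"""Cellular-automaton engine: toroidal lattice and the update operations.

The habitat is an ``L x L`` torus of sites, each empty or holding a single
replicator.  One generation consists of ``L**2`` asynchronous elementary
site updates (a random site with replacement: occupied sites face the
death draw, empty sites run the replication lottery) interleaved with
``round(D * L**2)`` diffusion swaps, followed by the between-generation
conformation update of every occupant.

All randomness flows through one ``numpy.random.Generator`` per run; the
jitted kernels consume the same underlying bit stream, so runs are
reproducible bit-for-bit given ``(params, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._kernels import EMPTY
from .core import (
    Conformation,
    Params,
    Phenotype,
    neighbourhood_offsets,
)

__all__ = [
    "Lattice",
    "SiteAssessment",
    "initialize",
    "local_metabolism",
    "fitness",
    "replication_lottery",
    "place_offspring",
    "death_update",
    "diffusion_step",
    "run_generation",
]


@dataclass
class Lattice:
    """L x L toroidal grid held as parallel trait arrays.

    ``conf`` encodes occupancy and conformation per site: -1 empty,
    0 non-enzymatic occupant, 1 expressing e1, 2 expressing e2.
    """

    e1: np.ndarray
    e2: np.ndarray
    k: np.ndarray
    conf: np.ndarray
    generation: int = 0

    @classmethod
    def empty(cls, side: int) -> "Lattice":
        return cls(
            e1=np.zeros((side, side)),
            e2=np.zeros((side, side)),
            k=np.zeros((side, side)),
            conf=np.full((side, side), EMPTY, dtype=np.int8),
        )

    @property
    def side(self) -> int:
        return self.conf.shape[0]

    @property
    def occupied(self) -> np.ndarray:
        """Boolean occupancy mask."""
        return self.conf >= 0

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.conf >= 0))

    def get(self, site: tuple[int, int]) -> Phenotype | None:
        i, j = (site[0] % self.side, site[1] % self.side)
        if self.conf[i, j] < 0:
            return None
        return Phenotype(
            float(self.e1[i, j]),
            float(self.e2[i, j]),
            float(self.k[i, j]),
            Conformation(int(self.conf[i, j])),
        )

    def set(self, site: tuple[int, int], p: Phenotype | None) -> None:
        i, j = (site[0] % self.side, site[1] % self.side)
        if p is None:
            self.conf[i, j] = EMPTY
            self.e1[i, j] = self.e2[i, j] = self.k[i, j] = 0.0
        else:
            self.e1[i, j] = p.e1
            self.e2[i, j] = p.e2
            self.k[i, j] = p.k
            self.conf[i, j] = np.int8(int(p.conformation))

    def copy(self) -> "Lattice":
        return Lattice(
            self.e1.copy(), self.e2.copy(), self.k.copy(), self.conf.copy(),
            self.generation,
        )


@dataclass(frozen=True)
class SiteAssessment:
    """Transient per-site lottery inputs: metabolic supply and fitness."""

    m: float
    w: float


def initialize(params: Params, rng: np.random.Generator | None = None) -> Lattice:
    """Random starting lattice: exactly ``round(init_occupancy * L**2)``
    sites occupied, positions uniform without replacement, each phenotype
    an independent uniform draw from the feasible volume."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    lat = Lattice.empty(params.L)
    n_occ = int(round(params.init_occupancy * params.L ** 2))
    flat = rng.choice(params.L ** 2, size=n_occ, replace=False)
    rows = (flat // params.L).astype(np.int64)
    cols = (flat % params.L).astype(np.int64)
    _kernels.fill_random_phenotypes(
        lat.e1, lat.e2, lat.k, lat.conf, rows, cols,
        params.b, params.g, params.E_max, params.k_min, params.k_max, rng,
    )
    return lat


def local_metabolism(site: tuple[int, int], lat: Lattice, params: Params) -> float:
    """Metabolic supply M of the replicator at ``site``: the geometric mean
    of the two expressed activity sums over the 3x3 Moore neighbourhood
    (focal site included).  Zero whenever either activity is absent."""
    i, j = (site[0] % lat.side, site[1] % lat.side)
    return float(_kernels.metabolic_supply(lat.e1, lat.e2, lat.conf, i, j))


def fitness(p: Phenotype, m: float) -> float:
    """Actual fitness W = k * M: replication rate times metabolic supply."""
    if m < 0:
        raise ValueError("metabolic supply must be non-negative")
    return p.k * m


def site_assessment(site: tuple[int, int], lat: Lattice, params: Params) -> SiteAssessment:
    p = lat.get(site)
    if p is None:
        return SiteAssessment(0.0, 0.0)
    m = local_metabolism(site, lat, params)
    return SiteAssessment(m, fitness(p, m))


def claim_weights(
    empty_site: tuple[int, int], lat: Lattice, params: Params
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Claimant coordinates and their lottery weights W_i for an empty site.

    Exposed for inspection and testing; ``replication_lottery`` performs
    the categorical draw over ``[*claimants, stay-empty]`` with weights
    ``[*W, W_e]``.
    """
    i, j = (empty_site[0] % lat.side, empty_site[1] % lat.side)
    offsets = neighbourhood_offsets(params.replication_neighbourhood)
    coords: list[tuple[int, int]] = []
    weights: list[float] = []
    for di, dj in offsets:
        ni, nj = (i + int(di)) % lat.side, (j + int(dj)) % lat.side
        if lat.conf[ni, nj] >= 0:
            a = site_assessment((ni, nj), lat, params)
            coords.append((ni, nj))
            weights.append(a.w)
    return coords, np.asarray(weights)


def replication_lottery(
    empty_site: tuple[int, int], lat: Lattice, params: Params, rng: np.random.Generator
) -> tuple[int, int] | None:
    """Draw the winner of the competition for an empty site.

    Each occupant i of the replication neighbourhood wins with probability
    ``W_i / (W_e + sum_j W_j)``; with probability ``W_e / (W_e + sum W)``
    the site stays empty (returns None).  Each claimant's W uses its own
    metabolic neighbourhood, centred on itself.
    """
    i, j = (empty_site[0] % lat.side, empty_site[1] % lat.side)
    if lat.conf[i, j] >= 0:
        raise RuntimeError(
            f"replication_lottery called on occupied site {empty_site}: scheduler bug"
        )
    offsets = neighbourhood_offsets(params.replication_neighbourhood)
    wi, wj = _kernels.lottery(
        lat.e1, lat.e2, lat.k, lat.conf, i, j, offsets, params.W_e, rng
    )
    if wi < 0:
        return None
    return int(wi), int(wj)


def place_offspring(
    winner: tuple[int, int],
    empty_site: tuple[int, int],
    lat: Lattice,
    params: Params,
    rng: np.random.Generator,
) -> None:
    """Put a copy of the winner into the empty site; with probability p_m
    the copy's traits are replaced by a fresh uniform feasible draw."""
    wi, wj = (winner[0] % lat.side, winner[1] % lat.side)
    i, j = (empty_site[0] % lat.side, empty_site[1] % lat.side)
    if lat.conf[wi, wj] < 0:
        raise RuntimeError("place_offspring: winner site is empty")
    if lat.conf[i, j] >= 0:
        raise RuntimeError("place_offspring: target site is occupied")
    _kernels.place_offspring(
        lat.e1, lat.e2, lat.k, lat.conf, wi, wj, i, j,
        params.p_m, params.b, params.g, params.E_max, params.k_min, params.k_max,
        rng,
    )


def death_update(
    site: tuple[int, int], lat: Lattice, params: Params, rng: np.random.Generator
) -> None:
    """Vacate an occupied site with probability p_d, independent of the
    occupant's traits; empty sites are untouched."""
    i, j = (site[0] % lat.side, site[1] % lat.side)
    if lat.conf[i, j] < 0:
        return
    if rng.random() < params.p_d:
        lat.conf[i, j] = EMPTY


def diffusion_step(lat: Lattice, params: Params, rng: np.random.Generator) -> None:
    """One site-swap event: a uniform site and a uniform neighbour in the
    diffusion neighbourhood exchange their contents (either may be empty
    unless ``diffusion_occupied_only``).  Conserves the phenotype multiset
    and the occupancy count."""
    offsets = neighbourhood_offsets(params.diffusion_neighbourhood)
    _kernels.diffusion_event(
        lat.e1, lat.e2, lat.k, lat.conf, offsets, params.diffusion_occupied_only, rng
    )


def run_generation(lat: Lattice, params: Params, rng: np.random.Generator) -> None:
    """Advance the lattice by one generation (in place)."""
    if lat.side != params.L:
        raise ValueError(f"lattice side {lat.side} != params.L {params.L}")
    rep_offsets = neighbourhood_offsets(params.replication_neighbourhood)
    diff_offsets = neighbourhood_offsets(params.diffusion_neighbourhood)
    n_diff = int(round(params.D * params.L ** 2))
    _kernels.generation(
        lat.e1, lat.e2, lat.k, lat.conf,
        rep_offsets, diff_offsets,
        params.p_d, params.p_m, n_diff,
        params.b, params.g, params.E_max, params.k_min, params.k_max, params.W_e,
        params.diffusion_occupied_only, rng,
    )
    lat.generation += 1
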