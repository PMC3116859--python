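"""Non-spatial mathematical core of the metabolic replicator model.

A replicator's heritable phenotype is a triple ``(e1, e2, k)``: two enzyme
activities catalysing the two keystone reactions of the shared metabolism,
and a basic replication rate.  The three traits live under a trade-off
surface ``C(e1, e2)``: investing in enzyme activity (a compact, stable
secondary structure) makes a molecule a worse template, so ``k`` is capped
by a value that decreases with total enzyme investment, while the two
activities compete with each other for the same structural budget.

This module defines the parameter container, the phenotype record, the
trade-off surface and its feasibility predicate, uniform mutant sampling
from the feasible phenotype volume, the specialization index, and the
between-generation conformation switch.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "Conformation",
    "Params",
    "Phenotype",
    "tradeoff_surface",
    "is_feasible",
    "specialization",
    "switch_probability",
    "conformation_switch",
    "sample_mutant",
    "sample_mutants",
    "surface_grid",
]


class Conformation(enum.IntEnum):
    """Secondary-structure state: which single activity is expressed.

    A replicator with both activities folds into one of two conformations
    and expresses only that activity within a generation.  ``NONE`` marks
    the non-enzymatic (parasite) phenotype with ``e1 = e2 = 0``.
    """

    NONE = 0
    EXPRESS_E1 = 1
    EXPRESS_E2 = 2


class Neighbourhood(str, enum.Enum):
    VON_NEUMANN = "von_neumann"  # 4 orthogonal neighbours
    MOORE = "moore"              # 8 surrounding sites


# Offsets shared by the lattice kernels; row-major (di, dj).
VON_NEUMANN_OFFSETS = np.array([(-1, 0), (1, 0), (0, -1), (0, 1)], dtype=np.int64)
MOORE_OFFSETS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)

_NEIGHBOURHOOD_OFFSETS = {
    Neighbourhood.VON_NEUMANN: VON_NEUMANN_OFFSETS,
    Neighbourhood.MOORE: MOORE_OFFSETS,
}


def neighbourhood_offsets(nb: "Neighbourhood | str") -> np.ndarray:
    return _NEIGHBOURHOOD_OFFSETS[Neighbourhood(nb)]


@dataclass(frozen=True)
class Params:
    """Model constants and run controls.

    Parameters
    ----------
    L : int
        Lattice side length; the habitat is an ``L x L`` torus.
    p_d : float
        Per-update death probability of an occupied site, in [0, 1].
    p_m : float
        Mutation probability per replication event, in [0, 1].
    D : float
        Diffusion intensity: mean number of site-swap events per site
        update; ``round(D * L**2)`` swaps are interleaved per generation.
    b : float
        Shape of the e1/e2 trade-off (> 0).  ``b < 1`` is convex (strong):
        the feasible enzyme region lies inside the line ``e1 + e2 = E_max``;
        ``b = 1`` is that line exactly; ``b > 1`` is concave (weak), and
        ``b -> inf`` removes the e1/e2 trade-off.
    g : float
        Shape of the enzymes-vs-replication trade-off (> 0); ``g < 1``
        convex (strong), ``g > 1`` concave (weak).
    E_max : float
        Absolute maximum of either enzyme activity.
    k_min, k_max : float
        Lowest and highest possible basic replication rates.
    W_e : float
        Empty-site weight in the replication lottery: the tendency of an
        empty site to stay empty when local claims are weak.
    replication_neighbourhood : Neighbourhood
        Claimant neighbourhood of an empty site (von Neumann by default).
    metabolic_neighbourhood_size : int
        Size ``n`` of the Moore metabolic neighbourhood (3x3 including the
        focal site, so ``n = 9``).
    diffusion_neighbourhood : Neighbourhood
        Neighbourhood from which a swap partner is drawn (Moore default).
    diffusion_occupied_only : bool
        If True, a swap is performed only when both chosen sites are
        occupied (the literal "two neighbouring replicators" reading);
        by default swaps with an empty partner are allowed, which is what
        transports replicators into empty territory.
    init_occupancy : float
        Fraction of sites occupied at initialization.
    generations : int
        Number of generations to simulate.
    seed : int
        Seed for the single per-run random stream.
    """

    L: int = 100
    p_d: float = 0.1
    p_m: float = 0.01
    D: float = 0.0
    b: float = 1.0
    g: float = 1.0
    E_max: float = 10.0
    k_min: float = 2.0
    k_max: float = 2.5
    W_e: float = 20.0
    replication_neighbourhood: Neighbourhood = Neighbourhood.VON_NEUMANN
    metabolic_neighbourhood_size: int = 9
    diffusion_neighbourhood: Neighbourhood = Neighbourhood.MOORE
    diffusion_occupied_only: bool = False
    init_occupancy: float = 0.8
    generations: int = 10_000
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "replication_neighbourhood", Neighbourhood(self.replication_neighbourhood)
        )
        object.__setattr__(
            self, "diffusion_neighbourhood", Neighbourhood(self.diffusion_neighbourhood)
        )
        self.validate()

    def validate(self) -> None:
        if self.L < 3:
            raise ValueError(f"L must be >= 3 (neighbourhoods wrap), got {self.L}")
        for name in ("p_d", "p_m", "init_occupancy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.D < 0:
            raise ValueError(f"D must be >= 0, got {self.D}")
        for name in ("b", "g", "E_max", "W_e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.k_min <= 0:
            raise ValueError(f"k_min must be > 0, got {self.k_min}")
        if self.k_max < self.k_min:
            raise ValueError(f"k_max ({self.k_max}) must be >= k_min ({self.k_min})")
        if self.metabolic_neighbourhood_size != 9:
            raise ValueError("only the 3x3 Moore metabolic neighbourhood (n=9) is supported")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")

    def replace(self, **changes) -> "Params":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = v.value if isinstance(v, enum.Enum) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "Params":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown Params fields: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class Phenotype:
    """Heritable traits of one replicator plus its current conformation."""

    e1: float
    e2: float
    k: float
    conformation: Conformation = Conformation.NONE

    def __post_init__(self):
        object.__setattr__(self, "conformation", Conformation(self.conformation))
        if self.conformation is Conformation.EXPRESS_E1 and not self.e1 > 0:
            raise ValueError("EXPRESS_E1 requires e1 > 0")
        if self.conformation is Conformation.EXPRESS_E2 and not self.e2 > 0:
            raise ValueError("EXPRESS_E2 requires e2 > 0")
        if self.conformation is Conformation.NONE and (self.e1 > 0 or self.e2 > 0):
            raise ValueError("conformation NONE is reserved for e1 = e2 = 0 (parasites)")


def _enzyme_load(e1, e2, b: float, E_max: float):
    """u = ((e1^b + e2^b)^(1/b)) / E_max, the normalized enzyme investment.

    Factored as max * (1 + (min/max)^b)^(1/b) so large b does not overflow.
    """
    hi = np.maximum(e1, e2)
    lo = np.minimum(e1, e2)
    with np.errstate(invalid="ignore"):
        ratio = np.where(hi > 0, lo / np.where(hi > 0, hi, 1.0), 0.0)
    return hi * (1.0 + ratio ** b) ** (1.0 / b) / E_max


def tradeoff_surface(e1, e2, params: Params):
    """Upper bound ``C(e1, e2)`` on the replication rate.

    ``C = k_min + (k_max - k_min) * (1 - u)**(1/g)`` with
    ``u = ((e1^b + e2^b)^(1/b)) / E_max``, defined on ``u <= 1``.
    Accepts scalars or arrays.

    Raises
    ------
    ValueError
        For negative activities or points outside the feasible enzyme
        region (``u > 1``).
    """
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if np.any(e1 < 0) or np.any(e2 < 0):
        raise ValueError("enzyme activities must be non-negative")
    u = _enzyme_load(e1, e2, params.b, params.E_max)
    if np.any(u > 1.0 + 1e-12):
        raise ValueError("outside feasible enzyme region (u > 1)")
    u = np.minimum(u, 1.0)
    c = params.k_min + (params.k_max - params.k_min) * (1.0 - u) ** (1.0 / params.g)
    return float(c) if c.ndim == 0 else c


def is_feasible(p: Phenotype, params: Params, *, atol: float = 1e-9) -> bool:
    """True iff ``(e1, e2, k)`` lies on or below the trade-off surface.

    Boundary points (``u = 1`` or ``k = C``) count as feasible, so absolute
    specialists ``(E_max, 0, k_min)`` exist.
    """
    if p.e1 < 0 or p.e2 < 0:
        return False
    u = _enzyme_load(p.e1, p.e2, params.b, params.E_max)
    if u > 1.0 + atol:
        return False
    cap = params.k_min + (params.k_max - params.k_min) * max(0.0, 1.0 - u) ** (1.0 / params.g)
    return params.k_min - atol <= p.k <= cap + atol


def specialization(e1: float, e2: float) -> float:
    """Specialization index ``s = |e1 - e2| / (e1 + e2)`` on [0, 1].

    ``s = 1`` for pure specialists (one activity zero) and ``s = 0`` for
    perfectly symmetric generalists.  The non-enzymatic phenotype
    ``e1 = e2 = 0`` is assigned ``s = 1``: it has no conformation to switch.
    """
    if e1 < 0 or e2 < 0:
        raise ValueError("enzyme activities must be non-negative")
    tot = e1 + e2
    if tot == 0.0:
        return 1.0
    return abs(e1 - e2) / tot


def switch_probability(e1: float, e2: float) -> float:
    """Between-generation conformation switch probability, ``1 - s``."""
    return 1.0 - specialization(e1, e2)


def conformation_switch(p: Phenotype, rng: np.random.Generator) -> Phenotype:
    """Apply the between-generation conformation update to one replicator.

    With probability ``1 - s`` the conformation toggles to the other
    expressed state, but only if that state's activity is positive.
    Specialists (``s = 1``) never switch; phenotypes with conformation
    ``NONE`` are returned unchanged without consuming randomness.
    """
    if p.conformation is Conformation.NONE:
        return p
    if rng.random() < switch_probability(p.e1, p.e2):
        if p.conformation is Conformation.EXPRESS_E1 and p.e2 > 0:
            return replace(p, conformation=Conformation.EXPRESS_E2)
        if p.conformation is Conformation.EXPRESS_E2 and p.e1 > 0:
            return replace(p, conformation=Conformation.EXPRESS_E1)
    return p


def _assign_conformation(e1: float, e2: float, rng: np.random.Generator) -> Conformation:
    """Conformation of a freshly folded (mutant or initial) phenotype:
    uniform among the nonzero activities, NONE if both are zero."""
    if e1 > 0 and e2 > 0:
        return Conformation.EXPRESS_E1 if rng.random() < 0.5 else Conformation.EXPRESS_E2
    if e1 > 0:
        return Conformation.EXPRESS_E1
    if e2 > 0:
        return Conformation.EXPRESS_E2
    return Conformation.NONE


def sample_mutant(params: Params, rng: np.random.Generator) -> Phenotype:
    """Draw one phenotype uniformly from the feasible volume.

    Rejection sampling from the bounding box
    ``[0, E_max]^2 x [k_min, k_max]``: a candidate is accepted when its
    enzyme point satisfies ``u <= 1`` and its rate lies below the surface.
    When ``k_max = k_min`` the k-dimension is degenerate and every feasible
    enzyme point carries ``k = k_min``.
    """
    e1, e2, k = _sample_mutant_scalar(
        params.b, params.g, params.E_max, params.k_min, params.k_max, rng
    )
    return Phenotype(e1, e2, k, _assign_conformation(e1, e2, rng))


def _sample_mutant_scalar(b, g, E_max, k_min, k_max, rng):
    # Pure-python twin of the jitted kernel draw; kept for clarity of the
    # rejection scheme.  The lattice engine uses the jitted version.
    while True:
        e1 = rng.random() * E_max
        e2 = rng.random() * E_max
        u = _enzyme_load(e1, e2, b, E_max)
        if u > 1.0:
            continue
        cap = k_min + (k_max - k_min) * (1.0 - u) ** (1.0 / g)
        if k_max == k_min:
            return e1, e2, k_min
        k = k_min + rng.random() * (k_max - k_min)
        if k <= cap:
            return e1, e2, k


def sample_mutants(n: int, params: Params, rng: np.random.Generator) -> list[Phenotype]:
    return [sample_mutant(params, rng) for _ in range(n)]


def surface_grid(params: Params, n: int = 101) -> "np.ndarray":
    """Tabulate the trade-off surface on an ``n x n`` grid of ``[0, E_max]^2``.

    Returns a structured float array of shape ``(n*n, 3)`` with columns
    ``(e1, e2, C)``; points outside the feasible enzyme region get
    ``C = nan``.  Intended for CSV export and surface inspection.
    """
    axis = np.linspace(0.0, params.E_max, n)
    g1, g2 = np.meshgrid(axis, axis, indexing="ij")
    u = _enzyme_load(g1, g2, params.b, params.E_max)
    c = np.full_like(u, np.nan)
    ok = u <= 1.0
    c[ok] = params.k_min + (params.k_max - params.k_min) * (1.0 - u[ok]) ** (1.0 / params.g)
    return np.column_stack([g1.ravel(), g2.ravel(), c.ravel()])
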