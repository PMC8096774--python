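"""Moiety conservation laws: exact enumeration and elemental structure.

A semi-positive conservation vector is a non-zero, non-negative integer
vector gamma with S^T gamma = 0; gamma^T x is then constant along every
trajectory of the mass-action ODEs (the total amount of one conserved
molecular group, or *moiety*).  The set of all such vectors is a pointed
polyhedral cone; its extreme rays are the minimal generators and are
computed here by a double-description pass over exact integer arithmetic:
start from the unit rays of the non-negative orthant and intersect with one
hyperplane gamma . S_j = 0 per reaction, combining adjacent positive /
negative rays.

Stacking the p generators row-wise gives the matrix N with N S = 0.  When a
permutation of the species puts an identity block in front, N = [I_p, N2],
the network is *weakly elemented*: the species carrying the identity block
(the elemental, or basic, species — proteins in free form) each belong to
exactly one conservation law, and the conservation equations solve as
x1 = c - N2 x2 for the elemental block.  If additionally every species is
covered by some law the network is *elemented* (equivalently conservative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import gcd

import numpy as np
import sympy

from .errors import ContractError, UnsupportedStructureError
from .network import ReactionNetwork, Species

__all__ = [
    "ConservationSet",
    "semipositive_generators",
    "verify_conservation_vector",
    "build_conservation_set",
    "conservation_analysis",
    "elemental_solve",
    "is_conservative",
    "rational_rank",
]


def rational_rank(S: np.ndarray) -> int:
    """Exact rank of an integer matrix (no floating-point thresholds)."""
    S = np.asarray(S)
    if S.size == 0:
        return 0
    return sympy.Matrix(S.tolist()).rank()


def _normalize(ray: tuple[int, ...]) -> tuple[int, ...]:
    g = 0
    for v in ray:
        g = gcd(g, v)
    return tuple(v // g for v in ray) if g > 1 else ray


def semipositive_generators(S) -> list[tuple[int, ...]]:
    """Minimal semi-positive integer generators of ker(S^T) in the orthant.

    Double-description scheme: rays start as the unit vectors e_1..e_n and
    each column of S is imposed as an equality constraint in turn.  Rays on
    the hyperplane survive; adjacent rays on opposite sides combine into a
    new ray on it.  All arithmetic is exact (Python integers), every output
    ray is scaled to coprime entries, and the result is sorted
    lexicographically by support and then by entries, so the output order is
    deterministic.

    An empty list is a valid result (trivial left null cone).
    """
    S = np.asarray(S, dtype=object)
    if S.ndim != 2:
        raise ContractError("S must be a matrix")
    n, r = S.shape
    rays: list[tuple[int, ...]] = [
        tuple(1 if i == t else 0 for i in range(n)) for t in range(n)
    ]
    for j in range(r):
        col = [int(S[i, j]) for i in range(n)]
        vals = [sum(c * g for c, g in zip(col, ray)) for ray in rays]
        keep = [ray for ray, v in zip(rays, vals) if v == 0]
        pos = [(ray, v) for ray, v in zip(rays, vals) if v > 0]
        neg = [(ray, v) for ray, v in zip(rays, vals) if v < 0]
        supports = [frozenset(i for i, g in enumerate(ray) if g)
                    for ray in rays]
        supp_of = {id(ray): s for ray, s in zip(rays, supports)}
        new: list[tuple[int, ...]] = []
        for ru, vu in pos:
            su = supp_of[id(ru)]
            for rw, vw in neg:
                sw = supp_of[id(rw)]
                union = su | sw
                # combinatorial adjacency: no third ray's support fits
                # inside the union of the pair's supports
                adjacent = True
                for other, so in zip(rays, supports):
                    if other is ru or other is rw:
                        continue
                    if so <= union:
                        adjacent = False
                        break
                if adjacent:
                    combo = tuple(vu * w - vw * u for u, w in zip(ru, rw))
                    new.append(_normalize(combo))
        seen = set(keep)
        rays = keep + [c for c in new if not (c in seen or seen.add(c))]
    uniq = sorted(
        set(map(_normalize, rays)),
        key=lambda g: (tuple(i for i, v in enumerate(g) if v), g),
    )
    return uniq


def verify_conservation_vector(net_or_S, gamma) -> bool:
    """True iff S^T gamma = 0 exactly (integer arithmetic)."""
    S = net_or_S.S if isinstance(net_or_S, ReactionNetwork) else net_or_S
    S = np.asarray(S, dtype=object)
    gamma = list(gamma)
    if len(gamma) != S.shape[0]:
        raise ContractError("gamma length does not match species count")
    n, r = S.shape
    for j in range(r):
        if sum(int(S[i, j]) * gamma[i] for i in range(n)) != 0:
            return False
    return True


@dataclass
class ConservationSet:
    """Conservation-law generators of one network plus elemental structure.

    ``N`` stacks the generator rows; when ``is_weakly_elemented`` the
    species order ``elemental_permutation`` (elemental species first, one
    per law, then the remaining species in table order) brings ``N`` into
    the block form ``[I_p, N2]``.
    """

    generators: list[tuple[int, ...]]
    N: np.ndarray                       # p x n, integer
    species: list[Species] | None = None
    rank_S: int = 0
    is_weakly_elemented: bool = False
    is_elemented: bool = False
    basis_ok: bool = True               # len(generators) == n - rank(S)
    elemental_species: list[int] = field(default_factory=list)  # per CL row
    elemental_permutation: list[int] = field(default_factory=list)
    N2: np.ndarray | None = None        # p x (n - p), over secondary order
    unconserved_species: list[int] = field(default_factory=list)
    trivial_laws: list[int] = field(default_factory=list)  # CL rows
    warnings: list[str] = field(default_factory=list)

    @property
    def p(self) -> int:
        return len(self.generators)

    @property
    def n(self) -> int:
        return self.N.shape[1]

    @property
    def secondary_species(self) -> list[int]:
        return self.elemental_permutation[self.p:]

    def species_names(self) -> list[str]:
        if self.species is not None:
            return [s.name for s in self.species]
        return [f"x{i}" for i in range(self.n)]

    def require_elemental(self, what: str) -> None:
        if not self.basis_ok:
            raise UnsupportedStructureError(
                f"{what}: the generator count ({self.p}) exceeds "
                f"n - rank(S) ({self.N.shape[1] - self.rank_S}); the "
                "generators do not form a basis of ker(S^T) and "
                "basis-dependent operations are disabled")
        if not self.is_weakly_elemented:
            raise UnsupportedStructureError(
                f"{what}: the network is not weakly elemented "
                "(N admits no identity minor)")

    def law_of_elemental(self, j: int) -> int:
        """CL row owning elemental species index ``j`` (table order)."""
        try:
            return self.elemental_species.index(j)
        except ValueError:
            raise UnsupportedStructureError(
                f"species index {j} is not elemental") from None


def build_conservation_set(S, generators,
                           species: list[Species] | None = None
                           ) -> ConservationSet:
    """Assemble a :class:`ConservationSet` from verified generators.

    Scans species in table order and greedily assigns to each conservation
    law the first unit column of ``N`` found, which makes the elemental
    choice deterministic.  If every law receives one, the network is weakly
    elemented and ``N2`` is recorded over the remaining (secondary) species
    in table order; it is elemented iff additionally no species column of
    ``N`` is zero.
    """
    S = np.asarray(S)
    n = S.shape[0]
    for g in generators:
        if not verify_conservation_vector(S, g):
            raise ContractError(f"vector {g} is not a conservation vector")
    gens = [tuple(int(v) for v in g) for g in generators]
    N = np.array(gens, dtype=np.int64).reshape(len(gens), n)
    cs = ConservationSet(generators=gens, N=N, species=species,
                         rank_S=rational_rank(S))
    p = len(gens)
    expected = n - cs.rank_S
    if p > expected:
        cs.basis_ok = False
        cs.warnings.append(
            f"{p} generators exceed n - rank(S) = {expected}: the cone "
            "needs more extreme rays than the left-null-space dimension; "
            "elemental operations are disabled")
    elif p < expected:
        cs.warnings.append(
            f"only {p} generators for a left null space of dimension "
            f"{expected}; some conservation relations have no "
            "semi-positive representative")

    assigned: list[int | None] = [None] * p
    for i in range(n):
        col = N[:, i]
        nz = np.nonzero(col)[0]
        if len(nz) == 1 and col[nz[0]] == 1 and assigned[nz[0]] is None:
            assigned[nz[0]] = i
    cs.unconserved_species = [int(i) for i in range(n)
                              if not N[:, i].any()]
    if species is not None:
        const = [i for i, s in enumerate(species) if s.is_constant]
        cs.trivial_laws = [
            row for row in range(p)
            if (nzc := np.nonzero(N[row])[0]).size == 1
            and int(nzc[0]) in const
        ]
    if cs.basis_ok and all(a is not None for a in assigned):
        cs.is_weakly_elemented = True
        cs.elemental_species = [int(a) for a in assigned]  # type: ignore
        rest = [i for i in range(n) if i not in set(cs.elemental_species)]
        cs.elemental_permutation = cs.elemental_species + rest
        cs.N2 = N[:, rest].copy()
        cs.is_elemented = not cs.unconserved_species
    return cs


def conservation_analysis(net: ReactionNetwork) -> ConservationSet:
    """Enumerate the generators of a network and build its ConservationSet."""
    gens = semipositive_generators(net.S)
    return build_conservation_set(net.S, gens, species=net.species)


def elemental_solve(cs: ConservationSet, c: np.ndarray,
                    x2: np.ndarray) -> np.ndarray:
    """Solve the conservation equations for the elemental block:
    x1 = c - N2 x2.

    ``x2`` is ordered as ``cs.secondary_species``.  The caller must check
    non-negativity of the result: a negative entry means ``x2`` is
    infeasible for the class ``c``.
    """
    cs.require_elemental("elemental_solve")
    c = np.asarray(c, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if c.shape != (cs.p,) or x2.shape != (cs.n - cs.p,):
        raise ContractError("dimension mismatch in elemental_solve")
    return c - cs.N2 @ x2


def is_conservative(S) -> bool:
    """True iff a strictly positive left null vector of S exists,
    i.e. every species is covered by some semi-positive generator."""
    S = np.asarray(S)
    gens = semipositive_generators(S)
    covered = set()
    for g in gens:
        covered.update(i for i, v in enumerate(g) if v)
    return len(covered) == S.shape[0]
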