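"""Stoichiometric compatibility classes (SCCs).

The dynamics confine every trajectory to the affine slice
``(x0 + span S) ∩ R^n_+``, equivalently ``{y >= 0 : N y = N x0}`` when the
generators form a basis of ker(S^T).  The invariant vector ``c = N x`` (the
total moiety concentrations) therefore identifies the class of a state.

``sample_class_point`` draws a random member of a fixed class with a
three-stage sequential construction:

1. species in no conservation law get a log10-uniform draw;
2. the non-elemental conserved species are visited in a random order, each
   set to ``u * min_j c_j / gamma_ji`` over the laws j that involve it
   (u ~ U[0,1], residual totals updated in place);
3. each elemental species absorbs the residual of its unique law.

The construction guarantees membership (N x = c) and non-negativity by
design; it is a specific sequential scheme, not a uniform sample of the
class polytope.
"""

from __future__ import annotations

import numpy as np

from .conservation import ConservationSet
from .errors import ContractError

__all__ = [
    "class_of",
    "same_class",
    "ideal_state",
    "sample_class_point",
    "random_class",
]

#: default log10-uniform range for species outside every conservation law
UNCONSERVED_RANGE = (1e-5, 1e5)
#: default log10-uniform range for random total moiety concentrations
CLASS_RANGE = (1e-2, 1e3)


def class_of(cs: ConservationSet, x: np.ndarray) -> np.ndarray:
    """Invariant vector c = N x identifying the class of state ``x``."""
    x = np.asarray(x, dtype=float)
    if x.shape != (cs.n,):
        raise ContractError(f"expected state of length {cs.n}")
    return cs.N @ x


def same_class(cs: ConservationSet, x: np.ndarray, y: np.ndarray,
               tol: float = 1e-9) -> bool:
    """True iff ||N x - N y||_inf <= tol * (1 + ||N x||_inf)."""
    cx, cy = class_of(cs, x), class_of(cs, y)
    scale = 1.0 + (np.max(np.abs(cx)) if cx.size else 0.0)
    diff = np.max(np.abs(cx - cy)) if cx.size else 0.0
    return bool(diff <= tol * scale)


def ideal_state(cs: ConservationSet, c: np.ndarray) -> np.ndarray:
    """State with x1 = c on the elemental species and zero elsewhere.

    Unconserved species are set to 0.  Requires a weakly elemented network.
    """
    cs.require_elemental("ideal_state")
    c = np.asarray(c, dtype=float)
    if c.shape != (cs.p,):
        raise ContractError(f"expected class vector of length {cs.p}")
    if np.any(c < 0):
        raise ContractError("class vector must be non-negative")
    x = np.zeros(cs.n)
    x[cs.elemental_species] = c
    return x


def sample_class_point(cs: ConservationSet, c: np.ndarray,
                       rng: np.random.Generator | int,
                       unconserved_range: tuple[float, float] = UNCONSERVED_RANGE,
                       ) -> np.ndarray:
    """Random member of the class ``c`` (three-stage scheme, see module doc).

    Constant species are kept at their declared values and excluded from the
    random draws; their (trivial) laws simply hand them the residual total in
    stage 3.  The returned state satisfies ``N x = c`` to within a 1e-10
    relative tolerance and is non-negative.
    """
    cs.require_elemental("sample_class_point")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    c = np.asarray(c, dtype=float).copy()
    if c.shape != (cs.p,):
        raise ContractError(f"expected class vector of length {cs.p}")
    if np.any(c < 0):
        raise ContractError("class vector must be non-negative")

    N = cs.N
    x = np.zeros(cs.n)
    constant = (np.array([s.is_constant for s in cs.species])
                if cs.species is not None else np.zeros(cs.n, dtype=bool))
    elemental = set(cs.elemental_species)

    lo, hi = np.log10(unconserved_range[0]), np.log10(unconserved_range[1])
    for i in cs.unconserved_species:
        if not constant[i]:
            x[i] = 10.0 ** rng.uniform(lo, hi)
        elif cs.species is not None:
            x[i] = cs.species[i].initial_concentration

    residual = c.copy()
    secondary = [i for i in range(cs.n)
                 if i not in elemental and N[:, i].any() and not constant[i]]
    for i in rng.permutation(len(secondary)):
        idx = secondary[i]
        laws = np.nonzero(N[:, idx])[0]
        bound = np.min(residual[laws] / N[laws, idx])
        x[idx] = rng.uniform(0.0, 1.0) * bound
        residual[laws] -= N[laws, idx] * x[idx]

    for row, i in enumerate(cs.elemental_species):
        x[i] = residual[row]
    return x


def random_class(cs: ConservationSet, rng: np.random.Generator | int,
                 c_range: tuple[float, float] = CLASS_RANGE) -> np.ndarray:
    """Random class vector: log10-uniform totals, with the trivial laws of
    constant species pinned to their declared concentrations."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lo, hi = np.log10(c_range[0]), np.log10(c_range[1])
    c = 10.0 ** rng.uniform(lo, hi, size=cs.p)
    if cs.species is not None:
        for row in cs.trivial_laws:
            i = int(np.nonzero(cs.N[row])[0][0])
            c[row] = cs.N[row, i] * cs.species[i].initial_concentration
    return c
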