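"""Core representation of a mass-action chemical reaction network.

A network is a list of species and a list of *irreversible* reactions.
Reversible reactions in the input tables are expanded into two irreversible
records sharing a ``parent_id``, so that every rate constant owns one column
of the stoichiometric matrix and a gain-of-function projection can zero a
single direction.

Concentrations are molar (nM); the dynamics are the polynomial ODE system

    dx/dt = S v(x, k),    v_j(x, k) = k_j * prod_i x_i^{s_ij}

with ``S`` the n-by-r stoichiometric matrix (products minus reactants) and
``s_ij`` the reactant stoichiometry of reaction j.  Species flagged constant
(non-consumable inflows) keep a null time derivative: their rows of S are
identically zero even when they take part in reactions.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, IntegrityError, ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "parse_network",
    "write_network",
    "mass_action_fluxes",
    "ode_rhs",
    "ode_jacobian",
]


@dataclass(frozen=True)
class Species:
    """A chemical species.

    ``is_constant`` marks non-consumable inflow species whose time
    derivative is identically zero.
    """

    name: str
    initial_concentration: float = 0.0
    is_constant: bool = False

    def __post_init__(self) -> None:
        if self.initial_concentration < 0:
            raise ValidationError(
                f"species {self.name!r}: initial concentration must be >= 0, "
                f"got {self.initial_concentration}"
            )


@dataclass(frozen=True)
class Reaction:
    """One irreversible mass-action reaction.

    ``reactants``/``products`` map species names to positive integer
    stoichiometries.  The reactant multiset defines the flux monomial.
    A reaction and its reverse share ``parent_id``.
    """

    id: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_constant: float
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if self.rate_constant <= 0:
            raise ValidationError(
                f"reaction {self.id!r}: rate constant must be > 0, "
                f"got {self.rate_constant}"
            )

    @property
    def reactant_dict(self) -> dict[str, int]:
        return dict(self.reactants)

    @property
    def product_dict(self) -> dict[str, int]:
        return dict(self.products)


class ReactionNetwork:
    """A mass-action CRN with its stoichiometric matrix.

    Species order is canonical (table order); every vector and matrix in the
    package uses it.  ``S`` is the n-by-r products-minus-reactants matrix
    with constant-species rows zeroed; ``R`` holds the reactant
    stoichiometries that define the flux monomials; ``k`` is the vector of
    rate constants.
    """

    def __init__(self, species: list[Species], reactions: list[Reaction],
                 _S_override: np.ndarray | None = None,
                 gof_removed: frozenset[int] = frozenset()):
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate species name(s): {dup}")
        rids = [r.id for r in reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({i for i in rids if rids.count(i) > 1})
            raise ValidationError(f"duplicate reaction id(s): {dup}")

        self.species = list(species)
        self.reactions = list(reactions)
        self.species_index = {s.name: i for i, s in enumerate(species)}
        self.gof_removed = gof_removed

        n, r = len(species), len(reactions)
        R = np.zeros((n, r), dtype=np.int64)
        P = np.zeros((n, r), dtype=np.int64)
        for j, rx in enumerate(reactions):
            for name, st in rx.reactants:
                i = self._resolve(name, rx)
                R[i, j] += st
            for name, st in rx.products:
                i = self._resolve(name, rx)
                P[i, j] += st
        S = P - R
        constant_rows = [i for i, s in enumerate(species) if s.is_constant]
        S[constant_rows, :] = 0
        if _S_override is not None:
            if _S_override.shape != S.shape:
                raise ContractError("stoichiometry override has wrong shape")
            S = np.asarray(_S_override, dtype=np.int64)
        self.R = R
        self.S = S
        self.k = np.array([rx.rate_constant for rx in reactions], dtype=float)
        # per-reaction reactant index/stoichiometry lists for the jacobian
        self._reactant_ij = [
            (np.nonzero(R[:, j])[0], R[np.nonzero(R[:, j])[0], j])
            for j in range(r)
        ]

    def _resolve(self, name: str, rx: Reaction) -> int:
        try:
            return self.species_index[name]
        except KeyError:
            raise ParseError(
                f"reaction {rx.id!r} references undeclared species {name!r}"
            ) from None

    # -- basic views ------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.species)

    @property
    def r(self) -> int:
        return len(self.reactions)

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def constant_mask(self) -> np.ndarray:
        return np.array([s.is_constant for s in self.species])

    def x0(self) -> np.ndarray:
        """Initial concentration vector in species-table order."""
        return np.array([s.initial_concentration for s in self.species])

    def with_stoichiometry(self, S: np.ndarray,
                           gof_removed: frozenset[int] = frozenset()
                           ) -> "ReactionNetwork":
        """Copy of this network with ``S`` replaced (rate constants kept)."""
        return ReactionNetwork(self.species, self.reactions,
                               _S_override=S, gof_removed=gof_removed)

    def reaction_index(self, rid: str) -> int:
        for j, rx in enumerate(self.reactions):
            if rx.id == rid:
                return j
        raise KeyError(f"no reaction with id {rid!r}")

    def __repr__(self) -> str:
        return (f"ReactionNetwork(n={self.n} species, r={self.r} reactions, "
                f"rank-deficiency p<= {self.n})")


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^\s*(?:(\d+)\s+)?(\S+)\s*$")


def _parse_side(expr: str, rx_id: str) -> tuple[tuple[str, int], ...]:
    """Parse a reaction side like ``A + K`` or ``2 X`` into (name, stoich)."""
    expr = (expr or "").strip()
    if not expr or expr in {"0", "-", "∅"}:
        return ()
    terms: dict[str, int] = {}
    for part in expr.split("+"):
        m = _TERM_RE.match(part)
        if not m:
            raise ParseError(
                f"reaction {rx_id!r}: cannot parse term {part.strip()!r}")
        coeff = int(m.group(1)) if m.group(1) else 1
        if coeff <= 0:
            raise ParseError(
                f"reaction {rx_id!r}: non-positive stoichiometry in "
                f"{part.strip()!r}")
        terms[m.group(2)] = terms.get(m.group(2), 0) + coeff
    return tuple(sorted(terms.items()))


def _read_table(table, **kw) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    if isinstance(table, str) and "\t" in table:
        table = io.StringIO(table)
    return pd.read_csv(table, sep="\t", comment="#", dtype=str,
                       skip_blank_lines=True, **kw)


def parse_network(species_table, reaction_table) -> ReactionNetwork:
    """Build a :class:`ReactionNetwork` from the two TSV tables.

    ``species_table`` columns: ``name``, ``initial_nM``, ``constant`` (0/1).
    ``reaction_table`` columns: ``id``, ``reactants``, ``products``,
    ``reversible`` (0/1), ``k_forward``, ``k_reverse`` (blank unless
    reversible).  Either argument may be a path, an open file, a TSV string
    or a DataFrame.  Reversible rows are expanded into two irreversible
    reactions sharing the row id as ``parent_id``.

    Reactions with an empty reactant side are accepted as zero-order
    (boundary inflow) fluxes but flagged in the log.
    """
    sdf = _read_table(species_table)
    rdf = _read_table(reaction_table)
    for col in ("name", "initial_nM", "constant"):
        if col not in sdf.columns:
            raise ParseError(f"species table is missing column {col!r}")
    for col in ("id", "reactants", "products", "reversible", "k_forward"):
        if col not in rdf.columns:
            raise ParseError(f"reaction table is missing column {col!r}")

    species = []
    for row in sdf.itertuples(index=False):
        try:
            conc = float(row.initial_nM)
        except (TypeError, ValueError):
            raise ParseError(
                f"species {row.name!r}: bad initial_nM {row.initial_nM!r}"
            ) from None
        species.append(Species(str(row.name), conc,
                               str(row.constant).strip() in {"1", "true", "True"}))

    reactions: list[Reaction] = []
    for row in rdf.itertuples(index=False):
        rid = str(row.id)
        reactants = _parse_side(row.reactants, rid)
        products = _parse_side(row.products, rid)
        if not reactants:
            logger.info("reaction %s has an empty reactant set "
                        "(zero-order boundary flux)", rid)
        reversible = str(row.reversible).strip() in {"1", "true", "True"}
        try:
            kf = float(row.k_forward)
        except (TypeError, ValueError):
            raise ParseError(f"reaction {rid!r}: bad k_forward "
                             f"{row.k_forward!r}") from None
        if reversible:
            kr_raw = getattr(row, "k_reverse", None)
            try:
                kr = float(kr_raw)
            except (TypeError, ValueError):
                raise ParseError(
                    f"reaction {rid!r}: reversible row needs a numeric "
                    f"k_reverse, got {kr_raw!r}") from None
            reactions.append(Reaction(rid, reactants, products, kf,
                                      parent_id=rid))
            reactions.append(Reaction(rid + "_rev", products, reactants, kr,
                                      parent_id=rid))
        else:
            reactions.append(Reaction(rid, reactants, products, kf))
    return ReactionNetwork(species, reactions)


def _format_side(terms: tuple[tuple[str, int], ...]) -> str:
    return " + ".join(f"{st} {name}" if st != 1 else name
                      for name, st in terms)


def write_network(net: ReactionNetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Serialize a network back to the two-table TSV dialect.

    Reversible pairs (identified by a shared ``parent_id``) are re-merged
    into single rows, so ``parse_network(*write_network(net))`` round-trips.
    """
    sdf = pd.DataFrame({
        "name": [s.name for s in net.species],
        "initial_nM": [repr(s.initial_concentration) for s in net.species],
        "constant": [int(s.is_constant) for s in net.species],
    })
    rows = []
    consumed: set[int] = set()
    by_parent: dict[str, list[int]] = {}
    for j, rx in enumerate(net.reactions):
        if rx.parent_id is not None:
            by_parent.setdefault(rx.parent_id, []).append(j)
    for j, rx in enumerate(net.reactions):
        if j in consumed:
            continue
        if rx.parent_id is not None:
            pair = by_parent[rx.parent_id]
            fwd = net.reactions[pair[0]]
            rev = net.reactions[pair[1]]
            consumed.update(pair)
            rows.append((rx.parent_id, _format_side(fwd.reactants),
                         _format_side(fwd.products), 1,
                         repr(fwd.rate_constant), repr(rev.rate_constant)))
        else:
            rows.append((rx.id, _format_side(rx.reactants),
                         _format_side(rx.products), 0,
                         repr(rx.rate_constant), ""))
    rdf = pd.DataFrame(rows, columns=["id", "reactants", "products",
                                      "reversible", "k_forward", "k_reverse"])
    return sdf, rdf


# ---------------------------------------------------------------------------
# Mass-action kinetics
# ---------------------------------------------------------------------------

def mass_action_fluxes(net: ReactionNetwork, x: np.ndarray,
                       neg_tol: float = 1e-9) -> np.ndarray:
    """Flux vector v_j = k_j * prod_i x_i^{s_ij} (nM/time).

    Concentrations below ``-neg_tol`` raise; values in ``[-neg_tol, 0)``
    are treated as zero.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (net.n,):
        raise ContractError(f"expected state of length {net.n}, "
                            f"got shape {x.shape}")
    if np.any(x < -neg_tol):
        bad = [net.species[i].name for i in np.nonzero(x < -neg_tol)[0]]
        raise IntegrityError(
            f"negative concentration(s) beyond tolerance for species {bad}")
    xc = np.maximum(x, 0.0)
    return net.k * np.prod(xc[:, None] ** net.R, axis=0)


def ode_rhs(net: ReactionNetwork, x: np.ndarray) -> np.ndarray:
    """Right-hand side S v(x, k); exactly zero for constant species."""
    return net.S @ _raw_fluxes(net, np.asarray(x, dtype=float))


def _raw_fluxes(net: ReactionNetwork, x: np.ndarray) -> np.ndarray:
    # internal: raw polynomial evaluation, no sign checks (integrators may
    # probe slightly negative states; the monomials remain well defined)
    return net.k * np.prod(x[:, None] ** net.R, axis=0)


def ode_jacobian(net: ReactionNetwork, x: np.ndarray) -> np.ndarray:
    """Jacobian of the mass-action right-hand side, d(Sv)/dx."""
    x = np.asarray(x, dtype=float)
    D = np.zeros((net.r, net.n))
    for j, (idx, st) in enumerate(net._reactant_ij):
        for a, i in enumerate(idx):
            term = net.k[j] * st[a] * x[i] ** (st[a] - 1)
            for b, i2 in enumerate(idx):
                if b != a:
                    term *= x[i2] ** st[b]
            D[j, i] = term
    return net.S @ D
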