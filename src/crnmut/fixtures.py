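"""Synthetic networks with known conservation structure.

Three families:

* ``fixture_isomerization`` (FIX1): the reversible two-species switch
  A <=> B, one conservation law (1, 1) and the closed-form steady state
  x_A = c k_r / (k_f + k_r).
* ``fixture_phospho_cycle`` (FIX2): a kinase/phosphatase futile cycle —
  substrate A is phosphorylated to A* by kinase K via the complex AK and
  dephosphorylated back by phosphatase P via A*P.  Three moieties
  (substrate, kinase, phosphatase), fully elemented and conservative.
* ``random_conservative_crn``: networks grown from binding and
  isomerization motifs so that every species carries at least one moiety
  by construction; the builder emits the ground-truth generator set as its
  own certificate.  Random *integer* stoichiometric matrices almost never
  have sign-constrained left kernels, which is why the generator composes
  motifs instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import Reaction, ReactionNetwork, Species

__all__ = [
    "FixtureSpec",
    "fixture_isomerization",
    "fixture_phospho_cycle",
    "random_conservative_crn",
    "FIXTURES",
]


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    expected_p: int
    expected_elemental: tuple[str, ...]
    closed_form: str | None = None
    seed: int | None = None


def _rev(rid: str, reactants, products, kf: float, kr: float):
    return [
        Reaction(rid, reactants, products, kf, parent_id=rid),
        Reaction(rid + "_rev", products, reactants, kr, parent_id=rid),
    ]


def fixture_isomerization(k_f: float = 1.0, k_r: float = 1.0,
                          a0: float = 1.0, b0: float = 0.0
                          ) -> ReactionNetwork:
    """FIX1: A <=> B.  S = [[-1, 1], [1, -1]], one law (1, 1)."""
    species = [Species("A", a0), Species("B", b0)]
    reactions = _rev("iso", (("A", 1),), (("B", 1),), k_f, k_r)
    return ReactionNetwork(species, reactions)


def fixture_phospho_cycle(k1f: float = 1.0, k1r: float = 1.0,
                          k2: float = 1.0, k3f: float = 1.0,
                          k3r: float = 1.0, k4: float = 1.0,
                          a0: float = 10.0, k0: float = 5.0,
                          p0: float = 5.0) -> ReactionNetwork:
    """FIX2: A + K <=> AK -> A* + K,  A* + P <=> A*P -> A + P.

    Six species (A, K, P, A*, AK, A*P), six irreversible columns, three
    moiety laws with supports {A, A*, AK, A*P}, {K, AK}, {P, A*P};
    elemental species A, K, P.
    """
    species = [Species("A", a0), Species("K", k0), Species("P", p0),
               Species("A*", 0.0), Species("AK", 0.0), Species("A*P", 0.0)]
    reactions = (
        _rev("bind_AK", (("A", 1), ("K", 1)), (("AK", 1),), k1f, k1r)
        + [Reaction("phos", (("AK", 1),), (("A*", 1), ("K", 1)), k2)]
        + _rev("bind_A*P", (("A*", 1), ("P", 1)), (("A*P", 1),), k3f, k3r)
        + [Reaction("dephos", (("A*P", 1),), (("A", 1), ("P", 1)), k4)]
    )
    return ReactionNetwork(species, reactions)


FIXTURES = {
    "isomerization": (fixture_isomerization,
                      FixtureSpec("isomerization", 1, ("A",),
                                  "x_A = c k_r / (k_f + k_r)")),
    "phospho_cycle": (fixture_phospho_cycle,
                      FixtureSpec("phospho_cycle", 3, ("A", "K", "P"))),
}


def random_conservative_crn(n_moieties: int, n_complexes: int,
                            seed: int | None = None
                            ) -> tuple[ReactionNetwork, list[tuple[int, ...]]]:
    """Random conservative network grown from motifs, with certificate.

    Starts from ``n_moieties`` isomerization pairs E_j <=> E_j' (so the
    degenerate call ``(1, 0)`` is exactly the FIX1 topology) and adds
    ``n_complexes`` motif species: either a binding complex of two existing
    species (possibly the same one twice, giving stoichiometry 2) or an
    isomer of an existing species.  Every species carries at least one
    moiety, so the network is conservative; the moiety-count vectors are
    the extreme rays of the semi-positive left-null cone (the free form
    E_j is in no other moiety's support, and the count of E_j in any
    non-negative kernel vector is its coefficient on gamma_j), and they are
    returned as the ground-truth generator set.
    """
    rng = np.random.default_rng(seed)
    species_names: list[str] = []
    counts: list[np.ndarray] = []        # moiety composition per species
    reactions: list[Reaction] = []
    x0: list[float] = []

    def add_species(name, vec, conc):
        species_names.append(name)
        counts.append(np.asarray(vec, dtype=np.int64))
        x0.append(conc)

    def unit(j):
        v = np.zeros(n_moieties, dtype=np.int64)
        v[j] = 1
        return v

    for j in range(n_moieties):
        add_species(f"E{j}", unit(j), float(rng.integers(1, 6)))
        add_species(f"E{j}m", unit(j), 0.0)
        kf, kr = float(rng.integers(1, 4)), float(rng.integers(1, 4))
        reactions.extend(_rev(f"iso{j}", ((f"E{j}", 1),),
                              ((f"E{j}m", 1),), kf, kr))

    for t in range(n_complexes):
        kf, kr = float(rng.integers(1, 4)), float(rng.integers(1, 4))
        if rng.uniform() < 0.3:
            a = int(rng.integers(0, len(species_names)))
            name = f"C{t}"
            add_species(name, counts[a], 0.0)
            reactions.extend(_rev(f"conv{t}", ((species_names[a], 1),),
                                  ((name, 1),), kf, kr))
        else:
            a = int(rng.integers(0, len(species_names)))
            b = int(rng.integers(0, len(species_names)))
            name = f"C{t}"
            add_species(name, counts[a] + counts[b], 0.0)
            if a == b:
                lhs = ((species_names[a], 2),)
            else:
                lhs = tuple(sorted([(species_names[a], 1),
                                    (species_names[b], 1)]))
            reactions.extend(_rev(f"bind{t}", lhs, ((name, 1),), kf, kr))

    species = [Species(nm, c0) for nm, c0 in zip(species_names, x0)]
    net = ReactionNetwork(species, reactions)
    generators = [tuple(int(counts[i][j]) for i in range(len(species)))
                  for j in range(n_moieties)]
    return net, generators
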