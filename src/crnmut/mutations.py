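"""Projection operators modeling loss- and gain-of-function mutations.

A *null LoF* mutation of an elemental species A_j wipes out the whole
moiety it anchors: the state projector P_Lj zeroes every secondary species
bound into law j, zeroes the j-th total c_j, and re-solves the conservation
equations for the elemental block (x1 = c~ - N2 x2~).  Other elemental
species may *increase*: molecules of theirs that were bound in shared
compounds return to free form.

A GoF mutation (constitutive activation) deletes the deactivation reactions
of the active form: the matrix projector G_H zeroes the columns of S listed
in H while keeping species, rate constants and flux monomials — the zeroed
fluxes simply no longer move the state.  When rank(G_H(S)) = rank(S) the
left null space, and hence the compatibility classes, are unchanged; under
global stability of all projected systems the final mutated steady state is
independent of the order in which mutations are applied.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np

from .classes import class_of
from .conservation import (ConservationSet, rational_rank,
                           verify_conservation_vector)
from .errors import ContractError, UnsupportedStructureError
from .network import ReactionNetwork

__all__ = [
    "LoFMutation",
    "GoFMutation",
    "MutationSpec",
    "MutationResult",
    "RankCheck",
    "lof_project",
    "gof_project",
    "check_rank_preserved",
    "apply_mutation_spec",
    "iterative_mutation_path",
    "deactivation_reactions",
]


@dataclass(frozen=True)
class LoFMutation:
    """Loss of function of one elemental species (name or table index)."""
    target: str | int


@dataclass(frozen=True)
class GoFMutation:
    """Gain of function: the reaction set H to remove (ids or indices)."""
    reactions: tuple[str | int, ...]

    def __post_init__(self):
        if not self.reactions:
            raise ContractError("a GoF mutation needs a non-empty "
                                "reaction set")


@dataclass(frozen=True)
class MutationSpec:
    """An ordered collection of LoF and GoF mutations.

    The order is recorded (it shapes intermediate trajectories) but, when
    the rank condition and global stability hold, it does not affect the
    final steady state.
    """
    lof: tuple[LoFMutation, ...] = ()
    gof: tuple[GoFMutation, ...] = ()


@dataclass
class RankCheck:
    preserved: bool
    rank_original: int
    rank_mutated: int
    kernel_verified: bool | None = None  # None when rank dropped


@dataclass
class MutationResult:
    network: ReactionNetwork
    x0: np.ndarray
    class_descriptor: np.ndarray | None
    scc_changing: bool
    removed_reactions: frozenset[int]


def _species_index(target, net_or_cs) -> int:
    if isinstance(target, (int, np.integer)):
        return int(target)
    if isinstance(net_or_cs, ReactionNetwork):
        return net_or_cs.species_index[target]
    names = net_or_cs.species_names()
    return names.index(target)


def lof_project(cs: ConservationSet, x: np.ndarray, j: str | int
                ) -> np.ndarray:
    """Apply the LoF projector of elemental species ``j`` to state ``x``.

    Returns the projected state in species-table order.  Raises when ``j``
    is not elemental: the projector is defined only for elemental species.
    """
    cs.require_elemental("lof_project")
    j = _species_index(j, cs)
    row = cs.law_of_elemental(j)  # raises if j not elemental
    x = np.asarray(x, dtype=float)
    if x.shape != (cs.n,):
        raise ContractError(f"expected state of length {cs.n}")

    out = x.copy()
    secondary = cs.secondary_species
    for i in secondary:
        if cs.N[row, i] != 0:
            out[i] = 0.0
    c = class_of(cs, x)
    c[row] = 0.0
    x2 = out[secondary]
    x1 = c - cs.N2 @ x2
    out[cs.elemental_species] = x1
    return out


def gof_project(S: np.ndarray, H) -> np.ndarray:
    """Return a copy of ``S`` with the columns in ``H`` zeroed."""
    S = np.asarray(S)
    H = sorted(set(int(h) for h in H))
    if not H:
        _warnings.warn("empty GoF reaction set: projection is a no-op")
        return S.copy()
    if H and (H[0] < 0 or H[-1] >= S.shape[1]):
        raise ContractError(f"reaction index out of range in {H}")
    out = S.copy()
    out[:, H] = 0
    return out


def check_rank_preserved(S: np.ndarray, H,
                         generators=None) -> RankCheck:
    """Check rank(G_H(S)) = rank(S) over exact rationals.

    When the rank is preserved the left null spaces coincide; if
    ``generators`` are supplied each one is verified against the projected
    matrix as an explicit kernel-equality certificate.
    """
    S = np.asarray(S)
    Sm = gof_project(S, H) if len(list(H)) else S.copy()
    r0, r1 = rational_rank(S), rational_rank(Sm)
    check = RankCheck(preserved=(r0 == r1), rank_original=r0,
                      rank_mutated=r1)
    if check.preserved and generators is not None:
        check.kernel_verified = all(
            verify_conservation_vector(Sm, g) for g in generators)
    return check


def _resolve_reactions(net: ReactionNetwork, refs) -> frozenset[int]:
    out = set()
    for ref in refs:
        if isinstance(ref, (int, np.integer)):
            if not 0 <= int(ref) < net.r:
                raise ContractError(f"reaction index {ref} out of range")
            out.add(int(ref))
        else:
            out.add(net.reaction_index(ref))
    return frozenset(out)


def apply_mutation_spec(net: ReactionNetwork, cs: ConservationSet,
                        spec: MutationSpec, x_e: np.ndarray
                        ) -> MutationResult:
    """Compose a full mutation spec into (mutated network, initial state).

    The stoichiometric matrix gets all GoF columns zeroed (order
    irrelevant); the physiological state ``x_e`` is pushed through the LoF
    projectors in the listed order.  The resulting class descriptor equals
    N x_e with every targeted law zeroed, for any order.  If the rank
    condition fails the result is stamped ``scc_changing`` (order
    independence is no longer guaranteed) and a warning is emitted.
    """
    H_union: frozenset[int] = frozenset()
    for g in spec.gof:
        H_union |= _resolve_reactions(net, g.reactions)
    scc_changing = False
    if H_union:
        check = check_rank_preserved(net.S, H_union, cs.generators)
        if not check.preserved:
            scc_changing = True
            _warnings.warn(
                "GoF projection drops the rank of S: the compatibility "
                "classes change and order independence is not guaranteed")
    S_mut = gof_project(net.S, H_union) if H_union else net.S.copy()
    mutated = net.with_stoichiometry(S_mut, gof_removed=H_union)

    x0 = np.asarray(x_e, dtype=float).copy()
    for m in spec.lof:
        x0 = lof_project(cs, x0, m.target)
    c = class_of(cs, x0) if cs.basis_ok else None
    return MutationResult(network=mutated, x0=x0, class_descriptor=c,
                          scc_changing=scc_changing,
                          removed_reactions=H_union)


def iterative_mutation_path(net: ReactionNetwork, cs: ConservationSet,
                            spec: MutationSpec, x_e: np.ndarray,
                            **integrate_kwargs):
    """Apply the mutations one at a time, re-converging after each.

    GoF mutations first (cumulatively projected S, starting from the
    previous stage's steady state), then LoF mutations one by one under the
    fully projected matrix.  Returns the list of per-stage
    :class:`~crnmut.dynamics.SteadyStateResult`; under the rank condition
    and global stability the last stage's steady state equals the direct
    route of :func:`apply_mutation_spec` followed by one integration.
    """
    results = []
    x = np.asarray(x_e, dtype=float).copy()
    H_sofar: frozenset[int] = frozenset()
    stage = 0
    for g in spec.gof:
        stage += 1
        H_sofar |= _resolve_reactions(net, g.reactions)
        current = net.with_stoichiometry(gof_project(net.S, H_sofar),
                                         gof_removed=H_sofar)
        res = _converge_stage(current, x, stage, cs, integrate_kwargs)
        results.append(res)
        x = res.x_e
    final_net = (net.with_stoichiometry(gof_project(net.S, H_sofar),
                                        gof_removed=H_sofar)
                 if H_sofar else net)
    for m in spec.lof:
        stage += 1
        x = lof_project(cs, x, m.target)
        res = _converge_stage(final_net, x, stage, cs, integrate_kwargs)
        results.append(res)
        x = res.x_e
    return results


def _converge_stage(network, x, stage, cs, integrate_kwargs):
    from .dynamics import integrate_to_steady
    try:
        return integrate_to_steady(network, x, conservation=cs,
                                   **integrate_kwargs)
    except Exception as exc:
        raise RuntimeError(
            f"mutation path failed to converge at stage {stage}: {exc}"
        ) from exc


def deactivation_reactions(net: ReactionNetwork, active_species: str
                           ) -> list[int]:
    """Suggest the deactivation reaction set H of an active species.

    Heuristic following the phosphatase pattern (active + Pase -> complex ->
    inactive + Pase): all reactions consuming the active species whose
    products do not contain it, plus the conversion steps that drain the
    bound intermediates those reactions produce without regenerating the
    active form.  The result is a *suggestion*; it is never auto-applied.
    """
    if active_species not in net.species_index:
        raise KeyError(f"species {active_species!r} not in network")
    H: list[int] = []
    intermediates: set[str] = set()
    for j, rx in enumerate(net.reactions):
        rd, pd_ = rx.reactant_dict, rx.product_dict
        if active_species in rd and active_species not in pd_:
            H.append(j)
            intermediates.update(pd_)
    for j, rx in enumerate(net.reactions):
        if j in H:
            continue
        rd, pd_ = rx.reactant_dict, rx.product_dict
        if (set(rd) & intermediates and active_species not in pd_
                and not (set(pd_) & intermediates)):
            H.append(j)
    if not H:
        _warnings.warn(f"species {active_species!r} has no consuming "
                       "reactions; empty deactivation set")
    return sorted(H)
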