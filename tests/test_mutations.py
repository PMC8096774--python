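"""LoF / GoF projection operators and mutation composition."""

import itertools

import numpy as np
import pytest

from crnmut import (GoFMutation, LoFMutation, MutationSpec,
                    UnsupportedStructureError, apply_mutation_spec,
                    check_rank_preserved, class_of, conservation_analysis,
                    deactivation_reactions, gof_project, ideal_state,
                    integrate_to_steady, iterative_mutation_path,
                    lof_project, random_conservative_crn)


def test_lof_on_ideal_state_only_zeroes_target(cs2):
    x = ideal_state(cs2, np.array([10.0, 5.0, 5.0]))
    out = lof_project(cs2, x, "K")
    expect = x.copy()
    expect[1] = 0.0
    assert np.array_equal(out, expect)


def test_lof_derived_example(cs2):
    x = np.array([4.0, 4.0, 2.0, 2.0, 1.0, 3.0])
    out = lof_project(cs2, x, "K")
    assert out.tolist() == [5.0, 0.0, 2.0, 2.0, 0.0, 3.0]
    # the A moiety bound in AK returned to free A (4 -> 5)


def test_lof_idempotent(cs2, rng):
    x = rng.uniform(0, 3, 6)
    once = lof_project(cs2, x, "P")
    assert np.allclose(lof_project(cs2, once, "P"), once)


def test_lof_rejects_non_elemental(cs2):
    with pytest.raises(UnsupportedStructureError):
        lof_project(cs2, np.ones(6), "AK")


def test_lof_class_mapping_property(cs2, rng):
    # states in one class map to one class, with c_j zeroed (exact on ints)
    c = np.array([7.0, 3.0, 4.0])
    from crnmut import sample_class_point
    x = sample_class_point(cs2, c, 1)
    y = sample_class_point(cs2, c, 2)
    cx = class_of(cs2, lof_project(cs2, x, "K"))
    cy = class_of(cs2, lof_project(cs2, y, "K"))
    assert np.allclose(cx, [7.0, 0.0, 4.0], atol=1e-12)
    assert np.allclose(cx, cy, atol=1e-12)


def test_gof_zeroes_columns_and_is_idempotent(fix2):
    H = [3, 5]
    S1 = gof_project(fix2.S, H)
    assert not S1[:, H].any()
    assert np.array_equal(S1, gof_project(S1, H))
    allcols = gof_project(fix2.S, range(fix2.r))
    assert not allcols.any()


def test_gof_empty_set_warns(fix2):
    with pytest.warns(UserWarning, match="no-op"):
        gof_project(fix2.S, [])


def test_rank_preserved_deactivation_block(fix2, cs2):
    H = deactivation_reactions(fix2, "A*")
    assert [fix2.reactions[j].id for j in H] == ["bind_A*P", "dephos"]
    check = check_rank_preserved(fix2.S, H, cs2.generators)
    assert check.preserved and check.rank_mutated == 3
    assert check.kernel_verified


def test_rank_check_trivial_and_dropping(fix1, fix2):
    assert check_rank_preserved(fix1.S, [0]).preserved      # rank stays 1
    # zeroing the whole phosphatase arm drops the rank
    drop = check_rank_preserved(fix2.S, [3, 4, 5])
    assert not drop.preserved and drop.kernel_verified is None


def test_deactivation_no_consumers_warns(fix2):
    from crnmut import ReactionNetwork, Species, Reaction
    net = ReactionNetwork([Species("X", 1.0), Species("Y", 0.0)],
                          [Reaction("r", (("Y", 1),), (("X", 1),), 1.0)])
    with pytest.warns(UserWarning, match="no consuming"):
        assert deactivation_reactions(net, "X") == []


def test_apply_spec_identity(fix2, cs2):
    x_e = np.array([1.0, 2.0, 3.0, 0.5, 0.25, 0.1])
    res = apply_mutation_spec(fix2, cs2, MutationSpec(), x_e)
    assert np.array_equal(res.network.S, fix2.S)
    assert np.array_equal(res.x0, x_e)
    assert not res.scc_changing


def test_lof_order_independent_class_descriptor(fix2, cs2):
    x_e = np.array([1.0, 2.0, 3.0, 0.5, 0.25, 0.1])
    specs = [MutationSpec(lof=(LoFMutation("A"), LoFMutation("P"))),
             MutationSpec(lof=(LoFMutation("P"), LoFMutation("A")))]
    descs = [apply_mutation_spec(fix2, cs2, s, x_e).class_descriptor
             for s in specs]
    assert np.allclose(descs[0], descs[1], atol=1e-12)
    assert descs[0][0] == 0 and descs[0][2] == 0


def test_scc_changing_stamp(fix2, cs2):
    spec = MutationSpec(gof=(GoFMutation((3, 4, 5)),))
    with pytest.warns(UserWarning, match="rank"):
        res = apply_mutation_spec(fix2, cs2, spec, np.ones(6))
    assert res.scc_changing


def test_lof_kills_kinase_arm_steady_state(fix2, cs2):
    # with the kinase lost, the whole substrate moiety relaxes to free A
    x0 = ideal_state(cs2, class_of(cs2, fix2.x0()))
    phys = integrate_to_steady(fix2, x0, conservation=cs2)
    res = apply_mutation_spec(fix2, cs2,
                              MutationSpec(lof=(LoFMutation("K"),)),
                              phys.x_e)
    mut = integrate_to_steady(res.network, res.x0, conservation=cs2)
    names = fix2.species_names
    expect = dict(zip(names, [10.0, 0.0, 5.0, 0.0, 0.0, 0.0]))
    for name, val in zip(names, mut.x_e):
        assert val == pytest.approx(expect[name], abs=1e-6)


def test_iterative_path_single_stage_equals_direct(fix2, cs2):
    x0 = ideal_state(cs2, class_of(cs2, fix2.x0()))
    phys = integrate_to_steady(fix2, x0, conservation=cs2)
    spec = MutationSpec(lof=(LoFMutation("K"),))
    path = iterative_mutation_path(fix2, cs2, spec, phys.x_e)
    assert len(path) == 1
    direct = apply_mutation_spec(fix2, cs2, spec, phys.x_e)
    dres = integrate_to_steady(direct.network, direct.x0, conservation=cs2)
    assert np.allclose(path[-1].x_e, dres.x_e, atol=1e-8)


def test_random_spec_permutations_share_endpoint():
    # a binding network stays globally stable under the projected dynamics,
    # so every mutation ordering must reach the same state
    net, _ = random_conservative_crn(3, 3, seed=11)
    cs = conservation_analysis(net)
    x_e = integrate_to_steady(net, net.x0(), conservation=cs).x_e
    lof_targets = [net.species_names[cs.elemental_species[0]],
                   net.species_names[cs.elemental_species[1]]]
    H = (1,)   # reverse direction of the first isomerization
    finals = []
    for order in itertools.permutations(lof_targets):
        spec = MutationSpec(lof=tuple(LoFMutation(t) for t in order),
                            gof=(GoFMutation(H),))
        res = apply_mutation_spec(net, cs, spec, x_e)
        assert not res.scc_changing
        finals.append(integrate_to_steady(res.network, res.x0,
                                          conservation=cs).x_e)
        finals.append(iterative_mutation_path(net, cs, spec, x_e)[-1].x_e)
    ref = finals[0]
    scale = 1 + np.max(np.abs(ref))
    for f in finals[1:]:
        assert np.max(np.abs(f - ref)) / scale < 1e-6
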