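"""Network construction, TSV parsing, and mass-action kinetics."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crnmut import (ParseError, Species, ValidationError, mass_action_fluxes,
                    ode_rhs, parse_network, write_network)
from crnmut.conservation import semipositive_generators
from crnmut.fixtures import fixture_phospho_cycle, random_conservative_crn
from crnmut.network import Reaction, ReactionNetwork

SPECIES_TSV = """name\tinitial_nM\tconstant
A\t1.0\t0
B\t0.0\t0
"""

REACTIONS_TSV = """id\treactants\tproducts\treversible\tk_forward\tk_reverse
iso\tA\tB\t1\t2.0\t1.0
"""


def test_parse_reversible_pair_expands_and_builds_S():
    net = parse_network(SPECIES_TSV, REACTIONS_TSV)
    assert net.n == 2 and net.r == 2
    assert net.S.tolist() == [[-1, 1], [1, -1]]
    assert [rx.parent_id for rx in net.reactions] == ["iso", "iso"]
    assert net.k.tolist() == [2.0, 1.0]


def test_expansion_count_many_reversible_rows():
    # 339 reversible + 172 irreversible rows expand to 850 columns
    lines = ["id\treactants\tproducts\treversible\tk_forward\tk_reverse"]
    species = ["name\tinitial_nM\tconstant", "X\t1.0\t0", "Y\t0.0\t0"]
    for i in range(339):
        lines.append(f"r{i}\tX\tY\t1\t1.0\t1.0")
    for i in range(172):
        lines.append(f"s{i}\tX\tY\t0\t1.0\t")
    net = parse_network("\n".join(species) + "\n", "\n".join(lines) + "\n")
    assert net.r == 339 * 2 + 172 == 850


def test_unknown_species_error_names_offender():
    bad = REACTIONS_TSV.replace("A\tB", "A\tX")
    with pytest.raises(ParseError, match="'X'"):
        parse_network(SPECIES_TSV, bad)


@pytest.mark.parametrize("field,value", [
    ("k_forward", "-1.0"), ("k_forward", "0.0")])
def test_nonpositive_rate_constant_rejected(field, value):
    bad = REACTIONS_TSV.replace("2.0", value)
    with pytest.raises((ValidationError, ParseError)):
        parse_network(SPECIES_TSV, bad)


def test_duplicate_ids_rejected():
    with pytest.raises(ValidationError, match="duplicate"):
        ReactionNetwork([Species("A"), Species("A")], [])


def test_roundtrip_write_parse(fix2):
    sdf, rdf = write_network(fix2)
    again = parse_network(sdf, rdf)
    assert again.species_names == fix2.species_names
    assert np.array_equal(again.S, fix2.S)
    assert np.array_equal(again.k, fix2.k)
    assert [rx.parent_id for rx in again.reactions] == \
        [rx.parent_id for rx in fix2.reactions]


def test_constant_species_rows_are_zero():
    net = parse_network(
        "name\tinitial_nM\tconstant\nEGF\t2.0\t1\nR\t1.0\t0\nC\t0.0\t0\n",
        "id\treactants\tproducts\treversible\tk_forward\tk_reverse\n"
        "b\tEGF + R\tC\t1\t1.0\t1.0\n")
    assert not net.S[0].any()          # constant species row
    x = np.array([2.0, 1.0, 0.5])
    assert ode_rhs(net, x)[0] == 0.0


def test_fluxes_and_rhs_on_isomerization(fix1):
    x = np.array([2.0, 3.0])
    v = mass_action_fluxes(fix1, x)
    assert v.tolist() == [2.0, 3.0]
    assert ode_rhs(fix1, x).tolist() == [1.0, -1.0]
    # equilibrium: x_B / x_A = k_f / k_r
    assert np.allclose(ode_rhs(fix1, np.array([1.5, 1.5])), 0)


def test_bimolecular_flux_and_zero_reactant(fix2):
    x = np.zeros(6)
    x[fix2.species_index["A"]] = 1.0
    x[fix2.species_index["K"]] = 2.0
    v = mass_action_fluxes(fix2, x)
    j = fix2.reaction_index("bind_AK")
    assert v[j] == pytest.approx(1.0 * 2.0 * fix2.k[j])
    # every other reaction has a zero-concentration reactant
    assert all(v[i] == 0 for i in range(fix2.r) if i != j)


def test_conservation_orthogonality_exact_on_rationals(fix2):
    # gamma^T (S v) = 0 exactly when evaluated over rationals
    gens = semipositive_generators(fix2.S)
    x = [Fraction(3, 7), Fraction(1, 2), Fraction(5, 3),
         Fraction(2, 9), Fraction(4, 5), Fraction(1, 6)]
    k = [Fraction(int(kk)) for kk in fix2.k]
    v = []
    for j in range(fix2.r):
        term = k[j]
        for i in range(fix2.n):
            term *= x[i] ** int(fix2.R[i, j])
        v.append(term)
    sdot = [sum(Fraction(int(fix2.S[i, j])) * v[j] for j in range(fix2.r))
            for i in range(fix2.n)]
    for g in gens:
        assert sum(gi * si for gi, si in zip(g, sdot)) == 0


@settings(max_examples=25, deadline=None)
@given(alpha=st.floats(min_value=0.1, max_value=10.0),
       seed=st.integers(0, 10**6))
def test_flux_homogeneity_in_each_reactant(alpha, seed):
    net, _ = random_conservative_crn(2, 3, seed)
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.1, 5.0, net.n)
    v = mass_action_fluxes(net, x)
    i = int(rng.integers(0, net.n))
    x2 = x.copy()
    x2[i] *= alpha
    v2 = mass_action_fluxes(net, x2)
    assert np.allclose(v2, v * alpha ** net.R[i, :])
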