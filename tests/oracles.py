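"""Independent brute-force oracles used by the tests.

The generator oracle takes a different route from the package's
double-description tableau: it computes a rational basis of the left null
space with sympy and then enumerates candidate supports exhaustively,
keeping the sign-definite kernel vectors of minimal support (which are the
extreme rays of the semi-positive cone).  Tractable for networks of up to
a dozen species.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import gcd

import numpy as np
import sympy


def _normalize_int(vec) -> tuple[int, ...]:
    fracs = [Fraction(v) for v in vec]
    den = 1
    for f in fracs:
        den = den * f.denominator // gcd(den, f.denominator)
    ints = [int(f * den) for f in fracs]
    g = 0
    for v in ints:
        g = gcd(g, v)
    if g:
        ints = [v // g for v in ints]
    if any(v < 0 for v in ints):
        if all(v <= 0 for v in ints):
            ints = [-v for v in ints]
    return tuple(ints)


def brute_force_generators(S) -> list[tuple[int, ...]]:
    """Extreme rays of ker(S^T) ∩ R^n_+ by exhaustive support search."""
    S = np.asarray(S)
    n = S.shape[0]
    basis = sympy.Matrix(S.tolist()).T.nullspace()
    if not basis:
        return []
    m = len(basis)
    B = [[Fraction(sympy.nsimplify(b[i])) for b in basis] for i in range(n)]

    found: list[tuple[int, ...]] = []
    found_supports: list[frozenset[int]] = []
    for size in range(1, n + 1):
        for T in combinations(range(n), size):
            Tset = frozenset(T)
            if any(s <= Tset for s in found_supports):
                continue
            rows = [B[i] for i in range(n) if i not in Tset]
            sol = _nullspace_frac(rows, m)
            if len(sol) != 1:
                continue
            a = sol[0]
            v = [sum(B[i][j] * a[j] for j in range(m)) for i in range(n)]
            if all(x >= 0 for x in v) or all(x <= 0 for x in v):
                vec = _normalize_int(v)
                if frozenset(i for i, x in enumerate(vec) if x) == Tset:
                    found.append(vec)
                    found_supports.append(Tset)
    return sorted(set(found),
                  key=lambda g: (tuple(i for i, v in enumerate(g) if v), g))


def _nullspace_frac(rows, m) -> list[list[Fraction]]:
    """Nullspace basis of a small rational matrix (m columns)."""
    mat = [list(r) for r in rows]
    pivots: list[int] = []
    ri = 0
    for c in range(m):
        piv = next((k for k in range(ri, len(mat)) if mat[k][c] != 0), None)
        if piv is None:
            continue
        mat[ri], mat[piv] = mat[piv], mat[ri]
        pv = mat[ri][c]
        mat[ri] = [x / pv for x in mat[ri]]
        for k in range(len(mat)):
            if k != ri and mat[k][c] != 0:
                f = mat[k][c]
                mat[k] = [x - f * y for x, y in zip(mat[k], mat[ri])]
        pivots.append(c)
        ri += 1
    free = [c for c in range(m) if c not in pivots]
    basis = []
    for fc in free:
        vec = [Fraction(0)] * m
        vec[fc] = Fraction(1)
        for r, pc in zip(range(ri), pivots):
            vec[pc] = -mat[r][fc]
        basis.append(vec)
    return basis


def closed_form_isomerization(c: float, k_f: float, k_r: float):
    """Equilibrium of A <=> B on the class with total c."""
    return np.array([c * k_r / (k_f + k_r), c * k_f / (k_f + k_r)])
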