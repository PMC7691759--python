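"""Coancestry recursion, COP matrices and PCA grouping."""

import itertools

import numpy as np
import pandas as pd
import pytest

from metgains import (
    Pedigree,
    PedigreeError,
    cop,
    cop_matrix,
    generate_pedigree,
    group_lines,
)


def ped_from(rows):
    return Pedigree(pd.DataFrame(rows, columns=["id", "parent1", "parent2"]))


@pytest.fixture(scope="module")
def textbook():
    """Founders A,B,C,D; full sibs S1,S2 (A x B); half sibs H1 (A x C),
    (S-family); cousins C1 (S1 x C), C2 (S2 x D)."""
    return ped_from(
        [
            ("A", "", ""), ("B", "", ""), ("C", "", ""), ("D", "", ""),
            ("S1", "A", "B"), ("S2", "A", "B"),
            ("H1", "A", "C"),
            ("C1", "S1", "C"), ("C2", "S2", "D"),
        ]
    )


def test_classic_coancestry_values(textbook):
    assert cop(textbook, "A", "A") == 0.5  # non-inbred self
    assert cop(textbook, "S1", "A") == 0.25  # parent-offspring
    assert cop(textbook, "S1", "S2") == 0.25  # full sibs
    assert cop(textbook, "S1", "H1") == 0.125  # half sibs (share A)
    assert cop(textbook, "C1", "C2") == 0.0625  # first cousins
    assert cop(textbook, "A", "B") == 0.0  # unrelated founders


def test_cop_symmetric(textbook):
    ids = textbook.ids()
    for i, j in itertools.combinations(ids, 2):
        assert cop(textbook, i, j) == cop(textbook, j, i)


def path_counting_cop(ped: Pedigree, i: str, j: str) -> float:
    """Independent oracle: Wright's path counting.

    f(i,j) = sum over common ancestors A and non-self-intersecting
    ancestor paths i<-...<-A->...->j of (1/2)^(n_edges + 1) (1 + F_A),
    where the two path branches share no individual except A.  F_A is
    the inbreeding coefficient f(p1(A), p2(A)).
    """
    def ancestors_paths(x):
        # all ancestor chains from x upward: list of tuples (path of ids)
        out = [(x,)]
        p1, p2 = ped.parents[x]
        for p in (p1, p2):
            if p is not None:
                out.extend((x,) + rest for rest in ancestors_paths(p))
        return out

    if i == j:
        p1, p2 = ped.parents[i]
        FA = path_counting_cop(ped, p1, p2) if p1 and p2 else 0.0
        return 0.5 * (1 + FA)
    total = 0.0
    for pi in ancestors_paths(i):
        for pj in ancestors_paths(j):
            if pi[-1] != pj[-1]:
                continue  # must meet in a common ancestor
            if set(pi[:-1]) & set(pj[:-1]):
                continue  # branches may share only the ancestor itself
            A = pi[-1]
            p1, p2 = ped.parents[A]
            FA = path_counting_cop(ped, p1, p2) if p1 and p2 else 0.0
            n_edges = (len(pi) - 1) + (len(pj) - 1)
            total += 0.5 ** (n_edges + 1) * (1 + FA)
    return total


@pytest.fixture(scope="module")
def inbred_fixture():
    """4 generations with a repeated grandparent on both sides."""
    return ped_from(
        [
            ("G", "", ""), ("H", "", ""), ("K", "", ""), ("M", "", ""),
            ("P", "G", "H"), ("Q", "G", "K"),  # half sibs through G
            ("R", "P", "Q"),                   # inbred (F = 1/8)
            ("S", "P", "M"),
            ("T", "R", "S"),                   # G appears on both sides
            ("U", "R", "Q"),
        ]
    )


def test_recursion_matches_path_counting_oracle(inbred_fixture):
    ped = inbred_fixture
    for i, j in itertools.combinations_with_replacement(ped.ids(), 2):
        assert cop(ped, i, j) == pytest.approx(
            path_counting_cop(ped, i, j), abs=1e-12
        ), (i, j)


def test_cop_matrix_consistent_with_pairwise(inbred_fixture):
    ped = inbred_fixture
    m = cop_matrix(ped)
    for a, i in zip(m.ids, range(len(m.ids))):
        for b, j in zip(m.ids, range(len(m.ids))):
            assert m.f[i, j] == pytest.approx(cop(ped, a, b), abs=1e-12)


def test_founders_identity_structure():
    ped = ped_from([(x, "", "") for x in "ABCD"])
    m = cop_matrix(ped)
    np.testing.assert_array_equal(m.f, 0.5 * np.eye(4))


def test_cop_matrix_psd_on_generated_pedigrees():
    for seed in range(3):
        table, _ = generate_pedigree(12, 60, 4, seed=seed)
        m = cop_matrix(Pedigree(table))
        assert np.linalg.eigvalsh(m.f).min() >= -1e-10


def test_unrelated_individual_leaves_coancestries_unchanged():
    base = [("A", "", ""), ("B", "", ""), ("S1", "A", "B"), ("S2", "A", "B")]
    m1 = cop_matrix(ped_from(base), ["A", "B", "S1", "S2"])
    m2 = cop_matrix(ped_from(base + [("Z", "", ""), ("Z2", "Z", "Z")]),
                    ["A", "B", "S1", "S2"])
    np.testing.assert_array_equal(m1.f, m2.f)


def test_selfed_ancestor_representable():
    ped = ped_from([("A", "", ""), ("X", "A", "A")])  # selfed A
    assert cop(ped, "X", "X") == pytest.approx(0.75)  # F_X = f(A,A) = 1/2


def test_cycle_detected():
    with pytest.raises(PedigreeError):
        ped_from([("A", "B", ""), ("B", "A", "")])


def test_unknown_id_errors(textbook):
    with pytest.raises(PedigreeError):
        cop(textbook, "A", "nope")


# ---- grouping ----

def test_two_disjoint_families_separate_perfectly():
    rows = [(f"A{i}", "", "") for i in range(2)] + [(f"B{i}", "", "") for i in range(2)]
    rows += [(f"a{i}", "A0", "A1") for i in range(6)]
    rows += [(f"b{i}", "B0", "B1") for i in range(6)]
    ped = ped_from(rows)
    ids = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
    m = cop_matrix(ped, ids)
    groups = {a.id: a.group for a in group_lines(m, n_groups=2, seed=0)}
    ga = {groups[f"a{i}"] for i in range(6)}
    gb = {groups[f"b{i}"] for i in range(6)}
    assert len(ga) == 1 and len(gb) == 1 and ga != gb


def test_each_line_its_own_group():
    table, _ = generate_pedigree(8, 6, 2, seed=1)
    ped = Pedigree(table)
    ids = [i for i in ped.ids() if i.startswith("L")]
    m = cop_matrix(ped, ids)
    out = group_lines(m, n_groups=len(ids), seed=0)
    assert len({a.group for a in out}) == len(ids)


def test_group_recovery_from_generated_truth():
    """4 ancestor groups, strong within-group mating: PCA + k-means
    recovers the truth labels with adjusted Rand >= 0.9 on 100 lines
    (mean over a small seed ensemble)."""
    from sklearn.metrics import adjusted_rand_score

    aris = []
    for seed in range(5):
        table, labels = generate_pedigree(16, 100, 4, seed=seed, within_group_prob=0.97)
        ped = Pedigree(table)
        ids = [i for i in ped.ids() if i.startswith("L")]
        m = cop_matrix(ped, ids)
        out = group_lines(m, n_groups=4, seed=seed)
        pred = [a.group for a in out]
        truth = [labels[a.id] for a in out]
        aris.append(adjusted_rand_score(truth, pred))
    assert np.mean(aris) >= 0.9
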