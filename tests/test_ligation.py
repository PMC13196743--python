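"""Overhang algebra and the fidelity model against hand-computed oracles."""

import itertools

import numpy as np
import pytest

from poolgate.ligation import (
    ALL_4MERS,
    PALINDROMIC_4MERS,
    JunctionSet,
    LigationMatrix,
    is_palindromic,
    junction_fidelity,
    revcomp,
    set_fidelity,
)

# ---------------------------------------------------------------------------
# reverse complement
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "seq,expected",
    [("AATG", "CATT"), ("ACGT", "ACGT"), ("TTAG", "CTAA"), ("A", "T")],
)
def test_revcomp_examples(seq, expected):
    assert revcomp(seq) == expected


def test_revcomp_involution_exhaustive():
    for s in ALL_4MERS:
        assert revcomp(revcomp(s)) == s


def test_revcomp_rejects_non_acgt():
    with pytest.raises(ValueError, match="position 2"):
        revcomp("AANG")


def test_sixteen_palindromes():
    assert len(PALINDROMIC_4MERS) == 16
    assert "ACGT" in PALINDROMIC_4MERS and "GGCC" in PALINDROMIC_4MERS


# ---------------------------------------------------------------------------
# junction fidelity against hand sums
# ---------------------------------------------------------------------------


def brute_fidelity(o, members, backbone, matrix):
    """Independent oracle: the fidelity formula written as explicit dict
    loops over species, no shared code with the scorer."""
    species = []
    for x in list(members) + list(backbone or ()):
        for sp in (x, revcomp(x)):
            if sp not in species:
                species.append(sp)
    num = matrix[o, revcomp(o)] + matrix[revcomp(o), o]
    den = sum(matrix[o, p] + matrix[revcomp(o), p] for p in species)
    return num / den


def test_identity_matrix_every_junction_perfect(identity_matrix):
    jset = JunctionSet(["AATC", "GGAT", "CCTA"], backbone=("AATG", "TTAG"))
    for o in jset.junctions:
        assert junction_fidelity(o, jset, identity_matrix) == 1.0


def test_uniform_matrix_two_junctions_no_backbone(uniform_matrix):
    jset = JunctionSet(["AATC", "GGAT"], backbone=None)
    assert junction_fidelity("AATC", jset, uniform_matrix) == pytest.approx(0.25)


def test_uniform_matrix_one_junction_plus_backbone(uniform_matrix):
    jset = JunctionSet(["AATC"], backbone=("AATG", "TTAG"))
    assert junction_fidelity("AATC", jset, uniform_matrix) == pytest.approx(1 / 6)


def test_junction_fidelity_matches_brute_force(synthetic_matrix):
    jset = JunctionSet(["AATC", "GGAT", "CCTA"], backbone=("AATG", "TTAG"))
    for o in jset.junctions:
        assert junction_fidelity(o, jset, synthetic_matrix) == pytest.approx(
            brute_fidelity(o, jset.junctions, jset.backbone, synthetic_matrix)
        )


def test_junction_fidelity_requires_membership(uniform_matrix):
    jset = JunctionSet(["AATC"], backbone=None)
    with pytest.raises(ValueError, match="not a member"):
        junction_fidelity("GGAT", jset, uniform_matrix)


def test_synthetic_singleton_fidelity_frozen_oracle_value():
    """With 90% on-target mass per row, a lone junction (no backbone) sees
    only its own two strands in the reaction, so nearly all off-target mass
    is absent and fidelity is far above 0.9 (value frozen from the brute
    oracle)."""
    m = LigationMatrix.make_synthetic(0.9, seed=1)
    jset = JunctionSet(["AATC"], backbone=None)
    expected = brute_fidelity("AATC", jset.junctions, None, m)
    got = junction_fidelity("AATC", jset, m)
    assert got == pytest.approx(expected)
    assert 0.999 < got < 1.0


# ---------------------------------------------------------------------------
# set fidelity
# ---------------------------------------------------------------------------


def test_set_fidelity_identity_is_one(identity_matrix):
    jset = JunctionSet(["AATC", "GGAT", "CCTA"], backbone=("AATG", "TTAG"))
    assert set_fidelity(jset, identity_matrix) == 1.0


def test_set_fidelity_uniform_two_junctions(uniform_matrix):
    jset = JunctionSet(["AATC", "GGAT"], backbone=None)
    assert set_fidelity(jset, uniform_matrix) == pytest.approx(0.0625)


def test_set_fidelity_zero_junction_annihilates():
    m = LigationMatrix.identity().values.copy()
    # make AATC ligate only off-target: zero its correct entries, add cross
    m[ALL_4MERS.index("AATC"), :] = 0
    m[ALL_4MERS.index("GATT"), :] = 0
    m[ALL_4MERS.index("AATC"), ALL_4MERS.index("GGAT")] = 1.0
    jset = JunctionSet(["AATC", "GGAT"], backbone=None)
    assert set_fidelity(jset, LigationMatrix(m)) == 0.0


def test_set_fidelity_is_product_of_junction_fidelities(synthetic_matrix):
    jset = JunctionSet(["AATC", "GGAT", "CCTA"], backbone=("AATG", "TTAG"))
    product = np.prod(
        [junction_fidelity(o, jset, synthetic_matrix) for o in jset.members]
    )
    assert set_fidelity(jset, synthetic_matrix) == pytest.approx(product)
    # excluding backbone divides their factors out
    product_j = np.prod(
        [junction_fidelity(o, jset, synthetic_matrix) for o in jset.junctions]
    )
    assert set_fidelity(
        jset, synthetic_matrix, include_backbone=False
    ) == pytest.approx(product_j)


def _random_legal_set(rng, n, backbone=("AATG", "TTAG")):
    claimed = set()
    for b in backbone:
        claimed |= {b, revcomp(b)}
    out = []
    while len(out) < n:
        s = "".join(rng.choice(list("ACGT"), size=4))
        if is_palindromic(s) or s in claimed:
            continue
        out.append(s)
        claimed |= {s, revcomp(s)}
    return JunctionSet(out, backbone=backbone)


def test_fidelity_bounded_on_random_sets(synthetic_matrix):
    rng = np.random.default_rng(0)
    for _ in range(1000):
        jset = _random_legal_set(rng, int(rng.integers(1, 12)))
        f = set_fidelity(jset, synthetic_matrix)
        assert 0.0 <= f <= 1.0


def test_adding_species_never_raises_fidelity(synthetic_matrix):
    """Growing the reaction only adds competing mass to each denominator."""
    rng = np.random.default_rng(1)
    for _ in range(50):
        jset = _random_legal_set(rng, 4)
        before = [junction_fidelity(o, jset, synthetic_matrix) for o in jset.junctions]
        bigger = _random_legal_set(rng, 5)
        while True:
            extra = bigger.junctions[-1]
            if extra not in jset.species() and revcomp(extra) not in jset.species():
                break
            bigger = _random_legal_set(rng, 5)
        grown = JunctionSet(jset.junctions + [extra], backbone=jset.backbone)
        after = [junction_fidelity(o, grown, synthetic_matrix) for o in jset.junctions]
        for b, a in zip(before, after):
            assert a <= b + 1e-12


# ---------------------------------------------------------------------------
# invariants and I/O
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "junctions,backbone,msg",
    [
        (["AATC", "AATC"], None, "duplicate"),
        (["AATC", "GATT"], None, "collides"),
        (["ACGT"], None, "palindromic"),
        (["CATT"], ("AATG", "TTAG"), "collides"),
    ],
)
def test_junction_set_invariants(junctions, backbone, msg):
    with pytest.raises(ValueError, match=msg):
        JunctionSet(junctions, backbone=backbone).validate()


def test_matrix_csv_roundtrip(tmp_path, synthetic_matrix):
    path = tmp_path / "matrix.csv"
    synthetic_matrix.to_csv(path)
    assert LigationMatrix.from_csv(path) == synthetic_matrix


def test_matrix_csv_missing_label_rejected(tmp_path, synthetic_matrix):
    path = tmp_path / "matrix.csv"
    synthetic_matrix.to_csv(path)
    import pandas as pd

    df = pd.read_csv(path, index_col=0).drop(index="AAAA")
    df.to_csv(path)
    with pytest.raises(ValueError, match="missing 4-mer"):
        LigationMatrix.from_csv(path)


def test_matrix_rejects_negative_entries():
    m = np.ones((256, 256))
    m[3, 7] = -1.0
    with pytest.raises(ValueError, match="negative"):
        LigationMatrix(m)


def test_make_synthetic_orthogonality_one_is_identity():
    assert LigationMatrix.make_synthetic(1.0, seed=5) == LigationMatrix.identity()


def test_make_synthetic_row_mass_split():
    m = LigationMatrix.make_synthetic(0.9, seed=2)
    rows = m.values.sum(axis=1)
    assert np.allclose(rows, 1.0)
    for i, s in enumerate(itertools.islice(ALL_4MERS, 8)):
        assert m[s, revcomp(s)] == pytest.approx(0.9)
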