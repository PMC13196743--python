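"""Breakpoint annealing: schedule, moves, initialization, and convergence
against an exhaustive-enumeration oracle on toy pools."""

import math

import numpy as np
import pytest

from poolgate.config import LayoutConfig, SAParams
from poolgate.annealer import (
    FragmentationPlan,
    InitializationError,
    _legal_window,
    acceptance_probability,
    diverse_pair,
    initialize_plan,
    optimize_pool,
    propose_move,
    temperature_at,
)
from poolgate.layout import GeneRecord
from poolgate.ligation import LigationMatrix, is_palindromic, revcomp


def _random_gene(gid, length, seed):
    rng = np.random.default_rng(seed)
    return GeneRecord(gid, "".join(rng.choice(list("ACGT"), size=length)))


TOY_CFG = LayoutConfig(oligo_len=120, min_fragment_len=20, gg_budget=10)


# ---------------------------------------------------------------------------
# temperature schedule and acceptance rule
# ---------------------------------------------------------------------------


def test_temperature_endpoints_and_midpoint():
    params = SAParams(n_steps=5001)
    assert temperature_at(0, params) == 5e-3
    assert temperature_at(5000, params) == pytest.approx(1e-5)
    mid = temperature_at(2500, params)
    assert mid == pytest.approx(math.sqrt(5e-3 * 1e-5))  # ~2.236e-4


def test_temperature_single_step_schedule():
    assert temperature_at(0, SAParams(n_steps=1)) == 5e-3


def test_acceptance_probability():
    assert acceptance_probability(0.02, 1e-4) == 1.0
    assert acceptance_probability(0.0, 1e-4) == 1.0
    assert acceptance_probability(-0.01, 0.005) == pytest.approx(math.exp(-2))
    with pytest.raises(ValueError):
        acceptance_probability(0.1, 0.0)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def test_initialize_equal_thirds():
    gene = _random_gene("g", 300, seed=0)
    plan = initialize_plan([gene], 3, LayoutConfig())
    # seed-0 sequence has clean 4-mers at the unshifted positions
    claimed = {"AATG", "CATT", "TTAG", "CTAA"}
    for p in (100, 200):
        ov = gene.seq[p : p + 4]
        assert not is_palindromic(ov) and ov not in claimed
    assert plan.breakpoints["g"] == [100, 200]


def test_initialize_identical_genes_diverge():
    """Two copies of one sequence cannot share junctions; the second gene's
    clashing breakpoints shift by >= 1 bp."""
    gene = _random_gene("x", 300, seed=0)
    plan = initialize_plan(
        [GeneRecord("a", gene.seq), GeneRecord("b", gene.seq)], 3, LayoutConfig()
    )
    for pa, pb in zip(plan.breakpoints["a"], plan.breakpoints["b"]):
        assert pa != pb
    plan.validate(LayoutConfig())


def test_initialize_homopolymer_fails():
    with pytest.raises(InitializationError):
        initialize_plan([GeneRecord("a", "A" * 300)], 3, LayoutConfig())


def test_initialized_plan_is_valid_on_random_pools():
    genes = [_random_gene(f"g{i}", 300, seed=i) for i in range(6)]
    plan = initialize_plan(genes, 3, LayoutConfig())
    plan.validate(LayoutConfig())


# ---------------------------------------------------------------------------
# move proposal
# ---------------------------------------------------------------------------


def test_propose_move_changes_exactly_one_breakpoint():
    genes = [_random_gene(f"g{i}", 60, seed=i + 3) for i in range(2)]
    plan = initialize_plan(genes, 2, TOY_CFG)
    rng = np.random.default_rng(0)
    for _ in range(50):
        move = propose_move(plan, TOY_CFG, rng)
        assert move is not None
        gid, j, pos = move
        assert pos != plan.breakpoints[gid][j]
        old = plan.breakpoints[gid][j]
        plan.breakpoints[gid][j] = pos
        plan.validate(TOY_CFG)
        plan.breakpoints[gid][j] = old


def test_propose_move_forced_and_frozen():
    """A two-position window forces the move to the other position; a
    one-position window (or one whose alternatives all violate invariants,
    e.g. palindromic AT-repeat 4-mers) freezes the junction entirely."""
    # L = 2*payload - 4 - 2*flank pins the single-junction window to width 1
    gene1 = _random_gene("g", 2 * TOY_CFG.payload - 4 - 8, seed=2)
    plan1 = initialize_plan([gene1], 2, TOY_CFG)
    window = _legal_window(len(gene1.seq), plan1.breakpoints["g"], 0, TOY_CFG, 4)
    assert len(window) == 1
    assert propose_move(plan1, TOY_CFG, np.random.default_rng(0)) is None

    # one base shorter: width-2 window, so every proposal is the other slot
    gene2 = _random_gene("h", 2 * TOY_CFG.payload - 5 - 8, seed=2)
    plan2 = initialize_plan([gene2], 2, TOY_CFG)
    window2 = _legal_window(len(gene2.seq), plan2.breakpoints["h"], 0, TOY_CFG, 4)
    assert len(window2) == 2
    cur = plan2.breakpoints["h"][0]
    other = [p for p in window2 if p != cur][0]
    if is_palindromic(gene2.seq[other : other + 4]):
        assert propose_move(plan2, TOY_CFG, np.random.default_rng(0)) is None
    else:
        for s in range(5):
            assert propose_move(plan2, TOY_CFG, np.random.default_rng(s)) == (
                "h", 0, other,
            )


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------


def test_identity_matrix_reaches_ceiling(identity_matrix):
    genes = [_random_gene(f"g{i}", 60, seed=i + 3) for i in range(2)]
    d = optimize_pool(
        genes, identity_matrix, SAParams(n_steps=10, n_restarts=1), TOY_CFG, F=2
    )
    assert d.predicted_fidelity == 1.0


def test_optimize_deterministic_under_seeds(synthetic_matrix):
    genes = [_random_gene(f"g{i}", 60, seed=i + 3) for i in range(2)]
    params = SAParams(n_steps=200, n_restarts=3, base_seed=5)
    a = optimize_pool(genes, synthetic_matrix, params, TOY_CFG, F=2)
    b = optimize_pool(genes, synthetic_matrix, params, TOY_CFG, F=2)
    assert a.plan.breakpoints == b.plan.breakpoints
    assert a.predicted_fidelity == b.predicted_fidelity
    assert a.seed == b.seed


def test_best_trace_monotone_and_final_beats_initial(synthetic_matrix):
    genes = [_random_gene(f"g{i}", 90, seed=i) for i in range(3)]
    d = optimize_pool(
        genes,
        synthetic_matrix,
        SAParams(n_steps=300, n_restarts=4),
        TOY_CFG,
        F=2,
        track_history=True,
    )
    for trace in d.history:
        assert all(b >= a for a, b in zip(trace, trace[1:]))
        assert trace[-1] >= trace[0]
    assert d.predicted_fidelity >= d.history[0][0]
    d.plan.validate(TOY_CFG)


def _brute_set_fidelity(overhangs, backbone, matrix):
    """Independent product-of-ratios oracle (dict arithmetic, no numpy)."""
    members = list(overhangs) + list(backbone)
    species = []
    for x in members:
        for sp in (x, revcomp(x)):
            if sp not in species:
                species.append(sp)
    fid = 1.0
    for o in members:
        num = matrix[o, revcomp(o)] + matrix[revcomp(o), o]
        den = sum(matrix[o, p] + matrix[revcomp(o), p] for p in species)
        fid *= num / den
    return fid


def _legal(overhangs, backbone):
    claimed = set()
    for b in backbone:
        claimed |= {b, revcomp(b)}
    for o in overhangs:
        if is_palindromic(o) or o in claimed or revcomp(o) in claimed:
            return False
        claimed |= {o, revcomp(o)}
    return True


def test_sa_matches_exhaustive_enumeration(synthetic_matrix):
    """Two genes x one junction, ~800 legal combinations: annealing at the
    published schedule recovers the enumerated optimum exactly."""
    m = LigationMatrix.make_synthetic(0.9, seed=7)
    genes = [_random_gene("a", 60, seed=3), _random_gene("b", 60, seed=4)]
    bb = TOY_CFG.backbone
    window = _legal_window(60, [30], 0, TOY_CFG, 4)
    best = -1.0
    for p1 in window:
        for p2 in window:
            ovs = (genes[0].seq[p1 : p1 + 4], genes[1].seq[p2 : p2 + 4])
            if _legal(ovs, bb):
                best = max(best, _brute_set_fidelity(ovs, bb, m))
    d = optimize_pool(
        genes, m, SAParams(n_steps=2000, n_restarts=10), TOY_CFG, F=2
    )
    assert d.predicted_fidelity == pytest.approx(best, abs=1e-12)


def test_single_junction_restarts_all_reach_optimum():
    """With one designable junction the optimum is a coordinate-wise search
    away, so essentially every restart should land on it."""
    m = LigationMatrix.make_synthetic(0.9, seed=7)
    gene = _random_gene("a", 60, seed=3)
    bb = TOY_CFG.backbone
    window = _legal_window(60, [30], 0, TOY_CFG, 4)
    best = max(
        _brute_set_fidelity((gene.seq[p : p + 4],), bb, m)
        for p in window
        if _legal((gene.seq[p : p + 4],), bb)
    )
    d = optimize_pool(
        gene and [gene],
        m,
        SAParams(n_steps=500, n_restarts=10),
        TOY_CFG,
        F=2,
        track_history=True,
    )
    finals = [t[-1] for t in d.history]
    hit = sum(math.isclose(f, best, abs_tol=1e-12) for f in finals)
    assert hit >= 9  # >= 90% of restarts
    assert d.predicted_fidelity == pytest.approx(best, abs=1e-12)


def test_diverse_pair_picks_most_distant():
    sets = [
        ["AAAC", "CCAA"],
        ["AAAC", "CCAG"],  # 1 mismatch from set 0
        ["GGTA", "TTCG"],  # far from both
    ]
    assert diverse_pair(sets) in {(0, 2), (1, 2)}
    with pytest.raises(ValueError):
        diverse_pair([["AAAC"]])
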