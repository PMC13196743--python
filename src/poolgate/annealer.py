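"""Simulated-annealing choice of fragmentation breakpoints.

Every gene in a subpool is cut at F-1 breakpoints; the 4-mer starting at each
breakpoint becomes the Golden Gate overhang joining the adjacent fragments.
Different breakpoint choices induce different overhang sets with very
different predicted fidelities, and the combinatorial space is far too large
to enumerate, so breakpoints are annealed: one random junction is relocated
per step, and worsening moves are accepted with probability exp(dF/T) under a
geometric temperature schedule.  The anneal is restarted from independent
seeds and the best run kept.

Conventions: breakpoints are 0-based indices into the coding sequence; the
overhang is ``seq[p:p+4]``; the upstream fragment ends at ``p+4`` and the
downstream fragment begins at ``p`` (adjacent fragments share the 4-bp
junction).  Terminal fragments additionally carry the two backbone overhangs
as their outer 4-mers.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import LayoutConfig, SAParams
from .layout import GeneRecord, fragments_per_gene
from .ligation import (
    FidelityScorer,
    JunctionSet,
    LigationMatrix,
    is_palindromic,
    revcomp,
)

__all__ = [
    "FragmentationPlan",
    "SubpoolDesign",
    "InitializationError",
    "initialize_plan",
    "propose_move",
    "acceptance_probability",
    "accept",
    "temperature_at",
    "optimize_pool",
    "diverse_pair",
]


class InitializationError(ValueError):
    """No conflict-free starting breakpoints exist within the legal windows."""


@dataclass
class FragmentationPlan:
    """Per-gene ordered breakpoints plus the sequences they cut.

    ``genes`` preserves pool input order (dict insertion order), which fixes
    the deterministic junction ordering used everywhere downstream.
    """

    genes: dict[str, str]
    breakpoints: dict[str, list[int]]
    backbone: tuple[str, str] | None = ("AATG", "TTAG")

    # -- junction views ---------------------------------------------------
    def overhang_at(self, gene_id: str, pos: int) -> str:
        return self.genes[gene_id][pos : pos + 4]

    def junction_items(self) -> list[tuple[str, int, int, str]]:
        """(gene_id, junction_index, position, overhang) in canonical order."""
        out = []
        for gid, bps in self.breakpoints.items():
            for j, p in enumerate(bps):
                out.append((gid, j, p, self.overhang_at(gid, p)))
        return out

    def junction_list(self) -> list[str]:
        return [ov for _, _, _, ov in self.junction_items()]

    def junction_set(self) -> JunctionSet:
        return JunctionSet(self.junction_list(), backbone=self.backbone)

    def claimed_species(self, exclude: tuple[str, int] | None = None) -> set[str]:
        """All overhang species in play (junctions + backbone, both strands),
        optionally excluding one junction's own pair."""
        species: set[str] = set()
        for gid, j, _, ov in self.junction_items():
            if exclude is not None and (gid, j) == exclude:
                continue
            species.add(ov)
            species.add(revcomp(ov))
        if self.backbone:
            for b in self.backbone:
                species.add(b)
                species.add(revcomp(b))
        return species

    # -- fragments --------------------------------------------------------
    def fragments(self, gene_id: str) -> list[str]:
        """Fragment sequences including shared 4-bp junctions and, on the
        terminal fragments, the backbone overhangs as outer 4-mers."""
        seq = self.genes[gene_id]
        left, right = self.backbone if self.backbone else ("", "")
        construct = left + seq + right
        offset = len(left)
        cuts = [p + offset for p in self.breakpoints[gene_id]]
        starts = [0] + cuts
        ends = [c + 4 for c in cuts] + [len(construct)]
        return [construct[s:e] for s, e in zip(starts, ends)]

    def construct(self, gene_id: str) -> str:
        left, right = self.backbone if self.backbone else ("", "")
        return left + self.genes[gene_id] + right

    # -- validation -------------------------------------------------------
    def validate(self, cfg: LayoutConfig) -> None:
        """Check breakpoint ordering, fragment length bounds, and the
        induced junction-set invariants; raises ``ValueError`` on the first
        violation."""
        for gid, bps in self.breakpoints.items():
            L = len(self.genes[gid])
            if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
                raise ValueError(f"gene {gid}: breakpoints not strictly increasing")
            if bps and not (0 <= bps[0] and bps[-1] <= L - 4):
                raise ValueError(f"gene {gid}: breakpoint outside sequence")
            for i, frag in enumerate(self.fragments(gid)):
                if not (cfg.min_fragment_len <= len(frag) <= cfg.payload):
                    raise ValueError(
                        f"gene {gid} fragment {i}: length {len(frag)} outside "
                        f"[{cfg.min_fragment_len}, {cfg.payload}]"
                    )
        self.junction_set().validate()


def _legal_window(
    L: int, bps: Sequence[int], j: int, cfg: LayoutConfig, flank: int
) -> range:
    """Inclusive legal positions for breakpoint j given its fixed neighbours.

    Both flanking fragments must stay within [min_fragment_len, payload];
    terminal fragments carry ``flank`` extra backbone bases.
    """
    lo = 0
    hi = L - 4
    if j == 0:
        lo = max(lo, cfg.min_fragment_len - 4 - flank)
        hi = min(hi, cfg.payload - 4 - flank)
    else:
        lo = max(lo, bps[j - 1] + cfg.min_fragment_len - 4)
        hi = min(hi, bps[j - 1] + cfg.payload - 4)
    if j == len(bps) - 1:
        # last fragment is gene[b_j:] + 3' flank: length L - b_j + flank
        lo = max(lo, L + flank - cfg.payload)
        hi = min(hi, L + flank - cfg.min_fragment_len)
    else:
        lo = max(lo, bps[j + 1] - cfg.payload + 4)
        hi = min(hi, bps[j + 1] - cfg.min_fragment_len + 4)
    return range(lo, hi + 1)


def _candidate_ok(ov: str, claimed: set[str]) -> bool:
    return (
        len(ov) == 4
        and not is_palindromic(ov)
        and ov not in claimed
        and revcomp(ov) not in claimed
    )


def initialize_plan(
    genes: Sequence[GeneRecord], F: int, cfg: LayoutConfig
) -> FragmentationPlan:
    """Deterministic starting plan: equal-length fragments, with clashing
    junctions (duplicate, reverse-complement, palindromic, or backbone-
    colliding 4-mers) resolved by alternating +-1, +-2, ... shifts inside the
    legal window, scanning genes in input order.
    """
    backbone = cfg.backbone if cfg.n_backbone else None
    flank = 4 if backbone else 0
    plan = FragmentationPlan(
        genes={g.id: g.seq for g in genes},
        breakpoints={g.id: [] for g in genes},
        backbone=backbone,
    )
    claimed = plan.claimed_species()  # backbone only at this point
    for g in genes:
        L = len(g.seq)
        bps = [round(i * L / F) for i in range(1, F)]
        for j in range(len(bps)):
            window = _legal_window(L, bps, j, cfg, flank)
            p0 = bps[j]
            chosen = None
            # alternating +1, -1, +2, -2, ... realised as nearest-first scan
            for p in sorted(window, key=lambda p: (abs(p - p0), p < p0)):
                if _candidate_ok(g.seq[p : p + 4], claimed):
                    chosen = p
                    break
            if chosen is None:
                raise InitializationError(
                    f"gene {g.id}, junction {j}: no conflict-free overhang "
                    f"in window [{window.start}, {window.stop - 1}]"
                )
            bps[j] = chosen
            ov = g.seq[chosen : chosen + 4]
            claimed.add(ov)
            claimed.add(revcomp(ov))
        plan.breakpoints[g.id] = bps
    return plan


def propose_move(
    plan: FragmentationPlan, cfg: LayoutConfig, rng: np.random.Generator
) -> tuple[str, int, int] | None:
    """Relocate one randomly chosen breakpoint to a uniformly sampled
    alternative legal position whose induced 4-mer keeps the junction set
    invariant-clean.  Junctions with no alternative are resampled; if every
    junction is frozen, returns None (no-move signal).
    """
    flank = 4 if plan.backbone else 0
    items = plan.junction_items()
    if not items:
        return None
    for idx in rng.permutation(len(items)):
        gid, j, cur, _ = items[idx]
        bps = plan.breakpoints[gid]
        claimed = plan.claimed_species(exclude=(gid, j))
        seq = plan.genes[gid]
        window = _legal_window(len(seq), bps, j, cfg, flank)
        options = [
            p
            for p in window
            if p != cur and _candidate_ok(seq[p : p + 4], claimed)
        ]
        if options:
            return gid, j, options[int(rng.integers(len(options)))]
    return None


def acceptance_probability(delta_fidelity: float, T: float) -> float:
    """Metropolis rule on the fidelity change: improvements always accepted,
    worsenings with probability exp(delta/T)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if delta_fidelity >= 0:
        return 1.0
    return math.exp(delta_fidelity / T)


def accept(delta_fidelity: float, T: float, rng: np.random.Generator) -> bool:
    p = acceptance_probability(delta_fidelity, T)
    return p >= 1.0 or rng.random() < p


def temperature_at(k: int, params: SAParams) -> float:
    """Geometric interpolation from t_high (step 0) to t_low (last step)."""
    if not 0 <= k <= params.n_steps - 1:
        raise ValueError(f"step {k} outside [0, {params.n_steps - 1}]")
    if params.n_steps == 1:
        return params.t_high
    frac = k / (params.n_steps - 1)
    return params.t_high * (params.t_low / params.t_high) ** frac


@dataclass
class SubpoolDesign:
    """One optimized subpool: genes, breakpoints, junctions, and provenance.

    ``predicted_fidelity`` is exactly ``set_fidelity`` recomputed on the
    final junction set; ``seed`` is the restart seed that won.
    """

    pool_index: int
    gene_ids: list[str]
    plan: FragmentationPlan
    junction_set: JunctionSet
    predicted_fidelity: float
    seed: int
    n_fragments: int
    primer_pair: str | None = None
    history: list[list[float]] | None = None

    def manifest_row(self) -> dict:
        return {
            "pool": self.pool_index,
            "gene_ids": ",".join(self.gene_ids),
            "fidelity": self.predicted_fidelity,
            "junctions": ",".join(self.junction_set.junctions),
            "backbone": ",".join(self.junction_set.backbone or ()),
            "seed": self.seed,
            "primer_pair": self.primer_pair if self.primer_pair else "",
        }


def _anneal(
    plan: FragmentationPlan,
    scorer: FidelityScorer,
    params: SAParams,
    cfg: LayoutConfig,
    rng: np.random.Generator,
) -> tuple[float, dict[str, list[int]], list[float]]:
    current = scorer.score(plan.junction_list())
    best = current
    best_bps = copy.deepcopy(plan.breakpoints)
    trace = [best]
    for k in range(params.n_steps):
        T = temperature_at(k, params)
        move = propose_move(plan, cfg, rng)
        if move is None:
            break
        gid, j, new_pos = move
        old_pos = plan.breakpoints[gid][j]
        plan.breakpoints[gid][j] = new_pos
        proposed = scorer.score(plan.junction_list())
        if accept(proposed - current, T, rng):
            current = proposed
        else:
            plan.breakpoints[gid][j] = old_pos
        if current > best:
            best = current
            best_bps = copy.deepcopy(plan.breakpoints)
        trace.append(best)
    return best, best_bps, trace


def optimize_pool(
    genes: Sequence[GeneRecord],
    matrix: LigationMatrix,
    params: SAParams,
    cfg: LayoutConfig,
    F: int | None = None,
    pool_index: int = 0,
    primer_pair: str | None = None,
    track_history: bool = False,
) -> SubpoolDesign:
    """Anneal one subpool ``params.n_restarts`` times from seeds
    ``base_seed + r`` and return the highest-fidelity design (ties broken by
    the lowest seed).  Fully reproducible from (genes, matrix, params, cfg).
    """
    cfg.validate()
    params.validate()
    if F is None:
        F = fragments_per_gene(max(len(g) for g in genes), cfg)
    init = initialize_plan(genes, F, cfg)
    scorer = FidelityScorer(
        matrix,
        init.backbone,
        include_backbone=cfg.fidelity_includes_backbone,
    )
    best_fid = -1.0
    best_bps: dict[str, list[int]] | None = None
    best_seed = -1
    history: list[list[float]] = []
    for r in range(params.n_restarts):
        seed = params.base_seed + r
        rng = np.random.default_rng(seed)
        plan_r = FragmentationPlan(
            genes=dict(init.genes),
            breakpoints=copy.deepcopy(init.breakpoints),
            backbone=init.backbone,
        )
        fid, bps, trace = _anneal(plan_r, scorer, params, cfg, rng)
        if track_history:
            history.append(trace)
        if fid > best_fid:
            best_fid = fid
            best_bps = bps
            best_seed = seed
    final = FragmentationPlan(
        genes=dict(init.genes), breakpoints=best_bps, backbone=init.backbone
    )
    final.validate(cfg)
    jset = final.junction_set()
    return SubpoolDesign(
        pool_index=pool_index,
        gene_ids=[g.id for g in genes],
        plan=final,
        junction_set=jset,
        predicted_fidelity=scorer.score(final.junction_list()),
        seed=best_seed,
        n_fragments=F,
        primer_pair=primer_pair,
        history=history if track_history else None,
    )


def diverse_pair(junction_sets: Sequence[Sequence[str]]) -> tuple[int, int]:
    """Among N same-size junction lists, pick the pair maximizing the summed
    per-site Hamming distance between their sorted junction lists — used to
    select maximally different replicate designs of the same pool."""
    if len(junction_sets) < 2:
        raise ValueError("need at least two junction sets")
    sorted_sets = [sorted(js) for js in junction_sets]
    n = len(sorted_sets[0])
    if any(len(s) != n for s in sorted_sets):
        raise ValueError("junction sets must have equal size")

    def dist(a: list[str], b: list[str]) -> int:
        return sum(
            sum(x != y for x, y in zip(sa, sb)) for sa, sb in zip(a, b)
        )

    best = (0, 1)
    best_d = -1
    for i in range(len(sorted_sets)):
        for j in range(i + 1, len(sorted_sets)):
            d = dist(sorted_sets[i], sorted_sets[j])
            if d > best_d:
                best_d = d
                best = (i, j)
    return best
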