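"""In-silico multiplexed Golden Gate reaction.

A deliberately minimal kinetic model whose purpose is to validate the
product-of-probabilities fidelity prediction, not mechanistic realism:
junction choices are independent, there is no re-ligation and no
concentration effect.  Each simulated event grows one construct from the
vector's 5' backbone overhang; at every exposed overhang ``o`` a partner
species ``p`` is drawn with probability proportional to
``m(o, p) + m(revcomp(o), p)`` over the species present, exactly mirroring
the fidelity model's denominator, so the pool-mean correct fraction converges
to ``expected_yield``.  Dead-end events (a partner species carried by no
fragment end) count as incorrect outcomes, the way misassemblies appear in
reads.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annealer import SubpoolDesign
from .config import LayoutConfig, Enzyme
from .emitter import OligoRecord, digest_oligo, scan_enzyme_sites
from .ligation import (
    DegenerateMatrixError,
    FidelityScorer,
    LigationMatrix,
    revcomp,
)

__all__ = [
    "AssemblyOutcome",
    "simulate_reaction",
    "expected_yield",
    "perfect_roundtrip",
    "RoundtripError",
]


@dataclass(frozen=True)
class AssemblyOutcome:
    """One distinct product: the ordered fragment ids actually joined."""

    code: tuple[str, ...]
    count: int
    is_correct: bool


class RoundtripError(ValueError):
    pass


def _fragment_ends(design: SubpoolDesign):
    """Per-fragment (id, left 4-mer, right 4-mer, sequence) plus the designed
    per-gene codes."""
    frags = []
    codes = {}
    for gid in design.gene_ids:
        parts = design.plan.fragments(gid)
        ids = [f"{gid}/{i}" for i in range(len(parts))]
        codes[gid] = tuple(ids)
        for fid, seq in zip(ids, parts):
            frags.append((fid, seq[:4], seq[-4:], seq))
    return frags, codes


def simulate_reaction(
    design: SubpoolDesign,
    matrix: LigationMatrix,
    n_events: int,
    seed: int,
    digest_products: bool = False,
    cut_survival: float = 0.1,
    enzyme: Enzyme = Enzyme(),
) -> list[AssemblyOutcome]:
    """Simulate ``n_events`` stochastic assembly events in one subpool.

    With ``digest_products`` on, any finished construct whose joined sequence
    contains an internal recognition site is re-cut and survives only with
    probability ``cut_survival`` (re-cut events are pooled under the code
    ``("<digested>",)``), emulating the depletion of site-containing designs.
    """
    if design.junction_set.backbone is None:
        raise ValueError("simulation requires backbone (vector) overhangs")
    rng = np.random.default_rng(seed)
    frags, designed_codes = _fragment_ends(design)
    code_set = set(designed_codes.values())
    bb5, bb3 = design.junction_set.backbone

    species = design.junction_set.species()
    M = matrix
    # partner-sampling weights per exposed overhang, cached
    weight_cache: dict[str, np.ndarray] = {}

    sp_index = {s: i for i, s in enumerate(species)}

    def cum_weights(o: str) -> np.ndarray:
        w = weight_cache.get(o)
        if w is None:
            rco = revcomp(o)
            w = np.array([M[o, p] + M[rco, p] for p in species])
            # the two orientation entries of one duplex belong to one event:
            # pool m(o,rc(o))+m(rc(o),o) as the correct-partner mass and
            # m(o,o)+m(rc(o),rc(o)) as the self-pairing mass, so the correct
            # probability equals junction_fidelity exactly for any matrix
            w[sp_index[rco]] = M[o, rco] + M[rco, o]
            if o in sp_index:
                w[sp_index[o]] = M[o, o] + M[rco, rco]
            total = w.sum()
            if total == 0:
                raise DegenerateMatrixError(
                    f"no ligation mass from exposed overhang {o}"
                )
            w = np.cumsum(w / total)
            weight_cache[o] = w
        return w

    by_left: dict[str, list[int]] = defaultdict(list)
    for i, (_, left, _, _) in enumerate(frags):
        by_left[left].append(i)

    max_joins = 4 * max(len(c) for c in code_set) if code_set else 8
    tally: Counter[tuple[tuple[str, ...], bool]] = Counter()
    for _ in range(n_events):
        code: list[str] = []
        joined_seq = bb5
        open_ov = bb5
        closed = False
        while len(code) <= max_joins:
            cw = cum_weights(open_ov)
            p = species[int(np.searchsorted(cw, rng.random() * cw[-1]))]
            target_left = revcomp(p)
            if target_left == bb3:
                closed = True  # ligated into the vector 3' site
                break
            cand = by_left.get(target_left)
            if not cand:
                break  # dead end
            i = cand[int(rng.integers(len(cand)))]
            fid, _, right, seq = frags[i]
            code.append(fid)
            joined_seq = joined_seq + seq[4:]
            open_ov = right
        is_correct = closed and tuple(code) in code_set
        key: tuple[str, ...] = tuple(code)
        if digest_products and closed:
            if scan_enzyme_sites(joined_seq, enzyme) and rng.random() > cut_survival:
                key = ("<digested>",)
                is_correct = False
        tally[(key, is_correct)] += 1
    return [
        AssemblyOutcome(code=c, count=n, is_correct=ok)
        for (c, ok), n in sorted(tally.items(), key=lambda kv: -kv[1])
    ]


def expected_yield(
    design: SubpoolDesign,
    matrix: LigationMatrix,
    include_backbone: bool = True,
) -> tuple[dict[str, float], float]:
    """Model-predicted per-gene correct-assembly probability and pool mean.

    Per gene: the product of that gene's own junction fidelities, times both
    backbone-site fidelities when ``include_backbone`` (every construct uses
    both vector ligations).
    """
    jset = design.junction_set
    scorer = FidelityScorer(matrix, jset.backbone, include_backbone=True)
    fids = scorer.junction_fidelities(jset.junctions)
    n_j = len(jset.junctions)
    bb_factor = float(np.prod(fids[n_j:])) if include_backbone else 1.0
    per_junction = dict(zip(range(n_j), fids[:n_j]))
    items = design.plan.junction_items()
    per_gene: dict[str, float] = {}
    for gid in design.gene_ids:
        idxs = [k for k, (g, _, _, _) in enumerate(items) if g == gid]
        per_gene[gid] = bb_factor * float(
            np.prod([per_junction[k] for k in idxs])
        )
    pool_mean = float(np.mean(list(per_gene.values())))
    return per_gene, pool_mean


def perfect_roundtrip(
    oligos: "Sequence[OligoRecord] | pd.DataFrame",
    cfg: LayoutConfig,
    reference: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Digest every oligo and rejoin fragments by exact overhang identity
    (the identity-matrix limit), reconstructing each pool's genes.

    Chains start at every fragment whose left 4-mer is the 5' backbone
    overhang and follow unique overhang matches until the 3' backbone
    overhang.  With ``reference`` given, any missing/extra/mismatching gene
    raises ``RoundtripError`` with a diff report — this failing is a release
    blocker.
    """
    if isinstance(oligos, pd.DataFrame):
        records = [
            (int(r.pool), str(r.gene_id), int(r.frag_idx), str(r.sequence))
            for r in oligos.itertuples()
        ]
    else:
        records = [(o.pool, o.gene_id, o.frag_idx, o.sequence) for o in oligos]

    bb5, bb3 = cfg.backbone
    pools: dict[int, list[str]] = defaultdict(list)
    for pool, _, _, seq in records:
        pools[pool].append(digest_oligo(seq, cfg.enzyme))

    out: dict[str, str] = {}
    problems: list[str] = []
    for pool, frags in sorted(pools.items()):
        by_left: dict[str, list[str]] = defaultdict(list)
        for f in frags:
            by_left[f[:4]].append(f)
        starts = by_left.get(bb5, [])
        for start in starts:
            seq = start
            used = 1
            while not seq.endswith(bb3):
                nxt = by_left.get(seq[-4:], [])
                if len(nxt) != 1:
                    problems.append(
                        f"pool {pool}: chain from {start[:12]}... stalls at "
                        f"overhang {seq[-4:]} ({len(nxt)} continuations)"
                    )
                    seq = ""
                    break
                seq = seq + nxt[0][4:]
                used += 1
                if used > len(frags):
                    problems.append(f"pool {pool}: cyclic chain from {start[:12]}...")
                    seq = ""
                    break
            if seq:
                gene = seq[len(bb5) : len(seq) - len(bb3)]
                out[f"pool{pool}:{len(out)}"] = gene

    if reference is not None:
        rebuilt = Counter(out.values())
        wanted = Counter(reference.values())
        missing = wanted - rebuilt
        extra = rebuilt - wanted
        for seq, n in missing.items():
            ids = [k for k, v in reference.items() if v == seq]
            problems.append(f"missing {n}x gene(s) {ids}")
        for seq, n in extra.items():
            problems.append(f"unexpected reconstructed sequence ({n}x, {len(seq)} nt)")
        if problems:
            raise RoundtripError("round trip failed:\n" + "\n".join(problems))
        # relabel by reference id for convenience
        seq_to_ids = defaultdict(list)
        for k, v in reference.items():
            seq_to_ids[v].append(k)
        relabeled = {}
        for v in out.values():
            relabeled[seq_to_ids[v].pop(0)] = v
        return relabeled
    if problems:
        raise RoundtripError("round trip failed:\n" + "\n".join(problems))
    return out
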