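"""Library layout arithmetic: fragments per gene, subpool capacity under a
junction budget, and the randomized near-uniform partition of genes into
subpools.

Every gene in a library is split into the same number of fragments, sized by
the longest gene — equal fragment counts keep assembly efficiency (and hence
library bias) comparable across constructs.  The junction budget per subpool
then fixes how many genes can be multiplexed in one reaction, and genes are
dealt into pools at random, irrespective of sequence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .config import LayoutConfig

__all__ = [
    "GeneRecord",
    "PoolLayout",
    "read_fasta",
    "fragments_per_gene",
    "pool_capacity",
    "partition_library",
    "search_space_size",
    "GeneTooLongError",
    "BudgetTooSmallError",
]


class GeneTooLongError(ValueError):
    pass


class BudgetTooSmallError(ValueError):
    pass


@dataclass(frozen=True)
class GeneRecord:
    """One codon-optimized coding sequence (A/C/G/T only, unique id)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - set("ACGT")
        if bad:
            raise ValueError(
                f"gene {self.id!r} contains non-ACGT characters {sorted(bad)}"
            )
        if not self.seq:
            raise ValueError(f"gene {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path) -> list[GeneRecord]:
    """Read genes from FASTA (wrapped or single-line); ids must be unique."""
    genes = [GeneRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    ids = [g.id for g in genes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate FASTA ids: {dupes}")
    return genes


def fragments_per_gene(max_gene_len: int, cfg: LayoutConfig) -> int:
    """Smallest fragment count F such that the longest gene fits: adjacent
    fragments share the 4-bp junction, so F fragments cover
    ``max_gene_len + 4*(F-1)`` bases and each must fit the oligo payload.

    ``cfg.fragments_override``, if set, wins unconditionally.
    """
    if max_gene_len <= 0:
        raise ValueError("max_gene_len must be positive")
    if cfg.fragments_override is not None:
        return cfg.fragments_override
    payload = cfg.payload
    for F in range(1, cfg.max_fragments + 1):
        if math.ceil((max_gene_len + cfg.overhang_len * (F - 1)) / F) <= payload:
            return F
    raise GeneTooLongError(
        f"a {max_gene_len}-nt gene needs more than {cfg.max_fragments} "
        f"fragments at payload {payload} nt"
    )


def pool_capacity(F: int, cfg: LayoutConfig) -> int:
    """Genes per subpool under the junction budget.

    Each F-fragment gene consumes F-1 designable junctions; the two backbone
    (vector) sites are counted inside the budget when
    ``cfg.budget_includes_backbone`` (the default) and outside otherwise.
    """
    if F < 2:
        raise ValueError(
            "pool_capacity requires F >= 2; single-fragment genes need no "
            "junctions and are capped only by cfg.max_pool_size"
        )
    budget = cfg.gg_budget
    if cfg.budget_includes_backbone:
        budget -= cfg.n_backbone
    cap = budget // (F - 1)
    if cap < 1:
        raise BudgetTooSmallError(
            f"budget {cfg.gg_budget} cannot host even one {F}-fragment gene"
        )
    return cap


@dataclass
class PoolLayout:
    """The gene-to-subpool assignment for one library."""

    n_fragments_per_gene: int
    genes_per_pool_max: int
    n_pools: int
    assignment: dict[str, int]
    pools: list[list[str]] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.assignment.items()), columns=["gene_id", "pool_index"]
        ).to_csv(path, sep="\t", index=False)


def partition_library(
    genes: Sequence["GeneRecord | str"],
    capacity: int,
    seed: int,
    n_fragments: int = 1,
    max_pools: int = 92,
) -> PoolLayout:
    """Randomly deal genes into ``ceil(n/capacity)`` subpools.

    A seeded shuffle followed by a round-robin deal distributes genes
    uniformly and guarantees the pool with the most genes has at most one
    more than the pool with the fewest.  Deterministic for a fixed seed.
    """
    if not genes:
        raise ValueError("cannot partition an empty gene list")
    if capacity < 1:
        raise ValueError("capacity must be >= 1")
    ids = [g if isinstance(g, str) else g.id for g in genes]
    n_pools = math.ceil(len(ids) / capacity)
    if n_pools > max_pools:
        warnings.warn(
            f"{n_pools} subpools exceeds the {max_pools}-subpool cap; "
            "emission will refuse this layout",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    pools: list[list[str]] = [[] for _ in range(n_pools)]
    for i, gid in enumerate(order):
        pools[i % n_pools].append(gid)
    assignment = {gid: p for p, pool in enumerate(pools) for gid in pool}
    return PoolLayout(
        n_fragments_per_gene=n_fragments,
        genes_per_pool_max=max(len(p) for p in pools),
        n_pools=n_pools,
        assignment=assignment,
        pools=pools,
    )


def search_space_size(
    n_genes: int, breakpoints_per_gene: int, options_per_breakpoint: int
) -> tuple[int, int | None]:
    """Size of the raw junction-combination space (repeats allowed) as an
    exact big integer, with its floor-log10 (None for zero).

    A modest pool — 10 genes x 3 breakpoints x 25 options each — already has
    ~1e41 combinations, which is why the optimizer anneals instead of
    enumerating.
    """
    if min(n_genes, breakpoints_per_gene, options_per_breakpoint) < 0:
        raise ValueError("arguments must be non-negative")
    value = options_per_breakpoint ** (n_genes * breakpoints_per_gene)
    log10 = len(str(value)) - 1 if value > 0 else None
    return value, log10
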