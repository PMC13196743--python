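"""End-to-end library design: validate genes, size fragments from the
longest gene, partition into subpools, anneal each subpool's junctions, and
emit the order-ready oligos plus the manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .annealer import FragmentationPlan, SubpoolDesign, optimize_pool
from .config import DesignConfig, LayoutConfig, SAParams
from .emitter import (
    OligoRecord,
    PrimerPair,
    emit_library,
    oligos_to_frame,
    validate_genes,
)
from .fixtures import placeholder_primer_table
from .layout import (
    GeneRecord,
    PoolLayout,
    fragments_per_gene,
    partition_library,
    pool_capacity,
)
from .ligation import JunctionSet, LigationMatrix

log = logging.getLogger("poolgate")

#: seed offset between subpools so restart seeds never collide across pools
_POOL_SEED_STRIDE = 100_000


@dataclass
class LibraryDesign:
    layout: PoolLayout
    designs: list[SubpoolDesign]
    oligos: list[OligoRecord]
    manifest: pd.DataFrame

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        oligos_to_frame(self.oligos).to_csv(outdir / "oligo_order.csv", index=False)
        self.manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
        self.layout.to_tsv(outdir / "pool_layout.tsv")
        plans = {
            d.pool_index: {
                "genes": d.plan.genes,
                "breakpoints": d.plan.breakpoints,
                "backbone": list(d.plan.backbone or ()),
                "fidelity": d.predicted_fidelity,
                "seed": d.seed,
                "n_fragments": d.n_fragments,
                "primer_pair": d.primer_pair,
            }
            for d in self.designs
        }
        (outdir / "design.json").write_text(json.dumps(plans, indent=1))

    @staticmethod
    def load_designs(outdir: str | Path) -> list[SubpoolDesign]:
        data = json.loads((Path(outdir) / "design.json").read_text())
        designs = []
        for pool, d in sorted(data.items(), key=lambda kv: int(kv[0])):
            plan = FragmentationPlan(
                genes=d["genes"],
                breakpoints={k: list(v) for k, v in d["breakpoints"].items()},
                backbone=tuple(d["backbone"]) if d["backbone"] else None,
            )
            designs.append(
                SubpoolDesign(
                    pool_index=int(pool),
                    gene_ids=list(d["genes"]),
                    plan=plan,
                    junction_set=plan.junction_set(),
                    predicted_fidelity=d["fidelity"],
                    seed=d["seed"],
                    n_fragments=d["n_fragments"],
                    primer_pair=d.get("primer_pair"),
                )
            )
        return designs


def design_library(
    genes: Sequence[GeneRecord],
    matrix: LigationMatrix,
    cfg: LayoutConfig | None = None,
    sa: SAParams | None = None,
    primer_table: Sequence[PrimerPair] | None = None,
    seed: int = 0,
) -> LibraryDesign:
    """Run the full design pipeline and return oligos + manifest.

    ``seed`` drives the gene partition and the pad sampling; annealing seeds
    come from ``sa.base_seed`` offset per pool, so a (genes, matrix, cfg, sa,
    seed) tuple reproduces the library byte for byte.
    """
    if not genes:
        raise ValueError("no genes supplied")
    cfg = cfg or LayoutConfig()
    sa = sa or SAParams()
    cfg.validate()
    sa.validate()
    validate_genes(genes, cfg)

    F = fragments_per_gene(max(len(g) for g in genes), cfg)
    capacity = pool_capacity(F, cfg) if F >= 2 else cfg.max_pool_size
    layout = partition_library(
        genes, capacity, seed=seed, n_fragments=F, max_pools=cfg.max_pools
    )
    by_id = {g.id: g for g in genes}

    designs: list[SubpoolDesign] = []
    for pool_index, pool_ids in enumerate(layout.pools):
        pool_sa = SAParams(
            t_high=sa.t_high,
            t_low=sa.t_low,
            n_steps=sa.n_steps,
            n_restarts=sa.n_restarts,
            base_seed=sa.base_seed + pool_index * _POOL_SEED_STRIDE,
        )
        design = optimize_pool(
            [by_id[i] for i in pool_ids],
            matrix,
            pool_sa,
            cfg,
            F=F,
            pool_index=pool_index,
        )
        log.info(
            "pool %d: %d genes, %d junctions, predicted fidelity %.4f (seed %d)",
            pool_index,
            len(pool_ids),
            len(design.junction_set.junctions),
            design.predicted_fidelity,
            design.seed,
        )
        designs.append(design)

    if primer_table is None:
        primer_table = placeholder_primer_table(
            layout.n_pools, seed=seed + 1, primer_len=cfg.primer_len
        )
    oligos, manifest = emit_library(designs, primer_table, cfg, seed=seed + 2)
    return LibraryDesign(
        layout=layout, designs=designs, oligos=oligos, manifest=manifest
    )


def load_config(path: str | Path | None) -> DesignConfig:
    return DesignConfig.from_file(path) if path else DesignConfig()
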