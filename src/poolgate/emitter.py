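"""Order-ready oligo emission.

Each designed fragment is wrapped into a uniform-length oligo::

    fwd_primer . left_pad . GGTCTC . N . [overhang..fragment..overhang] . N . GAGACC . right_pad . rc(rev_primer)

The two BsaI recognition sites are convergently oriented so digestion
releases the payload with both 4-bp overhangs intact.  Random padding between
primer and recognition site brings every oligo to the same length; pads are
sampled base-by-base with rejection of any window that would form a
recognition site on either strand (including across block boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annealer import SubpoolDesign
from .config import LayoutConfig, Enzyme
from .layout import GeneRecord
from .ligation import revcomp

__all__ = [
    "OligoRecord",
    "PrimerPair",
    "EmissionError",
    "scan_enzyme_sites",
    "build_oligo",
    "digest_oligo",
    "validate_genes",
    "emit_library",
    "read_primer_table",
    "oligos_to_frame",
]

_BASES = "ACGT"


class EmissionError(ValueError):
    pass


@dataclass(frozen=True)
class PrimerPair:
    pair_id: str
    fwd: str
    rev: str


@dataclass(frozen=True)
class OligoRecord:
    """One order-ready oligo and where its gene payload sits inside it."""

    oligo_id: str
    pool: int
    gene_id: str
    frag_idx: int
    sequence: str
    payload_span: tuple[int, int]  # half-open span of overhang..fragment..overhang


def scan_enzyme_sites(
    seq: str, enzyme: Enzyme = Enzyme()
) -> list[tuple[int, str]]:
    """All recognition-site occurrences, 0-based: ``(position, '+')`` for the
    site on the given strand and ``(position, '-')`` for the site read on the
    reverse strand (i.e. occurrences of its reverse complement)."""
    hits: list[tuple[int, str]] = []
    for motif, strand in ((enzyme.recognition, "+"), (enzyme.recognition_rc, "-")):
        start = seq.find(motif)
        while start != -1:
            hits.append((start, strand))
            start = seq.find(motif, start + 1)
    return sorted(hits)


def _pad(
    n: int,
    rng: np.random.Generator,
    left_context: str,
    right_context: str,
    enzyme: Enzyme,
    max_tries: int = 200,
) -> str:
    """Random pad of length n forming no recognition site on either strand,
    including windows spanning into the fixed flanking context."""
    motifs = (enzyme.recognition, enzyme.recognition_rc)
    k = len(enzyme.recognition)
    for _ in range(max_tries):
        out: list[str] = []
        ok = True
        for _ in range(n):
            placed = False
            for _ in range(16):  # per-base rejection against the left window
                b = _BASES[int(rng.integers(4))]
                window = (left_context + "".join(out))[-(k - 1) :] + b
                if not any(m in window for m in motifs):
                    out.append(b)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if not ok:
            continue
        full = left_context[-(k - 1) :] + "".join(out) + right_context[: k - 1]
        if not any(m in full for m in motifs):
            return "".join(out)
    raise EmissionError(f"could not sample a {n}-nt recognition-free pad")


def build_oligo(
    fragment: str,
    primers: PrimerPair,
    cfg: LayoutConfig,
    rng: np.random.Generator,
    oligo_id: str = "oligo",
    pool: int = 0,
    gene_id: str = "",
    frag_idx: int = 0,
) -> OligoRecord:
    """Wrap one fragment (overhang ends included) into a full-length oligo.

    Pads split as evenly as possible, the left pad taking the extra base on
    odd totals.  Deterministic under the supplied generator.
    """
    enzyme = cfg.enzyme
    rec = enzyme.recognition
    overhead = 2 * (cfg.primer_len + len(rec) + enzyme.spacer_len)
    pad_total = cfg.oligo_len - overhead - len(fragment)
    if pad_total < 0:
        raise EmissionError(
            f"fragment of {len(fragment)} nt exceeds payload "
            f"{cfg.oligo_len - overhead} nt"
        )
    left_n = (pad_total + 1) // 2
    right_n = pad_total - left_n
    if len(primers.fwd) != cfg.primer_len or len(primers.rev) != cfg.primer_len:
        raise EmissionError("primer length does not match cfg.primer_len")

    # spacers are sampled along with the pads; build left-to-right so each
    # random base sees its true upstream context
    fwd = primers.fwd
    rev_tail = revcomp(primers.rev)
    for _ in range(50):
        lpad = _pad(left_n, rng, fwd, rec, enzyme)
        lspacer = _pad(enzyme.spacer_len, rng, fwd + lpad + rec, fragment, enzyme)
        rspacer = _pad(
            enzyme.spacer_len, rng, fragment, enzyme.recognition_rc, enzyme
        )
        rpad = _pad(right_n, rng, enzyme.recognition_rc, rev_tail, enzyme)
        seq = (
            fwd + lpad + rec + lspacer + fragment + rspacer
            + enzyme.recognition_rc + rpad + rev_tail
        )
        expected = {
            (len(fwd) + len(lpad), "+"),
            (
                len(fwd) + len(lpad) + len(rec) + len(lspacer) + len(fragment)
                + len(rspacer),
                "-",
            ),
        }
        if set(scan_enzyme_sites(seq, enzyme)) == expected:
            start = len(fwd) + len(lpad) + len(rec) + len(lspacer)
            return OligoRecord(
                oligo_id=oligo_id,
                pool=pool,
                gene_id=gene_id,
                frag_idx=frag_idx,
                sequence=seq,
                payload_span=(start, start + len(fragment)),
            )
    raise EmissionError(f"pad rejection cap exceeded for {oligo_id}")


def digest_oligo(seq: str, enzyme: Enzyme = Enzyme()) -> str:
    """In-silico Type IIS digestion: return the released payload with both
    overhangs.  Requires exactly one convergent site pair."""
    hits = scan_enzyme_sites(seq, enzyme)
    plus = [p for p, s in hits if s == "+"]
    minus = [p for p, s in hits if s == "-"]
    if len(plus) != 1 or len(minus) != 1 or plus[0] >= minus[0]:
        raise EmissionError(
            f"expected one convergent recognition-site pair, found {hits}"
        )
    start = plus[0] + len(enzyme.recognition) + enzyme.spacer_len
    end = minus[0] - enzyme.spacer_len
    return seq[start:end]


def validate_genes(
    genes: Sequence[GeneRecord],
    cfg: LayoutConfig,
    severity: str | None = None,
) -> dict[str, list[tuple[int, str]]]:
    """Scan each assembled construct (gene plus backbone context) for
    internal recognition sites.  Internal sites get re-cut during assembly
    and the construct is depleted, so in 'error' mode any hit aborts the
    design naming the offending genes."""
    severity = severity or cfg.bsai_severity
    left, right = cfg.backbone if cfg.n_backbone else ("", "")
    report = {}
    for g in genes:
        hits = scan_enzyme_sites(left + g.seq + right, cfg.enzyme)
        if hits:
            report[g.id] = hits
    if report and severity == "error":
        raise EmissionError(
            "internal recognition sites in assembled constructs: "
            + ", ".join(sorted(report))
        )
    return report


def read_primer_table(path: str | Path) -> list[PrimerPair]:
    """TSV with columns pair_id, fwd, rev."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"pair_id", "fwd", "rev"}
    if not required.issubset(df.columns):
        raise ValueError(f"primer table needs columns {sorted(required)}")
    return [
        PrimerPair(r.pair_id, r.fwd.upper(), r.rev.upper())
        for r in df.itertuples()
    ]


def oligos_to_frame(oligos: Sequence[OligoRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "oligo_id": o.oligo_id,
                "pool": o.pool,
                "gene_id": o.gene_id,
                "frag_idx": o.frag_idx,
                "sequence": o.sequence,
            }
            for o in oligos
        ]
    )


def emit_library(
    designs: Sequence[SubpoolDesign],
    primer_table: Sequence[PrimerPair],
    cfg: LayoutConfig,
    seed: int,
) -> tuple[list[OligoRecord], pd.DataFrame]:
    """Package every subpool design into the order-ready oligo list and the
    per-pool manifest.  One primer pair per subpool, drawn without
    replacement from the table in order; ``n_oligos = sum(pool genes x F)``.
    """
    if not designs:
        raise ValueError("no designs to emit")
    if len(designs) > cfg.max_pools:
        raise EmissionError(
            f"{len(designs)} subpools exceeds the {cfg.max_pools}-subpool cap"
        )
    if len(primer_table) < len(designs):
        raise EmissionError(
            f"primer table has {len(primer_table)} pairs for "
            f"{len(designs)} subpools"
        )
    rng = np.random.default_rng(seed)
    oligos: list[OligoRecord] = []
    manifest_rows = []
    for design, pair in zip(designs, primer_table):
        design.primer_pair = pair.pair_id
        for gid in design.gene_ids:
            for i, frag in enumerate(design.plan.fragments(gid)):
                oligos.append(
                    build_oligo(
                        frag,
                        pair,
                        cfg,
                        rng,
                        oligo_id=f"p{design.pool_index}_{gid}_f{i}",
                        pool=design.pool_index,
                        gene_id=gid,
                        frag_idx=i,
                    )
                )
        manifest_rows.append(design.manifest_row())
    manifest = pd.DataFrame(manifest_rows)
    return oligos, manifest
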