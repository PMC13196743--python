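"""Synthetic sequence sets emulating the stress conditions used to exercise
the designer: pools of controlled pairwise identity (identical / high /
medium), controlled GC content (20-80%, held within 1% of target), and
tandem-repeat proteins (DARPin-like, five repeat units).  Also a placeholder
table of orthogonal-looking subpool primers.

Generated sets are self-validating: generation retries until the achieved
statistics sit inside the requested band and the achieved values are
returned alongside the sequences.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import edlib
import numpy as np

from .config import Enzyme
from .emitter import PrimerPair
from .layout import GeneRecord

__all__ = [
    "SequenceSetSpec",
    "SequenceSet",
    "GenerationError",
    "gen_sequence_set",
    "mean_pairwise_identity",
    "gc_content",
    "placeholder_primer_table",
    "write_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class GenerationError(RuntimeError):
    pass


def gc_content(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _identity(a: str, b: str) -> float:
    if len(a) == len(b):
        return sum(x == y for x, y in zip(a, b)) / len(a)
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def mean_pairwise_identity(seqs: Sequence[str]) -> float:
    """Mean identity over all unordered pairs.  Equal-length sets use
    positional identity; unequal lengths fall back to a global-alignment
    identity (1 - edit distance / longer length)."""
    pairs = list(itertools.combinations(seqs, 2))
    if not pairs:
        return 1.0
    return float(np.mean([_identity(a, b) for a, b in pairs]))


@dataclass(frozen=True)
class SequenceSetSpec:
    """Recipe for one stress set.

    ``target_identity`` may be a single fraction (band = +-1 percentage
    point, exact for 1.0) or an explicit (lo, hi) band, e.g. (0.49, 0.50)
    for the medium-identity condition.  ``target_gc`` is held within 1
    percentage point of target.  Lengths default to the 714-nt four-fragment
    test sequence scale.
    """

    mode: str  # "identity" | "gc" | "repeat"
    n_sequences: int = 3
    length: int = 714
    target_identity: "float | tuple[float, float] | None" = None
    target_gc: float | None = None
    n_repeats: int = 5
    seed: int = 0

    def identity_band(self) -> tuple[float, float] | None:
        t = self.target_identity
        if t is None:
            return None
        if isinstance(t, tuple):
            return t
        if t >= 1.0:
            return (1.0, 1.0)
        return (max(0.0, t - 0.01), min(1.0, t + 0.01))


@dataclass
class SequenceSet:
    genes: list[GeneRecord]
    achieved_identity: float
    achieved_gc: float
    spec: SequenceSetSpec = field(repr=False, default=None)

    def validate(self) -> None:
        band = self.spec.identity_band()
        if band and not band[0] - 1e-9 <= self.achieved_identity <= band[1] + 1e-9:
            raise GenerationError(
                f"identity {self.achieved_identity:.4f} outside band {band}"
            )
        if self.spec.target_gc is not None and abs(
            self.achieved_gc - self.spec.target_gc
        ) > 0.01:
            raise GenerationError(
                f"GC {self.achieved_gc:.4f} not within 1% of {self.spec.target_gc}"
            )


def _random_seq(L: int, rng: np.random.Generator, gc: float | None = None) -> str:
    if gc is None:
        return "".join(rng.choice(list("ACGT"), size=L))
    n_gc = round(L * gc)
    arr = np.array(
        list(
            "".join(rng.choice(list("GC"), size=n_gc))
            + "".join(rng.choice(list("AT"), size=L - n_gc))
        )
    )
    rng.shuffle(arr)
    return "".join(arr)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position with probability ``rate`` to a uniformly
    chosen different base."""
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < rate
    for i in np.flatnonzero(mask):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def _fix_gc(seq: str, target: float, rng: np.random.Generator) -> str:
    """Flip bases between the AT and GC classes until within 1% of target."""
    arr = np.array(list(seq))
    L = len(arr)
    for _ in range(L):
        gc = (np.isin(arr, list("GC"))).mean()
        if abs(gc - target) <= 0.009:
            break
        if gc > target:
            pool = np.flatnonzero(np.isin(arr, list("GC")))
            arr[rng.choice(pool)] = "AT"[int(rng.integers(2))]
        else:
            pool = np.flatnonzero(np.isin(arr, list("AT")))
            arr[rng.choice(pool)] = "GC"[int(rng.integers(2))]
    return "".join(arr)


_TRANSVERSION = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _scrub_sites(
    seq: str,
    rng: np.random.Generator,
    enzyme: Enzyme,
    left: str = "AATG",
    right: str = "TTAG",
) -> str:
    """Remove recognition sites (either strand) the way a codon optimizer
    would: flip one base inside each hit.  A<->T / G<->C swaps always break
    the motif and preserve GC content exactly.  Sites are scanned in the
    assembled-construct context (backbone flanks included) since a site
    formed across the vector junction is just as fatal."""
    motifs = (enzyme.recognition, enzyme.recognition_rc)
    arr = list(seq)
    for _ in range(100):
        s = left + "".join(arr) + right
        hits = [(s.find(m), len(m)) for m in motifs if m in s]
        if not hits:
            return "".join(arr)
        pos, k = hits[0]
        # flip only inside the mutable gene region
        span = [
            i - len(left)
            for i in range(pos, pos + k)
            if len(left) <= i < len(left) + len(arr)
        ]
        i = span[int(rng.integers(len(span)))]
        arr[i] = _TRANSVERSION[arr[i]]
    raise GenerationError("could not scrub recognition sites")


def _rate_for_identity(t: float) -> float:
    """Per-sequence substitution rate so that two independently mutated
    copies of one template match at fraction t per position:
    (1-r)^2 + r^2/3 = t, solved for the smaller root."""
    # (4/3) r^2 - 2 r + (1 - t) = 0
    disc = 4 - (16.0 / 3.0) * (1 - t)
    if disc < 0:
        raise GenerationError(f"identity {t} unreachable by substitution")
    return (2 - disc**0.5) / (8.0 / 3.0)


def _identity_family(
    template: str,
    n: int,
    band: tuple[float, float],
    rng: np.random.Generator,
    gc_target: float | None = None,
    max_iter: int = 60,
) -> list[str]:
    """Mutate independent copies of the template until the mean pairwise
    identity lands inside the band, bisecting the substitution rate."""
    if band[0] >= 1.0:
        return [template] * n
    lo_r, hi_r = 0.0, 0.75
    r = _rate_for_identity((band[0] + band[1]) / 2)
    enzyme = Enzyme()
    for _ in range(max_iter):
        seqs = [_mutate(template, r, rng) for _ in range(n)]
        if gc_target is not None:
            seqs = [_fix_gc(s, gc_target, rng) for s in seqs]
        seqs = [_scrub_sites(s, rng, enzyme) for s in seqs]
        ident = mean_pairwise_identity(seqs)
        if band[0] <= ident <= band[1]:
            return seqs
        if ident > band[1]:  # too similar: mutate harder
            lo_r = r
        else:
            hi_r = r
        r = (lo_r + hi_r) / 2
    raise GenerationError(
        f"could not reach identity band {band} within {max_iter} rounds"
    )


def gen_sequence_set(spec: SequenceSetSpec) -> SequenceSet:
    """Generate one self-validating stress set; deterministic under seed."""
    rng = np.random.default_rng(spec.seed)
    band = spec.identity_band()
    enzyme = Enzyme()

    if spec.mode == "identity":
        template = _scrub_sites(
            _random_seq(spec.length, rng, gc=spec.target_gc), rng, enzyme
        )
        if band is None:
            raise ValueError("identity mode requires target_identity")
        seqs = _identity_family(template, spec.n_sequences, band, rng)
    elif spec.mode == "gc":
        if spec.target_gc is None:
            raise ValueError("gc mode requires target_gc")
        template = _scrub_sites(
            _random_seq(spec.length, rng, gc=spec.target_gc), rng, enzyme
        )
        if band is None:
            seqs = [
                _scrub_sites(
                    _random_seq(spec.length, rng, gc=spec.target_gc), rng, enzyme
                )
                for _ in range(spec.n_sequences)
            ]
        else:
            seqs = _identity_family(
                template, spec.n_sequences, band, rng, gc_target=spec.target_gc
            )
    elif spec.mode == "repeat":
        unit_len = spec.length // spec.n_repeats
        unit = _random_seq(unit_len, rng, gc=spec.target_gc)
        copies = [_mutate(unit, 0.05, rng) for _ in range(spec.n_repeats)]
        template = _scrub_sites(
            ("".join(copies) + unit)[: spec.length], rng, enzyme
        )
        b = band or (0.85, 0.95)
        seqs = _identity_family(template, spec.n_sequences, b, rng)
    else:
        raise ValueError(f"unknown mode {spec.mode!r}")

    genes = [GeneRecord(f"{spec.mode}_{i}", s) for i, s in enumerate(seqs)]
    out = SequenceSet(
        genes=genes,
        achieved_identity=mean_pairwise_identity(seqs),
        achieved_gc=float(np.mean([gc_content(s) for s in seqs])),
        spec=spec,
    )
    if band or spec.target_gc is not None:
        if spec.mode != "repeat" or band:
            out.validate()
    return out


def placeholder_primer_table(
    n_pairs: int, seed: int, primer_len: int = 20, enzyme: Enzyme = Enzyme()
) -> list[PrimerPair]:
    """Distinct random primers standing in for an experimentally verified
    orthogonal set (synthetic placeholder: no Tm or cross-dimer screening,
    only distinctness and recognition-site exclusion)."""
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    primers: list[str] = []
    while len(primers) < 2 * n_pairs:
        s = "".join(rng.choice(list("ACGT"), size=primer_len))
        if s in seen:
            continue
        if enzyme.recognition in s or enzyme.recognition_rc in s:
            continue
        seen.add(s)
        primers.append(s)
    return [
        PrimerPair(f"pair{i}", primers[2 * i], primers[2 * i + 1])
        for i in range(n_pairs)
    ]


def write_fasta(genes: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.id}\n{g.seq}\n")
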