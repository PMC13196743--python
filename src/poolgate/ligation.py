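"""Overhang algebra and the data-driven ligation-fidelity model.

Golden Gate assembly joins DNA fragments through 4-base single-stranded
overhangs.  In a one-pot reaction every overhang species competes for every
other, and empirical ligase profiling shows substantial off-target ligation
between near-cognate pairs.  This module holds the 256x256 ligation-frequency
matrix and the fidelity model built on it: the probability that a given
overhang ligates to its Watson-Crick partner rather than to any other species
present in the reaction, and the set fidelity as the product of those
per-junction probabilities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ALL_4MERS",
    "PALINDROMIC_4MERS",
    "revcomp",
    "is_palindromic",
    "Overhang",
    "LigationMatrix",
    "JunctionSet",
    "junction_fidelity",
    "set_fidelity",
    "FidelityScorer",
    "DegenerateMatrixError",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: All 4-mers over {A,C,G,T} in lexicographic order (matrix row/col order).
ALL_4MERS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product("ACGT", repeat=4)
)
_KMER_INDEX: dict[str, int] = {s: i for i, s in enumerate(ALL_4MERS)}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T only, case-preserving on
    uppercase input).  Raises ``ValueError`` naming the first offending
    position for non-ACGT characters."""
    for i, c in enumerate(seq):
        if c not in "ACGT":
            raise ValueError(
                f"non-ACGT character {c!r} at position {i} in {seq!r}"
            )
    return seq.translate(_COMPLEMENT)[::-1]


def is_palindromic(seq: str) -> bool:
    """True if the overhang equals its own reverse complement (e.g. GGCC).

    Palindromic overhangs ligate to copies of themselves in both orientations
    and are therefore never usable as designable junctions.
    """
    return seq == revcomp(seq)


#: The 16 self-reverse-complementary 4-mers, excluded from candidate junctions.
PALINDROMIC_4MERS: frozenset[str] = frozenset(
    s for s in ALL_4MERS if is_palindromic(s)
)

#: index of the reverse complement of each 4-mer, by lexicographic index
_RC_INDEX: np.ndarray = np.array(
    [_KMER_INDEX[revcomp(s)] for s in ALL_4MERS], dtype=np.intp
)


class DegenerateMatrixError(ValueError):
    """Raised when a required matrix row carries no ligatable mass."""


def _check_overhang(seq: str) -> str:
    if len(seq) != 4:
        raise ValueError(f"overhang must be exactly 4 nt, got {seq!r}")
    seq = seq.upper()
    revcomp(seq)  # validates alphabet
    return seq


@dataclass(frozen=True)
class Overhang:
    """A 4-base Golden Gate overhang in canonical uppercase form."""

    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _check_overhang(self.seq))

    @property
    def rc(self) -> str:
        return revcomp(self.seq)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.seq


class LigationMatrix:
    """Ordered 256x256 table of ligation frequencies between 4-bp overhangs.

    Entry ``(a, b)`` is the observed (or synthetic) frequency of overhang
    ``a`` ligating to overhang ``b``.  Empirical matrices may be asymmetric;
    entries are used as given and both orientations are summed explicitly in
    the fidelity formula, so no symmetrization or row normalization is
    applied.  Frequencies are used unnormalized: the fidelity is a ratio, so
    row scaling cancels.
    """

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (256, 256):
            raise ValueError(f"expected a 256x256 matrix, got {values.shape}")
        if not np.isfinite(values).all():
            raise ValueError("ligation matrix contains non-finite entries")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative ligation frequency at ({ALL_4MERS[i]}, {ALL_4MERS[j]})"
            )
        self.values = values

    # -- access -----------------------------------------------------------
    def __getitem__(self, key: tuple[str, str]) -> float:
        a, b = key
        return float(self.values[_KMER_INDEX[_check_overhang(a)],
                                 _KMER_INDEX[_check_overhang(b)]])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LigationMatrix) and np.array_equal(
            self.values, other.values
        )

    # -- I/O --------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write as labeled CSV: rows/cols are the 256 4-mers in
        lexicographic order; cell (i, j) = frequency of overhang_i ligating
        to overhang_j."""
        df = pd.DataFrame(self.values, index=ALL_4MERS, columns=ALL_4MERS)
        df.to_csv(path, float_format="%.17g")  # lossless round trip

    @classmethod
    def from_csv(cls, path: str | Path) -> "LigationMatrix":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        missing = set(ALL_4MERS) - set(df.index)
        missing |= set(ALL_4MERS) - set(df.columns)
        if missing:
            raise ValueError(
                f"ligation matrix CSV is missing 4-mer labels: "
                f"{sorted(missing)[:5]}{'...' if len(missing) > 5 else ''}"
            )
        df = df.loc[list(ALL_4MERS), list(ALL_4MERS)]
        return cls(df.to_numpy(dtype=float))

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "LigationMatrix":
        """Perfectly orthogonal matrix: each overhang ligates only to its
        Watson-Crick partner."""
        m = np.zeros((256, 256))
        m[np.arange(256), _RC_INDEX] = 1.0
        return cls(m)

    @classmethod
    def make_synthetic(
        cls, orthogonality: float, seed: int, jitter: float = 0.5
    ) -> "LigationMatrix":
        """Synthesize a plausible ligase profile.

        Per row, fraction ``orthogonality`` of the mass sits on the correct
        Watson-Crick partner and the remaining ``1 - orthogonality`` is
        spread over the other 255 ordered partners.  The spread carries
        seeded multiplicative jitter (uniform in ``1 +/- jitter``,
        renormalized per row) so that different overhang choices genuinely
        differ in cross-talk — a perfectly even spread would make every
        same-size junction set score identically.  ``orthogonality=1.0``
        gives the exact identity pattern regardless of seed.
        """
        if not 0.0 < orthogonality <= 1.0:
            raise ValueError("orthogonality must be in (0, 1]")
        if orthogonality == 1.0:
            return cls.identity()
        rng = np.random.default_rng(seed)
        weights = rng.uniform(1.0 - jitter, 1.0 + jitter, size=(256, 256))
        weights[np.arange(256), _RC_INDEX] = 0.0
        weights /= weights.sum(axis=1, keepdims=True)
        m = (1.0 - orthogonality) * weights
        m[np.arange(256), _RC_INDEX] = orthogonality
        return cls(m)


def _as_seq(o: "Overhang | str") -> str:
    return _check_overhang(o.seq if isinstance(o, Overhang) else o)


@dataclass
class JunctionSet:
    """The designable junction overhangs of one subpool plus the two fixed
    backbone (vector ligation) overhangs.

    Invariants: no member is palindromic; no member equals another member or
    another member's reverse complement.  A junction's reverse complement is
    a distinct reaction species but not a separate designable junction, so
    uniqueness is enforced over junctions ∪ complements ∪ backbone.
    """

    junctions: list[str]
    backbone: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.junctions = [_as_seq(j) for j in self.junctions]
        if self.backbone is not None:
            b1, b2 = self.backbone
            self.backbone = (_as_seq(b1), _as_seq(b2))

    @property
    def members(self) -> list[str]:
        out = list(self.junctions)
        if self.backbone is not None:
            out.extend(self.backbone)
        return out

    def species(self) -> list[str]:
        """Distinct overhang species present in the reaction: every member
        plus its reverse complement, first-seen order."""
        seen: dict[str, None] = {}
        for x in self.members:
            seen.setdefault(x)
            seen.setdefault(revcomp(x))
        return list(seen)

    def validate(self) -> None:
        """Raise ``ValueError`` listing every clash (duplicate, reverse-
        complement collision, palindrome)."""
        clashes: list[str] = []
        claimed: dict[str, str] = {}
        for x in self.members:
            if is_palindromic(x):
                clashes.append(f"palindromic overhang {x}")
                continue
            for sp in (x, revcomp(x)):
                if sp in claimed and claimed[sp] != x:
                    clashes.append(f"{x} collides with {claimed[sp]}")
                    break
            else:
                claimed[x] = x
                claimed[revcomp(x)] = x
                continue
        # duplicates of the same literal overhang
        seen: set[str] = set()
        for x in self.members:
            if x in seen:
                clashes.append(f"duplicate overhang {x}")
            seen.add(x)
        if clashes:
            raise ValueError("invalid junction set: " + "; ".join(clashes))


def junction_fidelity(
    o: "Overhang | str", jset: JunctionSet, matrix: LigationMatrix
) -> float:
    """Probability that overhang ``o`` ligates to its Watson-Crick partner
    given every species present in the reaction.

    With R the distinct species (each member of junctions ∪ backbone plus its
    reverse complement), the fidelity is::

        [m(o, rc(o)) + m(rc(o), o)] / sum_{p in R} [m(o, p) + m(rc(o), p)]

    Both orientations are summed explicitly so asymmetric empirical matrices
    are used as given.
    """
    o = _as_seq(o)
    if o not in jset.members:
        raise ValueError(f"overhang {o} is not a member of the junction set")
    scorer = FidelityScorer(matrix, jset.backbone)
    fids = scorer.junction_fidelities(jset.junctions)
    members = list(jset.junctions) + (
        list(jset.backbone) if jset.backbone else []
    )
    return float(fids[members.index(o)])


def set_fidelity(
    jset: JunctionSet,
    matrix: LigationMatrix,
    include_backbone: bool = True,
) -> float:
    """Overall assembly fidelity: the product of per-junction fidelities.

    Backbone sites always contribute to every denominator (they are present
    in the reaction); whether their own two fidelities multiply into the
    product is controlled by ``include_backbone`` (default True).
    """
    jset.validate()
    scorer = FidelityScorer(
        matrix, jset.backbone, include_backbone=include_backbone
    )
    return scorer.score(jset.junctions)


class FidelityScorer:
    """Vectorized fidelity evaluation for a fixed matrix and backbone pair.

    Used heavily inside the annealer, where the junction list changes every
    step but matrix and backbone do not.  Performs no invariant validation;
    callers are responsible for legal sets.
    """

    def __init__(
        self,
        matrix: LigationMatrix,
        backbone: Sequence[str] | None = None,
        include_backbone: bool = True,
    ):
        self.M = matrix.values
        self.backbone_idx = (
            np.array([_KMER_INDEX[_as_seq(b)] for b in backbone], dtype=np.intp)
            if backbone
            else np.empty(0, dtype=np.intp)
        )
        self.include_backbone = include_backbone

    def _indices(self, junctions: Iterable[str]) -> np.ndarray:
        return np.array(
            [_KMER_INDEX[_as_seq(j)] for j in junctions], dtype=np.intp
        )

    def junction_fidelities(
        self, junctions: Sequence[str]
    ) -> np.ndarray:
        """Fidelity of each designable junction followed by the backbone
        sites (in order), as an array."""
        j_idx = self._indices(junctions)
        members = np.concatenate([j_idx, self.backbone_idx])
        rc = _RC_INDEX[members]
        species = np.unique(np.concatenate([members, rc]))
        num = self.M[members, rc] + self.M[rc, members]
        den = (
            self.M[np.ix_(members, species)].sum(axis=1)
            + self.M[np.ix_(rc, species)].sum(axis=1)
        )
        if (den == 0).any():
            bad = int(np.argwhere(den == 0)[0][0])
            raise DegenerateMatrixError(
                f"overhang {ALL_4MERS[members[bad]]} has zero total ligation "
                "mass over the species present"
            )
        return num / den

    def score(self, junctions: Sequence[str]) -> float:
        """Set fidelity: product over designable junctions (and, if
        configured, the backbone sites)."""
        fids = self.junction_fidelities(junctions)
        if not self.include_backbone and len(self.backbone_idx):
            fids = fids[: len(fids) - len(self.backbone_idx)]
        return float(np.prod(fids))
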