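"""Library QC: assembly-code demultiplexing, abundance uniformity metrics,
edit-distance triage, and sampling-coverage simulation.

Abundance is expressed as fold-from-median: a design's read count divided by
the library median.  The uniformity window is within 10-fold of the median;
a design is "observed" with at least one count.  Yield is the fraction of all
reads that are correct assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

__all__ = [
    "MatchResult",
    "AbundanceReport",
    "match_assembly_code",
    "abundance_report",
    "combine_replicate_counts",
    "edit_distance",
    "classify_edit_distance",
    "coverage_depth_sim",
    "expected_depth_uniform",
    "CoverageResult",
]


# ---------------------------------------------------------------------------
# barcode / assembly-code matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchResult:
    code: tuple[str, ...] | None
    pool: str | None
    rejected: bool
    reason: str | None = None

    @classmethod
    def reject(cls, reason: str) -> "MatchResult":
        return cls(code=None, pool=None, rejected=True, reason=reason)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def match_assembly_code(
    read: str,
    barcode_table: pd.DataFrame,
    max_mismatch: int = 3,
    junction_len: int = 4,
) -> MatchResult:
    """Decode a read of concatenated barcodes (``b1.junction.b2...``) into
    its assembly code.

    Each barcode segment must match a table entry within ``max_mismatch``
    Hamming distance (barcodes are designed >= 15 bp apart, so 3 mismatches
    discriminate cleanly).  Reads are rejected on partial coverage (length
    not matching a whole number of barcodes), any unmatched or ambiguous
    segment, or barcodes drawn from more than one subpool.

    ``barcode_table`` columns: barcode_id, pool, seq (all equal length).
    """
    seqs = barcode_table["seq"].astype(str).tolist()
    ids = barcode_table["barcode_id"].astype(str).tolist()
    pools = barcode_table["pool"].astype(str).tolist()
    lens = {len(s) for s in seqs}
    if len(lens) != 1:
        raise ValueError("all barcodes must share one length")
    bl = lens.pop()

    unit = bl + junction_len
    if (len(read) + junction_len) % unit != 0:
        return MatchResult.reject("partial_read")
    n = (len(read) + junction_len) // unit
    if n < 1:
        return MatchResult.reject("partial_read")

    code: list[str] = []
    hit_pools: set[str] = set()
    for i in range(n):
        seg = read[i * unit : i * unit + bl]
        dists = [_hamming(seg, s) for s in seqs]
        best = min(dists)
        if best > max_mismatch:
            return MatchResult.reject("unmatched_barcode")
        winners = [k for k, d in enumerate(dists) if d == best]
        if len(winners) > 1:
            return MatchResult.reject("ambiguous_barcode")
        k = winners[0]
        code.append(ids[k])
        hit_pools.add(pools[k])
    if len(hit_pools) > 1:
        return MatchResult.reject("mixed_pool")
    return MatchResult(code=tuple(code), pool=hit_pools.pop(), rejected=False)


# ---------------------------------------------------------------------------
# abundance metrics
# ---------------------------------------------------------------------------

@dataclass
class AbundanceReport:
    per_design: pd.DataFrame  # design_id, count, fold_from_median
    median_count: float
    fraction_observed: float
    fraction_within_10fold: float
    yield_: float

    def summary(self) -> dict:
        return {
            "median_count": self.median_count,
            "fraction_observed": self.fraction_observed,
            "fraction_within_10fold": self.fraction_within_10fold,
            "yield": self.yield_,
        }


def abundance_report(
    counts: Mapping[str, int], total_reads: int
) -> AbundanceReport:
    """Uniformity metrics for one library.

    The fold-from-median denominator is the median over designs with at
    least one count (unobserved designs still count against
    ``fraction_observed`` and fall outside the 10-fold window).
    """
    if not counts:
        raise ValueError("empty counts")
    values = np.array(list(counts.values()), dtype=float)
    if (values < 0).any():
        raise ValueError("negative counts")
    correct = values.sum()
    if total_reads < correct:
        raise ValueError("total_reads smaller than the sum of correct counts")
    observed = values[values >= 1]
    if observed.size == 0:
        raise ValueError("median undefined: every design has zero counts")
    median = float(np.median(observed))
    fold = values / median
    within = (fold >= 0.1) & (fold <= 10.0)
    df = pd.DataFrame(
        {
            "design_id": list(counts),
            "count": values.astype(int),
            "fold_from_median": fold,
        }
    )
    return AbundanceReport(
        per_design=df,
        median_count=median,
        fraction_observed=float((values >= 1).mean()),
        fraction_within_10fold=float(within.mean()),
        yield_=float(correct / total_reads) if total_reads else 0.0,
    )


def combine_replicate_counts(
    replicates: Sequence[Mapping[str, int]],
) -> dict[str, float]:
    """Combine replicate libraries: normalize each replicate by its total
    (sequence-perfect) reads, then sum per design."""
    out: dict[str, float] = {}
    for rep in replicates:
        total = sum(rep.values())
        if total == 0:
            continue
        for k, v in rep.items():
            out[k] = out.get(k, 0.0) + v / total
    return out


# ---------------------------------------------------------------------------
# edit-distance triage
# ---------------------------------------------------------------------------

def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (mismatches + insertions + deletions)."""
    return edlib.align(a, b, task="distance")["editDistance"]


def classify_edit_distance(d: int) -> str:
    """Triage a read by edit distance to its closest library sequence:
    0 is sequence-perfect; 1-10 is consistent with synthesis or sequencing
    error; beyond 10 the read likely reflects an assembly error."""
    if d < 0:
        raise ValueError("edit distance cannot be negative")
    if d == 0:
        return "perfect"
    if d <= 10:
        return "near_perfect"
    return "assembly_error"


# ---------------------------------------------------------------------------
# coverage simulation
# ---------------------------------------------------------------------------

@dataclass
class CoverageResult:
    depths: np.ndarray  # per-replicate depth at which all designs hit k
    mean: float
    quantiles: dict[float, float]


def coverage_depth_sim(
    abundances: Sequence[float],
    k: int = 10,
    read_error_rate: float = 0.0,
    seed: int = 0,
    n_reps: int = 20,
) -> CoverageResult:
    """Monte-Carlo coupon collector: how many reads must be drawn (with
    probabilities proportional to abundance, each read independently
    discarded with ``read_error_rate``) before every design is seen at least
    ``k`` times.

    Read error inflates the required depth by a uniform 1/(1-e) factor — it
    changes the budget, not the shape of the coverage curve.
    """
    a = np.asarray(abundances, dtype=float)
    if a.size == 0 or (a < 0).any():
        raise ValueError("abundances must be non-negative and non-empty")
    if (a == 0).any():
        zero = int(np.argwhere(a == 0)[0][0])
        raise ValueError(
            f"design {zero} has zero abundance: coverage unreachable"
        )
    if not 0 <= read_error_rate < 1:
        raise ValueError("read_error_rate must be in [0, 1)")
    p = a / a.sum()
    e = read_error_rate
    # categories: designs 0..n-1, plus a discard category
    probs = np.concatenate([(1 - e) * p, [e]])
    n = a.size
    rng = np.random.default_rng(seed)
    # initial draw sized from the rare-design bound, grown on demand
    chunk = int(3 * k / ((1 - e) * p.min())) + 100
    depths = np.empty(n_reps)
    for rep in range(n_reps):
        draws = rng.choice(n + 1, size=chunk, p=probs)
        while True:
            counts = np.bincount(draws, minlength=n + 1)[:n]
            if (counts >= k).all():
                break
            draws = np.concatenate(
                [draws, rng.choice(n + 1, size=chunk, p=probs)]
            )
        # depth = 1 + position of the latest k-th hit across designs
        last_needed = 0
        for i in range(n):
            hits = np.flatnonzero(draws == i)
            last_needed = max(last_needed, hits[k - 1])
        depths[rep] = last_needed + 1
    qs = {q: float(np.quantile(depths, q)) for q in (0.5, 0.9)}
    return CoverageResult(depths=depths, mean=float(depths.mean()), quantiles=qs)


def expected_depth_uniform(n: int, k: int = 1, read_error_rate: float = 0.0) -> float:
    """Closed-form comparison baseline: expected coupon-collector depth for
    ``n`` equally abundant designs at k=1, inflated by read error."""
    if k != 1:
        raise NotImplementedError("closed form provided for k=1 only")
    harmonic = sum(1.0 / i for i in range(1, n + 1))
    return n * harmonic / (1.0 - read_error_rate)
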