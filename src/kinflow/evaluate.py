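"""Evaluation: cyclic-sequencing speed model, read alignment, error breakdown.

The speed model answers "how many bases does one nucleotide flow deliver on
average?" for a fixed cyclic flow order.  Between two successive *matching*
flows the cycle wastes the flows of the intervening bases; each matching
flow incorporates a full homopolymer.  With uniformly distributed bases and
the order G,T,A,C, the homopolymer-collapsed next base is uniform over the
other three, at cyclic distance 1, 2 or 3, so a match costs two flows on
average; with a genome n-mer mix of 75% 1-mers, 24.5% 2-mers and 0.5%
3-or-longer (counted as 3), a matching flow delivers
0.75 + 0.49 + 0.015 = 1.255 bases - i.e. 1.255 bp per 2 flows ~ 0.63 bp per
flow.  The computation here is exact rational arithmetic and generalises to
any single-occurrence flow order and base composition.

Alignment is semi-global (the whole read against the best reference infix,
either strand) by edit distance, with a read "aligned" iff it meets a
minimum overlap length and a maximum error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import edlib
import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InputError
from .simulate import BASES, reverse_complement

__all__ = [
    "SpeedModelInput",
    "SpeedResult",
    "AlignmentReport",
    "ErrorBreakdown",
    "cyclic_speed",
    "align_reads",
    "error_breakdown",
]


@dataclass(frozen=True)
class SpeedModelInput:
    """Inputs of the cyclic-speed model.

    ``flow_order``: cyclic order, each base at most once.
    ``base_composition``: probabilities of A, C, G, T in the template.
    ``nmer_distribution``: probabilities of homopolymer length 1, 2 and
    >= 3 (lengths >= 3 contribute exactly 3 bases).
    Fractions keep the arithmetic exact; floats are converted.
    """

    flow_order: str = "GTAC"
    base_composition: tuple = (
        Fraction(1, 4),
        Fraction(1, 4),
        Fraction(1, 4),
        Fraction(1, 4),
    )
    nmer_distribution: tuple = (
        Fraction(75, 100),
        Fraction(245, 1000),
        Fraction(5, 1000),
    )

    def __post_init__(self) -> None:
        comp = tuple(Fraction(x).limit_denominator(10**12) for x in self.base_composition)
        nmer = tuple(Fraction(x).limit_denominator(10**12) for x in self.nmer_distribution)
        object.__setattr__(self, "base_composition", comp)
        object.__setattr__(self, "nmer_distribution", nmer)
        if len(comp) != 4 or any(p < 0 for p in comp) or sum(comp) != 1:
            raise InputError("base_composition must be 4 probabilities summing to 1")
        if len(nmer) != 3 or any(p < 0 for p in nmer) or sum(nmer) != 1:
            raise InputError("nmer_distribution must be 3 probabilities summing to 1")
        if len(set(self.flow_order)) != len(self.flow_order) or any(
            b not in BASES for b in self.flow_order
        ):
            raise InputError("flow_order must list distinct bases from ACGT")


@dataclass(frozen=True)
class SpeedResult:
    bases_per_matching_flow: Fraction
    flows_per_matching_flow: Fraction
    bases_per_flow: Fraction


def _solve_stationary(P: list[list[Fraction]]) -> list[Fraction]:
    """Exact stationary distribution of a small row-stochastic matrix."""
    n = len(P)
    # solve pi (P - I) = 0 with sum(pi) = 1: transpose system, replace last eq
    A = [[P[j][i] - (Fraction(1) if i == j else Fraction(0)) for j in range(n)] for i in range(n)]
    A[n - 1] = [Fraction(1)] * n
    b = [Fraction(0)] * (n - 1) + [Fraction(1)]
    # Gaussian elimination over the rationals
    for col in range(n):
        piv = next((r for r in range(col, n) if A[r][col] != 0), None)
        if piv is None:
            raise DegenerateInputError("stationary distribution is not unique")
        A[col], A[piv] = A[piv], A[col]
        b[col], b[piv] = b[piv], b[col]
        inv = Fraction(1) / A[col][col]
        A[col] = [a * inv for a in A[col]]
        b[col] *= inv
        for r in range(n):
            if r != col and A[r][col] != 0:
                f = A[r][col]
                A[r] = [ar - f * ac for ar, ac in zip(A[r], A[col])]
                b[r] -= f * b[col]
    return b


def cyclic_speed(model: SpeedModelInput) -> SpeedResult:
    """Expected bases per matching flow, flows per match, and bases per flow.

    Homopolymers are collapsed: after a matching flow of base c, the next
    template base differs from c and is distributed p(b)/(1-p(c)).  The cost
    in flows is the cyclic distance from c's slot to b's slot.  Matched-base
    frequencies follow the stationary distribution of the collapsed chain.
    All arithmetic is exact.
    """
    comp = dict(zip("ACGT", model.base_composition))
    order = model.flow_order
    L = len(order)
    present = [b for b in order if comp[b] > 0]
    missing = [b for b in BASES if comp[b] > 0 and b not in order]
    if missing:
        raise DegenerateInputError(
            f"bases {missing} occur in templates but never flow: unreachable"
        )
    if len(present) < 2:
        raise DegenerateInputError("collapsed chain needs at least two bases with mass")
    # collapsed next-base transition matrix over the present bases
    n = len(present)
    P = [
        [
            comp[b] / (1 - comp[c]) if b != c else Fraction(0)
            for b in present
        ]
        for c in present
    ]
    pi = _solve_stationary(P)
    pos = {b: order.index(b) for b in present}
    flows = Fraction(0)
    for i, c in enumerate(present):
        for j, b in enumerate(present):
            if b == c:
                continue
            d = (pos[b] - pos[c] - 1) % L + 1
            flows += pi[i] * P[i][j] * d
    p1, p2, p3 = model.nmer_distribution
    bases = p1 * 1 + p2 * 2 + p3 * 3
    return SpeedResult(
        bases_per_matching_flow=bases,
        flows_per_matching_flow=flows,
        bases_per_flow=bases / flows,
    )


@dataclass
class AlignmentReport:
    """Per-run alignment statistics against a reference."""

    total_reads: int
    aligned_count: int
    aligned_fraction: float
    mismatch_rate: float
    perfect_read_count: int
    min_overlap: int
    max_error_rate: float
    per_read: pd.DataFrame = field(repr=False, default=None)


def _cigar_counts(cigar: str) -> tuple[int, int, int, int]:
    """(matches, mismatches, insertions, deletions) from an extended cigar."""
    num = ""
    m = x = i = d = 0
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            m += n
        elif ch == "X":
            x += n
        elif ch == "I":
            i += n
        elif ch == "D":
            d += n
        elif ch == "M":  # unresolved match/mismatch; count as match
            m += n
    return m, x, i, d


def align_reads(
    reads: Sequence,
    reference: str,
    min_overlap: int = 15,
    max_error_rate: float = 0.1,
) -> AlignmentReport:
    """Semi-global alignment of each read to the best reference infix.

    Each read is aligned whole against every infix of the reference
    (edit-distance, via edlib's infix mode) on both strands.  Ties go to the
    forward strand and the leftmost location.  A read counts as aligned iff
    its length is at least ``min_overlap`` and its edit distance divided by
    its length is at most ``max_error_rate``.  The mismatch rate is total
    substitutions over total aligned read bases; indel counts are reported
    per read.  Reads may be strings or objects with ``sequence``/
    ``cluster_id`` attributes.
    """
    if not reference:
        raise InputError("empty reference")
    if min_overlap < 1:
        raise InputError("min_overlap must be >= 1")
    ref_rc = reverse_complement(reference)
    rows = []
    for idx, read in enumerate(reads):
        seq = read if isinstance(read, str) else read.sequence
        rid = f"read_{idx:05d}" if isinstance(read, str) else getattr(read, "cluster_id", str(idx))
        row = {
            "read_id": rid,
            "length": len(seq),
            "aligned": False,
            "strand": ".",
            "start": -1,
            "end": -1,
            "edit_distance": -1,
            "mismatches": 0,
            "insertions": 0,
            "deletions": 0,
        }
        if len(seq) >= min_overlap and len(seq) > 0:
            best = None
            for strand, ref in (("+", reference), ("-", ref_rc)):
                res = edlib.align(seq, ref, mode="HW", task="path")
                if res["editDistance"] < 0:
                    continue
                loc = res["locations"][0]
                key = (res["editDistance"], 0 if strand == "+" else 1, loc[0] or 0)
                if best is None or key < best[0]:
                    best = (key, strand, res)
            if best is not None:
                (dist, _, _), strand, res = best
                if dist / len(seq) <= max_error_rate:
                    _, x, ins, dele = _cigar_counts(res["cigar"])
                    start, end = res["locations"][0]
                    row.update(
                        aligned=True,
                        strand=strand,
                        start=int(start if start is not None else 0),
                        end=int(end) + 1,  # half-open
                        edit_distance=int(dist),
                        mismatches=x,
                        insertions=ins,
                        deletions=dele,
                    )
        rows.append(row)
    per_read = pd.DataFrame(rows)
    aligned = per_read[per_read.aligned]
    total_bases = int(aligned.length.sum())
    mism = int(aligned.mismatches.sum())
    return AlignmentReport(
        total_reads=len(per_read),
        aligned_count=int(aligned.shape[0]),
        aligned_fraction=float(aligned.shape[0] / max(len(per_read), 1)),
        mismatch_rate=float(mism / total_bases) if total_bases else 0.0,
        perfect_read_count=int((aligned.edit_distance == 0).sum()),
        min_overlap=min_overlap,
        max_error_rate=max_error_rate,
        per_read=per_read,
    )


@dataclass
class ErrorBreakdown:
    """Homopolymer confusion matrix of called vs true flow counts."""

    confusion: np.ndarray  # (true_class, called_class)
    undercall_count: int  # bases lost to under-called flows (deletions)
    overcall_count: int  # bases gained from over-called flows (insertions)
    n_flows_scored: int


def error_breakdown(
    calls: np.ndarray,
    truth: np.ndarray,
) -> ErrorBreakdown:
    """Tally called vs true homopolymer classes over all clusters and flows.

    Under-called flows contribute deletions (missing bases), over-called
    flows insertions.  Flows with call < 0 (unscored clusters) are ignored.
    """
    calls = np.asarray(calls, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if calls.shape != truth.shape:
        raise InputError("calls and truth must have identical shapes")
    mask = calls >= 0
    c = calls[mask].ravel()
    t = truth[mask].ravel()
    k = int(max(c.max(initial=0), t.max(initial=0))) + 1
    conf = np.zeros((k, k), dtype=int)
    np.add.at(conf, (t, c), 1)
    under = int(np.maximum(t - c, 0).sum())
    over = int(np.maximum(c - t, 0).sum())
    return ErrorBreakdown(
        confusion=conf,
        undercall_count=under,
        overcall_count=over,
        n_flows_scored=int(mask.sum()),
    )
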