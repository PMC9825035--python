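"""Self-comparison repeat detection and repeat-region masking.

Duplicated regions of an organelle genome are found by ungapped
seed-and-extend self-comparison (exact k-mer seeds, per-diagonal segment
scanning) on both strands, optionally treating the genome as circular.
Variants whose reference span intersects the masked union are removed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path

from organellotype.genome import revcomp
from organellotype.variants import VariantSite

DEFAULT_MIN_LEN = 100
DEFAULT_MIN_IDENTITY = 0.95
SEED_K = 21


class AmbiguityError(ValueError):
    """Raised when the input carries too many non-ACGT characters."""


@dataclass(frozen=True)
class RepeatPair:
    """Two near-identical intervals (0-based half-open) of one genome."""

    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    strand: str  # 'same' | 'inverted'
    identity: float

    def __post_init__(self) -> None:
        for iv in (self.interval_a, self.interval_b):
            if iv[1] <= iv[0]:
                raise ValueError(f"degenerate interval {iv}")
        if self.strand == "same" and self.interval_a == self.interval_b:
            raise ValueError("trivial self-match")

    @property
    def length(self) -> int:
        return self.interval_a[1] - self.interval_a[0]


@dataclass
class Mask:
    """Sorted, disjoint masked intervals (0-based half-open) of a genome."""

    intervals: list[tuple[int, int]]
    genome_length: int

    def __post_init__(self) -> None:
        prev_end = 0
        for s, e in self.intervals:
            if s < prev_end or e <= s or e > self.genome_length:
                raise ValueError("mask intervals must be sorted, disjoint, in range")
            prev_end = e

    def masked_length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def overlaps(self, start: int, end: int) -> bool:
        """True iff [start, end) intersects any masked interval."""
        i = bisect.bisect_right([s for s, _ in self.intervals], start)
        for s, e in self.intervals[max(0, i - 1) :]:
            if s >= end:
                break
            if start < e and s < end:
                return True
        return False


def _segments(match: list[bool], min_len: int, min_identity: float):
    """Segments of a match/mismatch track meeting length and identity.

    Uses a max-scoring-subsegment decomposition with match score
    +(1 - min_identity) and mismatch score -min_identity, so a segment has
    non-negative score iff its identity is >= min_identity; maximal-scoring
    segments therefore hug the true repeat boundaries instead of absorbing
    random flanking matches. Yields (start, length, identity).
    """
    n = len(match)
    if min_identity >= 1.0:
        i = 0
        while i < n:
            if match[i]:
                j = i
                while j < n and match[j]:
                    j += 1
                if j - i >= min_len:
                    yield i, j - i, 1.0
                i = j
            else:
                i += 1
        return
    w_match, w_mis = 1.0 - min_identity, -min_identity
    out: list[tuple[int, int]] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < min_len:
            continue
        best, best_range = 0.0, None
        cur, cur_start = 0.0, lo
        for i in range(lo, hi):
            if cur <= 0.0:
                cur, cur_start = 0.0, i
            cur += w_match if match[i] else w_mis
            if cur > best:
                best, best_range = cur, (cur_start, i + 1)
        if best_range is None:
            continue
        s, e = best_range
        if e - s >= min_len:
            out.append((s, e))
        stack.append((lo, s))
        stack.append((e, hi))
    for s, e in sorted(out):
        matched = sum(match[s:e])
        yield s, e - s, matched / (e - s)


def _seed_diagonals(seq_a: str, seq_b: str, k: int) -> set[int]:
    """Diagonals (offset into seq_b minus offset into seq_a) sharing a k-mer."""
    index: dict[str, list[int]] = {}
    for i in range(len(seq_a) - k + 1):
        index.setdefault(seq_a[i : i + k], []).append(i)
    diags: set[int] = set()
    for j in range(len(seq_b) - k + 1):
        for i in index.get(seq_b[j : j + k], ()):
            diags.add(j - i)
    return diags


def find_repeats(
    seq: str,
    min_len: int = DEFAULT_MIN_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    circular: bool = False,
    k: int = SEED_K,
    ambiguity_budget: float = 0.01,
) -> list[RepeatPair]:
    """Find all maximal repeat pairs of a genome on both strands.

    Parameters mirror a blastn-style self-comparison: pairs of intervals of
    length >= ``min_len`` whose ungapped identity is >= ``min_identity`` are
    reported with ``interval_a`` lexicographically <= ``interval_b``. On
    circular genomes the search runs on the doubled sequence and results are
    deduplicated modulo genome length, so origin-crossing repeats are found.
    """
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    seq = seq.upper()
    n = len(seq)
    bad = sum(c not in "ACGT" for c in seq)
    if n and bad / n > ambiguity_budget:
        raise AmbiguityError(
            f"{bad}/{n} non-ACGT characters exceed ambiguity budget {ambiguity_budget}"
        )
    k = min(k, min_len)
    work = seq + seq if circular else seq
    pairs: set[RepeatPair] = set()

    # same strand: diagonal d > 0, match[i] <=> work[i] == work[i+d]
    m = len(work)
    for d in sorted(x for x in _seed_diagonals(work, work, k) if x > 0):
        track = [work[i] == work[i + d] for i in range(m - d)]
        for start, length, ident in _segments(track, min_len, min_identity):
            _add_pair(pairs, (start, start + length), (start + d, start + d + length),
                      "same", ident, n, circular)

    # inverted: anti-diagonal c = i + j, i < j, match <=> work[i] == comp(work[j])
    rc = revcomp(work)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for dr in _seed_diagonals(work, rc, k):
        # rc position jr maps to genomic j = m - 1 - jr; diagonal dr = jr - ir
        c = m - 1 - dr  # i + j constant
        lo = max(0, c - m + 1)
        hi = (c - 1) // 2  # enforce i < j
        if hi < lo:
            continue
        track = [comp.get(work[c - i]) == work[i] for i in range(lo, hi + 1)]
        for off, length, ident in _segments(track, min_len, min_identity):
            i1 = lo + off
            i2 = i1 + length - 1
            a = (i1, i2 + 1)
            b = (c - i2, c - i1 + 1)
            _add_pair(pairs, a, b, "inverted", ident, n, circular)

    kept = pairs
    if circular:
        # the doubled sequence can report clipped versions of a wrapped repeat
        def iv_in(p_iv, q_iv) -> bool:
            for shift in (0, n, -n):
                if q_iv[0] <= p_iv[0] + shift and p_iv[1] + shift <= q_iv[1]:
                    return True
            return False

        def covered(p: RepeatPair, q: RepeatPair) -> bool:
            if q is p or q.strand != p.strand:
                return False
            if (q.length, q.interval_a, q.interval_b) <= (
                p.length, p.interval_a, p.interval_b
            ) and q.length <= p.length:
                return False  # prefer the longer (or canonically first) pair
            return (
                iv_in(p.interval_a, q.interval_a) and iv_in(p.interval_b, q.interval_b)
            ) or (
                iv_in(p.interval_a, q.interval_b) and iv_in(p.interval_b, q.interval_a)
            )

        kept = {p for p in pairs if not any(covered(p, q) for q in pairs)}
    return sorted(kept, key=lambda p: (p.interval_a, p.interval_b, p.strand))


def _add_pair(pairs, a, b, strand, ident, n, circular):
    if circular:
        if a[1] - a[0] > n:
            return  # longer than the genome: pure doubling artifact
        # canonicalize each interval start into [0, n); e > n encodes a wrap
        a = (a[0] % n, a[0] % n + (a[1] - a[0]))
        b = (b[0] % n, b[0] % n + (b[1] - b[0]))
    if a > b:
        a, b = b, a
    if a == b:
        return  # trivial self-match (or doubling artifact after wrapping)
    pairs.add(RepeatPair(interval_a=a, interval_b=b, strand=strand, identity=ident))


def build_mask(pairs: list[RepeatPair], genome_length: int) -> Mask:
    """Union of all repeat-pair intervals, merged and sorted.

    Intervals extending past genome_length (circular origin-crossers) wrap.
    """
    raw: list[tuple[int, int]] = []
    for p in pairs:
        for s, e in (p.interval_a, p.interval_b):
            length = e - s
            s %= genome_length
            e = s + length
            if e > genome_length:
                raw.append((s, genome_length))
                raw.append((0, e - genome_length))
            else:
                raw.append((s, e))
    raw.sort()
    merged: list[tuple[int, int]] = []
    for s, e in raw:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return Mask(intervals=merged, genome_length=genome_length)


def masked_fraction(mask: Mask) -> float:
    """Total masked length over genome length, in [0, 1]."""
    if mask.genome_length == 0:
        return 0.0
    return mask.masked_length() / mask.genome_length


def filter_variants(variants: list[VariantSite], mask: Mask) -> list[VariantSite]:
    """Drop variants whose reference span intersects the mask; keep order."""
    kept = []
    for v in variants:
        start = v.pos - 1
        end = start + len(v.ref)
        if end > mask.genome_length:
            raise ValueError(
                f"variant at pos {v.pos} extends past genome length {mask.genome_length}"
            )
        if not mask.overlaps(start, end):
            kept.append(v)
    return kept


def filter_vcf_file(in_path: str | Path, out_path: str | Path, mask: Mask) -> tuple[int, int]:
    """Pass-through VCF filtering: copy records whose reference span avoids
    the mask, preserving all fields. Returns (n_kept, n_removed)."""
    import pysam

    vf = pysam.VariantFile(str(in_path))
    out = pysam.VariantFile(str(out_path), "w", header=vf.header)
    kept = removed = 0
    for rec in vf:
        start = rec.pos - 1
        end = start + len(rec.ref)
        if mask.overlaps(start, end):
            removed += 1
        else:
            out.write(rec)
            kept += 1
    out.close()
    vf.close()
    return kept, removed


def write_mask_bed(mask: Mask, path: str | Path, name: str = "repeat") -> None:
    with open(path, "w") as fh:
        for i, (s, e) in enumerate(mask.intervals):
            fh.write(f"{name}\t{s}\t{e}\trepeat_{i + 1}\n")


def write_pairs_bed(pairs: list[RepeatPair], path: str | Path, name: str = "repeat") -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(pairs):
            for side, (s, e) in (("a", p.interval_a), ("b", p.interval_b)):
                fh.write(
                    f"{name}\t{s}\t{e}\tpair{i + 1}{side}\t"
                    f"{p.identity:.4f}\t{'+' if p.strand == 'same' else '-'}\n"
                )
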