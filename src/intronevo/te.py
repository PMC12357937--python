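"""Transposable-element signatures in newly gained introns.

A DNA-transposon insertion leaves a characteristic footprint: a short
target-site duplication (TSD, exact direct repeat) flanking the element,
terminal inverted repeats (TIR) at the element ends, often an internal
tandem array, and — because the element is mobile — similar copies
interspersed across the genome.  When an insertion lands in an exon and is
spliced out as a new intron, the splice gt/ag dinucleotides may lie INSIDE
the direct and inverted repeats, so the detectors here allow repeats to
straddle the exon/intron junctions.

Coordinates in TSD reports are relative to the intron: position 0 is the
first intron base, negative positions are in the 5' exonic flank, and
positions >= len(intron) are in the 3' flank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .gene_models import revcomp


@dataclass(frozen=True)
class TsdCandidate:
    length: int
    seq: str
    span5: tuple[int, int]  # intron-relative, half-open
    span3: tuple[int, int]


@dataclass(frozen=True)
class TirCandidate:
    arm_length: int
    identity: float
    left_arm: str
    right_arm: str
    left_start3: str
    right_end3: str
    left_offset: int = 0  # arm start distance from the element 5' end
    right_offset: int = 0  # arm end distance from the element 3' end


@dataclass(frozen=True)
class TandemRepeat:
    unit_length: int
    copies: float
    span: tuple[int, int]
    match_fraction: float
    low_complexity: bool = False


@dataclass(frozen=True)
class InterspersedHit:
    contig_id: str
    span: tuple[int, int]
    query_coverage: float
    identity: float


@dataclass
class TeClassification:
    is_putative_te: bool
    n_loci: int
    tsd: list[TsdCandidate] = field(default_factory=list)
    tir: TirCandidate | None = None
    tandem: TandemRepeat | None = None
    interspersed: list[InterspersedHit] = field(default_factory=list)


# ---------------------------------------------------------------------------
# target-site duplications


def _boundary_distance(start: int, end: int, boundary: int) -> int:
    """0 if [start,end) overlaps or abuts the boundary, else the gap in nt."""
    return max(start - boundary, boundary - end, 0)


def detect_tsd(
    flank5: str,
    intron: str,
    flank3: str,
    min_len: int = 3,
    max_len: int = 10,
    window: int = 10,
    exon_only: bool = False,
) -> list[TsdCandidate]:
    """Exact direct-repeat pairs bracketing the intron boundaries.

    Reports every exact L-mer (min_len <= L <= max_len) occurring once
    within ``window`` nt of the 5' exon/intron junction and once within
    ``window`` nt of the 3' junction, sorted by descending length, then by
    5'-junction proximity.  Each occurrence is assigned to the junction it
    is nearest to, so both copies of a candidate genuinely bracket the
    inserted element.  Repeats may straddle the junctions unless
    ``exon_only`` restricts occurrences to the exonic flanks.
    """
    if not flank5 or not flank3 or len(intron) < 4:
        return []
    full = (flank5 + intron + flank3).lower()
    off = len(flank5)
    b5, b3 = 0, len(intron)  # intron-relative junction coordinates
    out: list[TsdCandidate] = []
    for length in range(max_len, min_len - 1, -1):
        hits5: list[int] = []
        hits3: list[int] = []
        for a in range(len(full) - length + 1):
            rel = a - off
            d5 = _boundary_distance(rel, rel + length, b5)
            d3 = _boundary_distance(rel, rel + length, b3)
            if exon_only:
                near5 = rel + length <= b5 and d5 <= window
                near3 = rel >= b3 and d3 <= window
            else:
                near5 = d5 <= window and d5 <= d3
                near3 = d3 <= window and d3 < d5
            if near5:
                hits5.append(rel)
            if near3:
                hits3.append(rel)
        for a5 in hits5:
            for a3 in hits3:
                if a5 + length > a3:  # must be two distinct, ordered copies
                    continue
                s5 = full[a5 + off : a5 + off + length]
                s3 = full[a3 + off : a3 + off + length]
                if s5 == s3:
                    out.append(
                        TsdCandidate(
                            length=length,
                            seq=s5,
                            span5=(a5, a5 + length),
                            span3=(a3, a3 + length),
                        )
                    )
    out.sort(
        key=lambda c: (
            -c.length,
            _boundary_distance(c.span5[0], c.span5[1], b5),
            c.span5[0],
            c.span3[0],
        )
    )
    return out


# ---------------------------------------------------------------------------
# terminal inverted repeats


def _arm_identity(left: str, right: str) -> float:
    rc = revcomp(right)
    return sum(a == b for a, b in zip(left.lower(), rc.lower())) / len(left)


def detect_tir(
    element: str,
    min_arm: int = 8,
    max_mismatch: float = 0.2,
    end_slop: int = 4,
) -> TirCandidate | None:
    """Longest terminal-inverted-repeat arm pair of an element.

    For each pair of end offsets (0..end_slop nt trimmed from either end,
    to absorb element boundaries that do not coincide with the splice
    sites) the left arm is compared with the reverse complement of the
    right arm, starting at ``min_arm`` and extending greedily while the
    identity stays >= 1 - max_mismatch.  Returns the candidate with the
    longest arm (ties: higher identity, then smaller offsets), or None if
    no arm of minimum length qualifies anywhere.
    """
    n = len(element)
    if n < 2 * min_arm:
        return None
    best: TirCandidate | None = None
    for o5 in range(end_slop + 1):
        for o3 in range(end_slop + 1):
            avail = n - o5 - o3
            if avail < 2 * min_arm:
                continue
            ident = _arm_identity(
                element[o5 : o5 + min_arm],
                element[n - o3 - min_arm : n - o3],
            )
            if ident < 1 - max_mismatch:
                continue
            m, best_m, best_ident = min_arm, min_arm, ident
            while 2 * (m + 1) <= avail:
                m += 1
                ident = _arm_identity(
                    element[o5 : o5 + m], element[n - o3 - m : n - o3]
                )
                if ident < 1 - max_mismatch:
                    break
                best_m, best_ident = m, ident
            left = element[o5 : o5 + best_m]
            right = element[n - o3 - best_m : n - o3]
            cand = TirCandidate(
                arm_length=best_m,
                identity=best_ident,
                left_arm=left,
                right_arm=right,
                left_start3=left[:3].lower(),
                right_end3=right[-3:].lower(),
                left_offset=o5,
                right_offset=o3,
            )
            key = (cand.arm_length, cand.identity, -o5 - o3)
            if best is None or key > (
                best.arm_length, best.identity, -best.left_offset - best.right_offset
            ):
                best = cand
    return best


# ---------------------------------------------------------------------------
# tandem repeats


def _best_window(scores: Sequence[int], min_len: int) -> tuple[int, int] | None:
    """Max-sum contiguous window of length >= min_len; (start, end) or None."""
    n = len(scores)
    if n < min_len:
        return None
    prefix = [0] * (n + 1)
    for i, s in enumerate(scores):
        prefix[i + 1] = prefix[i] + s
    best = None
    best_sum = None
    min_idx = 0
    for end in range(min_len, n + 1):
        cand = end - min_len  # rightmost prefix index usable as window start
        if prefix[cand] < prefix[min_idx]:
            min_idx = cand
        s = prefix[end] - prefix[min_idx]
        if best_sum is None or s > best_sum:
            best_sum = s
            best = (min_idx, end)
    return best


def _match_fraction(seq: str, lag: int, start: int, end: int) -> float:
    compared = [
        seq[i] == seq[i + lag] for i in range(start, min(end, len(seq) - lag))
    ]
    return sum(compared) / len(compared) if compared else 0.0


def tandem_period(
    seq: str,
    min_unit: int = 5,
    max_unit: int = 100,
    min_match: float = 0.8,
    min_copies: float = 3.0,
    min_matches: int = 10,
) -> TandemRepeat | None:
    """Detect the tandem-repeat period of a sequence by shift-matching.

    For each candidate unit length k, positions i are scored by whether
    ``seq[i] == seq[i+k]``; the best-supported contiguous window is
    located by a weighted maximum-sum scan whose weights encode the
    match-fraction threshold.  Among unit lengths whose best window
    reaches the threshold, the one covering the most matching positions
    wins; exact ties go to the smallest unit, so a 74-nt period never
    shadows a true 37-nt repeat.  A call needs at least ``min_copies``
    units of span and ``min_matches`` matching positions — random sequence
    routinely contains two-copy-sized coincidences at short lags, so a
    confident period requires three copies' worth of evidence.
    Homopolymer-like signals (a sub-period shorter than ``min_unit`` that
    also clears the threshold over the same span) are flagged low
    complexity.
    """
    seq = seq.lower()
    n = len(seq)
    if n < 2 * min_unit:
        return None
    # weight -w for mismatches makes windows with fraction >= w/(1+w)
    # non-negative; w=4 corresponds to the default 0.8 threshold
    w = max(1, round(min_match / (1 - min_match))) if min_match < 1 else 4
    best: TandemRepeat | None = None
    best_matches = -1
    for k in range(min_unit, min(max_unit, n // 2) + 1):
        min_len = max(int((min_copies - 1) * k), 1)
        scores = [1 if seq[i] == seq[i + k] else -w for i in range(n - k)]
        win = _best_window(scores, min_len=min_len)
        if win is None:
            continue
        start, end = win
        length = end - start
        matches = sum(1 for i in range(start, end) if seq[i] == seq[i + k])
        fraction = matches / length
        if fraction < min_match or length < min_len or matches < min_matches:
            continue
        if matches > best_matches:
            span = (start, end + k)
            low = any(
                _match_fraction(seq, d, start, end) >= min_match
                for d in range(1, min_unit)
            )
            best = TandemRepeat(
                unit_length=k,
                copies=(length + k) / k,
                span=span,
                match_fraction=fraction,
                low_complexity=low,
            )
            best_matches = matches
    return best


# ---------------------------------------------------------------------------
# interspersed genomic copies (seed-and-extend k-mer scan)


def _diagonal_clusters(
    pairs: list[tuple[int, int]], gap_budget: int
) -> list[list[tuple[int, int]]]:
    """Group (qpos, cpos) seed pairs whose diagonals agree within the budget
    and which are positionally contiguous (no jump larger than a query)."""
    pairs = sorted(pairs, key=lambda p: (p[1] - p[0], p[1]))
    clusters: list[list[tuple[int, int]]] = []
    for q, c in pairs:
        d = c - q
        placed = False
        for cl in clusters:
            q0, c0 = cl[-1]
            if abs(d - (c0 - q0)) <= gap_budget:
                cl.append((q, c))
                placed = True
                break
        if not placed:
            clusters.append([(q, c)])
    return clusters


def scan_interspersed(
    query: str,
    contigs: Iterable[tuple[str, str]],
    k: int = 13,
    min_coverage: float = 0.5,
    min_identity: float = 0.8,
    gap_budget: int = 10,
    own_locus: tuple[str, int, int] | None = None,
) -> list[InterspersedHit]:
    """Find interspersed genomic copies of a query by seed-and-extend.

    Exact k-mer seed matches are chained by diagonal (offset agreement
    within ``gap_budget``), extended greedily outwards through matching
    bases, and scored ungapped on the dominant diagonal.  Hits must reach
    the coverage and identity thresholds; the query's own locus is excluded
    when its coordinates are supplied as ``(contig_id, start, end)``.
    """
    query = query.lower()
    if len(query) < k:
        return []
    seeds: dict[str, list[int]] = {}
    for i in range(len(query) - k + 1):
        seeds.setdefault(query[i : i + k], []).append(i)
    hits: list[InterspersedHit] = []
    for contig_id, contig in contigs:
        contig_l = contig.lower()
        pairs: list[tuple[int, int]] = []
        for j in range(len(contig_l) - k + 1):
            for qpos in seeds.get(contig_l[j : j + k], ()):
                pairs.append((qpos, j))
        if not pairs:
            continue
        occupied: list[tuple[int, int]] = []
        for cluster in _diagonal_clusters(pairs, gap_budget):
            diags = [c - q for q, c in cluster]
            diag = sorted(diags)[len(diags) // 2]
            qlo = min(q for q, _ in cluster)
            qhi = max(q for q, _ in cluster) + k
            # greedy ungapped extension through matching bases
            while (
                qlo > 0
                and 0 <= qlo - 1 + diag < len(contig_l)
                and query[qlo - 1] == contig_l[qlo - 1 + diag]
            ):
                qlo -= 1
            while (
                qhi < len(query)
                and 0 <= qhi + diag < len(contig_l)
                and query[qhi] == contig_l[qhi + diag]
            ):
                qhi += 1
            compared = [
                query[i] == contig_l[i + diag]
                for i in range(qlo, qhi)
                if 0 <= i + diag < len(contig_l)
            ]
            if not compared:
                continue
            identity = sum(compared) / len(compared)
            coverage = (qhi - qlo) / len(query)
            span = (qlo + diag, qhi + diag)
            if coverage < min_coverage or identity < min_identity:
                continue
            if own_locus is not None and contig_id == own_locus[0]:
                if span[0] < own_locus[2] and span[1] > own_locus[1]:
                    continue
            if any(span[0] < e and span[1] > s for s, e in occupied):
                continue  # one hit per locus
            occupied.append(span)
            hits.append(
                InterspersedHit(
                    contig_id=contig_id,
                    span=span,
                    query_coverage=coverage,
                    identity=identity,
                )
            )
    hits.sort(key=lambda h: (-h.query_coverage, -h.identity, h.contig_id))
    return hits


# ---------------------------------------------------------------------------
# composite classification


def classify_te(
    flank5: str,
    intron: str,
    flank3: str,
    contigs: Iterable[tuple[str, str]],
    min_loci: int = 3,
    own_locus: tuple[str, int, int] | None = None,
    **scan_kwargs,
) -> TeClassification:
    """Run all signature detectors and call the intron a putative TE.

    The call follows the interspersal criterion alone (an element similar
    to ``min_loci`` or more distinct genomic loci); TSD/TIR/tandem evidence
    is bundled for the report but does not gate the call.
    """
    tsd = detect_tsd(flank5, intron, flank3)
    tir = detect_tir(intron)
    tandem = tandem_period(intron) if len(intron) >= 10 else None
    hits = scan_interspersed(
        intron, contigs, own_locus=own_locus, **scan_kwargs
    )
    return TeClassification(
        is_putative_te=len(hits) >= min_loci,
        n_loci=len(hits),
        tsd=tsd,
        tir=tir,
        tandem=tandem,
        interspersed=hits,
    )
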