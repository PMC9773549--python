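"""Seed-and-extend local nucleotide aligner with megablast-style defaults.

The aligner finds exact word matches (contiguous 28-mers by default) between a
query and a subject and extends each seeded region to the best-scoring local
alignment under a +1/-2 match/mismatch scheme with linear (per-character) gap
costs. Raw scores are converted to bit scores with the Karlin-Altschul
transformation ``bits = (lambda * S - ln K) / ln 2`` using the constants the
NCBI blastn program applies to the +1/-2 scoring scheme, so bit-score cutoffs
expressed in blastn units carry over directly.

Extension is an exact Smith-Waterman restricted to a window around the seeds
of a query/subject pair. For small pairs the window covers every alignment
that can pass through a seed, so the reported raw score equals the optimal
local-alignment score whenever the optimum contains an exact seed word. For
large pairs the window starts narrow and is regrown whenever the optimal path
touches a window edge — the usual X-drop-style compromise, except that the
alignment inside the final window is exact rather than greedy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from numba import njit

__all__ = [
    "AlignmentParams",
    "AlignmentHit",
    "reverse_complement",
    "find_seed_hits",
    "extend_seed",
    "bitscore",
    "align_pair",
    "align_all",
    "hits_to_frame",
    "OUTFMT6_COLUMNS",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Column order of the tabular hit dialect (BLAST ``-outfmt 6``).
OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

# Full-window exact extension is used while query x window stays below this
# cell count; beyond it the adaptive regrowing window takes over.
_MAX_EXACT_CELLS = 4_000_000


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and reporting parameters.

    Defaults mirror the megablast task of blastn: word size 28, match +1,
    mismatch -2, linear gaps, both strands. ``karlin_lambda``/``karlin_k``
    are the blastn constants for the +1/-2 scheme (a perfect 64-nt match
    scores 119.3 bits, printed as 119 by blastn). ``gap_cost`` is charged per
    gap character; 2.5 reproduces the non-affine gap cost blastn derives for
    +1/-2 (mismatch plus half a match).
    """

    word_size: int = 28
    match_reward: int = 1
    mismatch_penalty: int = -2
    gap_cost: float = 2.5
    karlin_lambda: float = 1.28
    karlin_k: float = 0.46
    min_bitscore_report: float = 50.0
    search_both_strands: bool = True
    xdrop: float = 20.0

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if not (self.match_reward > 0 > self.mismatch_penalty):
            raise ValueError("need match_reward > 0 > mismatch_penalty")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")
        if self.gap_cost <= 0:
            raise ValueError("gap_cost must be positive")

    def with_floor(self, min_bitscore_report: float) -> "AlignmentParams":
        return replace(self, min_bitscore_report=min_bitscore_report)


@dataclass
class AlignmentHit:
    """One local alignment between a query and a subject.

    Intervals are 0-based half-open on the forward strand of each sequence;
    ``strand`` is '+' or '-' (minus means the query's reverse complement
    aligns to the subject forward strand).
    """

    query_id: str
    subject_id: str
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    strand: str
    matches: int
    mismatches: int
    gap_chars: int
    gap_opens: int
    length: int  # alignment columns, gaps included
    percent_identity: float
    query_coverage: float
    raw_score: float
    bitscore: float


def bitscore(raw_score: float, params: AlignmentParams) -> float:
    """Karlin-Altschul normalized score in bits."""
    return (params.karlin_lambda * raw_score - math.log(params.karlin_k)) / math.log(2.0)


_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3 and anything else (incl. N) as 4."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _words(seq: str, w: int) -> Iterable[tuple[str, int]]:
    seq = seq.upper()
    for i in range(len(seq) - w + 1):
        word = seq[i:i + w]
        if "N" not in word:
            yield word, i


def find_seed_hits(query: str, subject: str,
                   params: AlignmentParams | None = None) -> list[tuple[int, int, str]]:
    """Exact word matches between query (either strand) and subject.

    Returns ``(query_pos, subject_pos, strand)`` triples where ``query_pos``
    is the word start in the strand-oriented query (the reverse complement of
    the query for '-' seeds). Words containing N never match. Ordered by
    subject position, then query position, '+' before '-'.
    """
    params = params or AlignmentParams()
    w = params.word_size
    if len(query) < w or len(subject) < w:
        return []
    index: dict[str, list[tuple[int, str]]] = {}
    for word, i in _words(query, w):
        index.setdefault(word, []).append((i, "+"))
    if params.search_both_strands:
        for word, i in _words(reverse_complement(query), w):
            index.setdefault(word, []).append((i, "-"))
    seeds: list[tuple[int, int, str]] = []
    for word, j in _words(subject, w):
        for i, strand in index.get(word, ()):
            seeds.append((i, j, strand))
    seeds.sort(key=lambda t: (t[1], t[0], t[2]))
    return seeds


@njit(cache=True)
def _sw_matrix(q, s, match, mismatch, gap):  # pragma: no cover - numba kernel
    n, m = q.shape[0], s.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.float32)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            if qi == s[j - 1] and qi != 4:
                sc = H[i - 1, j - 1] + match
            else:
                sc = H[i - 1, j - 1] + mismatch
            up = H[i - 1, j] - gap
            if up > sc:
                sc = up
            left = H[i, j - 1] - gap
            if left > sc:
                sc = left
            if sc < 0.0:
                sc = 0.0
            H[i, j] = sc
            # first strict improvement in row-major order: deterministic
            if sc > best:
                best = sc
                bi = i
                bj = j
    return H, best, bi, bj


def _traceback(H: np.ndarray, q: np.ndarray, s: np.ndarray, bi: int, bj: int,
               params: AlignmentParams) -> tuple[int, int, int, int, int, int]:
    """Walk back from (bi, bj); returns (qs, ss, matches, mismatches, gap_chars, gap_opens)."""
    match, mismatch, gap = params.match_reward, params.mismatch_penalty, params.gap_cost
    i, j = bi, bj
    matches = mism = gaps = gap_opens = 0
    in_gap = False
    eps = 1e-4
    while i > 0 and j > 0 and H[i, j] > eps:
        diag = match if (q[i - 1] == s[j - 1] and q[i - 1] != 4) else mismatch
        if abs(H[i, j] - (H[i - 1, j - 1] + diag)) < eps:
            if diag == match:
                matches += 1
            else:
                mism += 1
            i -= 1
            j -= 1
            in_gap = False
        elif abs(H[i, j] - (H[i - 1, j] - gap)) < eps:
            gaps += 1
            if not in_gap:
                gap_opens += 1
            in_gap = True
            i -= 1
        else:
            gaps += 1
            if not in_gap:
                gap_opens += 1
            in_gap = True
            j -= 1
    return i, j, matches, mism, gaps, gap_opens


def _best_local(qarr: np.ndarray, sarr: np.ndarray, params: AlignmentParams):
    """Optimal local alignment of two encoded arrays, or None if score 0."""
    H, best, bi, bj = _sw_matrix(
        qarr, sarr, float(params.match_reward),
        float(params.mismatch_penalty), float(params.gap_cost))
    if best <= 0:
        return None
    qs, ss, matches, mism, gaps, gap_opens = _traceback(H, qarr, sarr, bi, bj, params)
    return float(best), qs, bi, ss, bj, matches, mism, gaps, gap_opens


def _seed_clusters(seeds: Sequence[tuple[int, int]], qlen: int
                   ) -> list[tuple[int, int, int, int]]:
    """Group seeds whose subject positions are within a query length of each
    other; returns (qmin, qmax, smin, smax) word-start bounding boxes."""
    spans = sorted((s, q) for q, s in seeds)
    clusters = []
    qmin = qmax = spans[0][1]
    smin = prev = spans[0][0]
    for s, q in spans[1:]:
        if s - prev > qlen:
            clusters.append((qmin, qmax, smin, prev))
            qmin = qmax = q
            smin = s
        else:
            qmin = min(qmin, q)
            qmax = max(qmax, q)
        prev = s
    clusters.append((qmin, qmax, smin, prev))
    return clusters


def _extend_cluster(qarr: np.ndarray, sarr: np.ndarray, box, params: AlignmentParams):
    """Exact SW in a window around one seed cluster.

    Starts from a window wide enough for any alignment through the seeds when
    that is cheap; otherwise starts narrow and regrows (x4) whenever the best
    path touches a window edge, until the path is interior or the window spans
    both sequences.
    """
    qlen, slen = len(qarr), len(sarr)
    w = params.word_size
    qmin, qmax, smin, smax = box
    full_pad = qlen + w  # covers any alignment through a seed
    cells_full = qlen * min(slen, (smax - smin) + w + 2 * full_pad)
    pad = full_pad if cells_full <= _MAX_EXACT_CELLS else 256
    while True:
        qlo = max(0, qmin - pad)
        qhi = min(qlen, qmax + w + pad)
        slo = max(0, smin - pad)
        shi = min(slen, smax + w + pad)
        res = _best_local(qarr[qlo:qhi], sarr[slo:shi], params)
        if res is None:
            return None
        score, qs, qe, ss, se, matches, mism, gaps, gap_opens = res
        at_edge = ((qs == 0 and qlo > 0) or (qe == qhi - qlo and qhi < qlen) or
                   (ss == 0 and slo > 0) or (se == shi - slo and shi < slen))
        if not at_edge:
            return score, (qlo + qs, qlo + qe, slo + ss, slo + se,
                           matches, mism, gaps, gap_opens)
        pad *= 4


def _extend_seeds(qarr: np.ndarray, sarr: np.ndarray,
                  seeds: Sequence[tuple[int, int]], params: AlignmentParams):
    """Best alignment over all seed clusters of one oriented query/subject pair."""
    best = None
    for box in _seed_clusters(seeds, len(qarr)):
        res = _extend_cluster(qarr, sarr, box, params)
        if res is None:
            continue
        score, detail = res
        # max score; ties: leftmost, then longest, on the subject
        key = (score, -detail[2], detail[3])
        if best is None or key > best[0]:
            best = (key, score, detail)
    if best is None:
        return None
    return best[1], best[2]


def _make_hit(query_id: str, subject_id: str, qlen: int, strand: str,
              score: float, detail, params: AlignmentParams) -> AlignmentHit:
    qs, qe, ss, se, matches, mism, gaps, gap_opens = detail
    if strand == "-":
        qs, qe = qlen - qe, qlen - qs
    length = matches + mism + gaps
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        query_interval=(qs, qe),
        subject_interval=(ss, se),
        strand=strand,
        matches=matches,
        mismatches=mism,
        gap_chars=gaps,
        gap_opens=gap_opens,
        length=length,
        percent_identity=100.0 * matches / length if length else 0.0,
        query_coverage=100.0 * (qe - qs) / qlen if qlen else 0.0,
        raw_score=score,
        bitscore=bitscore(score, params),
    )


def _best_hit_for_pair(query_id: str, query: str, subject_id: str, subject: str,
                       seeds_by_strand: dict[str, list[tuple[int, int]]],
                       params: AlignmentParams) -> AlignmentHit | None:
    sarr = encode(subject)
    best: AlignmentHit | None = None
    for strand in ("+", "-"):
        if strand not in seeds_by_strand:
            continue
        oriented = query if strand == "+" else reverse_complement(query)
        res = _extend_seeds(encode(oriented), sarr, seeds_by_strand[strand], params)
        if res is None:
            continue
        score, detail = res
        hit = _make_hit(query_id, subject_id, len(query), strand, score, detail, params)
        if best is None or hit.raw_score > best.raw_score:
            best = hit
    if best is None or best.bitscore < params.min_bitscore_report:
        return None
    return best


def align_pair(query: str, subject: str, params: AlignmentParams | None = None,
               query_id: str = "query", subject_id: str = "subject") -> AlignmentHit | None:
    """Best reportable hit between one query and one subject, or None.

    All seeds of the pair are extended and merged to the single best-scoring
    hit; ties between strands resolve to '+'.
    """
    params = params or AlignmentParams()
    seeds = find_seed_hits(query, subject, params)
    if not seeds:
        return None
    by_strand: dict[str, list[tuple[int, int]]] = {}
    for qpos, spos, strand in seeds:
        by_strand.setdefault(strand, []).append((qpos, spos))
    return _best_hit_for_pair(query_id, query, subject_id, subject, by_strand, params)


def extend_seed(query: str, subject: str, seed: tuple[int, int, str],
                params: AlignmentParams | None = None,
                query_id: str = "query", subject_id: str = "subject") -> AlignmentHit | None:
    """Extend one seed to its best-scoring hit, or None below the floor."""
    params = params or AlignmentParams()
    qpos, spos, strand = seed
    return _best_hit_for_pair(query_id, query, subject_id, subject,
                              {strand: [(qpos, spos)]}, params)


def _query_word_index(queries: Sequence[tuple[str, str]], params: AlignmentParams):
    """word -> list of (query_index, strand, word_start_in_oriented_query)."""
    index: dict[str, list[tuple[int, str, int]]] = {}
    w = params.word_size
    for qi, (_, seq) in enumerate(queries):
        for word, i in _words(seq, w):
            index.setdefault(word, []).append((qi, "+", i))
        if params.search_both_strands:
            for word, i in _words(reverse_complement(seq), w):
                index.setdefault(word, []).append((qi, "-", i))
    return index


def align_all(queries: Sequence[tuple[str, str]] | dict,
              subjects: Sequence[tuple[str, str]] | dict,
              params: AlignmentParams | None = None) -> list[AlignmentHit]:
    """Best hit per (query, subject) pair above the reporting floor.

    ``queries``/``subjects`` are ``(id, sequence)`` pairs (or mappings).
    The query set is word-indexed once and every subject is scanned against
    the index, so cost is linear in total subject length plus the seeded
    extensions. Output order: subjects in input order, then queries in input
    order (stable and deterministic).
    """
    params = params or AlignmentParams()
    if isinstance(queries, dict):
        queries = list(queries.items())
    if isinstance(subjects, dict):
        subjects = list(subjects.items())
    if not queries:
        raise ValueError("empty query set")
    index = _query_word_index(queries, params)
    w = params.word_size
    hits: list[AlignmentHit] = []
    for sid, sseq in subjects:
        seeds: dict[int, dict[str, list[tuple[int, int]]]] = {}
        for word, j in _words(sseq, w):
            for qi, strand, qpos in index.get(word, ()):
                seeds.setdefault(qi, {}).setdefault(strand, []).append((qpos, j))
        for qi in sorted(seeds):
            qid, qseq = queries[qi]
            hit = _best_hit_for_pair(qid, qseq, sid, sseq, seeds[qi], params)
            if hit is not None:
                hits.append(hit)
    return hits


def hits_to_frame(hits: Iterable[AlignmentHit]):
    """Hit list as a BLAST tabular (outfmt 6) DataFrame.

    Coordinates are converted to the 1-based inclusive convention; minus-strand
    hits carry descending subject coordinates. The evalue column is "NA"
    (cutoffs in this toolkit are bit-score based).
    """
    import pandas as pd

    rows = []
    for h in hits:
        qs, qe = h.query_interval
        ss, se = h.subject_interval
        if h.strand == "+":
            sstart, send = ss + 1, se
        else:
            sstart, send = se, ss + 1
        rows.append((h.query_id, h.subject_id, round(h.percent_identity, 3),
                     h.length, h.mismatches, h.gap_opens, qs + 1, qe,
                     sstart, send, "NA", round(h.bitscore, 1)))
    return pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)
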