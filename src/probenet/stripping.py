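"""Iterative "stripping" of host homology from viral genomes.

Viral genomes share enough sequence with their hosts (captured integrations,
pirated genes, telomere-like repeats) that reads matching an intact genome
cannot be called viral with confidence. Stripping excises every region of
the genome with host homology so that what remains is unambiguously viral:

* round 0 removes low-complexity intervals (a DUST-style triplet score) and
  tandem arrays of curated motifs (by default the telomeric repeat unit
  TAACCC, which several herpesvirus genomes carry);
* each subsequent round aligns all residual segments against the host
  database and deletes the whole query span of every hit, splitting
  segments and dropping fragments shorter than one probe length;
* rounds repeat until one removes nothing — deletion can create novel
  junctions or expose flanks that themselves match the host, which is why a
  single pass is not sufficient.

The residual segments keep their original genome coordinates, and every
removed interval is logged with its round and reason so alternative
stripping policies can be compared on the same audit trail.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .aligner import AlignmentParams, align_all

__all__ = [
    "DEFAULT_MIN_SEGMENT_LENGTH",
    "DEFAULT_CURATED_MOTIFS",
    "StrippedGenome",
    "StripLog",
    "low_complexity_mask",
    "find_motif_arrays",
    "strip_genome",
    "screen_stripped",
]

logger = logging.getLogger(__name__)

#: Residuals shorter than one probe length cannot anchor a read match with
#: meaningful specificity under a 28-nt seed, so they are dropped.
DEFAULT_MIN_SEGMENT_LENGTH = 64

#: Human telomeric repeat unit; tandem arrays of >=3 copies are excised.
DEFAULT_CURATED_MOTIFS = ("TAACCC",)

#: Conventional DUST score threshold.
DEFAULT_DUST_THRESHOLD = 2.0


@dataclass
class StrippedGenome:
    """Residual segments of a stripped genome, in original coordinates."""

    genome_id: str
    segments: list[tuple[int, int, str]]  # (start, end, sequence)
    rounds_used: int

    @property
    def residual_length(self) -> int:
        return sum(end - start for start, end, _ in self.segments)

    def segment_records(self) -> list[tuple[str, str]]:
        return [(f"{self.genome_id}|{start}-{end}", seq)
                for start, end, seq in self.segments]

    def concatenated_record(self) -> tuple[str, str]:
        coords = ";".join(f"{s}-{e}" for s, e, _ in self.segments)
        return (f"{self.genome_id} segments={coords}",
                "".join(seq for _, _, seq in self.segments))


@dataclass
class StripLog:
    """Per-round audit of removed intervals and residual lengths."""

    genome_id: str
    removed: list[tuple[int, int, int, str]] = field(default_factory=list)
    residual_lengths: list[int] = field(default_factory=list)

    def add(self, round_no: int, start: int, end: int, reason: str) -> None:
        self.removed.append((round_no, start, end, reason))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed,
                            columns=["round", "start", "end", "reason"])


def low_complexity_mask(sequence: str, window: int = 64,
                        threshold: float = DEFAULT_DUST_THRESHOLD) -> list[tuple[int, int]]:
    """DUST-style low-complexity intervals.

    Each window is scored as sum over triplet types of c*(c-1)/2 divided by
    (#triplets - 1); windows scoring above the threshold are masked and
    overlapping masked windows merge. A homopolymer scores (k-1)/2 per
    window (far above threshold); high-entropy random sequence scores ~0.5.
    """
    if window < 8:
        raise ValueError("window must be >= 8")
    seq = sequence.upper()
    n = len(seq)
    if n < window:
        window = n
    if window < 3:
        return []
    intervals: list[tuple[int, int]] = []
    k = window - 2  # triplets per window
    for start in range(0, n - window + 1):
        counts: dict[str, int] = {}
        for i in range(start, start + k):
            t = seq[i:i + 3]
            counts[t] = counts.get(t, 0) + 1
        score = sum(c * (c - 1) / 2 for c in counts.values()) / max(k - 1, 1)
        if score > threshold:
            if intervals and start <= intervals[-1][1]:
                intervals[-1] = (intervals[-1][0], start + window)
            else:
                intervals.append((start, start + window))
    return intervals


def find_motif_arrays(sequence: str, motifs=DEFAULT_CURATED_MOTIFS,
                      min_copies: int = 3) -> list[tuple[int, int]]:
    """Tandem arrays of >= min_copies of a curated motif (either strand)."""
    from .aligner import reverse_complement

    seq = sequence.upper()
    intervals = []
    units = set()
    for motif in motifs:
        units.add(motif.upper())
        units.add(reverse_complement(motif.upper()))
    for unit in sorted(units):
        pattern = re.compile(f"(?:{re.escape(unit)}){{{min_copies},}}")
        for m in pattern.finditer(seq):
            intervals.append((m.start(), m.end()))
    return _merge(intervals)


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for start, end in intervals[1:]:
        if start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _delete(segments: list[tuple[int, int, str]],
            removals: list[tuple[int, int]],
            min_segment_length: int) -> list[tuple[int, int, str]]:
    """Excise genome-coordinate intervals from segments, splitting and
    dropping fragments below the minimum length."""
    removals = _merge(removals)
    out: list[tuple[int, int, str]] = []
    for seg_start, seg_end, seq in segments:
        cuts = [(max(seg_start, s), min(seg_end, e))
                for s, e in removals if s < seg_end and e > seg_start]
        pos = seg_start
        pieces: list[tuple[int, int]] = []
        for s, e in cuts:
            if s > pos:
                pieces.append((pos, s))
            pos = max(pos, e)
        if pos < seg_end:
            pieces.append((pos, seg_end))
        for s, e in pieces:
            if e - s >= min_segment_length:
                out.append((s, e, seq[s - seg_start:e - seg_start]))
    return out


def strip_genome(genome: str, host_db, params: AlignmentParams | None = None,
                 curated_motifs=DEFAULT_CURATED_MOTIFS,
                 genome_id: str = "genome",
                 min_segment_length: int = DEFAULT_MIN_SEGMENT_LENGTH,
                 dust_window: int = 64,
                 dust_threshold: float = DEFAULT_DUST_THRESHOLD,
                 max_rounds: int | None = None) -> tuple[StrippedGenome, StripLog]:
    """Iteratively excise host-homologous and low-complexity regions.

    Terminates when an alignment round removes nothing; the terminal
    residual has zero host hits at the reporting floor. A genome consumed
    entirely yields an empty residual (valid; logged as a warning).
    """
    if len(genome) < 64:
        raise ValueError("genome shorter than one probe length")
    params = params or AlignmentParams()
    if isinstance(host_db, dict):
        host_db = list(host_db.items())
    log = StripLog(genome_id)
    genome = genome.upper()

    # round 0: low-complexity and curated-motif removal
    removals = [(s, e, "low-complexity")
                for s, e in low_complexity_mask(genome, dust_window, dust_threshold)]
    removals += [(s, e, "curated-motif")
                 for s, e in find_motif_arrays(genome, curated_motifs)]
    for s, e, reason in sorted(removals):
        log.add(0, s, e, reason)
    segments = _delete([(0, len(genome), genome)],
                       [(s, e) for s, e, _ in removals], min_segment_length)
    log.residual_lengths.append(sum(e - s for s, e, _ in segments))

    rounds = 0
    while segments:
        if max_rounds is not None and rounds >= max_rounds:
            break
        rounds += 1
        queries = [(f"{genome_id}|{s}-{e}", seq) for s, e, seq in segments]
        hits = align_all(queries, host_db, params)
        if not hits:
            break
        removals = []
        for h in hits:
            seg_start = int(h.query_id.rsplit("|", 1)[1].split("-")[0])
            qs, qe = h.query_interval
            removals.append((seg_start + qs, seg_start + qe))
        for s, e in _merge(removals):
            log.add(rounds, s, e, "host-match")
        segments = _delete(segments, removals, min_segment_length)
        log.residual_lengths.append(sum(e - s for s, e, _ in segments))
    if not segments:
        logger.warning("genome %s fully consumed by stripping", genome_id)
    return StrippedGenome(genome_id, segments, max(rounds, 1)), log


def screen_stripped(stripped, reads, host_db=None,
                    params: AlignmentParams | None = None,
                    cutoff: float | None = None) -> dict[str, int]:
    """Count reads matching each stripped genome's residual segments.

    Residual segments act as the query set; counts are distinct matching
    reads per genome, after host refiltering when a host database and cutoff
    are supplied (reuses the screening machinery).
    """
    from .screening import DEFAULT_HOST_BITSCORE_CUTOFF, refilter_host

    if isinstance(reads, dict):
        reads = list(reads.items())
    genomes = list(stripped)
    if not any(g.segments for g in genomes):
        raise ValueError("no residual segments in any stripped genome")
    queries = []
    genome_of = {}
    for g in genomes:
        for name, seq in g.segment_records():
            queries.append((name, seq))
            genome_of[name] = g.genome_id
    counts = {g.genome_id: 0 for g in genomes}
    if not queries or not reads:
        return counts
    hits = align_all(queries, reads, params)
    matched: dict[str, set[str]] = {}
    for h in hits:
        matched.setdefault(h.subject_id, set()).add(genome_of[h.query_id])
    if host_db is not None:
        lookup = dict(reads)
        pool = [(rid, lookup[rid]) for rid in sorted(matched)]
        kept, _, _ = refilter_host(pool, host_db,
                                   cutoff or DEFAULT_HOST_BITSCORE_CUTOFF, params)
        kept_ids = {rid for rid, _ in kept}
        matched = {rid: g for rid, g in matched.items() if rid in kept_ids}
    for rid, genome_ids in matched.items():
        for gid in genome_ids:
            counts[gid] += 1
    return counts
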