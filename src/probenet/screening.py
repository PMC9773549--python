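"""Screening read sets with a probe collection.

A screen has three stages. First, every probe is aligned against every read
(both strands) and all per-pair best hits above the reporting floor are
tabulated; counting rows per probe gives the raw per-probe counts. Second,
because sequence similarity is not transitive — a read matching a
host-filtered probe can still be of host origin via an intermediate sequence —
every matched read is re-aligned against the host database and discarded when
its best host bit score strictly exceeds a per-sample cutoff. Third, a read
matched by several probes is allocated to the single probe with the highest
bit score (ties to the lexicographically smallest probe name), so each
retained read contributes to exactly one probe's deduplicated count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .aligner import AlignmentHit, AlignmentParams, align_all, bitscore
from .probes import ProbeCollection

__all__ = [
    "DEFAULT_HOST_BITSCORE_CUTOFF",
    "ScreenCounts",
    "screen_reads",
    "refilter_host",
    "dedup_reads",
    "screen_sample",
    "suggest_host_cutoff",
    "crossmatch_matrix",
    "export_reads_by_probe",
]

logger = logging.getLogger(__name__)

#: Default bit-score cutoff above which a retrieved read is considered host
#: in origin; override per sample according to the dataset's read length.
DEFAULT_HOST_BITSCORE_CUTOFF = 150.0


@dataclass
class ScreenCounts:
    """Per-probe counts for one sample at the three screening stages."""

    sample_id: str
    raw_count: dict[str, int]
    filtered_count: dict[str, int]
    dedup_count: dict[str, int]
    mean_read_length: float
    host_bitscore_cutoff: float

    def to_frame(self) -> pd.DataFrame:
        probes = list(self.raw_count)
        return pd.DataFrame({
            "probe": probes,
            "raw": [self.raw_count[p] for p in probes],
            "filtered": [self.filtered_count[p] for p in probes],
            "dedup": [self.dedup_count[p] for p in probes],
        })


def screen_reads(probes: ProbeCollection, reads, params: AlignmentParams | None = None
                 ) -> list[AlignmentHit]:
    """All probe-vs-read hits above the reporting floor, both strands."""
    if len(probes) == 0:
        raise ValueError("empty probe collection")
    if isinstance(reads, dict):
        reads = list(reads.items())
    if not reads:
        logger.warning("empty read set: returning empty hit table")
        return []
    return align_all(probes.sequences(), reads, params)


def raw_counts(hits: list[AlignmentHit], probe_names) -> dict[str, int]:
    counts = {name: 0 for name in probe_names}
    for h in hits:
        counts[h.query_id] += 1
    return counts


def refilter_host(matched_reads, host_db, cutoff: float = DEFAULT_HOST_BITSCORE_CUTOFF,
                  params: AlignmentParams | None = None
                  ) -> tuple[list[tuple[str, str]], list[tuple[str, str]], dict[str, float]]:
    """Second-round host exclusion of retrieved reads.

    A read is discarded iff its best hit against the host database has a bit
    score strictly greater than ``cutoff``. Returns (kept, discarded,
    best_host_bitscore) where the mapping carries each read's best host bit
    score for audit (reads with no host hit are absent from it).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if isinstance(matched_reads, dict):
        matched_reads = list(matched_reads.items())
    if isinstance(host_db, dict):
        host_db = list(host_db.items())
    if not matched_reads:
        return [], [], {}
    # the refilter judges any host similarity, however weak, against the
    # cutoff, so the reporting floor drops to the seed-level minimum
    params = (params or AlignmentParams()).with_floor(0.0)
    best: dict[str, float] = {}
    for h in align_all(matched_reads, host_db, params):
        if h.query_id not in best or h.bitscore > best[h.query_id]:
            best[h.query_id] = h.bitscore
    kept = [(rid, seq) for rid, seq in matched_reads if best.get(rid, 0.0) <= cutoff]
    discarded = [(rid, seq) for rid, seq in matched_reads if best.get(rid, 0.0) > cutoff]
    return kept, discarded, best


def dedup_reads(hits: list[AlignmentHit]) -> dict[str, tuple[str, float]]:
    """Allocate each read to the probe with the highest-scoring hit.

    Ties break to the lexicographically smallest probe name. Returns
    ``read_id -> (probe_name, bitscore)``.
    """
    assignment: dict[str, tuple[str, float]] = {}
    for h in hits:
        cur = assignment.get(h.subject_id)
        if cur is None or (h.bitscore, ) > (cur[1], ) or \
                (h.bitscore == cur[1] and h.query_id < cur[0]):
            assignment[h.subject_id] = (h.query_id, h.bitscore)
    return assignment


def suggest_host_cutoff(mean_read_length: float,
                        params: AlignmentParams | None = None,
                        fraction: float = 0.8) -> float:
    """Heuristic cutoff: bit score of a perfect alignment spanning
    ``fraction`` of the mean read length. Documents, rather than claims, the
    practice of adjusting the host cutoff to each dataset's read size."""
    params = params or AlignmentParams()
    return bitscore(fraction * mean_read_length * params.match_reward, params)


def screen_sample(probes: ProbeCollection, reads, host_db, sample_id: str = "sample",
                  cutoff: float = DEFAULT_HOST_BITSCORE_CUTOFF,
                  params: AlignmentParams | None = None
                  ) -> tuple[ScreenCounts, list[AlignmentHit], list[tuple[str, str]]]:
    """Full screen of one sample: count, host-refilter, deduplicate.

    Returns the stage counts, the hits restricted to retained reads, and the
    retained reads themselves (for export to external contig assembly).
    """
    if isinstance(reads, dict):
        reads = list(reads.items())
    hits = screen_reads(probes, reads, params)
    names = probes.names()
    raw = raw_counts(hits, names)
    matched_ids = {h.subject_id for h in hits}
    matched = [(rid, seq) for rid, seq in reads if rid in matched_ids]
    kept, _discarded, _scores = refilter_host(matched, host_db, cutoff, params)
    kept_ids = {rid for rid, _ in kept}
    kept_hits = [h for h in hits if h.subject_id in kept_ids]
    filtered = raw_counts(kept_hits, names)
    assignment = dedup_reads(kept_hits)
    dedup = {name: 0 for name in names}
    for probe_name, _bits in assignment.values():
        dedup[probe_name] += 1
    mean_len = sum(len(s) for _, s in reads) / len(reads) if reads else 0.0
    counts = ScreenCounts(sample_id, raw, filtered, dedup, mean_len, cutoff)
    return counts, kept_hits, kept


def crossmatch_matrix(probes_by_class: dict[str, ProbeCollection],
                      targets_by_class: dict[str, list[tuple[str, str]]],
                      params: AlignmentParams | None = None) -> pd.DataFrame:
    """Class x class specificity audit.

    Entry (c1, c2) counts the class-c1 probes with at least one hit among
    the class-c2 target sequences. Empty target classes give zero columns.
    """
    classes1 = sorted(probes_by_class)
    classes2 = sorted(targets_by_class)
    matrix = pd.DataFrame(0, index=classes1, columns=classes2)
    for c2 in classes2:
        targets = targets_by_class[c2]
        if not targets:
            continue
        for c1 in classes1:
            collection = probes_by_class[c1]
            if len(collection) == 0:
                continue
            hits = align_all(collection.sequences(), targets, params)
            matrix.loc[c1, c2] = len({h.query_id for h in hits})
    return matrix


def export_reads_by_probe(assignment: dict[str, tuple[str, float]],
                          reads, out_dir) -> list[str]:
    """Write retained reads grouped by assigned probe as per-probe FASTA
    files (inputs for external contig assembly). Returns paths written."""
    from pathlib import Path
    from .io import write_fasta

    if isinstance(reads, dict):
        reads = list(reads.items())
    lookup = dict(reads)
    by_probe: dict[str, list[tuple[str, str]]] = {}
    for read_id, (probe_name, _bits) in sorted(assignment.items()):
        by_probe.setdefault(probe_name, []).append((read_id, lookup[read_id]))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for probe_name, recs in sorted(by_probe.items()):
        path = out_dir / f"{probe_name}.reads.fasta"
        write_fasta(recs, path)
        paths.append(str(path))
    return paths
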