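"""Design, naming, host filtering, and redundancy profiling of 64-mer probes.

Probes are 64-nt windows drawn semi-randomly from small-subunit rRNA
reference sequences at a target density (default 10 per kb), without any
selection for hypervariable or conserved regions: the collection is meant as
a retrieval net, not a classifier. Probes matching the host database are
discarded, and the all-vs-all "redundancy" of the surviving collection (how
many probes, self included, each probe matches) is profiled so downstream
readcounts can optionally be corrected for within-collection similarity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .aligner import AlignmentParams, align_all

__all__ = [
    "DOMAIN_CODES",
    "LOCI",
    "PROBE_LENGTH",
    "RRNASource",
    "ProbeRecord",
    "ProbeCollection",
    "generate_probes",
    "abbreviate_species",
    "name_probe",
    "parse_probe_name",
    "filter_probes_against_host",
    "compute_redundancy",
    "redundancy_histogram",
]

PROBE_LENGTH = 64

#: Taxonomic domain codes: A Archaea, B0-B6 Bacteria, C1-C4 Chloroplastida,
#: D Amoebozoa, E0 basal Eukaryota, F0-F6 Fungi, H0-H3 Holozoa/Metazoa,
#: R retroelements.
DOMAIN_CODES = frozenset(
    ["A", "D", "E0", "R"]
    + [f"B{i}" for i in range(7)]
    + [f"C{i}" for i in range(1, 5)]
    + [f"F{i}" for i in range(7)]
    + [f"H{i}" for i in range(4)]
)

LOCI = ("16S", "18S", "23S", "28S", "mt", "retro")

#: Display order of domain classes in reports (Archaea through Holozoa,
#: retroelements last).
CLASS_ORDER = "ABCDEFHR"


@dataclass(frozen=True)
class RRNASource:
    """One reference rRNA sequence a probe set is drawn from."""

    species_name: str
    domain_code: str
    locus: str
    sequence: str

    def __post_init__(self) -> None:
        if self.domain_code not in DOMAIN_CODES:
            raise ValueError(f"unknown domain code {self.domain_code!r}")
        if self.locus not in LOCI:
            raise ValueError(f"unknown locus {self.locus!r}")


@dataclass
class ProbeRecord:
    name: str
    sequence: str
    domain_code: str
    source_offset: int
    redundancy: int | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != PROBE_LENGTH:
            raise ValueError(f"probe {self.name}: length {len(self.sequence)} != {PROBE_LENGTH}")

    @property
    def domain_class(self) -> str:
        """Single-letter taxonomic class (first character of the code)."""
        return self.domain_code[0]


@dataclass
class ProbeCollection:
    """Ordered probe list; order (class A through H, then R) is the fixed
    display order used by reports."""

    probes: list[ProbeRecord] = field(default_factory=list)
    version: str = "0"

    def __post_init__(self) -> None:
        names = [p.name for p in self.probes]
        if len(set(names)) != len(names):
            raise ValueError("probe names must be unique")

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    def names(self) -> list[str]:
        return [p.name for p in self.probes]

    def sequences(self) -> list[tuple[str, str]]:
        return [(p.name, p.sequence) for p in self.probes]

    def sorted_taxonomically(self) -> "ProbeCollection":
        order = {c: i for i, c in enumerate(CLASS_ORDER)}
        probes = sorted(self.probes, key=lambda p: (order.get(p.domain_class, 99), p.name))
        return ProbeCollection(probes, self.version)

    def to_fasta(self, path) -> None:
        from .io import write_fasta
        write_fasta(self.sequences(), path)

    @classmethod
    def from_fasta(cls, path, version: str = "0") -> "ProbeCollection":
        from .io import read_sequences
        probes = []
        for name, seq in read_sequences(path):
            code = name.split("_", 1)[0]
            probes.append(ProbeRecord(name, seq, code if code in DOMAIN_CODES else "R",
                                      source_offset=-1))
        return cls(probes, version)


def _species_words(species_name: str) -> list[str]:
    words = [re.sub(r"[^0-9A-Za-z]", "", w) for w in species_name.split()]
    words = [w for w in words if w]
    if not words:
        raise ValueError("empty species name")
    return words


def _is_binomial(words: list[str]) -> bool:
    return len(words) > 1 and all(w.isalpha() and w.islower() for w in words[1:])


def abbreviate_species(species_name: str) -> str:
    """Abridged species label used inside probe names.

    Latin binomials collapse to genus initial + epithet ("Halobacterium
    salinarum" -> "Hsalinarum"); single-word taxa and strain-style labels
    ("Acidobacteria KBS96") keep the full label. Non-alphanumeric characters
    are removed.
    """
    words = _species_words(species_name)
    if _is_binomial(words):
        return words[0][0] + "".join(words[1:])
    return "".join(words)


def name_probe(source: RRNASource, index: int) -> str:
    """Structured probe name, e.g. ``A_Hsalinarum_16S1``.

    Binomial species append the probe number directly to the locus; other
    taxa separate locus and number with an underscore
    (``B3_AcidobacteriaKBS96_16S_8``), matching the two dialects in use.
    """
    if index < 1:
        raise ValueError("probe index starts at 1")
    if source.domain_code not in DOMAIN_CODES:
        raise ValueError(f"unknown domain code {source.domain_code!r}")
    words = _species_words(source.species_name)
    label = abbreviate_species(source.species_name)
    sep = "" if _is_binomial(words) else "_"
    return f"{source.domain_code}_{label}_{source.locus}{sep}{index}"


_NAME_RE = re.compile(
    r"^(?P<code>[A-Z][0-9]?)_(?P<species>[0-9A-Za-z]+)_"
    r"(?P<locus>16S|18S|23S|28S|mt|retro)_?(?P<index>[0-9]+)$"
)


def parse_probe_name(name: str) -> tuple[str, str, str, int]:
    """Invert :func:`name_probe`; accepts both separator dialects."""
    m = _NAME_RE.match(name)
    if not m or m.group("code") not in DOMAIN_CODES:
        raise ValueError(f"cannot parse probe name {name!r}")
    return (m.group("code"), m.group("species"), m.group("locus"), int(m.group("index")))


def generate_probes(source: RRNASource, density_per_kb: float = 10.0,
                    rng_seed: int | np.random.Generator = 0) -> list[ProbeRecord]:
    """Draw non-overlapping 64-mer probes from a source at ~density_per_kb.

    The source is partitioned into consecutive windows of
    ``stride = floor(1000 / density_per_kb)`` nt and one probe start is drawn
    uniformly inside each window (restricted so the probe stays inside the
    window and the sequence, making non-overlap structural). Windows
    containing ambiguous bases are skipped so probes are fully determinate.
    """
    if density_per_kb * PROBE_LENGTH / 1000.0 > 1.0:
        raise ValueError("density too high: probes could not be non-overlapping")
    seq = source.sequence.upper()
    n = len(seq)
    if n < PROBE_LENGTH:
        return []
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    stride = int(1000 // density_per_kb)
    probes: list[ProbeRecord] = []
    for w0 in range(0, n, stride):
        hi = min(w0 + stride, n) - PROBE_LENGTH
        if hi < w0:
            continue
        if "N" in seq[w0:min(w0 + stride, n)]:
            continue
        start = int(rng.integers(w0, hi + 1))
        probes.append(ProbeRecord(
            name=name_probe(source, len(probes) + 1),
            sequence=seq[start:start + PROBE_LENGTH],
            domain_code=source.domain_code,
            source_offset=start,
        ))
    return probes


def filter_probes_against_host(probes, host_db, params: AlignmentParams | None = None
                               ) -> tuple[list[ProbeRecord], list[ProbeRecord]]:
    """Split probes into (kept, discarded) by host homology.

    A probe is discarded iff it has at least one hit against the host
    database at the reporting floor; because probes share no reportable
    similarity with the host afterwards, re-screening the kept set against
    the same host database returns zero hits (fixed point).
    """
    params = params or AlignmentParams()
    probes = list(probes)
    if isinstance(host_db, dict):
        host_db = list(host_db.items())
    if not host_db:
        raise ValueError("host database is empty")
    hits = align_all([(p.name, p.sequence) for p in probes], host_db, params)
    flagged = {h.query_id for h in hits}
    kept = [p for p in probes if p.name not in flagged]
    discarded = [p for p in probes if p.name in flagged]
    return kept, discarded


def compute_redundancy(collection: ProbeCollection,
                       params: AlignmentParams | None = None) -> ProbeCollection:
    """All-vs-all comparison of the collection against itself.

    Fills each probe's ``redundancy`` with the number of probes it matches
    (self included, so unique probes have redundancy 1).
    """
    if len(collection) == 0:
        raise ValueError("empty probe collection")
    params = params or AlignmentParams()
    seqs = collection.sequences()
    hits = align_all(seqs, seqs, params)
    counts: dict[str, int] = {name: 0 for name, _ in seqs}
    for h in hits:
        counts[h.query_id] += 1
    for p in collection:
        p.redundancy = counts[p.name]
    return collection


#: Redundancy histogram bins reported in summaries.
REDUNDANCY_BINS = (
    ("1", lambda r: r == 1),
    ("2", lambda r: r == 2),
    ("3-5", lambda r: 3 <= r <= 5),
    ("6-19", lambda r: 6 <= r <= 19),
    (">=20", lambda r: r >= 20),
)


def redundancy_histogram(collection: ProbeCollection) -> dict[str, int]:
    """Counts of probes per redundancy bin {1, 2, 3-5, 6-19, >=20}."""
    if any(p.redundancy is None for p in collection):
        raise ValueError("redundancy not computed; run compute_redundancy first")
    return {label: sum(1 for p in collection if pred(p.redundancy))
            for label, pred in REDUNDANCY_BINS}
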