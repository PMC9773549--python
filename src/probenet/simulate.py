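"""Synthetic fixtures with recorded ground truth for every pipeline stage.

The generator emulates the statistical structure the normalization model
assumes: a host transcriptome in which housekeeping genes are present at
~50 transcript copies per cell, plus microbial rRNA pools whose copy
numbers are ``organisms_per_host_cell x host_cells x RBPC``. Reads are
sampled from the pooled transcripts in proportion to copy number, from both
strands, with independent substitution errors, and every read's origin is
recorded in a sidecar table (never in the read file itself).

Sequences are i.i.d. uniform over {A,C,G,T} unless supplied, so microbial
reads share no seed words with the host by construction; planted conserved
blocks (for redundancy and cross-matching fixtures) and batch-wide
contaminants are layered on top. Housekeeping and microbial transcripts are
fully tiled by probe windows at the default read length, so the read-capture
factor is common to both and cancels in normalization — the same assumption
the housekeeping normalization itself makes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .probes import RRNASource

__all__ = [
    "MicrobeSpec",
    "SimulationConfig",
    "PoolEntry",
    "SimulatedSample",
    "SimulatedStudy",
    "random_sequence",
    "simulate_host",
    "simulate_microbes",
    "simulate_reads",
    "plant_contaminants",
    "simulate_study",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


@dataclass
class MicrobeSpec:
    """One simulated organism: abundance in organisms per host cell and a
    class-specific ribosomes-per-cell constant."""

    name: str
    domain_code: str
    organisms_per_host_cell: float
    rbpc: float = 2000.0
    rrna_length: int = 1500
    locus: str = "16S"
    sequence: str | None = None


@dataclass
class SimulationConfig:
    """Full specification of one synthetic study; a fixed seed gives
    byte-identical outputs."""

    rng_seed: int = 0
    host_cell_count: float = 10.0
    housekeeping_copies_per_cell: dict[str, float] = field(
        default_factory=lambda: {"PGK1": 50.0, "NSE": 50.0})
    # at read length 150 every read start (0..L-150) overlaps each probe
    # window by >= one seed word, so per-probe housekeeping capture is 1,
    # matching the ~1 per-organism capture of probe-tiled rRNA sources
    hk_transcript_length: int = 230
    hk_probe_offsets: tuple[int, ...] = (44, 110)
    host_filler_transcripts: int = 20
    host_filler_length: int = 1000
    host_filler_copies_per_cell: float = 25.0
    microbes: list[MicrobeSpec] = field(default_factory=list)
    contaminants: list[MicrobeSpec] = field(default_factory=list)
    read_length: int = 150
    read_error_rate: float = 0.0
    reads_per_sample: int = 4000
    sample_count: int = 1

    def __post_init__(self) -> None:
        if self.read_error_rate < 0 or self.host_cell_count < 0:
            raise ValueError("rates must be >= 0")
        for m in list(self.microbes) + list(self.contaminants):
            if m.organisms_per_host_cell < 0:
                raise ValueError(f"{m.name}: abundance must be >= 0")

    def to_yaml(self) -> str:
        data = dataclasses.asdict(self)
        data["hk_probe_offsets"] = list(self.hk_probe_offsets)
        return yaml.safe_dump(data, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        data = yaml.safe_load(text)
        data["hk_probe_offsets"] = tuple(data.get("hk_probe_offsets", (44, 110)))
        data["microbes"] = [MicrobeSpec(**m) for m in data.get("microbes", [])]
        data["contaminants"] = [MicrobeSpec(**m) for m in data.get("contaminants", [])]
        return cls(**data)


@dataclass
class PoolEntry:
    """One transcript species in the sampling pool; ``copies`` is its
    molecule count, the sampling weight."""

    name: str
    sequence: str
    copies: float
    origin: str


@dataclass
class SimulatedSample:
    sample_id: str
    reads: list[tuple[str, str]]
    truth: pd.DataFrame  # read_id, origin, source, start, strand


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    host_transcripts: list[tuple[str, str]]
    hk_probes: dict[str, list[tuple[str, str]]]
    rrna_sources: list[RRNASource]
    samples: list[SimulatedSample]
    expected_reads: dict[str, float]  # origin -> expected read count per sample

    @property
    def host_db(self) -> list[tuple[str, str]]:
        return self.host_transcripts


def simulate_host(config: SimulationConfig, rng: np.random.Generator
                  ) -> tuple[list[tuple[str, str]], list[PoolEntry],
                             dict[str, list[tuple[str, str]]]]:
    """Host transcriptome: filler transcripts plus housekeeping genes.

    Housekeeping transcripts enter the pool at copies_per_cell x host_cells;
    two 64-mer probes per gene are cut from fixed offsets so that, at the
    configured read length, every read from the transcript overlaps a probe
    window (capture factor 1).
    """
    transcripts: list[tuple[str, str]] = []
    pool: list[PoolEntry] = []
    hk_probes: dict[str, list[tuple[str, str]]] = {}
    cells = config.host_cell_count
    for gene, copies_per_cell in config.housekeeping_copies_per_cell.items():
        seq = random_sequence(rng, config.hk_transcript_length)
        name = f"host_{gene}"
        transcripts.append((name, seq))
        if cells > 0:
            pool.append(PoolEntry(name, seq, copies_per_cell * cells,
                                  f"housekeeping:{gene}"))
        hk_probes[gene] = [
            (f"HK_{gene}_{i + 1}", seq[off:off + 64])
            for i, off in enumerate(config.hk_probe_offsets)
        ]
    for i in range(config.host_filler_transcripts):
        seq = random_sequence(rng, config.host_filler_length)
        name = f"host_tx{i + 1}"
        transcripts.append((name, seq))
        if cells > 0:
            pool.append(PoolEntry(name, seq, config.host_filler_copies_per_cell * cells,
                                  "host"))
    return transcripts, pool, hk_probes


def simulate_microbes(config: SimulationConfig, rng: np.random.Generator,
                      specs: list[MicrobeSpec] | None = None,
                      origin_prefix: str = "microbe"
                      ) -> tuple[list[RRNASource], list[PoolEntry]]:
    """Microbial rRNA pool; copy number = theta x host_cells x RBPC."""
    sources: list[RRNASource] = []
    pool: list[PoolEntry] = []
    for spec in (config.microbes if specs is None else specs):
        seq = spec.sequence or random_sequence(rng, spec.rrna_length)
        source = RRNASource(spec.name, spec.domain_code, spec.locus, seq)
        sources.append(source)
        copies = spec.organisms_per_host_cell * config.host_cell_count * spec.rbpc
        if copies > 0:
            pool.append(PoolEntry(f"rRNA_{spec.name}", seq, copies,
                                  f"{origin_prefix}:{spec.name}"))
    return sources, pool


def simulate_reads(pool: list[PoolEntry], config: SimulationConfig,
                   rng: np.random.Generator, sample_id: str = "sample"
                   ) -> SimulatedSample:
    """Sample reads from the pool in proportion to copy number.

    Uniform fragment start, either strand with equal probability,
    substitution errors at the configured rate. Entries shorter than the
    read length are skipped with a warning.
    """
    import logging
    from .aligner import reverse_complement

    usable = [e for e in pool if len(e.sequence) >= config.read_length]
    for e in pool:
        if len(e.sequence) < config.read_length:
            logging.getLogger(__name__).warning(
                "pool entry %s shorter than read length: skipped", e.name)
    reads: list[tuple[str, str]] = []
    rows = []
    if usable and config.reads_per_sample > 0:
        weights = np.array([e.copies for e in usable], dtype=float)
        probs = weights / weights.sum()
        picks = rng.choice(len(usable), size=config.reads_per_sample, p=probs)
        for k, idx in enumerate(picks):
            entry = usable[idx]
            start = int(rng.integers(0, len(entry.sequence) - config.read_length + 1))
            frag = entry.sequence[start:start + config.read_length]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                frag = reverse_complement(frag)
            if config.read_error_rate > 0:
                arr = np.frombuffer(frag.encode(), dtype=np.uint8).copy()
                err = rng.random(len(arr)) < config.read_error_rate
                if err.any():
                    shifts = rng.integers(1, 4, size=int(err.sum()))
                    base_idx = np.searchsorted(_BASES, arr[err])
                    arr[err] = _BASES[(base_idx + shifts) % 4]
                frag = arr.tobytes().decode("ascii")
            read_id = f"{sample_id}_r{k + 1}"
            reads.append((read_id, frag))
            rows.append((read_id, entry.origin, entry.name, start, strand))
    truth = pd.DataFrame(rows, columns=["read_id", "origin", "source", "start", "strand"])
    return SimulatedSample(sample_id, reads, truth)


def plant_contaminants(pools: list[list[PoolEntry]], config: SimulationConfig,
                       rng: np.random.Generator) -> list[list[PoolEntry]]:
    """Inject identical contaminant organisms into every sample's pool.

    The same sequences at the same copy numbers go into all samples of the
    batch, emulating reagent contamination; returns the pools (modified in
    place) for chaining. No contaminants configured -> identity.
    """
    if not config.contaminants:
        return pools
    _, entries = simulate_microbes(config, rng, config.contaminants,
                                   origin_prefix="contaminant")
    for pool in pools:
        pool.extend(entries)
    return pools


#: Group sizes of the planted-similarity synthetic reference collection:
#: 634 unique probes, 50 similar pairs, groups of 3-5 totalling 122 probes,
#: and larger conserved groups totalling 161 probes (1017 probes in all).
SYNTHETIC_COLLECTION_GROUPS = (
    [1] * 634 + [2] * 50 + [3] * 10 + [4] * 8 + [5] * 12
    + [6, 10, 15, 20, 25, 35, 50]
)


def synthetic_reference_collection(rng_seed: int = 0,
                                   group_sizes=None,
                                   shared_block: int = 32):
    """Synthetic stand-in for a full-scale reference probe collection.

    Builds a collection of random 64-mers with planted similarity groups:
    every member of a group carries the same ``shared_block``-nt conserved
    segment (at a random offset), so all-vs-all redundancy of a member
    equals its group size, while probes from different groups share no seed
    word. The default composition plants 1017 probes of which 634 are
    unique — a synthetic surrogate, at the same scale and redundancy mix,
    for a deposited collection that is not redistributed here.
    """
    from .probes import DOMAIN_CODES, ProbeCollection, ProbeRecord

    rng = np.random.default_rng(rng_seed)
    sizes = list(SYNTHETIC_COLLECTION_GROUPS if group_sizes is None else group_sizes)
    codes = sorted(DOMAIN_CODES - {"R"})
    probes = []
    for gid, size in enumerate(sizes, start=1):
        code = codes[gid % len(codes)]
        block = random_sequence(rng, shared_block) if size > 1 else ""
        for k in range(1, size + 1):
            if size == 1:
                seq = random_sequence(rng, 64)
            else:
                off = int(rng.integers(0, 64 - shared_block + 1))
                seq = random_sequence(rng, 64)
                seq = seq[:off] + block + seq[off + shared_block:]
            locus = "16S" if code[0] in "AB" else "18S"
            probes.append(ProbeRecord(
                name=f"{code}_Syngroup{gid}_{locus}_{k}",
                sequence=seq, domain_code=code, source_offset=-1))
    return ProbeCollection(probes, version="synthetic-1.0")


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate the full multi-sample study with ground truth.

    Host transcripts and microbial/contaminant sequences are drawn once and
    shared by all samples; reads are sampled independently per sample.
    """
    rng = np.random.default_rng(config.rng_seed)
    transcripts, host_pool, hk_probes = simulate_host(config, rng)
    sources, microbe_pool = simulate_microbes(config, rng)
    # contaminant organisms are part of the probe-design universe too: the
    # net is meant to catch them so decontamination can then remove them
    cont_sources, cont_pool = simulate_microbes(config, rng, config.contaminants,
                                                origin_prefix="contaminant")
    sources = sources + cont_sources
    pools = [list(host_pool) + list(microbe_pool) + list(cont_pool)
             for _ in range(config.sample_count)]
    samples = [
        simulate_reads(pools[i], config, rng, sample_id=f"S{i + 1}")
        for i in range(config.sample_count)
    ]
    total = sum(e.copies for e in pools[0]) if pools and pools[0] else 0.0
    expected = {}
    if total > 0:
        for e in pools[0]:
            expected[e.origin] = expected.get(e.origin, 0.0) + \
                e.copies / total * config.reads_per_sample
    return SimulatedStudy(config, transcripts, hk_probes, sources, samples, expected)
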