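"""Normalization of filtered readcounts to per-host-cell abundances.

The amount of biological material behind an RNA-seq library is estimated
from housekeeping-gene probe counts: with ~50 transcripts per cell for the
panel genes, ``host_cells = mean(per-gene mean probe count) / 50``. Microbial
probe counts divided by the host-cell estimate give reads per host cell, and
dividing further by a ribosomes-per-cell (RBPC) constant for the probe's
taxonomic class converts rRNA reads to microbial cell equivalents. Both steps
are deliberately free of depth or read-length corrections: any factor common
to housekeeping and microbial transcripts cancels in the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .probes import ProbeCollection, parse_probe_name

__all__ = [
    "HousekeepingPanel",
    "RBPCTable",
    "NormalizedProfile",
    "estimate_host_cells",
    "normalize_profile",
    "microbes_per_host_cell",
    "latent_virus_detection_limit",
    "redundancy_normalize",
]

#: Default transcript copies per cell for panel housekeeping genes
#: (measured range 46-64 for PGK1; 50 adopted).
DEFAULT_TRANSCRIPTS_PER_CELL = 50.0


@dataclass
class HousekeepingPanel:
    """Housekeeping probe panel for one tissue type.

    The shipped default ("brain") averages PGK1 (2 probes) and NSE/ENO2
    (2 probes). HMGCR is recognized but excluded from the default mean: its
    expression runs ~fivefold lower, which would bias the cell estimate.
    """

    name: str = "brain"
    genes: dict[str, int] = field(default_factory=lambda: {"PGK1": 2, "NSE": 2})
    transcripts_per_cell: float = DEFAULT_TRANSCRIPTS_PER_CELL

    def __post_init__(self) -> None:
        if not self.genes or any(n < 1 for n in self.genes.values()):
            raise ValueError("panel needs >=1 gene with >=1 probe")
        if self.transcripts_per_cell <= 0:
            raise ValueError("transcripts_per_cell must be positive")


@dataclass
class RBPCTable:
    """Ribosomes per cell by taxonomic class.

    Defaults: 2000 for prokaryotes (A, B; a compromise for slow growth in
    tissue) and 10000 for eukaryotic microbes (C, D, E, F, H; fivefold
    greater, scaled down from fast-growth yeast values).
    """

    values: dict[str, float] = field(default_factory=lambda: {
        "A": 2000.0, "B": 2000.0,
        "C": 10000.0, "D": 10000.0, "E": 10000.0, "F": 10000.0, "H": 10000.0,
    })

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.values.values()):
            raise ValueError("RBPC values must be positive")

    def for_class(self, domain_class: str) -> float:
        if domain_class not in self.values:
            raise KeyError(f"no RBPC value for class {domain_class!r}")
        return self.values[domain_class]


@dataclass
class NormalizedProfile:
    """Per-probe normalized abundances for one sample."""

    sample_id: str
    host_cells: float
    reads_per_host_cell: dict[str, float]
    microbes_per_host_cell: dict[str, float] = field(default_factory=dict)
    redundancy_normalized: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        probes = list(self.reads_per_host_cell)
        frame = pd.DataFrame({
            "probe": probes,
            "reads_per_host_cell": [self.reads_per_host_cell[p] for p in probes],
        })
        if self.microbes_per_host_cell:
            frame["microbes_per_host_cell"] = [
                self.microbes_per_host_cell[p] for p in probes]
        return frame


def estimate_host_cells(hk_counts: dict[str, float | list[float]],
                        panel: HousekeepingPanel | None = None) -> float:
    """Host-cell equivalent of a library from housekeeping probe counts.

    ``hk_counts`` maps gene name to a probe count or list of probe counts;
    per-gene means are averaged over genes and divided by the panel's
    transcripts-per-cell. All-zero counts signal an unusable library.
    """
    panel = panel or HousekeepingPanel()
    gene_means = []
    for gene in panel.genes:
        if gene not in hk_counts:
            raise KeyError(f"panel gene {gene!r} missing from housekeeping counts")
        counts = hk_counts[gene]
        if isinstance(counts, (int, float)):
            counts = [float(counts)]
        gene_means.append(sum(counts) / len(counts))
    mean = sum(gene_means) / len(gene_means)
    if mean <= 0:
        raise ValueError("cannot normalize sample: all housekeeping counts are zero")
    return mean / panel.transcripts_per_cell


def normalize_profile(counts, host_cells: float, sample_id: str | None = None
                      ) -> NormalizedProfile:
    """Per-probe deduplicated counts divided by the host-cell estimate.

    ``counts`` is a ScreenCounts or a plain probe->count mapping.
    """
    if host_cells <= 0:
        raise ValueError("host_cells must be positive")
    if hasattr(counts, "dedup_count"):
        sample_id = sample_id or counts.sample_id
        mapping = counts.dedup_count
    else:
        mapping = counts
        sample_id = sample_id or "sample"
    rphc = {probe: n / host_cells for probe, n in mapping.items()}
    return NormalizedProfile(sample_id, host_cells, rphc)


def microbes_per_host_cell(profile: NormalizedProfile,
                           rbpc: RBPCTable | None = None,
                           class_of: dict[str, str] | None = None
                           ) -> NormalizedProfile:
    """Convert reads per host cell into microbial cells per host cell.

    Each probe's value is divided by the RBPC constant of its taxonomic
    class; classes come from parsing probe names unless ``class_of`` is
    given. The profile is updated in place and returned.
    """
    rbpc = rbpc or RBPCTable()
    out = {}
    for probe, value in profile.reads_per_host_cell.items():
        cls = class_of[probe] if class_of else parse_probe_name(probe)[0][0]
        out[probe] = value / rbpc.for_class(cls)
    profile.microbes_per_host_cell = out
    return profile


def class_totals(profile: NormalizedProfile,
                 class_of: dict[str, str] | None = None) -> dict[str, float]:
    """Sum of microbes per host cell over the probes of each class."""
    if not profile.microbes_per_host_cell:
        raise ValueError("run microbes_per_host_cell first")
    totals: dict[str, float] = {}
    for probe, value in profile.microbes_per_host_cell.items():
        cls = class_of[probe] if class_of else parse_probe_name(probe)[0][0]
        totals[cls] = totals.get(cls, 0.0) + value
    return totals


def latent_virus_detection_limit(transcripts_per_infected_cell: float = 50.0,
                                 host_cells: float = 10.0) -> float:
    """Infected-cell equivalent of a single latency transcript.

    One detected transcript represents ``1 / transcripts_per_infected_cell``
    infected cells, reported per ``host_cells`` host cells (the value is the
    same regardless of the denominator chosen: 0.02 infected cells per 10
    host cells at 50 transcripts per infected cell).
    """
    if transcripts_per_infected_cell <= 0 or host_cells <= 0:
        raise ValueError("arguments must be positive")
    return 1.0 / transcripts_per_infected_cell


def redundancy_normalize(profile: NormalizedProfile,
                         collection: ProbeCollection) -> NormalizedProfile:
    """Divide each probe's reads per host cell by its redundancy.

    Corrects for within-collection probe similarity; the uncorrected values
    are retained alongside. Requires redundancy to be computed.
    """
    redundancy = {p.name: p.redundancy for p in collection}
    missing = [p for p in profile.reads_per_host_cell
               if redundancy.get(p) in (None,)]
    if missing:
        raise ValueError(f"redundancy missing for probes: {missing[:5]}")
    profile.redundancy_normalized = {
        probe: value / redundancy[probe]
        for probe, value in profile.reads_per_host_cell.items()}
    return profile
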