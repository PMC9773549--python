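"""Fixed-order heatmap matrices and per-organism summaries.

Profiles are displayed with probes in their fixed taxonomic order (classes
A through H, then R) as rows and samples as columns. The color convention:
values below the cutoff map to blue, the cutoff itself to white, and values
at or above the maximum to red, with a linear white-to-red ramp between.
Rendering is delegated to any plotting backend; this module produces the
matrix and the color-scale annotation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .probes import parse_probe_name

__all__ = ["HeatmapSpec", "heatmap_matrix", "aggregate_by_organism", "render_png"]

from dataclasses import dataclass


@dataclass(frozen=True)
class HeatmapSpec:
    """Color semantics: below cutoff = blue, cutoff = white, >= max = red."""

    cutoff: float = 0.0
    max_value: float = 1.0
    log2: bool = False

    def __post_init__(self) -> None:
        if self.cutoff > self.max_value:
            raise ValueError("cutoff must be <= max_value")

    def color_scale(self) -> dict:
        return {
            "below_cutoff": "blue",
            "cutoff": {"value": self.cutoff, "color": "white"},
            "max": {"value": self.max_value, "color": "red"},
            "ramp": "linear white to red between cutoff and max",
            "log2": self.log2,
        }


def heatmap_matrix(batch: pd.DataFrame, spec: HeatmapSpec | None = None
                   ) -> tuple[pd.DataFrame, dict]:
    """Probe x sample matrix in fixed row order plus color annotation.

    ``batch`` rows must already share one probe order across samples (they
    are a wide batch); values are log2(x+1)-transformed when the spec says
    so (the +1 admits zeros). Permuting samples permutes columns only.
    """
    spec = spec or HeatmapSpec()
    if batch.index.has_duplicates:
        raise ValueError("duplicate probe rows")
    matrix = batch.copy()
    if spec.log2:
        matrix = np.log2(matrix + 1.0)
    return matrix, spec.color_scale()


def aggregate_by_organism(profile, log2: bool = False) -> pd.Series:
    """Sum reads per host cell over each source organism's probes.

    Probe names are parsed to (domain, organism); unparseable names raise
    with the offending names listed. Optionally log2(x+1)-transformed.
    """
    values = profile.reads_per_host_cell if hasattr(profile, "reads_per_host_cell") \
        else dict(profile)
    sums: dict[str, float] = {}
    bad: list[str] = []
    for probe, value in values.items():
        try:
            code, species, _locus, _idx = parse_probe_name(probe)
        except ValueError:
            bad.append(probe)
            continue
        organism = f"{code}_{species}"
        sums[organism] = sums.get(organism, 0.0) + value
    if bad:
        raise ValueError(f"unparseable probe names: {bad}")
    series = pd.Series(sums, name="reads_per_host_cell")
    if log2:
        series = np.log2(series + 1.0)
    return series


def render_png(matrix: pd.DataFrame, spec: HeatmapSpec, path) -> None:
    """Optional PNG rendering via matplotlib (blue/white-to-red semantics)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap, TwoSlopeNorm

    cmap = LinearSegmentedColormap.from_list("probenet", ["blue", "white", "red"])
    vmax = max(spec.max_value, spec.cutoff + 1e-9)
    norm = TwoSlopeNorm(vmin=min(matrix.values.min(), spec.cutoff - 1e-9),
                        vcenter=spec.cutoff, vmax=vmax)
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * matrix.shape[1]),
                                    max(4, 0.02 * matrix.shape[0])))
    ax.imshow(matrix.values, aspect="auto", cmap=cmap, norm=norm,
              interpolation="nearest")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
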