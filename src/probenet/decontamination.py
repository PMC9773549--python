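"""Contamination exclusion on batches of normalized profiles.

Reagent contamination leaves the same signal in every sample processed in
parallel, so probes positive across a whole batch are zeroed
(:func:`drop_multipositive`). Environmental and skin contamination is
handled by subtracting reference batches — any probe positive in any
reference sample is zeroed in every target sample
(:func:`subtract_reference`); subtractions compose and commute. The
complementary view, probes present in most samples of a batch
(:func:`core_signals`), surfaces candidate core community members.

Batches are wide DataFrames: rows = probes in collection order, columns =
samples. Every operation returns a removal log from which the input batch
can be reconstructed exactly.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "batch_from_profiles",
    "drop_multipositive",
    "subtract_reference",
    "subtract_blocklist",
    "core_signals",
    "restore",
]


def batch_from_profiles(profiles, value: str = "reads_per_host_cell") -> pd.DataFrame:
    """Assemble NormalizedProfiles into a wide probe x sample batch.

    All profiles must share the same probe vector (same probes, same order).
    """
    if not profiles:
        raise ValueError("no profiles")
    columns = {}
    probe_order = None
    for prof in profiles:
        values = getattr(prof, value)
        probes = list(values)
        if probe_order is None:
            probe_order = probes
        elif probes != probe_order:
            raise ValueError(f"profile {prof.sample_id!r}: probe vector mismatch")
        columns[prof.sample_id] = [values[p] for p in probes]
    return pd.DataFrame(columns, index=pd.Index(probe_order, name="probe"))


def _check_batch(batch: pd.DataFrame, min_samples: int = 1) -> None:
    if batch.shape[1] < min_samples:
        raise ValueError(f"batch needs >= {min_samples} samples, has {batch.shape[1]}")


def drop_multipositive(batch: pd.DataFrame, presence_fraction: float = 1.0,
                       epsilon: float = 0.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Zero probes positive in >= presence_fraction of the batch's samples.

    Presence means value > epsilon (default 0; the epsilon floor guards
    against numeric dust). Returns (cleaned batch, removal log of the
    original rows for the affected probes).
    """
    _check_batch(batch, min_samples=2)
    present = (batch > epsilon).mean(axis=1)
    flagged = present[present >= presence_fraction].index
    log = batch.loc[flagged].copy()
    log.insert(0, "reason", "multi-positive")
    out = batch.copy()
    out.loc[flagged] = 0.0
    return out, log


def subtract_reference(batch: pd.DataFrame, reference: pd.DataFrame,
                       epsilon: float = 0.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Zero, in every target sample, any probe positive in any reference sample.

    Monotone (values only ever drop to zero) and order-independent, so
    successive subtractions against independent references (e.g. tapwater,
    then skin) compose. An empty reference is the identity.
    """
    if reference.shape[1] and list(reference.index) != list(batch.index):
        raise ValueError("probe vector mismatch between batch and reference")
    if reference.shape[1] == 0:
        return batch.copy(), batch.iloc[0:0].copy()
    flagged = reference.index[(reference > epsilon).any(axis=1)]
    flagged = flagged[batch.loc[flagged].gt(epsilon).any(axis=1)]
    log = batch.loc[flagged].copy()
    log.insert(0, "reason", "reference-positive")
    out = batch.copy()
    out.loc[flagged] = 0.0
    return out, log


def subtract_blocklist(batch: pd.DataFrame, blocklist) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Zero probes by name (known-contaminant lists).

    No list ships as authoritative: common contaminant species can
    themselves be disease-relevant, so the choice is left to the analyst.
    """
    flagged = [p for p in batch.index if p in set(blocklist)]
    log = batch.loc[flagged].copy()
    log.insert(0, "reason", "blocklist")
    out = batch.copy()
    out.loc[flagged] = 0.0
    return out, log


def core_signals(batch: pd.DataFrame, min_fraction: float = 0.75,
                 epsilon: float = 0.0) -> list[str]:
    """Probes positive in strictly more than min_fraction of samples."""
    _check_batch(batch, min_samples=2)
    present = (batch > epsilon).mean(axis=1)
    return list(present[present > min_fraction].index)


def restore(batch: pd.DataFrame, log: pd.DataFrame) -> pd.DataFrame:
    """Undo a removal: put the logged original rows back into the batch."""
    out = batch.copy()
    if len(log):
        out.loc[log.index] = log.drop(columns=["reason"])
    return out
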