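"""Bundled reference tables from the published four-population wheat study.

Small TSVs of printed per-chromosome statistics, used as *inputs* to the
summary/aggregation operations (the aggregates — densities, coverages,
totals — are always recomputed, never stored).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("mapforge.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def consensus_characteristics() -> pd.DataFrame:
    """Per-chromosome markers / recombinant bins / length (cM) of the
    published 29,692-marker consensus map."""
    return _load("consensus_characteristics.tsv")


def bin_map_alignment() -> pd.DataFrame:
    """Per-chromosome EST/SNP/bin counts from the deletion-bin alignment."""
    return _load("bin_map_alignment.tsv")


def reference_comparison() -> pd.DataFrame:
    """Per-chromosome consistent / new / inconsistent marker counts from the
    comparison against the earlier 40K consensus map."""
    return _load("reference_comparison.tsv")


def marker_sharing() -> pd.DataFrame:
    """Markers shared by exactly 1..4 of the four individual maps."""
    return _load("marker_sharing.tsv")


def multi_locus_counts() -> pd.DataFrame:
    """Number of assays mapped to 2 and to 3 positions."""
    return _load("multi_locus_counts.tsv")
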