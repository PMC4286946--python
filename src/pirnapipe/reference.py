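"""Bundled reference tables from the published chicken germ-cell small-RNA
profiles: per-sample library totals, upregulated-tag counts by category, and
the top PGC-enriched piRNA tags with their per-sample RPKM values and
reported fold changes.  Used for regression checks of the fold-change and
percentage routines against printed values."""

from __future__ import annotations

from importlib import resources

import pandas as pd

SAMPLES = ["PGCs", "Stage X", "GSCs", "CEFs"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("pirnapipe.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def top_pirnas() -> pd.DataFrame:
    """Top repeat- and genic-origin piRNA tags upregulated in PGCs: sequence,
    per-sample RPKM (PGCs, Stage X, GSCs, CEFs) and the reported fold change."""
    return _load("top_pirnas.tsv")


def upregulated_counts() -> pd.DataFrame:
    """Upregulated unique-tag counts by annotation category, one column per
    focal sample."""
    return _load("upregulated_counts.tsv")


def library_totals() -> pd.DataFrame:
    """Raw/clean read and base totals and unique-read counts per sample."""
    return _load("library_totals.tsv")
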