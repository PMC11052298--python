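"""Packaged published reference tables for the nine-species panel.

These small fixtures carry the printed species-level summaries (machinery
counts, start-codon counts, AUG%, DITE, N_AC, MeanMFE) so the regression
stages can run without downloading and reprocessing the RefSeq genomes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("transelect.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_machinery_counts() -> pd.DataFrame:
    """Genome length, CDS count, rrn operon and tRNA gene counts by rank."""
    return _load("machinery_counts.tsv")


def load_start_codon_counts() -> pd.DataFrame:
    """Start-codon counts (AUG/GUG/YUG/AUH, group size N) per species x class."""
    return _load("start_codon_counts.tsv")


def load_aug_percent(full_precision: bool = True) -> pd.DataFrame:
    """AUG% regression input (AUG%, RankGT, GC%, GE).

    With ``full_precision`` (default) AUG% is recomputed as 100*AUG/N from
    the start-codon counts, avoiding the 4-dp rounding of the printed
    percentage column; otherwise the printed values are returned.
    """
    if not full_precision:
        return _load("aug_percent.tsv")
    df = load_start_codon_counts().copy()
    df["AUG%"] = 100.0 * df["AUG"] / df["N"]
    return df[["species", "AUG%", "RankGT", "GC%", "GE"]]


def load_dite() -> pd.DataFrame:
    """Species-level DITE and its published midranks."""
    return _load("dite.tsv")


def load_n_ac() -> pd.DataFrame:
    """Effective number of anticodons per species and its midranks."""
    return _load("n_ac.tsv")


def load_mean_mfe() -> pd.DataFrame:
    """MeanMFE regression input (RankGT, class GC%, GE, MeanMFE)."""
    return _load("mean_mfe.tsv")
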