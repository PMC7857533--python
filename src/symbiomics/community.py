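"""Nematode community profiling from filtered similarity hits.

Contigs from genome-skimming assemblies are matched against a reference
marker database; filtered hits are converted from assembler kmer coverage
to read coverage with C = C_K * R / (R - K + 1) and aggregated into
per-sample species abundances (relative percentages) and group-level
absolute coverages.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HIT_COLUMNS = [
    "sample_id",
    "query_id",
    "species",
    "percent_identity",
    "alignment_length",
    "kmer_coverage",
    "kmer_length",
    "read_length",
]


def convert_coverage(c_k, r, k):
    """Read coverage C from kmer coverage C_K: C = C_K * R / (R - K + 1).

    Accepts scalars or arrays; R and K are in bases with 1 <= K <= R.
    """
    c_k = np.asarray(c_k, dtype=float)
    r = np.asarray(r, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(r <= 0):
        raise ValueError("read length R must be positive")
    if np.any(k < 1) or np.any(k > r):
        raise ValueError("kmer length K must satisfy 1 <= K <= R")
    if np.any(c_k < 0):
        raise ValueError("kmer coverage must be nonnegative")
    out = c_k * r / (r - k + 1.0)
    return float(out) if out.ndim == 0 else out


def filter_hits(hits: pd.DataFrame, min_identity: float = 75.0, min_length: int = 100) -> pd.DataFrame:
    """Keep hits with identity strictly above ``min_identity`` and length >= ``min_length``.

    Order of surviving rows is preserved; the filter is idempotent.
    """
    keep = (hits["percent_identity"] > min_identity) & (hits["alignment_length"] >= min_length)
    return hits.loc[keep].copy()


def aggregate_abundance(
    hits: pd.DataFrame, group_lookup: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample species abundances and group-level coverage sums.

    Each hit's kmer coverage is converted to read coverage; coverages of
    hits to the same species within a sample are added (combining
    variants).  Relative percentage is 100 * C / (sample total).  Species
    not present in ``group_lookup`` fall into the ``other`` group.

    Returns ``(species_table, group_table)``.
    """
    df = hits.copy()
    df["coverage"] = convert_coverage(
        df["kmer_coverage"].to_numpy(), df["read_length"].to_numpy(), df["kmer_length"].to_numpy()
    )
    species = (
        df.groupby(["sample_id", "species"], sort=True)["coverage"].sum().reset_index()
    )
    species["group_label"] = species["species"].map(lambda s: group_lookup.get(s, "other"))
    totals = species.groupby("sample_id")["coverage"].transform("sum")
    zero = totals == 0
    if zero.any():
        for sample in species.loc[zero, "sample_id"].unique():
            logger.warning("sample %s has zero total coverage; no abundances reported", sample)
        species = species.loc[~zero].copy()
        totals = totals.loc[~zero]
    species["relative_percent"] = 100.0 * species["coverage"] / totals
    group = (
        species.groupby(["sample_id", "group_label"], sort=True)["coverage"]
        .sum()
        .reset_index()
        .rename(columns={"coverage": "total_coverage"})
    )
    return species, group
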