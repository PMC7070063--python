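"""Abundance profiles from contig-level pseudo-alignment counts.

A contig's coverage is count * 200 / length (200 bp standing in for the
read-pair length).  A MAG's abundance in a sample is the length-weighted
mean of its contig coverages divided by the sample's millions of mapped
read-pairs; a BACL inherits its representative MAG's profile verbatim.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from magniche._stats import spearman_dissimilarity

READ_PAIR_LENGTH = 200

logger = logging.getLogger(__name__)


def contig_coverage(est_count: float, contig_length: float) -> float:
    """Coverage of one contig: count x 200 / length."""
    if contig_length <= 0:
        raise ValueError("contig length must be positive")
    if est_count < 0:
        raise ValueError("negative count")
    return est_count * READ_PAIR_LENGTH / contig_length


def mag_abundance(
    coverages, lengths, mapped_read_pairs: float
) -> float:
    """Length-weighted mean contig coverage per million mapped read-pairs."""
    coverages = np.asarray(coverages, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if coverages.size == 0:
        raise ValueError("need at least one contig")
    total = lengths.sum()
    if total <= 0:
        raise ValueError("total contig length must be positive")
    if mapped_read_pairs <= 0:
        raise ValueError("mapped read-pairs must be positive")
    weighted = float(np.dot(coverages, lengths) / total)
    return weighted / (mapped_read_pairs / 1e6)


def mag_abundance_table(
    contig_counts: dict[str, pd.DataFrame],
    contig_to_mag: pd.Series,
    mapped_read_pairs: pd.Series,
) -> pd.DataFrame:
    """MAG x sample abundance matrix.

    ``contig_counts`` maps sample_id to a table with columns contig_id,
    length, est_count; ``contig_to_mag`` maps contig_id to mag_id;
    ``mapped_read_pairs`` maps sample_id to the sample's total.
    """
    samples = sorted(contig_counts)
    mags = sorted(contig_to_mag.unique())
    out = pd.DataFrame(0.0, index=mags, columns=samples)
    for sample in samples:
        table = contig_counts[sample]
        pairs = float(mapped_read_pairs[sample])
        cov = table["est_count"].to_numpy() * READ_PAIR_LENGTH / table[
            "length"
        ].to_numpy(dtype=float)
        frame = pd.DataFrame(
            {
                "mag": contig_to_mag.reindex(table["contig_id"]).to_numpy(),
                "wcov": cov * table["length"].to_numpy(dtype=float),
                "length": table["length"].to_numpy(dtype=float),
            }
        )
        grouped = frame.groupby("mag").sum()
        out[sample] = (grouped["wcov"] / grouped["length"]) / (pairs / 1e6)
    out = out.fillna(0.0)
    empty = out.columns[(out.sum(axis=0) == 0)]
    for sample in empty:
        logger.warning("sample %s has zero abundance for every MAG", sample)
    return out


def bacl_abundance(
    representatives: dict[str, str], mag_abundances: pd.DataFrame
) -> pd.DataFrame:
    """Each BACL's profile is its representative MAG's profile, verbatim."""
    missing = [b for b, m in representatives.items() if m not in mag_abundances.index]
    if missing:
        raise ValueError(f"representative abundance missing for: {sorted(missing)}")
    bacls = sorted(representatives)
    rows = mag_abundances.loc[[representatives[b] for b in bacls]]
    rows.index = bacls
    return rows


def abundance_dissimilarity(profiles: pd.DataFrame) -> pd.DataFrame:
    """(1 - Spearman rho)/2 between per-sample abundance vectors."""
    return spearman_dissimilarity(profiles)
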