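"""Gene (orthologous-group) profiles for MAGs and BACLs.

Profiles count, per genome, the occurrences of each orthologous-group label
carrying the exact "@NOG" suffix; BACL profiles are the arithmetic mean of
their members' profiles.  Dissimilarity between profiles is (1 - rho)/2
with rho the Spearman rank correlation.
"""

from __future__ import annotations

from collections import Counter

import pandas as pd

from magniche._stats import spearman_dissimilarity

NOG_SUFFIX = "@NOG"


def build_mag_profile(annotation_rows) -> dict[str, float]:
    """Count orthologous groups from one MAG's gene annotations.

    ``annotation_rows`` yields, per gene, an iterable (or comma-separated
    string) of labels.  Only labels ending in exactly "@NOG" are counted
    (e.g. "COG0001@NOG" yes, "K00001@ko" and "X@biNOG" no); a gene with
    several retained labels increments each.  The suffix is stripped from
    the stored label.
    """
    counts: Counter[str] = Counter()
    for labels in annotation_rows:
        if isinstance(labels, str):
            labels = labels.split(",") if labels else []
        for label in labels:
            label = label.strip()
            if label.endswith(NOG_SUFFIX) and len(label) > len(NOG_SUFFIX):
                counts[label[: -len(NOG_SUFFIX)]] += 1
    return dict(counts)


def profiles_from_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Wide MAG x label count table from a long annotation table.

    Expects columns mag_id, gene_id, labels (comma-separated).
    """
    required = {"mag_id", "gene_id", "labels"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    per_mag = {
        mag: build_mag_profile(group["labels"].fillna(""))
        for mag, group in annotation.groupby("mag_id", sort=True)
    }
    table = pd.DataFrame.from_dict(per_mag, orient="index").fillna(0.0)
    return table.sort_index().sort_index(axis=1)


def bacl_profile(member_profiles: list[dict[str, float]]) -> dict[str, float]:
    """Per-label arithmetic mean over member MAGs, absences counted as 0."""
    if not member_profiles:
        raise ValueError("cannot average an empty cluster")
    labels = sorted({label for p in member_profiles for label in p})
    n = len(member_profiles)
    return {
        label: sum(p.get(label, 0.0) for p in member_profiles) / n
        for label in labels
    }


def bacl_profiles(
    mag_profiles: pd.DataFrame, labels: dict[str, str]
) -> pd.DataFrame:
    """BACL x label mean-count table (missing labels treated as zero)."""
    mags = [m for m in mag_profiles.index if m in labels]
    if not mags:
        raise ValueError("no profiled MAG has a cluster label")
    groups = pd.Series({m: labels[m] for m in mags}, name="bacl")
    out = mag_profiles.loc[mags].groupby(groups).mean()
    out.index.name = None
    return out.sort_index()


def prevalence_filter(
    profiles: pd.DataFrame, min_frac: float = 0.10
) -> pd.DataFrame:
    """Keep labels present (count > 0) in at least ``min_frac`` of entities.

    The threshold is ceil(min_frac * n) entities, so "at least 10%" keeps a
    label present in 2 of 20 clusters and drops one present in only 1.
    """
    if profiles.empty:
        raise ValueError("no profiles to filter")
    n = profiles.shape[0]
    needed = -(-int(min_frac * n * 1e9) // int(1e9))  # ceil without float drift
    needed = max(needed, 1)
    prevalence = (profiles > 0).sum(axis=0)
    kept = prevalence[prevalence >= needed].index
    return profiles[kept]


def profile_dissimilarity(profiles: pd.DataFrame) -> pd.DataFrame:
    """(1 - Spearman rho)/2 between entity profiles over the shared labels."""
    return spearman_dissimilarity(profiles)
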