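"""Genome catalogue construction: QC gating, species clustering (BACLs),
representative selection, exclusion flags and rarefaction curves."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

COMPLETENESS_MIN = 75.0
CONTAMINATION_MAX = 5.0
CLUSTER_ANI_THRESHOLD = 0.965
EXCLUSION_ANI_CUTOFF = 0.95

_SYMMETRY_TOL = 1e-9


@dataclass
class MagRecord:
    mag_id: str
    sample_id: str
    completeness: float
    contamination: float
    contigs: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.completeness < 0 or self.completeness > 100:
            raise ValueError(f"{self.mag_id}: completeness outside [0, 100]")
        if self.contamination < 0:
            raise ValueError(f"{self.mag_id}: negative contamination")
        if any(length <= 0 for _, length in self.contigs):
            raise ValueError(f"{self.mag_id}: non-positive contig length")


@dataclass
class BaclAssignment:
    """Cluster membership, representatives and exclusion flags."""

    labels: dict[str, str]  # mag_id -> bacl_id
    representatives: dict[str, str]  # bacl_id -> mag_id
    excluded: set[str] = field(default_factory=set)

    def members(self, bacl_id: str) -> list[str]:
        return sorted(m for m, b in self.labels.items() if b == bacl_id)

    @property
    def bacl_ids(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def retained_bacls(self) -> list[str]:
        return [b for b in self.bacl_ids if b not in self.excluded]


def qc_gate(mags: list[MagRecord]) -> list[MagRecord]:
    """Keep genomes with completeness >= 75% and contamination <= 5%."""
    return [
        m
        for m in mags
        if m.completeness >= COMPLETENESS_MIN and m.contamination <= CONTAMINATION_MAX
    ]


def _check_ani(ani: pd.DataFrame) -> np.ndarray:
    values = np.asarray(ani, dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError("ANI matrix must be square")
    if not np.all(np.abs(values - values.T) <= _SYMMETRY_TOL):
        raise ValueError("ANI matrix is not symmetric within 1e-9")
    if not np.allclose(np.diag(values), 1.0):
        raise ValueError("ANI matrix diagonal must be 1")
    return values


def cluster_mags(
    ani: pd.DataFrame, threshold: float = CLUSTER_ANI_THRESHOLD
) -> dict[str, str]:
    """Average-linkage clustering of genomes at d = 1 - ANI.

    Clusters are flat clusters of the average-linkage dendrogram cut at
    height 1 - threshold (inclusive).  The input is reindexed by sorted
    mag_id first, so the labelling is invariant to input permutation;
    cluster ids (BACL1, BACL2, ...) follow the order of each cluster's
    lexicographically smallest member.
    """
    values = _check_ani(ani)
    mag_ids = sorted(str(m) for m in ani.index)
    order = [list(ani.index).index(m) for m in mag_ids]
    dist = 1.0 - values[np.ix_(order, order)]
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # kill <=1e-9 asymmetry before squareform

    if len(mag_ids) == 1:
        return {mag_ids[0]: "BACL1"}
    condensed = squareform(dist, checks=False)
    merge = linkage(condensed, method="average")
    flat = fcluster(merge, t=1.0 - threshold, criterion="distance")

    first_member: dict[int, str] = {}
    for mag, cluster in zip(mag_ids, flat):
        first_member.setdefault(cluster, mag)
    ordered = sorted(first_member, key=lambda c: first_member[c])
    rename = {cluster: f"BACL{i + 1}" for i, cluster in enumerate(ordered)}
    return {mag: rename[cluster] for mag, cluster in zip(mag_ids, flat)}


def select_representative(
    members: list[tuple[str, float, float]],
) -> str:
    """MAG with the highest completeness minus contamination; ties go to the
    lexicographically smallest mag_id."""
    if not members:
        raise ValueError("cannot pick a representative from an empty cluster")
    return min(members, key=lambda m: (-(m[1] - m[2]), m[0]))[0]


def exclusion_filter(
    ani: pd.DataFrame,
    labels: dict[str, str],
    cutoff: float = EXCLUSION_ANI_CUTOFF,
) -> set[str]:
    """BACLs containing any MAG with ANI strictly > cutoff to a MAG of a
    different BACL (risk of cross-cluster read recruitment)."""
    mags = [m for m in ani.index if m in labels]
    sub = ani.loc[mags, mags].to_numpy()
    bacls = np.array([labels[m] for m in mags])
    excluded: set[str] = set()
    n = len(mags)
    for i in range(n):
        for j in range(i + 1, n):
            if bacls[i] != bacls[j] and sub[i, j] > cutoff:
                excluded.add(bacls[i])
                excluded.add(bacls[j])
    return excluded


def assign_bacls(
    quality: pd.DataFrame,
    ani: pd.DataFrame,
    threshold: float = CLUSTER_ANI_THRESHOLD,
    cutoff: float = EXCLUSION_ANI_CUTOFF,
) -> BaclAssignment:
    """QC-gate, cluster, pick representatives and flag exclusions in one go.

    ``quality`` needs columns mag_id, completeness, contamination (sample_id
    optional).  Only QC-passing MAGs present in the ANI matrix are used.
    """
    if cutoff >= threshold:
        raise ValueError("exclusion cutoff must be below the clustering threshold")
    if (quality["completeness"] < 0).any() or (quality["contamination"] < 0).any():
        raise ValueError("negative quality values")
    passed = quality[
        (quality["completeness"] >= COMPLETENESS_MIN)
        & (quality["contamination"] <= CONTAMINATION_MAX)
    ]
    keep = [m for m in ani.index if m in set(passed["mag_id"])]
    if not keep:
        raise ValueError("no MAGs pass the QC gate")
    labels = cluster_mags(ani.loc[keep, keep], threshold=threshold)
    qual = passed.set_index("mag_id")
    reps: dict[str, str] = {}
    for bacl in sorted(set(labels.values())):
        members = [
            (m, float(qual.loc[m, "completeness"]), float(qual.loc[m, "contamination"]))
            for m, b in labels.items()
            if b == bacl
        ]
        reps[bacl] = select_representative(members)
    excluded = exclusion_filter(ani.loc[keep, keep], labels, cutoff=cutoff)
    return BaclAssignment(labels=labels, representatives=reps, excluded=excluded)


def rarefaction(
    incidence: pd.DataFrame, n_perm: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Distribution of distinct cluster counts under random sample subsets.

    ``incidence`` is samples x clusters (boolean / 0-1).  For every subset
    size k = 1..n_samples, draws ``n_perm`` random k-subsets of samples
    without replacement and counts the distinct clusters present.  Returns a
    DataFrame with one row per draw: columns k, n_bacls.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    inc = np.asarray(incidence, dtype=bool)
    n_samples = inc.shape[0]
    rng = np.random.default_rng(seed)
    rows_k = []
    rows_n = []
    for k in range(1, n_samples + 1):
        for _ in range(n_perm):
            idx = rng.choice(n_samples, size=k, replace=False)
            rows_k.append(k)
            rows_n.append(int(inc[idx].any(axis=0).sum()))
    return pd.DataFrame({"k": rows_k, "n_bacls": rows_n})
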