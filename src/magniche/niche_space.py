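"""Virtual niche space: PCoA with Cailliez correction, environmental
arrows, and a priori niche gradients (log abundance ratios) with their
inclusion filters."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from magniche._stats import spearman_rho

_EIG_TOL = 1e-8


@dataclass
class NicheSpace:
    coordinates: pd.DataFrame  # entity x axis (PC1..PCk)
    eigenvalues: np.ndarray  # all eigenvalues, decreasing
    variance_explained: np.ndarray  # per retained axis
    cailliez_constant: float
    arrows: pd.DataFrame | None = None  # variable x axis, in [-1, 1]


@dataclass
class GradientSpec:
    """Definition of one a priori niche gradient.

    ``mode`` "group": log of (mean over numerator samples + eps) over
    (mean over denominator samples + eps).  ``mode`` "paired": mean over
    sample pairs of log((numerator + eps)/(denominator + eps)).
    Inclusion requires max abundance over ``scope_samples`` strictly above
    ``threshold``.
    """

    name: str
    mode: str  # "group" | "paired"
    numerator: list[str] = field(default_factory=list)
    denominator: list[str] = field(default_factory=list)
    pairs: list[tuple[str, str]] = field(default_factory=list)
    threshold: float = 0.01
    pseudocount: float = 0.001
    scope_samples: list[str] | None = None

    def involved_samples(self) -> list[str]:
        if self.scope_samples is not None:
            return list(self.scope_samples)
        if self.mode == "paired":
            return sorted({s for pair in self.pairs for s in pair})
        return sorted(set(self.numerator) | set(self.denominator))


@dataclass
class NicheGradient:
    name: str
    values: pd.Series  # per-entity log ratio
    included: pd.Series  # per-entity bool
    threshold: float
    pseudocount: float


def _double_center(matrix: np.ndarray) -> np.ndarray:
    n = matrix.shape[0]
    centering = np.eye(n) - np.ones((n, n)) / n
    return centering @ matrix @ centering


def cailliez_constant(dissim: np.ndarray) -> float:
    """Smallest additive constant on off-diagonal dissimilarities that makes
    the configuration Euclidean (largest real eigenvalue of the standard
    2n x 2n companion matrix)."""
    n = dissim.shape[0]
    delta1 = _double_center(-0.5 * dissim**2)
    delta2 = _double_center(-0.5 * dissim)
    top = np.hstack([np.zeros((n, n)), 2.0 * delta1])
    bottom = np.hstack([-np.eye(n), -4.0 * delta2])
    eigvals = np.linalg.eigvals(np.vstack([top, bottom]))
    return float(max(eigvals.real))


def pcoa_cailliez(dissim: pd.DataFrame, k: int = 10) -> NicheSpace:
    """Principal coordinates of a dissimilarity matrix, Cailliez-corrected.

    If the double-centered Gower matrix has a negative eigenvalue beyond
    tolerance, the Cailliez constant is added to the off-diagonal
    dissimilarities before eigendecomposition.  Coordinates are eigenvectors
    scaled by sqrt(eigenvalue), axes ordered by decreasing eigenvalue, each
    axis oriented so its largest-magnitude coordinate is positive.
    """
    values = np.asarray(dissim, dtype=float)
    if np.isnan(values).any():
        raise ValueError("dissimilarity matrix contains missing entries")
    if not np.allclose(values, values.T, atol=1e-9):
        raise ValueError("dissimilarity matrix is not symmetric")
    n = values.shape[0]

    gower = _double_center(-0.5 * values**2)
    eigvals = np.linalg.eigvalsh(gower)
    constant = 0.0
    if eigvals.min() < -_EIG_TOL:
        constant = cailliez_constant(values)
        corrected = values + constant
        np.fill_diagonal(corrected, 0.0)
        gower = _double_center(-0.5 * corrected**2)

    eigvals, eigvecs = np.linalg.eigh(gower)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    positive = eigvals > _EIG_TOL
    n_axes = min(k, int(positive.sum()))
    coords = eigvecs[:, :n_axes] * np.sqrt(eigvals[:n_axes])
    for axis in range(n_axes):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col

    total_positive = eigvals[positive].sum()
    var_explained = eigvals[:n_axes] / total_positive if total_positive > 0 else (
        np.zeros(n_axes)
    )
    frame = pd.DataFrame(
        coords,
        index=dissim.index,
        columns=[f"PC{i + 1}" for i in range(n_axes)],
    )
    return NicheSpace(
        coordinates=frame,
        eigenvalues=eigvals,
        variance_explained=var_explained,
        cailliez_constant=constant,
    )


def variance_explained(eigenvalues: np.ndarray) -> np.ndarray:
    """Fraction lambda_i / sum of positive lambdas, for positive axes."""
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    positive = eigenvalues[eigenvalues > _EIG_TOL]
    if positive.size == 0:
        raise ValueError("no positive eigenvalues")
    return positive / positive.sum()


def env_arrows(
    abundances: pd.DataFrame,
    metadata: pd.DataFrame,
    space: NicheSpace,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Two-stage Spearman arrows relating axes to environmental variables.

    Stage 1: per entity, Spearman rho across samples between its abundance
    profile and each variable (samples with missing variable values dropped
    pairwise).  Stage 2: per axis, Spearman rho across entities between
    those stage-1 correlations and the axis scores.  Endpoints lie in
    [-1, 1].
    """
    if variables is None:
        variables = [
            c
            for c in metadata.columns
            if pd.api.types.is_numeric_dtype(metadata[c])
        ]
    samples = [s for s in abundances.columns if s in metadata.index]
    if not samples:
        raise ValueError("no overlap between abundance samples and metadata")
    coords = space.coordinates.loc[abundances.index]
    arrows = pd.DataFrame(index=variables, columns=coords.columns, dtype=float)
    for var in variables:
        env = metadata.loc[samples, var].astype(float)
        usable = env.dropna()
        if usable.nunique() <= 1:
            raise ValueError(f"environmental variable {var!r} is constant")
        stage1 = np.array(
            [
                spearman_rho(
                    abundances.loc[entity, usable.index].to_numpy(),
                    usable.to_numpy(),
                )
                if abundances.loc[entity, usable.index].nunique() > 1
                else 0.0
                for entity in abundances.index
            ]
        )
        for axis in coords.columns:
            arrows.loc[var, axis] = spearman_rho(
                stage1, coords[axis].to_numpy()
            )
    return arrows


def gradient_log_ratio(
    abundances: pd.DataFrame, spec: GradientSpec
) -> NicheGradient:
    """Per-entity log abundance ratio along one a priori gradient."""
    eps = spec.pseudocount
    if spec.mode == "group":
        if not spec.numerator or not spec.denominator:
            raise ValueError(f"gradient {spec.name!r}: empty sample group")
        _require(abundances, spec.numerator + spec.denominator, spec.name)
        num = abundances[spec.numerator].mean(axis=1)
        den = abundances[spec.denominator].mean(axis=1)
        values = np.log((num + eps) / (den + eps))
    elif spec.mode == "paired":
        if not spec.pairs:
            raise ValueError(f"gradient {spec.name!r}: no sample pairs")
        flat = [s for pair in spec.pairs for s in pair]
        _require(abundances, flat, spec.name)
        logs = [
            np.log((abundances[a] + eps) / (abundances[b] + eps))
            for a, b in spec.pairs
        ]
        values = pd.concat(logs, axis=1).mean(axis=1)
    else:
        raise ValueError(f"unknown gradient mode {spec.mode!r}")

    scope = spec.involved_samples()
    _require(abundances, scope, spec.name)
    included = abundances[scope].max(axis=1) > spec.threshold
    return NicheGradient(
        name=spec.name,
        values=pd.Series(values, index=abundances.index),
        included=included,
        threshold=spec.threshold,
        pseudocount=eps,
    )


def _require(abundances: pd.DataFrame, samples: list[str], name: str) -> None:
    missing = [s for s in samples if s not in abundances.columns]
    if missing:
        raise ValueError(f"gradient {name!r}: missing samples {missing}")


def rank_axes_by_variable(arrows: pd.DataFrame) -> pd.Series:
    """For each axis, the variable with the largest |endpoint| (diagnostic)."""
    return arrows.abs().idxmax(axis=0)
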