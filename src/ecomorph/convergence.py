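"""Phylogenetic convergence of ecomorph groups: the Wheatsheaf index.

The index asks how phenotypically similar a focal group of species is,
given how distantly related they are. Phenotypic distances between
species means are penalized for phylogenetic proximity (close relatives'
similarity is discounted), and w is the ratio of the mean penalized
distance over all species pairs to the mean over focal pairs: w > 1
means the focal group is tighter than the tree alone would predict.
Significance comes from size-matched random focal sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import patristic_matrix


@dataclass
class PenalizedDistanceMatrix:
    species: list[str]
    distances: np.ndarray       # symmetric, zero diagonal
    penalty: np.ndarray         # sqrt(t_ij / t_max) divisor actually applied


@dataclass
class ConvergenceResult:
    focal: str
    w: float
    p: float
    n_perm: int
    per_trait: pd.DataFrame | None = None


def phylogenetic_penalty(tree: dendropy.Tree, species: list[str]) -> np.ndarray:
    """Divisor matrix sqrt(t_ij / t_max) from patristic distances.

    Dividing phenotypic distances by this factor inflates distances
    between close relatives, discounting similarity that is merely
    shared ancestry. Zero patristic distances between distinct species
    (zero-length terminal branches) borrow the smallest positive
    distance so the divisor stays finite.
    """
    t = patristic_matrix(tree, species)
    off = t[~np.eye(len(species), dtype=bool)]
    if off.size == 0 or off.max() <= 0:
        raise ValueError("tree has no positive patristic distances")
    positive = off[off > 0]
    t = np.where((t <= 0) & ~np.eye(len(species), dtype=bool), positive.min(), t)
    pen = np.sqrt(t / off.max())
    np.fill_diagonal(pen, 1.0)
    return pen


def penalized_distances(species_means: pd.DataFrame, tree: dendropy.Tree) -> PenalizedDistanceMatrix:
    """Euclidean distances between species means, penalty-divided."""
    species = list(species_means.index)
    d = squareform(pdist(species_means.to_numpy(dtype=float)))
    pen = phylogenetic_penalty(tree, species)
    return PenalizedDistanceMatrix(species=species, distances=d / pen, penalty=pen)


def _pair_mean(d: np.ndarray, idx: np.ndarray) -> float:
    sub = d[np.ix_(idx, idx)]
    n = len(idx)
    return float(sub.sum() / (n * (n - 1)))


def _w_from_matrix(d: np.ndarray, focal_idx: np.ndarray) -> float:
    n = d.shape[0]
    all_mean = float(d.sum() / (n * (n - 1)))
    focal_mean = _pair_mean(d, focal_idx)
    if focal_mean == 0:
        return np.inf
    return all_mean / focal_mean


def wheatsheaf(
    species_means: pd.DataFrame,
    tree: dendropy.Tree,
    focal: set | list,
    n_perm: int = 999,
    seed: int = 0,
    focal_label: str = "",
) -> ConvergenceResult:
    """Wheatsheaf convergence index for a focal species set.

    ``species_means`` are per-species means of the scaled trait matrix
    (SE-weighting disabled: scaled values carry no meaningful standard
    errors). The p-value is the smoothed fraction of size-matched random
    focal sets whose index meets or exceeds the observed one.
    """
    focal = sorted(set(focal))
    species = list(species_means.index)
    missing = sorted(set(focal) - set(species))
    if missing:
        raise ValueError(f"focal species missing from trait table: {missing}")
    if len(focal) < 2:
        raise ValueError("focal group needs at least two species")
    pdm = penalized_distances(species_means, tree)
    pos = {s: i for i, s in enumerate(pdm.species)}
    focal_idx = np.array([pos[s] for s in focal], dtype=int)
    w = _w_from_matrix(pdm.distances, focal_idx)

    rng = np.random.default_rng(seed)
    n = len(species)
    ge = 0
    for _ in range(n_perm):
        draw = rng.choice(n, size=len(focal), replace=False)
        ge += _w_from_matrix(pdm.distances, draw) >= w
    p = (ge + 1) / (n_perm + 1)
    return ConvergenceResult(focal=focal_label, w=float(w), p=float(p), n_perm=n_perm)


def signature_scan(
    species_means: pd.DataFrame,
    tree: dendropy.Tree,
    focal: set | list,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    focal_label: str = "",
) -> ConvergenceResult:
    """Per-trait Wheatsheaf scan marking the focal group's signature traits.

    Each trait column is tested on its own; signature traits are those
    whose per-trait convergence is greater than expected by chance
    (p < alpha). The multivariate index is returned alongside.
    """
    focal = sorted(set(focal))
    if len(focal) < 2:
        raise ValueError("focal group needs at least two species")
    overall = wheatsheaf(species_means, tree, focal, n_perm=n_perm, seed=seed, focal_label=focal_label)
    species = list(species_means.index)
    pen = phylogenetic_penalty(tree, species)
    pos = {s: i for i, s in enumerate(species)}
    focal_idx = np.array([pos[s] for s in focal], dtype=int)
    n = len(species)
    rng = np.random.default_rng(seed)
    draws = np.array([rng.choice(n, size=len(focal), replace=False) for _ in range(n_perm)])

    rows = []
    x = species_means.to_numpy(dtype=float)
    for j, trait in enumerate(species_means.columns):
        d = np.abs(x[:, [j]] - x[:, [j]].T) / pen
        w = _w_from_matrix(d, focal_idx)
        ge = sum(_w_from_matrix(d, draw) >= w for draw in draws)
        p = (ge + 1) / (n_perm + 1)
        rows.append((trait, w, p, p < alpha))
    per_trait = pd.DataFrame(rows, columns=["trait", "w_trait", "p_trait", "signature"])
    return ConvergenceResult(
        focal=focal_label, w=overall.w, p=overall.p, n_perm=n_perm, per_trait=per_trait
    )
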