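"""Diversity and phylogenetic statistics.

Covers the beta-diversity stack used to compare communities across
platforms: inverse Simpson rarefaction, distance-based neighbour-joining
trees with midpoint rooting, the generalized UniFrac family d^(alpha)
(including the unweighted d^U and variance-adjusted d^VAW forms), classical
PCoA, and perMANOVA.

Generalized UniFrac between communities A and B on a rooted tree with
branch lengths b_i and branch proportions p_Ai, p_Bi (fraction of each
community descending through branch i):

    d^(alpha) = sum_i b_i (p_Ai+p_Bi)^alpha |p_Ai-p_Bi|/(p_Ai+p_Bi)
                / sum_i b_i (p_Ai+p_Bi)^alpha        over branches with
                                                      p_Ai+p_Bi > 0.

alpha = 1 is the classical weighted-normalized UniFrac; alpha -> 0 removes
the abundance weighting of shared branches.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .classify import AlignmentParams, DEFAULT_PARAMS, align_semi_global
from .io_formats import OTUTable, SequenceRecord

logger = logging.getLogger(__name__)

UNIFRAC_VARIANTS = ("d_W", "d_0.5", "d_0", "d_U", "d_VAW")


# ---------------------------------------------------------------------------
# Alpha diversity


def inverse_simpson(counts: Sequence[float]) -> float:
    """Inverse Simpson index 1 / sum(p_i^2): the effective number of equally
    abundant taxa."""
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative counts")
    total = arr.sum()
    if total == 0:
        raise ValueError("all-zero count vector")
    p = arr / total
    return float(1.0 / np.square(p).sum())


@dataclass(frozen=True)
class RarefactionCurve:
    depths: tuple[int, ...]
    mean: tuple[float, ...]
    sd: tuple[float, ...]
    n_reps: int
    seed: int


def rarefaction_curve(
    counts: Sequence[int],
    depths: Sequence[int],
    n_reps: int = 10,
    seed: int = 0,
) -> RarefactionCurve:
    """Inverse Simpson under repeated subsampling without replacement."""
    arr = np.asarray(counts, dtype=np.int64)
    total = int(arr.sum())
    if any(d > total for d in depths):
        raise ValueError(f"depth exceeds total count {total}")
    if any(d < 1 for d in depths):
        raise ValueError("depths must be >= 1")
    rng = np.random.default_rng(seed)
    means, sds = [], []
    for depth in depths:
        values = [
            inverse_simpson(rng.multivariate_hypergeometric(arr, depth))
            for _ in range(n_reps)
        ]
        means.append(float(np.mean(values)))
        sds.append(float(np.std(values)))
    return RarefactionCurve(
        depths=tuple(int(d) for d in depths),
        mean=tuple(means),
        sd=tuple(sds),
        n_reps=n_reps,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Trees


def nj_tree(distance_matrix: DistanceMatrix) -> TreeNode:
    """Neighbour-joining tree from a distance matrix.

    Negative branch lengths (an NJ artefact) are clamped to zero with the
    deficit shifted onto the sibling branch, preserving leaf-to-leaf path
    lengths through the parent as closely as possible.
    """
    if not isinstance(distance_matrix, DistanceMatrix):
        distance_matrix = DistanceMatrix(distance_matrix)
    ids = list(distance_matrix.ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 taxa")
    if len(ids) == 2:
        d = float(distance_matrix[ids[0], ids[1]])
        return TreeNode.read([f"({ids[0]}:{d / 2},{ids[1]}:{d / 2});"])
    tree = _skbio_nj(distance_matrix)
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            deficit = node.length
            node.length = 0.0
            siblings = [s for s in node.parent.children if s is not node]
            for sib in siblings:
                if sib.length is not None:
                    sib.length = max(0.0, sib.length + deficit / len(siblings))
            logger.info("nj_tree: clamped negative branch (%.4g) at %s", deficit, node.name)
    return tree


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    tips = list(tree.tips())
    if len(tips) < 2:
        return tree.copy()
    total = sum((n.length or 0.0) for n in tree.traverse(include_self=False))
    if total == 0:
        logger.warning("midpoint_root: zero-length tree, keeping current root")
        return tree.copy()
    if len(tips) == 2:  # degenerate case: root exactly between the two tips
        a, b = tips
        half = a.distance(b) / 2
        return TreeNode.read([f"({a.name}:{half},{b.name}:{half});"])
    return tree.root_at_midpoint()


def alignment_distance_matrix(
    records: Sequence[SequenceRecord],
    params: AlignmentParams = DEFAULT_PARAMS,
) -> DistanceMatrix:
    """Pairwise (1 - alignment identity) distances between sequences."""
    n = len(records)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = align_semi_global(records[i], records[j], params)
            mat[i, j] = mat[j, i] = 1.0 - aln.identity
    return DistanceMatrix(mat, ids=[r.id for r in records])


def reference_tree(
    records: Sequence[SequenceRecord],
    params: AlignmentParams = DEFAULT_PARAMS,
) -> TreeNode:
    """Midpoint-rooted NJ tree on alignment-identity distances."""
    return midpoint_root(nj_tree(alignment_distance_matrix(records, params)))


# ---------------------------------------------------------------------------
# UniFrac


def _branch_table(tree: TreeNode) -> tuple[list[TreeNode], np.ndarray, dict[str, int], list[list[int]]]:
    """Per-branch lengths and the leaf sets descending through each branch."""
    nodes = [n for n in tree.traverse(include_self=False)]
    lengths = np.array([(n.length or 0.0) for n in nodes])
    leaf_index: dict[str, int] = {}
    for tip in tree.tips():
        leaf_index[tip.name] = len(leaf_index)
    below: list[list[int]] = []
    for node in nodes:
        below.append([leaf_index[t.name] for t in node.tips()] if not node.is_tip() else [leaf_index[node.name]])
    return nodes, lengths, leaf_index, below


def _branch_proportions(
    tree: TreeNode, profiles: Sequence[Mapping[str, float]]
) -> tuple[np.ndarray, np.ndarray]:
    """Returns (branch lengths b, matrix P of shape n_branches x n_profiles)."""
    _, lengths, leaf_index, below = _branch_table(tree)
    for profile in profiles:
        missing = [leaf for leaf in profile if leaf not in leaf_index]
        if missing:
            raise ValueError(f"profile leaves missing from tree: {missing}")
    leaf_mass = np.zeros((len(leaf_index), len(profiles)))
    for k, profile in enumerate(profiles):
        for leaf, value in profile.items():
            leaf_mass[leaf_index[leaf], k] = value
    P = np.vstack([leaf_mass[idx].sum(axis=0) for idx in below])
    return lengths, P


def _check_profile(profile: Mapping[str, float]) -> None:
    total = sum(profile.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"profile sums to {total}, not 1")
    if any(v < 0 for v in profile.values()):
        raise ValueError("negative abundance in profile")


def generalized_unifrac(
    tree: TreeNode,
    profile_a: Mapping[str, float],
    profile_b: Mapping[str, float],
    alpha: float = 0.5,
) -> float:
    """Generalized UniFrac distance d^(alpha) between two communities."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    _check_profile(profile_a)
    _check_profile(profile_b)
    b, P = _branch_proportions(tree, [profile_a, profile_b])
    pa, pb = P[:, 0], P[:, 1]
    m = pa + pb
    occupied = m > 0
    if not occupied.any():
        raise ValueError("profiles place no mass on the tree")
    weight = b[occupied] * np.power(m[occupied], alpha)
    ratio = np.abs(pa[occupied] - pb[occupied]) / m[occupied]
    denom = weight.sum()
    if denom == 0:
        return 0.0
    return float(np.dot(weight, ratio) / denom)


def unweighted_unifrac(
    tree: TreeNode,
    profile_a: Mapping[str, float],
    profile_b: Mapping[str, float],
) -> float:
    """Unweighted UniFrac d^U: branch-length fraction unique to one side."""
    _check_profile(profile_a)
    _check_profile(profile_b)
    b, P = _branch_proportions(tree, [profile_a, profile_b])
    pa, pb = P[:, 0] > 0, P[:, 1] > 0
    occupied = pa | pb
    denom = b[occupied].sum()
    if denom == 0:
        return 0.0
    return float(b[pa ^ pb].sum() / denom)


def variance_adjusted_unifrac(
    tree: TreeNode,
    profile_a: Mapping[str, float],
    profile_b: Mapping[str, float],
) -> float:
    """Variance-adjusted weighted UniFrac d^VAW.

    Each branch term is down-weighted by sqrt(m_i (m_total - m_i)), the
    binomial-variance factor of the combined branch proportion m_i; branches
    where that factor vanishes (empty, or carrying the entire combined mass)
    contribute nothing to either sum.
    """
    _check_profile(profile_a)
    _check_profile(profile_b)
    b, P = _branch_proportions(tree, [profile_a, profile_b])
    pa, pb = P[:, 0], P[:, 1]
    m = pa + pb
    m_total = 2.0
    var = m * (m_total - m)
    ok = var > 1e-15
    if not ok.any():
        return 0.0
    w = b[ok] / np.sqrt(var[ok])
    denom = np.dot(w, m[ok])
    if denom == 0:
        return 0.0
    return float(np.dot(w, np.abs(pa[ok] - pb[ok])) / denom)


def unifrac_matrix(
    table: OTUTable,
    tree: TreeNode,
    variants: Sequence[str] = UNIFRAC_VARIANTS,
) -> dict[str, DistanceMatrix]:
    """All pairwise sample distances for each requested UniFrac variant.

    Variants: ``d_W`` (alpha=1 weighted), ``d_0.5``, ``d_0``, ``d_U``
    (unweighted), ``d_VAW`` (variance-adjusted).
    """
    unknown = set(variants) - set(UNIFRAC_VARIANTS)
    if unknown:
        raise ValueError(f"unknown UniFrac variants {sorted(unknown)}")
    if len(table.samples) < 2:
        raise ValueError("need at least 2 samples")
    rel = table.relative_abundance()
    profiles = [
        {taxon: float(rel.loc[taxon, s]) for taxon in table.taxa}
        for s in table.samples
    ]
    out: dict[str, DistanceMatrix] = {}
    n = len(profiles)
    for variant in variants:
        mat = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            if variant == "d_W":
                d = generalized_unifrac(tree, profiles[i], profiles[j], alpha=1.0)
            elif variant == "d_0.5":
                d = generalized_unifrac(tree, profiles[i], profiles[j], alpha=0.5)
            elif variant == "d_0":
                d = generalized_unifrac(tree, profiles[i], profiles[j], alpha=0.0)
            elif variant == "d_U":
                d = unweighted_unifrac(tree, profiles[i], profiles[j])
            else:
                d = variance_adjusted_unifrac(tree, profiles[i], profiles[j])
            mat[i, j] = mat[j, i] = d
        out[variant] = DistanceMatrix(mat, ids=table.samples)
    return out


# ---------------------------------------------------------------------------
# Ordination


@dataclass(frozen=True)
class PCoAResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: tuple[float, ...]  # descending, negatives reported
    proportion_explained: tuple[float, ...]  # over positive eigenvalues


def pcoa(distance_matrix: DistanceMatrix) -> PCoAResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centres -D^2/2, eigendecomposes, and keeps axes with positive
    eigenvalues; coordinates are eigenvectors scaled by sqrt(eigenvalue).
    Negative eigenvalues (non-Euclidean input) are reported but their axes
    dropped. Axis signs are fixed so the largest-magnitude loading on each
    axis is positive.
    """
    if not isinstance(distance_matrix, DistanceMatrix):
        distance_matrix = DistanceMatrix(distance_matrix)
    D = distance_matrix.data
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(abs(eigvals).max(), 1.0) * 1e-12
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    for k in range(coords.shape[1]):
        if coords.shape[0] and coords[np.argmax(np.abs(coords[:, k])), k] < 0:
            coords[:, k] = -coords[:, k]
    pos_sum = eigvals[positive].sum()
    proportions = tuple(
        float(v / pos_sum) if pos_sum > 0 else 0.0 for v in eigvals[positive]
    )
    frame = pd.DataFrame(
        coords,
        index=list(distance_matrix.ids),
        columns=[f"PC{k + 1}" for k in range(coords.shape[1])],
    )
    return PCoAResult(
        coordinates=frame,
        eigenvalues=tuple(float(v) for v in eigvals),
        proportion_explained=proportions,
    )


# ---------------------------------------------------------------------------
# perMANOVA


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int


def _pseudo_f(D2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    n = D2.shape[0]
    g = len(groups)
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for grp in groups:
        idx = np.flatnonzero(labels == grp)
        sub = D2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    denom = ss_within / (n - g)
    if denom == 0:
        return math.inf if ss_between > 1e-12 else 0.0
    return (ss_between / (g - 1)) / denom


def permanova(
    distance_matrix: DistanceMatrix,
    group_labels: Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
    exact: bool = False,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    pseudo-F is computed from squared distances via the standard partition
    (total SS = sum of squared distances / n, within-group SS analogously per
    group). With ``exact=True`` all distinct label arrangements are
    enumerated and p is the exact fraction with F >= observed (identity
    included); otherwise p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations)
    over seeded random label permutations.
    """
    if not isinstance(distance_matrix, DistanceMatrix):
        distance_matrix = DistanceMatrix(distance_matrix)
    labels = np.asarray(group_labels)
    n = distance_matrix.shape[0]
    if labels.shape[0] != n:
        raise ValueError("label count != sample count")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        small = groups[counts < 2].tolist()
        raise ValueError(f"groups with a single sample: {small}")
    D2 = distance_matrix.data**2
    f_obs = _pseudo_f(D2, labels, groups)
    if exact:
        distinct = sorted(set(itertools.permutations(labels)))
        f_perms = [_pseudo_f(D2, np.asarray(perm), groups) for perm in distinct]
        hits = sum(1 for f in f_perms if f >= f_obs - 1e-12)
        return PermanovaResult(
            pseudo_f=float(f_obs),
            p_value=hits / len(distinct),
            n_permutations=len(distinct),
            seed=seed,
        )
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _pseudo_f(D2, perm, groups) >= f_obs - 1e-12:
            hits += 1
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=(1 + hits) / (1 + n_permutations),
        n_permutations=n_permutations,
        seed=seed,
    )
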