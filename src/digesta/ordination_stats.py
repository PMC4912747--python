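"""Multivariate and resampling statistics for community/process correlation.

Implemented from first principles (newick parsing is delegated to
scikit-bio's ``TreeNode``; all distance/ordination arithmetic is done
here):

* **UniFrac** phylogenetic distances between communities.  Unweighted:
  branch length unique to one community divided by the branch length
  leading to any taxon observed in either (Lozupone & Knight 2005).
  Weighted: sum over branches of length times the absolute difference of
  descendant read proportions, divided in the normalised variant by the
  same sum with the proportions added, giving a value in [0, 1].
* **PCoA** (principal coordinate analysis): Gower double-centering of
  -d^2/2 followed by an eigendecomposition; coordinates are eigenvectors
  scaled by the square roots of the positive eigenvalues.  Negative
  eigenvalues (non-Euclidean distances) are reported, not corrected.
* **CCA** (canonical correspondence analysis, ter Braak 1986): the
  chi-square residual matrix of the community table is regressed onto the
  constraint table by row-mass-weighted least squares and the fitted part
  decomposed by SVD, yielding constrained eigenvalues, site/feature
  scores and constraint biplot scores; the residual axes are ordinary CA
  axes of the unexplained part.
* A **Monte-Carlo permutation two-group test** on the two-sample t
  statistic with the add-one p estimator p = (1 + #{|t*| >= |t|}) / (B + 1),
  which can never return 0 (the floor at B = 999 permutations is 0.001).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "unifrac",
    "unifrac_matrix",
    "PcoaResult",
    "pcoa",
    "OrdinationResult",
    "cca",
    "major_feature_filter",
    "PermutationTestResult",
    "permutation_group_test",
]


# ---------------------------------------------------------------------------
# UniFrac


def _as_tree(tree) -> TreeNode:
    if isinstance(tree, TreeNode):
        return tree
    if isinstance(tree, str) and "(" in tree:
        return TreeNode.read(io.StringIO(tree))
    return TreeNode.read(str(tree))


def _tip_counts(counts) -> dict[str, float]:
    if isinstance(counts, Mapping):
        return {str(k): float(v) for k, v in counts.items()}
    if isinstance(counts, pd.Series):
        return {str(k): float(v) for k, v in counts.items()}
    raise TypeError("community counts must be a mapping or pandas Series keyed by tip name")


def unifrac(tree, counts_a, counts_b, *, weighted: bool = False, normalized: bool = True) -> float:
    """UniFrac distance between two communities on a shared tree.

    ``counts_a``/``counts_b`` map tree tip names to read counts.  Every
    taxon with a non-zero count must be a tip of the tree (a missing taxon
    raises with its id).  Identical communities give 0; communities on
    disjoint subtrees give 1 (unweighted, and weighted-normalised).
    """
    t = _as_tree(tree)
    a = _tip_counts(counts_a)
    b = _tip_counts(counts_b)
    tip_names = {tip.name for tip in t.tips()}
    for label, comm in (("A", a), ("B", b)):
        missing = [k for k, v in comm.items() if v > 0 and k not in tip_names]
        if missing:
            raise ValueError(f"community {label}: taxa missing from the tree: {missing}")
    total_a = sum(v for v in a.values() if v > 0)
    total_b = sum(v for v in b.values() if v > 0)
    if total_a == 0 or total_b == 0:
        raise ValueError("both communities must contain at least one read")

    unique = shared_denom = 0.0  # unweighted accumulators
    raw = wnorm = 0.0  # weighted accumulators
    for node in t.postorder(include_self=False):
        if node.is_tip():
            ca = a.get(node.name, 0.0)
            cb = b.get(node.name, 0.0)
            node._uf = (max(ca, 0.0), max(cb, 0.0))
        else:
            ca = sum(child._uf[0] for child in node.children)
            cb = sum(child._uf[1] for child in node.children)
            node._uf = (ca, cb)
        length = node.length or 0.0
        if length <= 0:
            continue
        pa, pb = ca / total_a, cb / total_b
        raw += length * abs(pa - pb)
        wnorm += length * (pa + pb)
        if ca > 0 or cb > 0:
            shared_denom += length
            if (ca > 0) != (cb > 0):
                unique += length
    for node in t.postorder(include_self=False):
        del node._uf
    if weighted:
        if not normalized:
            return raw
        return raw / wnorm if wnorm > 0 else 0.0
    return unique / shared_denom if shared_denom > 0 else 0.0


def unifrac_matrix(tree, table: pd.DataFrame, *, weighted: bool = False) -> pd.DataFrame:
    """Pairwise UniFrac distances between the columns of an OTUs x samples table."""
    t = _as_tree(tree)
    samples = list(table.columns)
    n = len(samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = unifrac(t, table[samples[i]], table[samples[j]], weighted=weighted)
    return pd.DataFrame(d, index=samples, columns=samples)


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class PcoaResult:
    """Embedding of a distance matrix: one column per positive eigenvalue."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all, descending (negatives reported, no axes)
    proportion_explained: np.ndarray  # per retained axis, of the positive total


def pcoa(distances, ids: Sequence[str] | None = None) -> PcoaResult:
    """Principal coordinate analysis by Gower double-centering.

    B = -1/2 J d^2 J with J = I - 11'/n is eigendecomposed; coordinates
    are eigenvectors scaled by sqrt(eigenvalue) for the positive
    eigenvalues.  For distances that derive from points in Euclidean space
    the embedding reproduces the inputs exactly (up to rotation).
    """
    if isinstance(distances, pd.DataFrame):
        ids = list(distances.index) if ids is None else list(ids)
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
        ids = [f"s{i}" for i in range(d.shape[0])] if ids is None else list(ids)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric (tolerance 1e-12)")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), 1.0) * 1e-12 if vals.size else 0.0
    pos = vals > tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    pos_total = vals[pos].sum()
    prop = vals[pos] / pos_total if pos_total > 0 else np.zeros(int(pos.sum()))
    cols = [f"PC{k + 1}" for k in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=cols),
        eigenvalues=vals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# CCA


@dataclass
class OrdinationResult:
    """Constrained correspondence analysis output.

    ``site_scores`` are linear-combination (LC) scores, ``wa_site_scores``
    weighted averages of feature scores; ``feature_scores`` are in
    principal coordinates (scaling type 2); ``biplot_scores`` are weighted
    correlations of the standardised constraints with the LC axes.
    """

    eigenvalues: np.ndarray  # constrained, non-increasing, in [0, 1]
    residual_eigenvalues: np.ndarray
    site_scores: pd.DataFrame
    wa_site_scores: pd.DataFrame
    feature_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    total_inertia: float
    constrained_inertia: float

    @property
    def proportion_explained(self) -> np.ndarray:
        """Fraction of the total inertia carried by each constrained axis."""
        return self.eigenvalues / self.total_inertia


_RANK_TOL = 1e-10


def cca(community: pd.DataFrame, constraints: pd.DataFrame) -> OrdinationResult:
    """Canonical correspondence analysis of a community on constraints.

    ``community`` is a samples x features non-negative matrix (counts or
    relative abundances; used as-is), ``constraints`` a samples x
    variables numeric table.  The total inertia is the community table's
    chi-square statistic divided by its grand total; the constrained
    eigenvalues sum to the part of it explained by the constraints.
    Constant or collinear constraint columns raise rather than being
    silently dropped.
    """
    y_df = community if isinstance(community, pd.DataFrame) else pd.DataFrame(community)
    x_df = constraints if isinstance(constraints, pd.DataFrame) else pd.DataFrame(constraints)
    if len(y_df) != len(x_df):
        raise ValueError("community and constraint tables must share the sample axis")
    y = y_df.to_numpy(dtype=float)
    x = x_df.to_numpy(dtype=float)
    if np.any(y < 0):
        raise ValueError("community matrix must be non-negative")
    if np.any(~np.isfinite(x)):
        raise ValueError("constraint table contains missing or non-finite values")
    if np.any(y.sum(axis=1) <= 0) or np.any(y.sum(axis=0) <= 0):
        raise ValueError("community rows and columns must each have positive totals")

    grand = y.sum()
    p = y / grand
    r = p.sum(axis=1)  # row (sample) masses
    c = p.sum(axis=0)  # column (feature) masses
    expected = np.outer(r, c)
    qbar = (p - expected) / np.sqrt(expected)
    total_inertia = float((qbar**2).sum())

    # weighted centring and scaling of the constraints
    xc = x - r @ x
    sd = np.sqrt(r @ (xc**2))
    if np.any(sd <= _RANK_TOL * max(1.0, float(np.abs(x).max()))):
        bad = [str(x_df.columns[k]) for k in np.where(sd <= _RANK_TOL)[0]]
        raise ValueError(f"constraint column(s) without variance: {bad}")
    xc = xc / sd
    xw = np.sqrt(r)[:, None] * xc
    q, rmat = np.linalg.qr(xw)
    diag = np.abs(np.diag(rmat))
    if np.any(diag < _RANK_TOL * diag.max()):
        raise ValueError("constraint table is rank deficient (collinear columns)")

    fitted = q @ (q.T @ qbar)
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    keep = s**2 > max(total_inertia, 1.0) * 1e-12
    u, s, vt = u[:, keep], s[keep], vt[keep]
    eig = s**2

    resid = qbar - fitted
    s_res = np.linalg.svd(resid, compute_uv=False)
    resid_eig = (s_res**2)[(s_res**2) > max(total_inertia, 1.0) * 1e-12]

    axes = [f"CCA{k + 1}" for k in range(len(eig))]
    inv_sqrt_r = 1.0 / np.sqrt(r)
    inv_sqrt_c = 1.0 / np.sqrt(c)
    site_lc = inv_sqrt_r[:, None] * u  # standard coordinates (scaling 2)
    feature = inv_sqrt_c[:, None] * (vt.T * s)  # principal coordinates
    with np.errstate(divide="ignore", invalid="ignore"):
        wa = inv_sqrt_r[:, None] * (qbar @ vt.T) / s
    biplot = xw.T @ u  # weighted correlation: both factors have unit norm

    return OrdinationResult(
        eigenvalues=eig,
        residual_eigenvalues=resid_eig,
        site_scores=pd.DataFrame(site_lc, index=y_df.index, columns=axes),
        wa_site_scores=pd.DataFrame(wa, index=y_df.index, columns=axes),
        feature_scores=pd.DataFrame(feature, index=y_df.columns, columns=axes),
        biplot_scores=pd.DataFrame(biplot, index=x_df.columns, columns=axes),
        total_inertia=total_inertia,
        constrained_inertia=float(eig.sum()),
    )


def major_feature_filter(community: pd.DataFrame, threshold: float = 0.02) -> pd.DataFrame:
    """Keep features holding at least ``threshold`` of the grand total.

    The inclusive >= matches the convention of selecting "major" taxa
    (e.g. OTUs with >= 2 % of all sequences) before constrained ordination.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly between 0 and 1")
    y = community.to_numpy(dtype=float)
    share = y.sum(axis=0) / y.sum()
    keep = share >= threshold
    if not keep.any():
        raise ValueError("no feature reaches the abundance threshold")
    return community.loc[:, keep].copy()


# ---------------------------------------------------------------------------
# Permutation test


@dataclass(frozen=True)
class PermutationTestResult:
    statistic: float  # two-sample t on the original labels
    p_value: float
    n_permutations: int
    degenerate: bool = False


def _t_stat(a: np.ndarray, b: np.ndarray, axis: int = -1) -> np.ndarray:
    na, nb = a.shape[axis], b.shape[axis]
    ma, mb = a.mean(axis=axis), b.mean(axis=axis)
    va = a.var(axis=axis, ddof=1) if na > 1 else np.zeros_like(ma)
    vb = b.var(axis=axis, ddof=1) if nb > 1 else np.zeros_like(mb)
    dof = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / dof if dof > 0 else np.zeros_like(ma)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return t


def permutation_group_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_permutations: int = 999,
    seed=None,
) -> PermutationTestResult:
    """Monte-Carlo permutation test of a two-group difference.

    The statistic is the pooled-variance two-sample t on the original
    labels; group labels are then shuffled ``n_permutations`` times and
    the two-sided p value estimated with the add-one estimator
    p = (1 + #{|t*| >= |t|}) / (n_permutations + 1), whose smallest
    achievable value at 999 permutations is 0.001.  Both groups having
    zero variance and equal means is degenerate: p = 1 is returned flagged.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    t_obs = float(_t_stat(a, b))
    if np.isnan(t_obs):  # zero variance, equal means: no evidence either way
        return PermutationTestResult(0.0, 1.0, n_permutations, degenerate=True)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pooled = np.concatenate([a, b])
    perms = rng.permuted(np.tile(pooled, (n_permutations, 1)), axis=1)
    t_perm = _t_stat(perms[:, : a.size], perms[:, a.size :], axis=1)
    t_perm = np.where(np.isnan(t_perm), 0.0, t_perm)  # keep +/-inf: exact-split ties
    exceed = int(np.sum(np.abs(t_perm) >= abs(t_obs)))
    p = (1 + exceed) / (n_permutations + 1)
    return PermutationTestResult(t_obs, p, n_permutations)
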