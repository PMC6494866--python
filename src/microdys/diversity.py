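"""Alpha/beta diversity, ordination, and community-level hypothesis tests.

Conventions: Shannon entropy is reported in bits (log base 2; a natural-log
variant is available via ``base=e``); Faith's phylogenetic diversity
includes the path to the root; rarefaction drops samples shallower than the
target depth (logged) rather than erroring; the PERMANOVA p-value uses the
add-one estimator (1 + #{F_perm >= F_obs}) / (1 + n_perm) so p is never 0.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ttest_ind
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd
from statsmodels.stats.multitest import multipletests

from microdys._errors import DegenerateInputError, EmptyResultError
from microdys.tables_io import CountTable

logger = logging.getLogger(__name__)


def rarefy(table: CountTable, depth: int, seed=None) -> CountTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped and logged.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    depths = table.depths()
    keep = depths[depths >= depth].index
    dropped = sorted(set(table.sample_ids) - set(keep))
    if dropped:
        logger.info("rarefy: dropped %d samples below depth %d: %s", len(dropped), depth, dropped)
    if len(keep) == 0:
        raise EmptyResultError(f"no samples have >= {depth} reads")
    out = {}
    for sid in keep:
        col = table.counts[sid].to_numpy()
        if col.sum() == depth:
            out[sid] = col
        else:
            out[sid] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(out, index=table.counts.index)
    return CountTable(counts, table.taxonomy)


def _proportions(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise DegenerateInputError("all-zero sample")
    return c / total


def shannon(counts, base: float = 2.0) -> float:
    """Shannon diversity −Σ pᵢ log pᵢ (base 2 by default → bits)."""
    p = _proportions(counts)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(base))


def observed_taxa(counts) -> int:
    """Number of taxa with a positive count."""
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise DegenerateInputError("all-zero sample")
    return int((c > 0).sum())


def pielou_evenness(counts) -> float:
    """Shannon diversity divided by its maximum log2(richness); 1 if a
    single taxon is present."""
    obs = observed_taxa(counts)
    if obs == 1:
        return 1.0
    return shannon(counts, base=2.0) / math.log2(obs)


def faith_pd(counts, taxon_ids, tree: TreeNode) -> float:
    """Faith's phylogenetic diversity (includes the path to the root)."""
    c = np.asarray(counts, dtype=float)
    present = {t for t, v in zip(taxon_ids, c) if v > 0}
    tips = {t.name for t in tree.tips()}
    missing = present - tips
    if missing:
        raise ValueError(f"taxa present in sample but missing from tree: {sorted(missing)}")
    return float(_skbio_faith_pd(c, list(taxon_ids), tree))


def alpha_diversity_table(
    table: CountTable, tree: TreeNode | None = None, rarefy_depth: int | None = None, seed=None
) -> pd.DataFrame:
    """Per-sample observed taxa, Shannon (bits), Pielou evenness, Faith PD."""
    if rarefy_depth is not None:
        table = rarefy(table, rarefy_depth, seed)
    rows = {}
    for sid in table.sample_ids:
        col = table.counts[sid].to_numpy()
        row = {
            "observed_taxa": observed_taxa(col),
            "shannon": shannon(col),
            "pielou_evenness": pielou_evenness(col),
        }
        if tree is not None:
            row["faith_pd"] = faith_pd(col, table.taxon_ids, tree)
        rows[sid] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "#SampleID"
    out.attrs["rarefy_depth"] = rarefy_depth
    return out


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarity between samples."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = table.counts.to_numpy(dtype=float).T
    if (X.sum(axis=1) == 0).any():
        raise DegenerateInputError("Bray–Curtis undefined for all-zero samples")
    return DistanceMatrix(squareform(pdist(X, metric="braycurtis")), ids=table.sample_ids)


def unweighted_unifrac(table: CountTable, tree: TreeNode) -> DistanceMatrix:
    """Unweighted (presence/absence) UniFrac between samples."""
    X = table.counts.to_numpy(dtype=np.int64).T
    return beta_diversity(
        "unweighted_unifrac", X, ids=table.sample_ids, taxa=table.taxon_ids, tree=tree
    )


@dataclass
class Ordination:
    """Classical (metric) multidimensional scaling of a distance matrix."""

    coordinates: pd.DataFrame       # samples x axes (PC1, PC2, ...)
    eigenvalues: np.ndarray         # all eigenvalues, sorted descending
    proportion_explained: np.ndarray  # relative to the sum of positive eigenvalues


def pcoa(dm: DistanceMatrix) -> Ordination:
    """Principal coordinates analysis via double-centered eigendecomposition.

    Negative eigenvalues (from non-Euclidean dissimilarities) are reported;
    axes are restricted to positive eigenvalues and % variance is computed
    relative to the positive-eigenvalue sum.
    """
    n = dm.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    D2 = dm.data ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    coordinates = pd.DataFrame(coords, index=list(dm.ids), columns=axes)
    prop = evals[pos] / evals[pos].sum()
    return Ordination(coordinates, evals, prop)


def _permanova_f(D2: np.ndarray, groups: np.ndarray, uniq: np.ndarray) -> float:
    """Pseudo-F from a squared distance matrix and integer group codes."""
    n = D2.shape[0]
    sst = D2[np.triu_indices(n, k=1)].sum() / n
    ssw = 0.0
    for g in uniq:
        idx = np.flatnonzero(groups == g)
        sub = D2[np.ix_(idx, idx)]
        ssw += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    k = len(uniq)
    ssa = sst - ssw
    return (ssa / (k - 1)) / (ssw / (n - k))


def permanova(dm: DistanceMatrix, labels, n_perm=999, seed=None) -> dict:
    """Permutational multivariate ANOVA on a distance matrix.

    Parameters
    ----------
    labels : sequence
        Group label per sample, aligned with ``dm.ids``.
    n_perm : int or "all"
        Number of random label permutations, or ``"all"`` for exhaustive
        enumeration of every ordering (exact p; feasible only for small n).

    Returns
    -------
    dict with ``pseudo_F``, ``p_value``, ``n_permutations``.
    """
    labels = np.asarray(labels)
    uniq, groups = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(groups)
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    D2 = dm.data ** 2
    f_obs = _permanova_f(D2, groups, np.arange(len(uniq)))
    if n_perm == "all":
        hits = 0
        total = 0
        for perm in itertools.permutations(range(len(groups))):
            f = _permanova_f(D2, groups[list(perm)], np.arange(len(uniq)))
            hits += f >= f_obs - 1e-12
            total += 1
        p = hits / total
        n_used = total
    else:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        hits = 0
        g = groups.copy()
        for _ in range(int(n_perm)):
            rng.shuffle(g)
            if _permanova_f(D2, g, np.arange(len(uniq))) >= f_obs - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + int(n_perm))
        n_used = int(n_perm)
    return {"pseudo_F": float(f_obs), "p_value": float(p), "n_permutations": n_used}


def axis_group_tests(axis_values, labels) -> pd.DataFrame:
    """All pairwise Welch t-tests on one ordination axis, BH-corrected.

    Pairs where a group has < 2 samples are skipped with a warning.
    """
    x = pd.Series(np.asarray(axis_values, dtype=float))
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for a, b in itertools.combinations(uniq, 2):
        xa, xb = x[labels == a], x[labels == b]
        if len(xa) < 2 or len(xb) < 2:
            logger.warning("axis_group_tests: skipping pair (%s, %s): group too small", a, b)
            continue
        t, p = ttest_ind(xa, xb, equal_var=False)
        rows.append({"group_a": a, "group_b": b, "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
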