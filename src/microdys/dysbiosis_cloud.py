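"""Reference-cloud dysbiosis index with 2-SD classification.

Pipeline: relative abundances → multiplicative zero replacement → centered
log-ratio (CLR) transform → Aitchison (Euclidean-on-CLR) distances → each
sample's "cloud statistic" = its mean distance to the (k nearest of the)
healthy reference samples, leave-one-out when the sample is itself a
reference.  The dysbiosis index (DI) is the natural log of the cloud
statistic.  A sample is called dysbiotic when its cloud statistic exceeds
the reference mean by more than two reference standard deviations
(one-sided upper rule; unusually *small* distances are still healthy-like).

An orthogonal validation path reclassifies samples by applying the same
2-SD rule to logit-transformed symptom-index scores of the reference group
and refitting a random forest on those labels, using the out-of-bag
probability of the dysbiotic class as an independent probability-based
index; agreement between the two indices is summarised by Pearson
correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.special import logit
from scipy.stats import pearsonr, shapiro
from skbio import DistanceMatrix
from sklearn.ensemble import RandomForestClassifier

from microdys._errors import DegenerateInputError
from microdys.tables_io import CountTable, collapse_to_rank

logger = logging.getLogger(__name__)

__all__ = [
    "CloudResult",
    "AgreementResult",
    "multiplicative_replacement",
    "clr_transform",
    "aitchison_distance",
    "table_to_clr",
    "cloud_statistic",
    "classify_dysbiosis",
    "cloud_analysis",
    "orthogonal_validation",
    "agreement_correlation",
]


@dataclass
class CloudResult:
    """Per-sample cloud statistic, dysbiosis index, and classification."""

    samples: pd.DataFrame     # columns: cloud_stat, di, classification
    reference_mean: float
    reference_sd: float
    threshold: float          # reference_mean + 2 * reference_sd
    k_neighbors: object       # int or "all"

    @property
    def classification(self) -> pd.Series:
        return self.samples["classification"]


@dataclass
class AgreementResult:
    """Agreement between the distance-based and probability-based indices."""

    pearson_r: float
    p_value: float
    label_concordance: float  # fraction of samples with identical labels
    n: int


def multiplicative_replacement(proportions, delta=None) -> np.ndarray:
    """Replace zeros with ``delta`` and rescale nonzeros to keep row sums 1.

    ``delta`` may be a scalar or per-row vector; by default it is
    0.5 / (number of parts) per row, a conventional sub-detection value when
    depths are unknown.  Each row must lie on the simplex.  ``delta`` must
    stay below the smallest nonzero proportion of its row.
    """
    X = np.atleast_2d(np.asarray(proportions, dtype=float))
    if (X < 0).any():
        raise ValueError("proportions must be non-negative")
    rowsums = X.sum(axis=1)
    if (rowsums == 0).any():
        raise DegenerateInputError("all-zero row")
    if not np.allclose(rowsums, 1.0, atol=1e-8):
        raise ValueError("rows must sum to 1 (simplex)")
    if delta is None:
        delta = 0.5 / X.shape[1]
    d = np.broadcast_to(np.asarray(delta, dtype=float), (X.shape[0],)).copy()
    zeros = X == 0
    min_nonzero = np.where(X > 0, X, np.inf).min(axis=1)
    if (d >= min_nonzero).any():
        raise ValueError("delta must be smaller than the smallest nonzero proportion")
    nz_mass = 1.0 - zeros.sum(axis=1) * d
    out = np.where(zeros, d[:, None], X * nz_mass[:, None])
    return out


def clr_transform(positive_proportions) -> np.ndarray:
    """Centered log-ratio transform; every output row sums to zero."""
    X = np.atleast_2d(np.asarray(positive_proportions, dtype=float))
    if (X <= 0).any():
        raise ValueError("CLR requires strictly positive entries (replace zeros first)")
    logX = np.log(X)
    return logX - logX.mean(axis=1, keepdims=True)


def aitchison_distance(clr_matrix, ids=None) -> DistanceMatrix:
    """Euclidean distance between CLR rows (= Aitchison distance)."""
    X = np.atleast_2d(np.asarray(clr_matrix, dtype=float))
    ids = list(ids) if ids is not None else [str(i) for i in range(X.shape[0])]
    return DistanceMatrix(squareform(pdist(X, metric="euclidean")), ids=ids)


def table_to_clr(table: CountTable, delta=None) -> pd.DataFrame:
    """Counts → proportions → zero replacement → CLR (samples x taxa).

    The default replacement value is 0.5 / depth per sample (half a read at
    that sample's sequencing depth).
    """
    props = table.proportions().T.to_numpy()  # samples x taxa
    if delta is None:
        delta = 0.5 / table.depths().to_numpy(dtype=float)
    clr = clr_transform(multiplicative_replacement(props, delta))
    return pd.DataFrame(clr, index=table.sample_ids, columns=table.taxon_ids)


def cloud_statistic(query_clr: pd.DataFrame, reference_clr: pd.DataFrame, k="all") -> pd.Series:
    """Mean Aitchison distance from each query sample to the reference cloud.

    ``k`` selects the number of nearest reference neighbors averaged
    (``"all"`` uses every reference sample).  A query that is itself a
    reference sample (matched by index label) is excluded from its own
    reference set (leave-one-out).
    """
    ref_ids = list(reference_clr.index)
    n_ref = len(ref_ids)
    if n_ref < 3:
        raise ValueError("reference cloud needs at least 3 samples")
    usable_min = n_ref - 1  # leave-one-out reduces the pool for reference queries
    if k != "all":
        k = int(k)
        if k < 1 or k > usable_min:
            raise ValueError(f"k must be in [1, {usable_min}] (leave-one-out reference size)")
    D = cdist(query_clr.to_numpy(), reference_clr.to_numpy())
    stats = np.empty(D.shape[0])
    ref_pos = {rid: j for j, rid in enumerate(ref_ids)}
    for i, qid in enumerate(query_clr.index):
        row = D[i]
        j = ref_pos.get(qid)
        if j is not None:
            row = np.delete(row, j)
        if k == "all":
            stats[i] = row.mean()
        else:
            stats[i] = np.sort(row)[:k].mean()
    return pd.Series(stats, index=query_clr.index, name="cloud_stat")


def classify_dysbiosis(stats: pd.Series, reference_stats: pd.Series, k="all") -> CloudResult:
    """Apply the 2-SD rule to cloud statistics.

    ``reference_stats`` must be leave-one-out statistics of the reference
    samples.  Threshold = reference mean + 2 * sample SD (n−1 denominator);
    classification is strict: a statistic exactly at the threshold is
    healthy-like.  The dysbiosis index is ln(cloud_stat).
    """
    ref = np.asarray(reference_stats, dtype=float)
    mean, sd = float(ref.mean()), float(ref.std(ddof=1))
    if sd == 0:
        raise DegenerateInputError("reference cloud statistics are constant")
    threshold = mean + 2 * sd
    with np.errstate(divide="ignore"):
        di = np.log(stats.to_numpy(dtype=float))
    classification = np.where(stats.to_numpy() > threshold, "dysbiotic", "healthy-like")
    samples = pd.DataFrame(
        {"cloud_stat": stats, "di": di, "classification": classification}, index=stats.index
    )
    return CloudResult(samples, mean, sd, threshold, k)


def cloud_analysis(
    table: CountTable,
    metadata: pd.DataFrame,
    reference_group: str = "healthy",
    level: str | None = "genus",
    k="all",
    delta=None,
) -> CloudResult:
    """End-to-end dysbiosis scoring of a cohort against its healthy cloud.

    The CLR basis is computed jointly on all samples; reference statistics
    come from leave-one-out within the reference group.  ``level`` collapses
    the table to a taxonomic rank first (None = use taxa as provided).
    """
    if level is not None and table.taxonomy is not None:
        table = collapse_to_rank(table, level)
    clr = table_to_clr(table, delta=delta)
    meta = metadata.loc[clr.index]
    ref_ids = meta.index[meta["group"] == reference_group]
    if len(ref_ids) < 3:
        raise ValueError(f"reference group {reference_group!r} has fewer than 3 samples")
    reference_clr = clr.loc[ref_ids]
    stats = cloud_statistic(clr, reference_clr, k=k)
    return classify_dysbiosis(stats, stats.loc[ref_ids], k=k)


def orthogonal_validation(
    si: pd.Series,
    healthy_ids,
    seed=None,
    n_trees: int = 500,
    features: pd.DataFrame | None = None,
    eps: float = 1e-6,
) -> dict:
    """Validate the cloud classification via the symptom index.

    Healthy-group SI scores are logit-transformed (clipped to (eps, 1−eps));
    Shapiro–Wilk normality of the healthy logit scores is reported
    (descriptively — it never gates the analysis).  Samples whose logit(SI)
    exceeds the healthy mean + 2 SD are labelled dysbiotic, and a random
    forest refit on these labels (on ``features``, defaulting to logit(SI)
    itself) yields an out-of-bag probability-based index per sample.

    Returns a dict with ``labels`` (Series), ``probability_index`` (Series),
    ``normality_p``, ``threshold``.
    """
    si = pd.Series(si, dtype=float)
    healthy_ids = [h for h in healthy_ids if h in si.index]
    if len(healthy_ids) < 3:
        raise ValueError("need at least 3 healthy samples")
    z = logit(si.clip(eps, 1 - eps))
    hz = z.loc[healthy_ids]
    if np.ptp(hz.to_numpy()) == 0:
        raise DegenerateInputError("healthy SI scores are constant")
    normality_p = float(shapiro(hz).pvalue)
    threshold = float(hz.mean() + 2 * hz.std(ddof=1))
    labels = pd.Series(
        np.where(z > threshold, "dysbiotic", "healthy-like"), index=si.index, name="label"
    )
    X = features.loc[si.index].to_numpy() if features is not None else z.to_numpy()[:, None]
    if labels.nunique() < 2:
        logger.warning("orthogonal_validation: single-class labels; index set to 0")
        prob = pd.Series(0.0, index=si.index, name="probability_index")
        return {
            "labels": labels,
            "probability_index": prob,
            "normality_p": normality_p,
            "threshold": threshold,
        }
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=True,
        bootstrap=True,
        max_features="sqrt",
        random_state=np.random.default_rng(seed).integers(2**31) if seed is not None else 0,
    )
    rf.fit(X, labels.to_numpy())
    dys_col = list(rf.classes_).index("dysbiotic")
    oob = rf.oob_decision_function_[:, dys_col]
    oob = np.nan_to_num(oob, nan=0.5)  # samples never out-of-bag (rare at 500 trees)
    prob = pd.Series(oob, index=si.index, name="probability_index")
    return {
        "labels": labels,
        "probability_index": prob,
        "normality_p": normality_p,
        "threshold": threshold,
    }


def agreement_correlation(
    cloud_scores: pd.Series,
    probability_index: pd.Series,
    labels_a: pd.Series | None = None,
    labels_b: pd.Series | None = None,
) -> AgreementResult:
    """Pearson correlation between the two dysbiosis indices.

    If both label series are given, the per-sample label concordance
    (fraction of identical classifications) is reported as well.
    """
    x = pd.Series(cloud_scores, dtype=float)
    y = pd.Series(probability_index, dtype=float).reindex(x.index)
    if y.isna().any():
        raise ValueError("the two indices must cover the same samples")
    if np.ptp(x.to_numpy()) == 0 or np.ptp(y.to_numpy()) == 0:
        raise DegenerateInputError("constant index values")
    r, p = pearsonr(x, y)
    concordance = np.nan
    if labels_a is not None and labels_b is not None:
        la = pd.Series(labels_a).reindex(x.index)
        lb = pd.Series(labels_b).reindex(x.index)
        concordance = float((la == lb).mean())
    return AgreementResult(float(r), float(p), concordance, len(x))
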